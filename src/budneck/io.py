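"""Plain-CSV readers and writers for all pipeline tables.

Files are ordinary comma-separated tables with optional ``#``-prefixed header
comments (the simulation seed is always recorded there for provenance).
Round-tripping any generated cohort through its writer/reader is lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .coloc import RimProfile
from .flip import FlipTrace
from .segregation import AnaphaseTimeline, CircleCellObservation

__all__ = [
    "write_flip_traces", "read_flip_traces",
    "write_circle_observations", "read_circle_observations",
    "write_timelines", "read_timelines",
    "write_rim_profiles", "read_rim_profiles",
]


def _write(df: pd.DataFrame, path: str | Path, comments: dict | None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (comments or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def write_flip_traces(traces: Iterable[FlipTrace], path: str | Path, seed: int | None = None) -> None:
    rows = []
    for tr in traces:
        for frame, (t, y) in enumerate(zip(tr.times, tr.intensities)):
            rows.append({"cell_id": tr.cell_id, "role": tr.role, "frame": frame,
                         "time_s": t, "intensity": y})
    _write(pd.DataFrame(rows), path, {"seed": seed} if seed is not None else None)


def read_flip_traces(path: str | Path) -> list[FlipTrace]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    traces = []
    for (cid, role), g in df.groupby(["cell_id", "role"], sort=False):
        g = g.sort_values("frame")
        traces.append(FlipTrace(str(cid), str(role), g["time_s"].to_numpy(), g["intensity"].to_numpy()))
    return traces


def write_circle_observations(
    obs: Iterable[CircleCellObservation], path: str | Path, seed: int | None = None
) -> None:
    df = pd.DataFrame(
        [
            {"cell_id": o.cell_id, "circle_count": o.circle_count,
             "circles_in_mother": o.circles_in_mother, "experiment_id": o.experiment_id}
            for o in obs
        ]
    )
    _write(df, path, {"seed": seed} if seed is not None else None)


def read_circle_observations(path: str | Path) -> list[CircleCellObservation]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return [
        CircleCellObservation(str(r.cell_id), int(r.circle_count),
                              int(r.circles_in_mother), str(r.experiment_id))
        for r in df.itertuples()
    ]


def write_timelines(timelines: Iterable[AnaphaseTimeline], path: str | Path, seed: int | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "cell_id": t.cell_id,
                "t_entry_min": t.t_entry,
                "t_dumbbell_min": t.t_dumbbell,
                "t_karyo_min": t.t_karyo,
                "passage_times_min": ";".join(repr(p) for p in t.passage_times),
                "experiment_id": t.experiment_id,
            }
            for t in timelines
        ]
    )
    _write(df, path, {"seed": seed} if seed is not None else None)


def read_timelines(path: str | Path) -> list[AnaphaseTimeline]:
    df = pd.read_csv(path, comment="#", keep_default_na=False, float_precision="round_trip")
    out = []
    for r in df.itertuples():
        raw = str(r.passage_times_min)
        passages = [float(x) for x in raw.split(";") if x]
        out.append(
            AnaphaseTimeline(
                cell_id=str(r.cell_id),
                t_dumbbell=float(r.t_dumbbell_min),
                t_karyo=float(r.t_karyo_min),
                passage_times=passages,
                experiment_id=str(r.experiment_id),
            )
        )
    return out


def write_rim_profiles(profiles: Iterable[RimProfile], path: str | Path, seed: int | None = None) -> None:
    rows = []
    for p in profiles:
        for i in range(p.n_positions):
            rows.append({"cell_id": p.cell_id, "position_index": i,
                         "gfp": p.gfp[i], "mcherry": p.mcherry[i]})
    _write(pd.DataFrame(rows), path, {"seed": seed} if seed is not None else None)


def read_rim_profiles(path: str | Path, circular: bool = True) -> list[RimProfile]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    out = []
    for cid, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("position_index")
        out.append(RimProfile(str(cid), g["gfp"].to_numpy(), g["mcherry"].to_numpy(), circular=circular))
    return out
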