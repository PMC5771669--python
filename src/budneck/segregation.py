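"""DNA-circle segregation statistics: propagation frequency, stage durations, flux.

Non-centromeric DNA circles (model circles and endogenous extrachromosomal
rDNA circles) are retained in the yeast mother cell during mitosis. The
propagation frequency measures how often individual circles nonetheless end
up in the bud. Anaphase cells carrying 1, 2 or 4 circles are scored for
circles retained in the mother; with n_i cells of class i and p_i the
per-circle retention fraction within class i, the propagation frequency is

    1 - (1*n1*p1 + 2*n2*p2 + 4*n4*p4) / (1*n1 + 2*n2 + 4*n4),

i.e. the circle-weighted fraction of circles that reached the bud.

Time-lapse movies additionally resolve *when* circles pass the bud neck:
early anaphase (nuclear entry into the bud until the dumbbell-shaped nucleus
forms) versus late anaphase (dumbbell until karyokinesis). The passage flux
per stage is the number of first appearances of a circle in the daughter
compartment divided by the summed stage duration over all cells (events per
cell-minute).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CircleCellObservation",
    "PropagationEstimate",
    "AnaphaseTimeline",
    "StageFlux",
    "propagation_frequency",
    "stage_durations",
    "propagation_flux",
    "propagation_summary",
]

CIRCLE_CLASSES = (1, 2, 4)


@dataclass
class CircleCellObservation:
    """One anaphase cell scored for circles in mother vs bud."""

    cell_id: str
    circle_count: int
    circles_in_mother: int
    experiment_id: str = "exp1"

    def __post_init__(self) -> None:
        if self.circle_count not in CIRCLE_CLASSES:
            raise ValueError(f"circle_count must be one of {CIRCLE_CLASSES}")
        if not 0 <= self.circles_in_mother <= self.circle_count:
            raise ValueError("circles_in_mother must lie in [0, circle_count]")


@dataclass
class PropagationEstimate:
    """Pooled circle-propagation frequency plus per-experiment replicates."""

    frequency: float  # pooled over all cells
    per_experiment: dict[str, float]
    mean: float  # mean over experiments
    sem: float  # SEM over experiments (nan with a single experiment)
    n_cells: int


@dataclass
class AnaphaseTimeline:
    """Event times of one cell's anaphase, minutes from nuclear entry (t=0)."""

    cell_id: str
    t_dumbbell: float
    t_karyo: float
    passage_times: list[float] = field(default_factory=list)
    experiment_id: str = "exp1"
    t_entry: float = 0.0

    def __post_init__(self) -> None:
        if not self.t_entry == 0.0:
            raise ValueError("t_entry is 0 by convention")
        if not 0.0 < self.t_dumbbell < self.t_karyo:
            raise ValueError("event times must satisfy 0 < t_dumbbell < t_karyo")
        for t in self.passage_times:
            if not 0.0 <= t <= self.t_karyo:
                raise ValueError("passage times must lie within [0, t_karyo]")

    @property
    def early_duration(self) -> float:
        return self.t_dumbbell - self.t_entry

    @property
    def late_duration(self) -> float:
        return self.t_karyo - self.t_dumbbell


@dataclass
class StageFlux:
    """Circle passages per minute within one anaphase stage."""

    stage: str  # "early" or "late"
    n_events: int
    observed_minutes: float
    flux: float  # n_events / observed_minutes
    sd: float = float("nan")  # across experiments, when >1 experiment


def _class_sums(obs: Sequence[CircleCellObservation]) -> tuple[float, float]:
    """Return (weighted retained, weighted total) = (Σ i·nᵢ·pᵢ, Σ i·nᵢ)."""
    retained_sum = 0.0
    total_sum = 0.0
    for i in CIRCLE_CLASSES:
        cells = [o for o in obs if o.circle_count == i]
        n_i = len(cells)
        if n_i == 0:
            continue  # empty class contributes 0 to both sums
        p_i = sum(o.circles_in_mother for o in cells) / (i * n_i)
        retained_sum += i * n_i * p_i
        total_sum += i * n_i
    return retained_sum, total_sum


def propagation_frequency(obs: Iterable[CircleCellObservation]) -> PropagationEstimate:
    """Circle-weighted frequency of propagation to the bud.

    p_i is the per-circle retention fraction within class i (circles retained
    in mothers of class-i cells over i*n_i circles); the statistic then equals
    the fraction of all circles, weighted by class size, that reached the bud.
    Replicate experiments (``experiment_id``) additionally yield a mean ± SEM
    across experiments.
    """
    obs = list(obs)
    if not obs:
        raise ValueError("no observations")
    retained, total = _class_sums(obs)
    pooled = 1.0 - retained / total

    per_exp: dict[str, float] = {}
    for exp in sorted({o.experiment_id for o in obs}):
        r, t = _class_sums([o for o in obs if o.experiment_id == exp])
        per_exp[exp] = 1.0 - r / t
    freqs = np.array(list(per_exp.values()))
    sem = float(freqs.std(ddof=1) / np.sqrt(freqs.size)) if freqs.size > 1 else float("nan")
    return PropagationEstimate(
        frequency=pooled,
        per_experiment=per_exp,
        mean=float(freqs.mean()),
        sem=sem,
        n_cells=len(obs),
    )


def _valid_timelines(timelines: Iterable[AnaphaseTimeline]) -> list[AnaphaseTimeline]:
    ok = []
    for tl in timelines:
        if not 0.0 < tl.t_dumbbell < tl.t_karyo:
            warnings.warn(f"rejecting cell {tl.cell_id}: non-monotone event times", stacklevel=3)
            continue
        ok.append(tl)
    if not ok:
        raise ValueError("no valid timelines")
    return ok


def stage_durations(timelines: Iterable[AnaphaseTimeline]) -> pd.DataFrame:
    """Mean ± SEM of early, late and total anaphase duration (minutes).

    Returns a tidy frame with one row per (experiment, stage) plus pooled
    rows (experiment_id = "pooled"). SEM is over cells within the grouping.
    """
    tls = _valid_timelines(timelines)
    rows = []
    df = pd.DataFrame(
        {
            "experiment_id": [t.experiment_id for t in tls],
            "early": [t.early_duration for t in tls],
            "late": [t.late_duration for t in tls],
            "total": [t.t_karyo for t in tls],
        }
    )
    groups = [("pooled", df)] + [(e, g) for e, g in df.groupby("experiment_id")]
    for name, g in groups:
        for stage in ("early", "late", "total"):
            vals = g[stage].to_numpy()
            sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            rows.append(
                {
                    "experiment_id": name,
                    "stage": stage,
                    "mean_min": vals.mean(),
                    "sem_min": float(sem),
                    "n_cells": vals.size,
                }
            )
    return pd.DataFrame(rows)


def propagation_flux(timelines: Iterable[AnaphaseTimeline]) -> tuple[StageFlux, StageFlux]:
    """Stage-resolved circle passage flux (first appearances per cell-minute).

    An event at time t is attributed to early anaphase when t <= t_dumbbell
    (events are recorded at the first frame the circle is seen in the
    daughter, so a boundary-frame event belongs to the early window) and to
    late anaphase otherwise. The denominator is the summed stage duration
    over all cells. When several experiments are present, the SD of
    per-experiment fluxes is reported alongside.
    """
    tls = _valid_timelines(timelines)

    def stage_stats(subset: Sequence[AnaphaseTimeline]) -> tuple[tuple[int, float], tuple[int, float]]:
        e_events = sum(1 for t in subset for p in t.passage_times if p <= t.t_dumbbell)
        l_events = sum(1 for t in subset for p in t.passage_times if p > t.t_dumbbell)
        e_min = sum(t.early_duration for t in subset)
        l_min = sum(t.late_duration for t in subset)
        return (e_events, e_min), (l_events, l_min)

    (e_events, e_min), (l_events, l_min) = stage_stats(tls)
    if e_min <= 0 or l_min <= 0:
        raise ValueError("zero observed minutes in a stage; flux undefined")

    exps = sorted({t.experiment_id for t in tls})
    e_sd = l_sd = float("nan")
    if len(exps) > 1:
        per_e, per_l = [], []
        for exp in exps:
            (ee, em), (le, lm) = stage_stats([t for t in tls if t.experiment_id == exp])
            if em > 0:
                per_e.append(ee / em)
            if lm > 0:
                per_l.append(le / lm)
        e_sd = float(np.std(per_e, ddof=1)) if len(per_e) > 1 else float("nan")
        l_sd = float(np.std(per_l, ddof=1)) if len(per_l) > 1 else float("nan")

    return (
        StageFlux("early", e_events, e_min, e_events / e_min, e_sd),
        StageFlux("late", l_events, l_min, l_events / l_min, l_sd),
    )


def propagation_summary(estimates: Mapping[str, float]) -> pd.DataFrame:
    """Pairwise fold changes between condition-level estimates.

    ``estimates`` maps condition name to a frequency or flux. Returns a tidy
    frame (condition_a, condition_b, value_a, value_b, ratio); a zero
    denominator yields a NaN ratio (undefined), not an error.
    """
    if not estimates:
        raise ValueError("need at least one condition")
    rows = []
    for a, va in estimates.items():
        for b, vb in estimates.items():
            if a == b:
                continue
            ratio = va / vb if vb != 0 else float("nan")
            rows.append({"condition_a": a, "condition_b": b, "value_a": va, "value_b": vb, "ratio": ratio})
    if not rows:  # single condition: report it alone
        (a, va), = estimates.items()
        rows.append({"condition_a": a, "condition_b": a, "value_a": va, "value_b": va, "ratio": 1.0})
    return pd.DataFrame(rows)
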