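"""DNA-circle / nuclear-pore colocalization from rim intensity profiles.

DNA circles anchor to nuclear pore complexes (NPCs); their confinement by the
bud-neck diffusion barrier requires that anchorage. The assay records, for
each anaphase nucleus carrying a single labeled circle, a two-channel
intensity profile along the nuclear rim (NPC marker in GFP, circle marker in
mCherry). Per cell, the profile is aligned to the brightest mCherry pixel
(the circle); the aligned GFP traces are averaged per offset, reported only
at offsets supported by more than 10 cells, and the enrichment at the circle
is expressed as a fold change over the rim-wide mean GFP intensity
(normalized to 1). An intact circle-NPC association shows a GFP peak at
offset 0; detachment flattens it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = ["RimProfile", "AlignedProfile", "ColocResult", "align_profiles", "circle_fold_change"]

logger = logging.getLogger(__name__)

MIN_CELLS_PER_OFFSET = 10  # offsets reported only where n_cells > 10, strictly


@dataclass
class RimProfile:
    """Two-channel intensity trace along one nuclear rim (SPB region excluded)."""

    cell_id: str
    gfp: np.ndarray
    mcherry: np.ndarray
    circular: bool = True
    spb_index: int | None = None  # optional, enables the proximity filter

    def __post_init__(self) -> None:
        self.gfp = np.asarray(self.gfp, dtype=float)
        self.mcherry = np.asarray(self.mcherry, dtype=float)
        if self.gfp.size != self.mcherry.size:
            raise ValueError("GFP and mCherry channels must have equal length")
        if self.gfp.size < 21:
            raise ValueError("rim profiles need at least 21 positions")

    @property
    def n_positions(self) -> int:
        return self.gfp.size


@dataclass
class AlignedProfile:
    """Mean GFP per offset relative to the circle (offset 0 = mCherry peak)."""

    offsets: np.ndarray  # integer positions relative to the circle
    mean_gfp: np.ndarray
    sem_gfp: np.ndarray
    n_cells: np.ndarray

    def at_offset(self, offset: int) -> float:
        idx = np.nonzero(self.offsets == offset)[0]
        if idx.size == 0:
            raise KeyError(f"offset {offset} not present (masked or out of range)")
        return float(self.mean_gfp[idx[0]])


@dataclass
class ColocResult:
    """Rim-normalized GFP enrichment at the circle position."""

    fold_at_circle: float
    rim_mean_normalized: float = 1.0
    n_cells: int = 0


def _circle_index(profile: RimProfile, background: float) -> int | None:
    """Index of the brightest mCherry pixel; None rejects an all-background cell."""
    mch = profile.mcherry - background
    if mch.max() <= 0:
        logger.warning("cell %s rejected: mCherry at background everywhere", profile.cell_id)
        return None
    peak = int(np.argmax(mch))  # ties: first occurrence in scan order
    if np.count_nonzero(mch == mch.max()) > 1:
        logger.info("cell %s: non-unique mCherry maximum, using first occurrence", profile.cell_id)
    return peak


def align_profiles(
    profiles: Iterable[RimProfile],
    background: float = 0.0,
    exclude_near_spb: int | None = None,
) -> AlignedProfile:
    """Align background-subtracted GFP traces to each cell's circle position.

    Circular profiles wrap (offsets -n//2 .. (n-1)//2); linear profiles
    contribute only the offsets they cover. Offsets supported by 10 or fewer
    cells are masked out entirely. ``exclude_near_spb`` drops cells whose
    circle lies within that many positions of the recorded SPB index.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to align")
    if background < 0:
        raise ValueError("background must be non-negative")

    sums: dict[int, list[float]] = {}
    kept = 0
    for prof in profiles:
        peak = _circle_index(prof, background)
        if peak is None:
            continue
        if exclude_near_spb is not None and prof.spb_index is not None:
            d = abs(peak - prof.spb_index)
            if prof.circular:
                d = min(d, prof.n_positions - d)
            if d <= exclude_near_spb:
                logger.info("cell %s excluded: circle within %d positions of SPB", prof.cell_id, d)
                continue
        kept += 1
        gfp = prof.gfp - background
        n = prof.n_positions
        for idx in range(n):
            off = idx - peak
            if prof.circular:
                off = (off + n // 2) % n - n // 2  # wrap into [-n//2, (n-1)//2)
            sums.setdefault(off, []).append(gfp[idx])

    offsets, means, sems, counts = [], [], [], []
    for off in sorted(sums):
        vals = np.asarray(sums[off])
        if vals.size <= MIN_CELLS_PER_OFFSET:  # strict n > 10
            continue
        offsets.append(off)
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0)
        counts.append(vals.size)
    return AlignedProfile(
        offsets=np.asarray(offsets, dtype=int),
        mean_gfp=np.asarray(means),
        sem_gfp=np.asarray(sems),
        n_cells=np.asarray(counts, dtype=int),
    )


def circle_fold_change(
    aligned: AlignedProfile,
    profiles: Iterable[RimProfile],
    background: float = 0.0,
) -> ColocResult:
    """GFP enrichment at the circle relative to the rim-wide mean (set to 1).

    The denominator is the mean background-subtracted GFP over all positions
    of all cells; the numerator is the aligned mean GFP at offset 0 on the
    same scale. A non-positive rim mean aborts.
    """
    profiles = list(profiles)
    if aligned.offsets.size == 0 or 0 not in aligned.offsets:
        raise ValueError("offset 0 missing from the aligned profile (too few cells?)")
    rim = np.concatenate([p.gfp - background for p in profiles])
    rim_mean = float(rim.mean())
    if rim_mean <= 0:
        raise ValueError("rim-wide mean GFP is non-positive; check the background")
    n_at_zero = int(aligned.n_cells[np.nonzero(aligned.offsets == 0)[0][0]])
    return ColocResult(
        fold_at_circle=aligned.at_offset(0) / rim_mean,
        rim_mean_normalized=1.0,
        n_cells=n_at_zero,
    )
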