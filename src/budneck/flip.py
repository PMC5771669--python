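"""Barrier-index analysis of fluorescence loss in photobleaching (FLIP) traces.

In a FLIP experiment a small region of the mother part of a dividing nucleus
is bleached at every acquisition frame while fluorescence is monitored in the
mother and bud compartments and in neighbouring, unbleached control cells.
After background subtraction, mother and bud traces are corrected for
acquisition photobleaching by dividing by the frame-wise mean of the controls,
rescaled to start at 100%, pooled across cells, and fit to a one-phase decay

    Y(t) = P + (100 - P) * exp(-K * t)

with the initial value constrained to 100. The time for a compartment to lose
25% of its signal, t75 = (1/K) * ln((100 - P) / (75 - P)), is computed for
each compartment, and the Barrier Index is the ratio

    BI = t75(bud) / t75(mother).

A tight bud-neck diffusion barrier slows fluorescence loss in the unbleached
bud, giving a high BI; a leaky barrier gives a BI near 1. When the bud's
plateau never falls below the threshold the BI is censored ("n.d.").
Standard errors propagate from the fit covariance by the delta method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FlipTrace",
    "NormalizedDecay",
    "DecayFit",
    "BarrierIndex",
    "normalize_traces",
    "pool_profiles",
    "fit_one_phase_decay",
    "time_to_fraction",
    "barrier_index",
    "cross_run_normalize",
    "analyze_flip_cohort",
]

ROLES = ("mother", "bud", "control")


@dataclass
class FlipTrace:
    """Per-frame integrated fluorescence of one region (mother, bud, control)."""

    cell_id: str
    role: str
    times: np.ndarray  # seconds, strictly increasing, ~equally spaced
    intensities: np.ndarray  # a.u.

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.times.size < 10:
            raise ValueError("a FLIP trace needs at least 10 frames")
        if self.times.size != self.intensities.size:
            raise ValueError("times and intensities differ in length")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(dt) > 0.01 * dt.mean():
            raise ValueError("frames must be equally spaced within 1%")


@dataclass
class NormalizedDecay:
    """Control-corrected trace rescaled so the first frame is exactly 100%."""

    times: np.ndarray
    percent: np.ndarray
    n_cells: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.percent = np.asarray(self.percent, dtype=float)
        if not np.isfinite(self.percent).all():
            raise ValueError("normalized decay contains non-finite values")
        if self.percent[0] != 100.0:
            raise ValueError("normalized decay must start at exactly 100")


@dataclass
class DecayFit:
    """One-phase decay fit with Y0 fixed at 100: Y(t) = P + (100-P)e^(-Kt)."""

    plateau: float
    k: float  # per second, >= 0
    se_plateau: float
    se_k: float
    cov_pk: float
    rss: float
    n_points: int
    y0: float = 100.0
    converged: bool = True

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.plateau + (self.y0 - self.plateau) * np.exp(-self.k * np.asarray(t, dtype=float))


@dataclass
class BarrierIndex:
    """t75(bud)/t75(mother) with delta-method standard error."""

    value: float
    se: float
    censored: bool
    t75_mother: float
    t75_bud: float
    se_t75_mother: float = float("nan")
    se_t75_bud: float = float("nan")

    def __str__(self) -> str:  # censored BIs are reported as "n.d.", not inf
        if self.censored:
            return "BI = n.d. (bud plateau above threshold)"
        return f"BI = {self.value:.3g} ± {self.se:.2g}"


def _common_grid(traces: Sequence[FlipTrace]) -> np.ndarray:
    grid = traces[0].times
    for tr in traces[1:]:
        if tr.times.size != grid.size or not np.allclose(tr.times, grid, rtol=0, atol=1e-9 + 1e-6 * grid[-1]):
            raise ValueError(f"trace {tr.cell_id!r} is not on the shared time grid")
    return grid


def normalize_traces(
    mother: FlipTrace,
    bud: FlipTrace,
    controls: Iterable[FlipTrace],
    background: float = 0.0,
) -> tuple[NormalizedDecay, NormalizedDecay]:
    """Background-subtract, control-correct, and rescale mother/bud to 100%.

    Every trace has ``background`` subtracted; mother and bud are then divided
    frame-wise by the mean of the control traces (correcting fluorescence loss
    due to exposure alone) and rescaled so their first frame equals 100.

    Raises ``ValueError`` when the control mean is non-positive at any frame
    (degenerate background) or the traces do not share one time grid.
    """
    controls = list(controls)
    if not controls:
        raise ValueError("at least one control trace is required")
    grid = _common_grid([mother, bud, *controls])

    ctrl = np.mean([c.intensities for c in controls], axis=0) - background
    if np.any(ctrl <= 0):
        bad = int(np.argmax(ctrl <= 0))
        raise ValueError(
            f"control mean non-positive at frame {bad} after background "
            f"subtraction ({ctrl[bad]:.3g} a.u.); check the background estimate"
        )

    out = []
    for tr in (mother, bud):
        corrected = (tr.intensities - background) / ctrl
        if corrected[0] <= 0:
            raise ValueError(f"{tr.role} trace non-positive at first frame after correction")
        percent = 100.0 * corrected / corrected[0]
        percent[0] = 100.0  # exact by construction; guard float rounding
        out.append(NormalizedDecay(times=grid, percent=percent))
    return out[0], out[1]


def pool_profiles(decays: Sequence[NormalizedDecay]) -> NormalizedDecay:
    """Frame-wise mean of single-cell profiles (one pooled profile per cohort)."""
    decays = list(decays)
    if not decays:
        raise ValueError("cannot pool an empty collection of profiles")
    grid = decays[0].times
    for d in decays[1:]:
        if d.percent.size != grid.size or not np.allclose(d.times, grid):
            raise ValueError("profiles must share one time grid to be pooled")
    mean = np.mean([d.percent for d in decays], axis=0)
    mean[0] = 100.0  # exact by construction; guard float summation
    return NormalizedDecay(times=grid, percent=mean, n_cells=sum(d.n_cells for d in decays))


def _model(t: np.ndarray, plateau: float, k: float) -> np.ndarray:
    return plateau + (100.0 - plateau) * np.exp(-k * t)


def fit_one_phase_decay(decay: NormalizedDecay) -> DecayFit:
    """Least-squares one-phase-decay fit with Y0 constrained to 100%.

    K is constrained non-negative and the plateau below 100. Non-convergence
    or an unidentifiable fit (e.g. a flat trace, where plateau and K trade
    off) is returned flagged via ``converged=False``, never silently.
    """
    t, y = decay.times, decay.percent
    if t.size < 10:
        raise ValueError("need at least 10 points to fit")

    y_end = float(np.median(y[-max(3, t.size // 10):]))
    p0_plateau = min(y_end, 99.0)
    # crude K guess from the half-way crossing of the initial span
    half = (100.0 + p0_plateau) / 2.0
    below = np.nonzero(y <= half)[0]
    p0_k = math.log(2.0) / t[below[0]] if below.size and t[below[0]] > 0 else 1.0 / max(t[-1], 1.0)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _model, t, y,
                p0=[p0_plateau, p0_k],
                bounds=([-np.inf, 0.0], [100.0, np.inf]),
                maxfev=20000,
            )
        ok = np.all(np.isfinite(pcov))
    except (RuntimeError, ValueError):
        popt = np.array([p0_plateau, 0.0])
        pcov = np.full((2, 2), np.nan)
        ok = False

    resid = y - _model(t, *popt)
    return DecayFit(
        plateau=float(popt[0]),
        k=float(popt[1]),
        se_plateau=float(np.sqrt(pcov[0, 0])) if ok else float("nan"),
        se_k=float(np.sqrt(pcov[1, 1])) if ok else float("nan"),
        cov_pk=float(pcov[0, 1]) if ok else float("nan"),
        rss=float(resid @ resid),
        n_points=int(t.size),
        converged=bool(ok),
    )


def time_to_fraction(fit: DecayFit, threshold: float = 75.0) -> tuple[float, float, bool]:
    """Time for the fitted curve to reach ``threshold`` percent of initial.

    Closed form t = (1/K) ln((100-P)/(thr-P)); censored (returns nan) when the
    plateau sits at or above the threshold or K = 0, i.e. the curve never
    reaches it. The standard error comes from the delta method with
    dt/dK = -t/K and dt/dP = (1/K)(100-thr)/((100-P)(thr-P)), including the
    plateau-K covariance when the fit provides it.
    """
    if not (0.0 < threshold < 100.0):
        raise ValueError("threshold must be in (0, 100) percent")
    p, k = fit.plateau, fit.k
    if p >= threshold or k <= 0.0:
        return float("nan"), float("nan"), True

    t = (1.0 / k) * math.log((100.0 - p) / (threshold - p))
    dt_dk = -t / k
    dt_dp = (1.0 / k) * (100.0 - threshold) / ((100.0 - p) * (threshold - p))
    cov = fit.cov_pk if math.isfinite(fit.cov_pk) else 0.0
    var = (
        dt_dk**2 * fit.se_k**2
        + dt_dp**2 * fit.se_plateau**2
        + 2.0 * dt_dk * dt_dp * cov
    )
    se = math.sqrt(var) if math.isfinite(var) and var >= 0 else float("nan")
    return t, se, False


def barrier_index(fit_mother: DecayFit, fit_bud: DecayFit, threshold: float = 75.0) -> BarrierIndex:
    """BI = t75(bud) / t75(mother), censored when the bud never reaches 75%.

    The bleached mother compartment must decay past the threshold; a censored
    mother is an error, while a censored bud yields a censored (n.d.) BI.
    SE by relative-error propagation over the ratio of two independent fits.
    """
    tm, se_tm, cens_m = time_to_fraction(fit_mother, threshold)
    tb, se_tb, cens_b = time_to_fraction(fit_bud, threshold)
    if cens_m:
        raise ValueError("mother (bleached) compartment never reaches the threshold; no BI defined")
    if cens_b:
        return BarrierIndex(
            value=float("nan"), se=float("nan"), censored=True,
            t75_mother=tm, t75_bud=float("nan"),
            se_t75_mother=se_tm,
        )
    bi = tb / tm
    rel = math.sqrt((se_tb / tb) ** 2 + (se_tm / tm) ** 2) if tb > 0 and tm > 0 else float("nan")
    return BarrierIndex(
        value=bi, se=bi * rel, censored=False,
        t75_mother=tm, t75_bud=tb,
        se_t75_mother=se_tm, se_t75_bud=se_tb,
    )


def cross_run_normalize(
    bi_target: BarrierIndex,
    bi_reference_same_run: BarrierIndex,
    bi_reference_baseline: BarrierIndex,
) -> BarrierIndex:
    """Rescale a BI measured on one microscope onto a baseline instrument's scale.

    value = target * baseline_reference / same_run_reference, with the SE
    propagated over the triple ratio. Used when a condition is acquired on a
    different instrument than the bulk of the dataset, with a shared reference
    strain imaged on both.
    """
    for bi in (bi_target, bi_reference_same_run, bi_reference_baseline):
        if bi.censored:
            raise ValueError("cannot cross-run normalize with a censored BI")
        if bi.value == 0:
            raise ValueError("cannot normalize against a zero BI")
    value = bi_target.value * bi_reference_baseline.value / bi_reference_same_run.value
    rel = math.sqrt(
        (bi_target.se / bi_target.value) ** 2
        + (bi_reference_baseline.se / bi_reference_baseline.value) ** 2
        + (bi_reference_same_run.se / bi_reference_same_run.value) ** 2
    )
    return BarrierIndex(
        value=value, se=abs(value) * rel, censored=False,
        t75_mother=bi_target.t75_mother, t75_bud=bi_target.t75_bud,
        se_t75_mother=bi_target.se_t75_mother, se_t75_bud=bi_target.se_t75_bud,
    )


def analyze_flip_cohort(
    traces: Iterable[FlipTrace],
    background: float = 0.0,
    threshold: float = 75.0,
) -> dict:
    """Full FLIP pipeline on one cohort: normalize, pool, fit, Barrier Index.

    ``traces`` holds mother/bud pairs (matched by cell_id) plus shared control
    traces. The default follows the pooled-profile protocol: single-cell
    normalized profiles are averaged per compartment and each pooled profile
    is fit once. Returns a dict with the pooled decays, both fits, and the BI.
    """
    traces = list(traces)
    controls = [t for t in traces if t.role == "control"]
    mothers = {t.cell_id: t for t in traces if t.role == "mother"}
    buds = {t.cell_id: t for t in traces if t.role == "bud"}
    cells = sorted(set(mothers) & set(buds))
    if not cells:
        raise ValueError("no mother/bud pairs found in the cohort")

    m_decays, b_decays = [], []
    for cid in cells:
        m, b = normalize_traces(mothers[cid], buds[cid], controls, background)
        m_decays.append(m)
        b_decays.append(b)

    pooled_m = pool_profiles(m_decays)
    pooled_b = pool_profiles(b_decays)
    fit_m = fit_one_phase_decay(pooled_m)
    fit_b = fit_one_phase_decay(pooled_b)
    bi = barrier_index(fit_m, fit_b, threshold)
    return {
        "n_cells": len(cells),
        "pooled_mother": pooled_m,
        "pooled_bud": pooled_b,
        "fit_mother": fit_m,
        "fit_bud": fit_b,
        "barrier_index": bi,
    }
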