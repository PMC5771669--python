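"""Synthetic cohorts with the statistical structure the analyses assume.

Every downstream stage of the pipeline (FLIP barrier index, circle
segregation, stage-resolved passage flux, NPC colocalization) is testable
against cohorts generated here, without any microscopy data. The generators
emulate already-extracted tabular quantities, not images:

* two-compartment fluorescence exchange across the bud neck under a bleach
  pulse at every frame, with global acquisition photobleaching and additive
  observation noise (:func:`gen_flip_traces`);
* anaphase cells carrying 1, 2 or 4 DNA circles, each circle independently
  ending in the bud (:func:`gen_circle_observations`);
* per-cell anaphase timelines with stage-specific per-circle passage hazards
  (:func:`gen_timelines`);
* closed nuclear-rim intensity profiles with NPC punctae and a DNA circle
  either attached to a punctum or sitting between punctae
  (:func:`gen_rim_profiles`).

Latent dynamics are noise-free and deterministic given the seed; noise is
applied to reported values only, so exact recurrence oracles remain available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .flip import FlipTrace
from .segregation import AnaphaseTimeline, CircleCellObservation
from .coloc import RimProfile

__all__ = [
    "FlipSimConfig",
    "SegregationSimConfig",
    "TimelineSimConfig",
    "RimSimConfig",
    "gen_flip_traces",
    "flip_latent_trajectory",
    "gen_circle_observations",
    "gen_timelines",
    "gen_rim_profiles",
]

_INITIAL_SIGNAL = 1000.0  # a.u. latent signal per compartment before background


@dataclass
class FlipSimConfig:
    """Parameters of the two-compartment FLIP simulation.

    The per-frame update applies, in order: the bleach pulse (a fraction
    ``bleach_fraction`` of the mother's latent signal removed), exchange of a
    fraction ``exchange_rate`` of the inter-compartment signal difference
    across the bud neck, then global acquisition photobleaching
    ``acquisition_decay`` on every cell including controls. ``volume_ratio``
    (mother/bud) shifts the exchange equilibrium; 1 means symmetric
    compartments.
    """

    n_cells: int = 20
    frame_interval: float = 4.0  # seconds; acquisitions run at 3-5 s spacing
    n_frames: int = 70  # ~4-5 min movies
    bleach_fraction: float = 0.05
    exchange_rate: float = 0.01
    acquisition_decay: float = 0.002
    noise_sd: float = 5.0
    background: float = 50.0
    n_controls: int = 4
    volume_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_frames < 10:
            raise ValueError("need at least 1 cell and 10 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for name in ("bleach_fraction", "acquisition_decay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.exchange_rate <= 0.5:
            # above 0.5 the linear update overshoots the equilibration point
            raise ValueError("exchange_rate must lie in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 3 <= self.n_controls <= 5:
            raise ValueError("n_controls must be in 3..5")
        if self.volume_ratio <= 0:
            raise ValueError("volume_ratio must be positive")


def flip_latent_trajectory(config: FlipSimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free latent (mother, bud, control) signals over the movie.

    Per frame t -> t+1 with b = bleach_fraction, x = exchange_rate,
    a = acquisition_decay, rho = volume_ratio:

        flux = x * (B - M / rho)          # toward equal concentration
        M'   = (1 - a) * ((1 - b) * M + flux)
        B'   = (1 - a) * (B - flux)
        C'   = (1 - a) * C

    At rho = 1 the flux is x*(B - M), and total latent signal M + B is
    conserved whenever a = b = 0 (exchange only redistributes).
    """
    b, x, a = config.bleach_fraction, config.exchange_rate, config.acquisition_decay
    rho = config.volume_ratio
    m = np.empty(config.n_frames)
    bud = np.empty(config.n_frames)
    ctrl = np.empty(config.n_frames)
    m[0] = bud[0] = ctrl[0] = _INITIAL_SIGNAL
    for t in range(config.n_frames - 1):
        flux = x * (bud[t] - m[t] / rho)
        m[t + 1] = (1.0 - a) * ((1.0 - b) * m[t] + flux)
        bud[t + 1] = (1.0 - a) * (bud[t] - flux)
        ctrl[t + 1] = (1.0 - a) * ctrl[t]
    return m, bud, ctrl


def gen_flip_traces(config: FlipSimConfig) -> list[FlipTrace]:
    """Simulate a FLIP cohort: mother+bud traces per dividing cell, shared controls.

    All dividing cells follow the same latent dynamics; cells differ only in
    observation noise, mirroring pooled single-cell profiles. Reported value =
    latent + background + N(0, noise_sd). Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    times = np.arange(config.n_frames) * config.frame_interval
    m, bud, ctrl = flip_latent_trajectory(config)

    def observe(latent: np.ndarray) -> np.ndarray:
        noise = rng.normal(0.0, config.noise_sd, latent.size) if config.noise_sd > 0 else 0.0
        return latent + config.background + noise

    traces: list[FlipTrace] = []
    for i in range(config.n_cells):
        traces.append(FlipTrace(f"cell{i:03d}", "mother", times, observe(m)))
        traces.append(FlipTrace(f"cell{i:03d}", "bud", times, observe(bud)))
    for j in range(config.n_controls):
        traces.append(FlipTrace(f"ctrl{j:02d}", "control", times, observe(ctrl)))
    return traces


@dataclass
class SegregationSimConfig:
    """Cohort of anaphase cells carrying 1, 2 or 4 model DNA circles.

    ``class_mix`` gives the proportions of 1-, 2- and 4-circle cells;
    ``p_pass`` is the per-circle probability of ending in the bud.
    """

    n_cells: int = 300
    class_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)
    p_pass: float = 0.04
    n_experiments: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.size == 0:
            raise ValueError("class_mix must not be empty")
        if mix.size != 3 or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("class_mix must be 3 non-negative proportions summing to 1")
        if not 0.0 <= self.p_pass <= 1.0:
            raise ValueError("p_pass must lie in [0, 1]")
        if self.n_cells < 1 or self.n_experiments < 1:
            raise ValueError("need at least one cell and one experiment")


def gen_circle_observations(config: SegregationSimConfig) -> list[CircleCellObservation]:
    """Each cell draws its circle count from the mix; each circle lands in the
    bud independently with probability ``p_pass``. Cells are assigned to
    ``n_experiments`` replicates round-robin."""
    rng = np.random.default_rng(config.seed)
    counts = rng.choice([1, 2, 4], size=config.n_cells, p=np.asarray(config.class_mix))
    in_bud = rng.binomial(counts, config.p_pass)
    return [
        CircleCellObservation(
            cell_id=f"cell{i:05d}",
            circle_count=int(c),
            circles_in_mother=int(c - nb),
            experiment_id=f"exp{i % config.n_experiments + 1}",
        )
        for i, (c, nb) in enumerate(zip(counts, in_bud))
    ]


@dataclass
class TimelineSimConfig:
    """Anaphase timelines with stage-specific per-circle passage hazards.

    Early anaphase runs from nuclear entry into the bud to the dumbbell shape;
    late anaphase from the dumbbell to karyokinesis. Durations (minutes) are
    truncated normal (>0); each circle's first passage to the bud follows an
    exponential clock with hazard ``hazard_early`` or ``hazard_late`` per
    minute in the respective stage, at most one passage per circle. Event
    times snap to the acquisition grid (default 1 frame per minute).
    """

    n_cells: int = 100
    early_mean: float = 3.9
    early_sd: float = 1.0
    late_mean: float = 14.5
    late_sd: float = 3.0
    hazard_early: float = 0.03  # passages per circle per minute
    hazard_late: float = 0.004
    circles_per_cell: int = 1
    frame_interval_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_mean <= 0 or self.late_mean <= 0:
            raise ValueError("stage duration means must be positive")
        if self.early_sd < 0 or self.late_sd < 0:
            raise ValueError("stage duration sds must be non-negative")
        if self.hazard_early < 0 or self.hazard_late < 0:
            raise ValueError("hazards must be non-negative")
        if self.circles_per_cell < 1 or self.n_cells < 1:
            raise ValueError("need at least one circle and one cell")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        worst = max(self.hazard_early, self.hazard_late) * self.circles_per_cell
        if worst * self.frame_interval_min > 1.0:
            warnings.warn(
                "expected passages per frame exceed 1; the one-passage-per-circle "
                "model will saturate", stacklevel=2,
            )


def _truncnorm_positive(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd  # truncate at zero
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def gen_timelines(config: TimelineSimConfig) -> list[AnaphaseTimeline]:
    """Simulate anaphase timelines; deterministic given seed.

    Stage boundaries are snapped to the frame grid first (at least one frame
    per stage), then passage clocks run in continuous time within the snapped
    stages and each event is recorded at the first frame at which the circle
    would be seen in the daughter compartment (ceiling to the grid).
    """
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_min
    early = _truncnorm_positive(config.early_mean, config.early_sd, config.n_cells, rng)
    late = _truncnorm_positive(config.late_mean, config.late_sd, config.n_cells, rng)
    early = np.maximum(np.round(early / dt), 1) * dt
    late = np.maximum(np.round(late / dt), 1) * dt

    timelines = []
    for i in range(config.n_cells):
        t_dumbbell = float(early[i])
        t_karyo = float(early[i] + late[i])
        passages = []
        for _ in range(config.circles_per_cell):
            t = _first_passage(config.hazard_early, config.hazard_late, early[i], late[i], rng)
            if t is not None:
                passages.append(min(float(np.ceil(t / dt) * dt), t_karyo))
        timelines.append(
            AnaphaseTimeline(
                cell_id=f"cell{i:05d}",
                t_dumbbell=t_dumbbell,
                t_karyo=t_karyo,
                passage_times=sorted(passages),
            )
        )
    return timelines


def _first_passage(
    h_early: float, h_late: float, d_early: float, d_late: float, rng: np.random.Generator
) -> float | None:
    """Continuous first-passage time of one circle, or None if it never passes."""
    if h_early > 0:
        t = rng.exponential(1.0 / h_early)
        if t < d_early:
            return t
    if h_late > 0:
        t = rng.exponential(1.0 / h_late)
        if t < d_late:
            return d_early + t
    return None


@dataclass
class RimSimConfig:
    """Closed nuclear-rim profiles with NPC punctae and one labeled DNA circle.

    The GFP channel carries a baseline rim signal with punctae elevated
    ``npc_peak_amplitude``-fold above baseline; the mCherry channel carries a
    single peak at the circle position. With probability ``p_attached`` the
    circle coincides with a punctum, otherwise it sits midway between two
    punctae. Peak widths are Gaussian sigmas in position units.
    """

    n_cells: int = 60
    n_positions: int = 64
    npc_peak_amplitude: float = 2.0
    p_attached: float = 1.0
    mcherry_peak_width: float = 1.5
    gfp_peak_width: float = 1.5
    n_punctae: int = 8
    noise_sd: float = 0.0
    background: float = 10.0
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positions < 21:
            raise ValueError("need at least 21 rim positions for the offset window")
        if not 0.0 <= self.p_attached <= 1.0:
            raise ValueError("p_attached must lie in [0, 1]")
        if self.mcherry_peak_width >= self.n_positions or self.gfp_peak_width >= self.n_positions:
            raise ValueError("peak widths must be smaller than the rim length")
        if self.npc_peak_amplitude < 1.0:
            raise ValueError("npc_peak_amplitude is a fold elevation, must be >= 1")
        if self.n_punctae < 1 or self.n_punctae > self.n_positions // 2:
            raise ValueError("n_punctae must be in 1..n_positions//2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _circular_gauss(n: int, center: float, sigma: float) -> np.ndarray:
    """Unit-amplitude Gaussian bump on a closed rim of n positions."""
    pos = np.arange(n, dtype=float)
    d = np.abs(pos - center)
    d = np.minimum(d, n - d)  # circular distance
    return np.exp(-0.5 * (d / sigma) ** 2)


def gen_rim_profiles(config: RimSimConfig) -> list[RimProfile]:
    """Simulate rim profile cohorts; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_positions
    spacing = n / config.n_punctae

    profiles = []
    for i in range(config.n_cells):
        # quasi-regular punctae: per-punctum jitter keeps inter-punctum offsets
        # incoherent across cells, so only the circle offset aligns
        phase = rng.uniform(0, spacing)
        jitter = rng.uniform(-spacing / 8.0, spacing / 8.0, config.n_punctae)
        punctae = (phase + spacing * np.arange(config.n_punctae) + jitter) % n

        gfp = np.full(n, config.baseline)
        amp = (config.npc_peak_amplitude - 1.0) * config.baseline
        if amp > 0:
            for c in punctae:
                gfp += amp * _circular_gauss(n, c, config.gfp_peak_width)

        if rng.uniform() < config.p_attached:
            circle = punctae[rng.integers(config.n_punctae)]
        else:
            j = rng.integers(config.n_punctae)
            nxt = punctae[(j + 1) % config.n_punctae]
            gap = (nxt - punctae[j]) % n
            circle = (punctae[j] + gap / 2.0) % n  # true midpoint between punctae
        mch = 0.1 * config.baseline + config.baseline * _circular_gauss(
            n, circle, config.mcherry_peak_width
        )

        if config.noise_sd > 0:
            gfp = gfp + rng.normal(0, config.noise_sd, n)
            mch = mch + rng.normal(0, config.noise_sd, n)
        profiles.append(
            RimProfile(
                cell_id=f"cell{i:04d}",
                gfp=gfp + config.background,
                mcherry=mch + config.background,
                circular=True,
            )
        )
    return profiles
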