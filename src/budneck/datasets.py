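"""Bundled condition-level reference measurements.

Published summary statistics for the growth conditions the simulators
emulate: optimal growth (30 °C, 2% glucose), heat stress (37 °C, 2%
glucose), calorie restriction (0.1% glucose) and the barrier-defective
*bud6Δ* mutant. These condition-level numbers (propagation frequencies,
stage durations, stage fluxes, barrier indices, median lifespans) are inputs
for worked examples and fold-change arithmetic — e.g. circle retention is
1 − propagation frequency, giving 96% at 30 °C versus 83% at 37 °C.

A NaN barrier index marks a condition where the bud fluorescence failed to
decay past the 75% threshold, so no BI could be determined (censored).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["condition_summaries"]

_ROWS = [
    # condition, genotype, temp_C, glucose_%, propagation freq ± SEM,
    # early/late flux ± SD (per min), anaphase total/early/late min ± SEM,
    # BI ± SEM, median lifespan (generations)
    {
        "condition": "30C_2pct", "genotype": "WT", "temperature_c": 30, "glucose_pct": 2.0,
        "propagation_frequency": 0.04, "propagation_frequency_sem": 0.01,
        "flux_early_per_min": 0.03, "flux_early_sd": 0.01,
        "flux_late_per_min": 0.004, "flux_late_sd": 0.003,
        "anaphase_total_min": 19.7, "anaphase_total_sem": 0.3,
        "anaphase_early_min": 3.9, "anaphase_early_sem": 0.14,
        "anaphase_late_min": 14.5, "anaphase_late_sem": 0.46,
        "barrier_index": 41.9, "barrier_index_sem": 4.1,
        "median_lifespan_gen": 23.0,
    },
    {
        "condition": "37C_2pct", "genotype": "WT", "temperature_c": 37, "glucose_pct": 2.0,
        "propagation_frequency": 0.17, "propagation_frequency_sem": 0.01,
        "flux_early_per_min": 0.06, "flux_early_sd": 0.004,
        "flux_late_per_min": float("nan"), "flux_late_sd": float("nan"),
        "anaphase_total_min": 15.7, "anaphase_total_sem": 0.5,
        "anaphase_early_min": 3.4, "anaphase_early_sem": 0.1,
        "anaphase_late_min": 12.9, "anaphase_late_sem": 0.46,
        "barrier_index": 24.6, "barrier_index_sem": 2.5,
        "median_lifespan_gen": 32.5,
    },
    {
        "condition": "30C_0.1pct", "genotype": "WT", "temperature_c": 30, "glucose_pct": 0.1,
        "propagation_frequency": 0.04, "propagation_frequency_sem": 0.005,
        "flux_early_per_min": 0.01, "flux_early_sd": 0.01,
        "flux_late_per_min": float("nan"), "flux_late_sd": float("nan"),
        "anaphase_total_min": float("nan"), "anaphase_total_sem": float("nan"),
        "anaphase_early_min": 5.2, "anaphase_early_sem": 0.36,
        "anaphase_late_min": float("nan"), "anaphase_late_sem": float("nan"),
        "barrier_index": 68.6, "barrier_index_sem": 15.0,
        "median_lifespan_gen": 30.0,
    },
    {
        "condition": "37C_0.1pct", "genotype": "WT", "temperature_c": 37, "glucose_pct": 0.1,
        "propagation_frequency": 0.06, "propagation_frequency_sem": 0.01,
        "flux_early_per_min": float("nan"), "flux_early_sd": float("nan"),
        "flux_late_per_min": float("nan"), "flux_late_sd": float("nan"),
        "anaphase_total_min": float("nan"), "anaphase_total_sem": float("nan"),
        "anaphase_early_min": float("nan"), "anaphase_early_sem": float("nan"),
        "anaphase_late_min": float("nan"), "anaphase_late_sem": float("nan"),
        "barrier_index": float("nan"), "barrier_index_sem": float("nan"),  # censored ("n.d.")
        "median_lifespan_gen": 27.0,
    },
    {
        "condition": "bud6_30C_2pct", "genotype": "bud6D", "temperature_c": 30, "glucose_pct": 2.0,
        "propagation_frequency": 0.13, "propagation_frequency_sem": 0.01,
        "flux_early_per_min": 0.10, "flux_early_sd": 0.02,
        "flux_late_per_min": float("nan"), "flux_late_sd": float("nan"),
        "anaphase_total_min": float("nan"), "anaphase_total_sem": float("nan"),
        "anaphase_early_min": float("nan"), "anaphase_early_sem": float("nan"),
        "anaphase_late_min": float("nan"), "anaphase_late_sem": float("nan"),
        "barrier_index": 25.3, "barrier_index_sem": 3.2,
        "median_lifespan_gen": 39.0,
    },
    {
        "condition": "bud6_30C_0.1pct", "genotype": "bud6D", "temperature_c": 30, "glucose_pct": 0.1,
        "propagation_frequency": 0.04, "propagation_frequency_sem": 0.007,
        "flux_early_per_min": float("nan"), "flux_early_sd": float("nan"),
        "flux_late_per_min": float("nan"), "flux_late_sd": float("nan"),
        "anaphase_total_min": float("nan"), "anaphase_total_sem": float("nan"),
        "anaphase_early_min": float("nan"), "anaphase_early_sem": float("nan"),
        "anaphase_late_min": float("nan"), "anaphase_late_sem": float("nan"),
        "barrier_index": 57.0, "barrier_index_sem": 9.9,
        "median_lifespan_gen": 28.5,
    },
]


def condition_summaries() -> pd.DataFrame:
    """Condition-level reference statistics, one row per condition."""
    return pd.DataFrame(_ROWS).set_index("condition")
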