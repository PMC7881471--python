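"""Canonical synthetic experiments exercising the whole pipeline.

These are the package's standard study conditions: cohorts of 34 + 34
subjects matching the framework's target cohort size, with effects
planted at fixed, documented strengths.

* **Null calibration** — no planted effects; repeated nested CV must
  stay at chance.
* **Recovery** — five regional effects of standardized size d = 2 on
  volume/area measures plus four thickness-coupling edge effects
  (rho = 0.9) on ROI pairs disjoint from the regional effects.  The
  channels are kept disjoint deliberately: a planted *thickness*
  regional effect perturbs every edge touching its ROI, which makes the
  planted edge list unrecoverable as ground truth.  Classification
  accuracy and top-15 selection-frequency recovery are the outcomes.
* **Weight sweep** — cohorts where only one channel carries signal; the
  accuracy curve over the kernel weight must peak on the informative
  side.
"""

from __future__ import annotations

import pandas as pd

from .atlas import AtlasHierarchy, load_atlas
from .classify import CVConfig, CVReport, frequency_table, nested_cv, weight_sweep
from .features import assemble_blocks
from .selection import SelectionConfig
from .synth import SimulationConfig, ground_truth_feature_names, simulate_cohort

__all__ = [
    "NULL_CONFIG",
    "RECOVERY_CONFIG",
    "NET_SIGNAL_CONFIG",
    "ROI_SIGNAL_CONFIG",
    "run_null_experiment",
    "run_recovery_experiment",
    "run_sweep_experiment",
]

#: No planted effects: the two groups are exchangeable.
NULL_CONFIG = SimulationConfig()

#: Five regional effects (d = 2, volume/area measures) and four
#: thickness-coupling edges (rho = 0.9) on disjoint ROI sets.
RECOVERY_CONFIG = SimulationConfig(
    planted_roi_effects=(
        (7, "wm_volume", 2.0),
        (45, "gm_volume", 2.0),
        (35, "csf_volume", 2.0),
        (73, "surface_area", 2.0),
        (19, "gm_volume", 2.0),
    ),
    planted_edge_effects=(
        (15, 55, 0.9),
        (27, 63, 0.9),
        (16, 66, 0.9),
        (36, 61, 0.9),
    ),
)

#: Only network-channel signal: eight coupled edges, no regional effects.
NET_SIGNAL_CONFIG = SimulationConfig(
    planted_edge_effects=(
        (15, 55, 0.9),
        (27, 63, 0.9),
        (16, 66, 0.9),
        (36, 61, 0.9),
        (7, 45, 0.9),
        (19, 73, 0.9),
        (10, 35, 0.9),
        (22, 58, 0.9),
    ),
)

#: Only regional-channel signal: the five recovery ROI effects.
ROI_SIGNAL_CONFIG = SimulationConfig(
    planted_roi_effects=RECOVERY_CONFIG.planted_roi_effects,
)


def _blocks(config: SimulationConfig, seed: int, atlas: AtlasHierarchy):
    cohort = simulate_cohort(config, seed=seed, atlas=atlas)
    return cohort, assemble_blocks(atlas, cohort.subjects)


def run_null_experiment(
    seed: int,
    repetitions: int = 20,
    atlas: AtlasHierarchy | None = None,
) -> CVReport:
    """Nested CV on a no-effect cohort; mean ACC should sit at chance."""
    atlas = atlas or load_atlas()
    cohort, blocks = _blocks(NULL_CONFIG, seed, atlas)
    return nested_cv(
        blocks,
        cohort.labels,
        CVConfig(repetitions=repetitions),
        SelectionConfig(screen_floor=1),
        seed=seed + 1,
    )


def run_recovery_experiment(
    seed: int,
    repetitions: int = 20,
    top_k: int = 15,
    atlas: AtlasHierarchy | None = None,
) -> dict:
    """Planted-effect recovery: accuracy plus top-``top_k`` frequency hits."""
    atlas = atlas or load_atlas()
    cohort, blocks = _blocks(RECOVERY_CONFIG, seed, atlas)
    report = nested_cv(
        blocks,
        cohort.labels,
        CVConfig(repetitions=repetitions),
        SelectionConfig(screen_floor=1),
        seed=seed + 1,
    )
    truth = ground_truth_feature_names(cohort)
    hits = {}
    tables = {}
    for role, key in (("roi", "roi"), ("net", "edges")):
        table = frequency_table(report, atlas, top_k=top_k, role=role)
        tables[role] = table
        top = set(table["feature"])
        hits[role] = sum(1 for f in truth[key] if f in top)
    return {
        "report": report,
        "cohort": cohort,
        "accuracy": report.metrics_mean.acc,
        "roi_hits": hits["roi"],
        "edge_hits": hits["net"],
        "n_roi_planted": len(truth["roi"]),
        "n_edge_planted": len(truth["edges"]),
        "tables": tables,
    }


def run_sweep_experiment(
    seed: int,
    repetitions: int = 5,
    beta_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    atlas: AtlasHierarchy | None = None,
) -> dict[str, pd.DataFrame]:
    """Kernel-weight sweeps on single-channel-signal cohorts.

    Returns the accuracy curve per cohort kind (``"net_signal"``,
    ``"roi_signal"``).  The network-signal curve should peak at small
    beta (network kernel dominant) and the regional-signal curve at
    large beta.
    """
    atlas = atlas or load_atlas()
    out = {}
    for name, config in (("net_signal", NET_SIGNAL_CONFIG), ("roi_signal", ROI_SIGNAL_CONFIG)):
        cohort, blocks = _blocks(config, seed, atlas)
        out[name] = weight_sweep(
            blocks,
            cohort.labels,
            beta_grid,
            CVConfig(repetitions=repetitions),
            SelectionConfig(screen_floor=1),
            seed=seed + 1,
        )
    return out
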