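"""Synthetic two-group cohorts of ROI morphometry with planted effects.

The generator emulates the tabular output of a morphometric MRI
pipeline: per subject, five measures for each bottom-layer ROI plus the
within-ROI thickness dispersion, with globals derived consistently from
the generated regions.  Group differences are planted two ways:

* **ROI effects** shift one measure of one ROI in the high-self-esteem
  group by ``d`` subject-level standard deviations (a standardized
  effect size).
* **Edge effects** couple the thickness deviations of an ROI pair in
  the high group (shared latent component with correlation ``rho``)
  while the low group's deviations stay independent.  Marginal
  distributions are unchanged, so the difference is visible only in the
  pairwise thickness similarity — a pure network effect.  The pair's
  baseline mean thicknesses are equalized so the similarity edge is
  sensitive to the coupling.

Baseline constants (2.5 mm mean thickness, regional volumes of a few
thousand mm^3) are plausibility defaults of this package, not measured
values.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .atlas import AtlasHierarchy, load_atlas
from .features import (
    MEASURES,
    ROI_COLUMNS,
    SubjectMorphometry,
    read_cohort_tables,
    write_cohort_tables,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

_MEASURES_SET = set(MEASURES)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model for one synthetic cohort.

    Parameters
    ----------
    n_per_group
        Subjects per group (high/low); the default matches the 34 + 34
        cohort the pipeline is sized for.
    thickness_base, thickness_roi_sd
        Mean cortical thickness (mm) and the between-ROI spread of the
        regional template means.
    thickness_subject_sd
        Subject-level SD of each ROI's thickness around its template
        mean — the noise scale in which thickness effect sizes are
        expressed.
    thickness_within_sd, thickness_within_roi_sd
        Within-ROI thickness dispersion (the sigma entering the
        similarity kernel) and its between-ROI spread.
    gm_base, wm_base, csf_base, area_base
        Regional baselines for the volumetric (mm^3) and surface-area
        (mm^2) measures; regional templates scatter around them
        log-normally with coefficient of variation ``template_cv``.
    noise_cv
        Subject-level multiplicative noise on volumes and areas.
    global_factor_sd, thickness_factor_sd
        SDs (log scale) of per-subject global size and thickness
        factors; these cancel under normalization.
    planted_roi_effects
        Tuples ``(roi_index, measure, d)``: shift the high group by
        ``d`` subject-level SDs of that measure.
    planted_edge_effects
        Tuples ``(roi_i, roi_j, rho)``: couple the pair's thickness
        deviations with correlation ``rho`` in the high group.
    """

    n_per_group: int = 34
    thickness_base: float = 2.5
    thickness_roi_sd: float = 0.2
    thickness_subject_sd: float = 0.15
    thickness_within_sd: float = 0.25
    thickness_within_roi_sd: float = 0.05
    gm_base: float = 6000.0
    wm_base: float = 4000.0
    csf_base: float = 1500.0
    area_base: float = 2500.0
    template_cv: float = 0.3
    noise_cv: float = 0.08
    global_factor_sd: float = 0.05
    thickness_factor_sd: float = 0.03
    planted_roi_effects: tuple[tuple[int, str, float], ...] = ()
    planted_edge_effects: tuple[tuple[int, int, float], ...] = ()
    max_resample: int = 20

    def validate(self, atlas: AtlasHierarchy) -> "SimulationConfig":
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        n4 = atlas.n_rois(4)
        for roi, measure, d in self.planted_roi_effects:
            if not 1 <= roi <= n4:
                raise ValueError(f"planted ROI effect names unknown ROI {roi}")
            if measure not in _MEASURES_SET:
                raise ValueError(f"planted ROI effect names unknown measure {measure!r}")
            if not np.isfinite(d):
                raise ValueError("planted effect sizes must be finite")
        touched: set[int] = set()
        for i, j, rho in self.planted_edge_effects:
            if not (1 <= i <= n4 and 1 <= j <= n4) or i == j:
                raise ValueError(f"planted edge effect names invalid ROI pair ({i}, {j})")
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"edge coupling must lie in [0, 1), got {rho}")
            if i in touched or j in touched:
                raise ValueError(f"ROI {i if i in touched else j} appears in two edge effects")
            touched.update((i, j))
        for name in (
            "thickness_base",
            "thickness_subject_sd",
            "thickness_within_sd",
            "gm_base",
            "wm_base",
            "csf_base",
            "area_base",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        return self


@dataclass
class SyntheticCohort:
    """Generated subjects plus the exact planted ground truth."""

    subjects: list[SubjectMorphometry]
    ground_truth: dict = field(default_factory=dict)
    config: SimulationConfig | None = None

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.subjects]


def simulate_cohort(
    config: SimulationConfig | None = None,
    seed: int = 0,
    atlas: AtlasHierarchy | None = None,
) -> SyntheticCohort:
    """Draw one two-group cohort from the generative model.

    The high-self-esteem group carries the planted effects.  Globals
    (total intracranial volume, global mean thickness, total surface
    area) are computed from the generated regional values, so
    normalization behaves exactly as it would on pipeline output.
    Identical seeds give identical cohorts.
    """
    config = config or SimulationConfig()
    atlas = atlas or load_atlas()
    config.validate(atlas)
    rng = np.random.default_rng(seed)
    n4 = atlas.n_rois(4)
    n = config.n_per_group

    # regional templates (shared by both groups)
    mu_t = rng.normal(config.thickness_base, config.thickness_roi_sd, n4)
    sigma_t = np.maximum(
        rng.normal(config.thickness_within_sd, config.thickness_within_roi_sd, n4), 0.05
    )
    vol_templates = {
        "gm_volume": config.gm_base,
        "wm_volume": config.wm_base,
        "csf_volume": config.csf_base,
        "surface_area": config.area_base,
    }
    templates = {
        m: base * rng.lognormal(0.0, config.template_cv, n4)
        for m, base in vol_templates.items()
    }
    # equalize baseline thickness within each coupled pair so the
    # similarity edge responds to the coupling rather than a fixed offset
    for i, j, _rho in config.planted_edge_effects:
        shared = 0.5 * (mu_t[i - 1] + mu_t[j - 1])
        mu_t[i - 1] = mu_t[j - 1] = shared

    labels = ["high"] * n + ["low"] * n
    subjects: list[SubjectMorphometry] = []
    s_subj = config.thickness_subject_sd
    for k, label in enumerate(labels):
        g_vol = rng.lognormal(0.0, config.global_factor_sd)
        h_th = rng.lognormal(0.0, config.thickness_factor_sd)

        dev = rng.normal(0.0, s_subj, n4)
        if label == "high":
            for i, j, rho in config.planted_edge_effects:
                shared = rng.normal(0.0, 1.0)
                for roi in (i, j):
                    dev[roi - 1] = s_subj * (
                        np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.normal()
                    )
        else:
            # burn the same number of draws so both groups share the
            # per-subject RNG stream layout
            for _ in config.planted_edge_effects:
                rng.normal()
                rng.normal(size=2)

        data = pd.DataFrame(index=pd.RangeIndex(1, n4 + 1, name="roi_index"))
        thickness = mu_t + dev
        if label == "high":
            for roi, measure, d in config.planted_roi_effects:
                if measure == "thickness_mean":
                    thickness[roi - 1] += d * s_subj
        data["thickness_mean"] = np.maximum(thickness, 0.1) * h_th
        data["thickness_sd"] = sigma_t * h_th
        for m, tmpl in templates.items():
            noise = rng.normal(0.0, config.noise_cv, n4)
            vals = tmpl * g_vol * (1.0 + noise)
            if label == "high":
                for roi, measure, d in config.planted_roi_effects:
                    if measure == m:
                        vals[roi - 1] += d * tmpl[roi - 1] * config.noise_cv
            bad = vals <= 0
            for _ in range(config.max_resample):
                if not bad.any():
                    break
                vals = np.where(
                    bad, tmpl * g_vol * (1.0 + rng.normal(0.0, config.noise_cv, n4)), vals
                )
                bad = vals <= 0
            if (vals <= 0).any():
                raise ValueError(
                    f"measure {m} could not be made positive; adjust noise_cv"
                )
            data[m] = vals
        data = data[list(ROI_COLUMNS)]
        subjects.append(
            SubjectMorphometry(
                subject_id=f"S{k + 1:03d}",
                label=label,
                data=data,
                tiv=float(
                    data[["gm_volume", "wm_volume", "csf_volume"]].to_numpy().sum()
                ),
                mean_thickness=float(data["thickness_mean"].mean()),
                total_area=float(data["surface_area"].sum()),
            ).validate(n_rois=n4)
        )

    ground_truth = {
        "roi_effects": [
            {"roi": roi, "measure": m, "d": d} for roi, m, d in config.planted_roi_effects
        ],
        "edge_effects": [
            {"roi_i": i, "roi_j": j, "rho": rho}
            for i, j, rho in config.planted_edge_effects
        ],
    }
    return SyntheticCohort(subjects=subjects, ground_truth=ground_truth, config=config)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, out_dir: Union[str, Path]) -> None:
    """Write measures/subjects CSVs plus a ground-truth sidecar JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_tables(cohort.subjects, out / "measures.csv", out / "subjects.csv")
    sidecar = {"ground_truth": cohort.ground_truth}
    if cohort.config is not None:
        sidecar["config"] = asdict(cohort.config)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, default=list)


def read_cohort(in_dir: Union[str, Path], n_rois: int | None = None) -> SyntheticCohort:
    """Read a cohort directory written by :func:`write_cohort`.

    A missing ground-truth sidecar yields an empty ground truth with a
    warning (the cohort itself is still usable).
    """
    in_dir = Path(in_dir)
    subjects = read_cohort_tables(
        in_dir / "measures.csv", in_dir / "subjects.csv", n_rois=n_rois
    )
    sidecar_path = in_dir / "ground_truth.json"
    ground_truth: dict = {}
    config = None
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        ground_truth = sidecar.get("ground_truth", {})
        raw = sidecar.get("config")
        if raw is not None:
            raw["planted_roi_effects"] = tuple(
                tuple(e) for e in raw.get("planted_roi_effects", ())
            )
            raw["planted_edge_effects"] = tuple(
                tuple(e) for e in raw.get("planted_edge_effects", ())
            )
            config = SimulationConfig(**raw)
    else:
        warnings.warn(f"no ground-truth sidecar in {in_dir}; loading without it", stacklevel=2)
    return SyntheticCohort(subjects=subjects, ground_truth=ground_truth, config=config)


def ground_truth_feature_names(cohort: SyntheticCohort) -> dict[str, list[str]]:
    """Canonical feature names of the planted effects (for recovery checks)."""
    from .features import edge_feature_name, roi_feature_name

    roi = [
        roi_feature_name(e["roi"], e["measure"])
        for e in cohort.ground_truth.get("roi_effects", [])
    ]
    edges = []
    for e in cohort.ground_truth.get("edge_effects", []):
        i, j = sorted((int(e["roi_i"]), int(e["roi_j"])))
        edges.append(edge_feature_name(4, i, j))
    return {"roi": roi, "edges": edges}
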