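"""Regional morphometry, similarity networks and feature blocks.

Each subject contributes five morphometric measures per bottom-layer ROI
(gray-matter, white-matter and CSF volume, mean cortical thickness and
cortical surface area) plus the within-ROI standard deviation of
thickness.  Measures are first normalized against the subject's own
globals (total intracranial volume, global mean thickness, total
cortical surface area) to remove inter-individual scale.

For every layer of the ROI hierarchy a morphometric similarity network
is built: the edge between ROIs i and j is the Gaussian similarity of
their mean cortical thicknesses,

    C(i, j) = exp(-(t_i - t_j)^2 / (2 * (sigma_i^2 + sigma_j^2))),

where sigma_i is the within-ROI thickness standard deviation.  Coarser
layers use ROI statistics obtained by averaging the constituent
bottom-layer means and standard deviations.  The strict upper triangle
of each layer's matrix, flattened row-major, is that layer's edge
feature vector; the whole-brain layer (a single node) contributes no
edges.  With the default 78/36/14/1 hierarchy the per-layer edge counts
are 3003, 630, 91 and 0, hence 3724 features for the union of all
layers, and the ROI block holds 78 x 5 = 390 features.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .atlas import AtlasHierarchy, count_layer_edges

__all__ = [
    "MEASURES",
    "ROI_COLUMNS",
    "MorphometryError",
    "SubjectMorphometry",
    "LayerNetwork",
    "normalize_subject",
    "edge_similarity",
    "merge_thickness_stats",
    "build_layer_network",
    "vectorize_network",
    "assemble_blocks",
    "roi_feature_name",
    "edge_feature_name",
    "parse_feature_name",
    "write_cohort_tables",
    "read_cohort_tables",
]

#: The five per-ROI measures forming the ROI feature block, in block order.
MEASURES = ("gm_volume", "wm_volume", "csf_volume", "thickness_mean", "surface_area")

#: All per-ROI columns carried by a subject record.
ROI_COLUMNS = (
    "gm_volume",
    "wm_volume",
    "csf_volume",
    "thickness_mean",
    "thickness_sd",
    "surface_area",
)

_VOLUME_MEASURES = ("gm_volume", "wm_volume", "csf_volume")

#: Feature-block names and their expected lengths under the default atlas.
BLOCK_NAMES = ("roi_L4", "net_L4", "net_L3", "net_L2", "net_all")


class MorphometryError(ValueError):
    """Raised for invalid morphometry values or degenerate similarity input."""


@dataclass(frozen=True)
class SubjectMorphometry:
    """One subject's per-ROI morphometry plus global normalizers.

    ``data`` is indexed by bottom-layer ROI index and carries the columns
    of :data:`ROI_COLUMNS`.  ``normalized`` records whether the values
    have already been divided by the subject globals.
    """

    subject_id: str
    label: str
    data: pd.DataFrame
    tiv: float
    mean_thickness: float
    total_area: float
    normalized: bool = False

    def validate(self, n_rois: int | None = None) -> "SubjectMorphometry":
        missing = set(ROI_COLUMNS) - set(self.data.columns)
        if missing:
            raise MorphometryError(
                f"subject {self.subject_id}: missing ROI columns {sorted(missing)}"
            )
        if n_rois is not None and len(self.data) != n_rois:
            raise MorphometryError(
                f"subject {self.subject_id}: expected {n_rois} ROI records, "
                f"got {len(self.data)}"
            )
        if self.data.index.has_duplicates:
            dup = int(self.data.index[self.data.index.duplicated()][0])
            raise MorphometryError(f"subject {self.subject_id}: duplicate ROI index {dup}")
        vals = self.data[list(ROI_COLUMNS)].to_numpy(float)
        if not np.isfinite(vals).all():
            raise MorphometryError(f"subject {self.subject_id}: non-finite measure")
        strict = [c for c in ROI_COLUMNS if c != "thickness_sd"]
        if (self.data[strict].to_numpy(float) <= 0).any():
            bad = next(
                c for c in strict if (self.data[c].to_numpy(float) <= 0).any()
            )
            raise MorphometryError(
                f"subject {self.subject_id}: non-positive {bad}"
            )
        if (self.data["thickness_sd"].to_numpy(float) < 0).any():
            raise MorphometryError(f"subject {self.subject_id}: negative thickness_sd")
        return self

    def roi_indices(self) -> np.ndarray:
        return self.data.index.to_numpy(int)


@dataclass(frozen=True)
class LayerNetwork:
    """Symmetric ROI x ROI similarity matrix for one hierarchy layer."""

    layer: int
    matrix: np.ndarray  # (n, n), entries in (0, 1], unit diagonal

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_subject(raw: SubjectMorphometry) -> SubjectMorphometry:
    """Divide each measure by the subject's matching global.

    Volumes are divided by total intracranial volume, thickness (mean and
    within-ROI SD alike, so similarity ratios are preserved) by the global
    mean thickness, and surface area by the total cortical area.
    Idempotent on an already-normalized subject.
    """
    if raw.normalized:
        return raw
    for field, value in (
        ("tiv", raw.tiv),
        ("mean_thickness", raw.mean_thickness),
        ("total_area", raw.total_area),
    ):
        if not (value > 0 and math.isfinite(value)):
            raise MorphometryError(
                f"subject {raw.subject_id}: global {field} must be positive, got {value}"
            )
    data = raw.data.copy()
    for col in _VOLUME_MEASURES:
        data[col] = data[col] / raw.tiv
    data["thickness_mean"] = data["thickness_mean"] / raw.mean_thickness
    data["thickness_sd"] = data["thickness_sd"] / raw.mean_thickness
    data["surface_area"] = data["surface_area"] / raw.total_area
    return replace(raw, data=data, normalized=True)


# ---------------------------------------------------------------------------
# similarity networks
# ---------------------------------------------------------------------------


def edge_similarity(t_i: float, sigma_i: float, t_j: float, sigma_j: float) -> float:
    """Gaussian similarity of two ROI thickness statistics.

    Returns ``exp(-(t_i - t_j)**2 / (2 * (sigma_i**2 + sigma_j**2)))``,
    which lies in (0, 1] and equals 1 iff the means coincide.  When both
    dispersions are zero the similarity is 1 for equal means and
    undefined otherwise.
    """
    s2 = sigma_i * sigma_i + sigma_j * sigma_j
    diff = t_i - t_j
    if s2 == 0.0:
        if diff == 0.0:
            return 1.0
        raise MorphometryError(
            "degenerate dispersion: sigma_i = sigma_j = 0 with unequal means"
        )
    return math.exp(-(diff * diff) / (2.0 * s2))


def merge_thickness_stats(
    atlas: AtlasHierarchy,
    subject: SubjectMorphometry,
    layer: int,
    sigma_rule: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI thickness mean and dispersion at a given layer.

    Compound ROIs of coarse layers take the unweighted average of their
    constituents' thickness means; the compound dispersion is by default
    the average of the constituent standard deviations
    (``sigma_rule="mean"``), with a root-mean-square pooling alternative
    (``sigma_rule="pooled"``).

    Returns
    -------
    (t, sigma)
        Arrays ordered by the layer's ROI index (1..n).
    """
    if sigma_rule not in ("mean", "pooled"):
        raise ValueError(f"unknown sigma_rule {sigma_rule!r}")
    data = subject.data.sort_index()
    t4 = data["thickness_mean"].to_numpy(float)
    s4 = data["thickness_sd"].to_numpy(float)
    if layer == 4:
        return t4, s4
    idx_pos = {int(i): k for k, i in enumerate(data.index)}
    n = atlas.n_rois(layer)
    t = np.empty(n)
    s = np.empty(n)
    for i in range(1, n + 1):
        members = atlas.preimage(layer, i)
        pos = [idx_pos[m] for m in members]
        t[i - 1] = t4[pos].mean()
        if sigma_rule == "mean":
            s[i - 1] = s4[pos].mean()
        else:
            s[i - 1] = math.sqrt(np.mean(s4[pos] ** 2))
    return t, s


def build_layer_network(
    atlas: AtlasHierarchy,
    subject: SubjectMorphometry,
    layer: int,
    sigma_rule: str = "mean",
) -> LayerNetwork:
    """Similarity network over all ROI pairs of one layer."""
    t, s = merge_thickness_stats(atlas, subject, layer, sigma_rule=sigma_rule)
    d2 = np.subtract.outer(t, t) ** 2
    s2 = np.add.outer(s**2, s**2)
    degenerate = (s2 == 0.0) & (d2 > 0.0)
    if degenerate.any():
        i, j = np.argwhere(degenerate)[0]
        raise MorphometryError(
            f"subject {subject.subject_id}: degenerate dispersion for layer-{layer} "
            f"ROI pair ({i + 1}, {j + 1})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.exp(-d2 / (2.0 * s2))
    mat[s2 == 0.0] = 1.0  # equal means with zero spread
    np.fill_diagonal(mat, 1.0)
    return LayerNetwork(layer=layer, matrix=mat)


def edge_feature_name(layer: int, i: int, j: int) -> str:
    """Canonical name of the edge feature between ROI i and j (1-based, i < j)."""
    return f"net_L{layer}|{i:02d}-{j:02d}"


def roi_feature_name(roi_index: int, measure: str) -> str:
    """Canonical name of one ROI-block feature."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    return f"roi_L4|{roi_index:02d}|{measure}"


def parse_feature_name(name: str) -> dict[str, object]:
    """Decode a canonical feature name into its components."""
    parts = name.split("|")
    if parts[0] == "roi_L4" and len(parts) == 3:
        return {"kind": "roi", "layer": 4, "roi": int(parts[1]), "measure": parts[2]}
    if parts[0].startswith("net_L") and len(parts) == 2:
        i, j = parts[1].split("-")
        return {"kind": "edge", "layer": int(parts[0][5:]), "roi_i": int(i), "roi_j": int(j)}
    raise ValueError(f"unrecognized feature name {name!r}")


def vectorize_network(net: LayerNetwork) -> tuple[list[str], np.ndarray]:
    """Strict upper triangle of a layer network, flattened row-major.

    The vector order is (1,2), (1,3), ..., (1,n), (2,3), ..., (n-1,n);
    a single-node network yields an empty vector.
    """
    n = net.n_rois
    iu, ju = np.triu_indices(n, k=1)
    names = [edge_feature_name(net.layer, i + 1, j + 1) for i, j in zip(iu, ju)]
    return names, net.matrix[iu, ju]


# ---------------------------------------------------------------------------
# block assembly
# ---------------------------------------------------------------------------


def assemble_blocks(
    atlas: AtlasHierarchy,
    cohort: Sequence[SubjectMorphometry],
    sigma_rule: str = "mean",
) -> dict[str, pd.DataFrame]:
    """Build every feature block for a cohort.

    Subjects are normalized (if not already) and validated against the
    atlas.  Returns a mapping of block name to a subjects x features
    DataFrame: ``roi_L4`` (normalized measures, ROI-major then measure
    order), ``net_L4``/``net_L3``/``net_L2`` (per-layer edge vectors) and
    ``net_all`` (edge vectors of layers 4, 3, 2, 1 concatenated; the
    whole-brain layer is empty).  Feature order is deterministic and
    independent of the cohort.
    """
    if not cohort:
        raise MorphometryError("empty cohort")
    n4 = atlas.n_rois(4)
    subjects = []
    for s in cohort:
        s.validate(n_rois=n4)
        want = set(range(1, n4 + 1))
        have = set(int(i) for i in s.data.index)
        if have != want:
            missing = min(want - have) if want - have else min(have - want)
            raise MorphometryError(
                f"subject {s.subject_id}: ROI record {missing} "
                + ("missing" if want - have else "unexpected")
            )
        subjects.append(normalize_subject(s))

    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise MorphometryError(f"duplicate subject_id {dup!r}")

    roi_names = [roi_feature_name(i, m) for i in range(1, n4 + 1) for m in MEASURES]
    roi_rows = []
    for s in subjects:
        data = s.data.sort_index()
        roi_rows.append(data[list(MEASURES)].to_numpy(float).ravel())
    blocks: dict[str, pd.DataFrame] = {
        "roi_L4": pd.DataFrame(np.vstack(roi_rows), index=ids, columns=roi_names)
    }

    net_frames: dict[int, pd.DataFrame] = {}
    for layer in (4, 3, 2, 1):
        names: list[str] | None = None
        rows = []
        for s in subjects:
            net = build_layer_network(atlas, s, layer, sigma_rule=sigma_rule)
            nm, vec = vectorize_network(net)
            if names is None:
                names = nm
            rows.append(vec)
        net_frames[layer] = pd.DataFrame(
            np.vstack(rows) if names else np.empty((len(ids), 0)),
            index=ids,
            columns=names or [],
        )
    for layer in (4, 3, 2):
        blocks[f"net_L{layer}"] = net_frames[layer]
    blocks["net_all"] = pd.concat(
        [net_frames[layer] for layer in (4, 3, 2, 1)], axis=1
    )
    return blocks


def block_manifest(blocks: Mapping[str, pd.DataFrame]) -> dict[str, list[str]]:
    """Feature names per block, in emission order."""
    return {name: list(df.columns) for name, df in blocks.items()}


def write_blocks(blocks: Mapping[str, pd.DataFrame], out_dir: Union[str, Path]) -> None:
    """Write each block as a wide CSV plus a JSON manifest of feature order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in blocks.items():
        df.to_csv(out / f"block_{name}.csv", index_label="subject_id")
    with open(out / "feature_manifest.json", "w") as fh:
        json.dump(block_manifest(blocks), fh, indent=1)


# ---------------------------------------------------------------------------
# cohort table I/O
# ---------------------------------------------------------------------------

_MEASURE_COLUMNS = ("subject_id", "roi_index") + ROI_COLUMNS
_SUBJECT_COLUMNS = ("subject_id", "label", "tiv", "mean_thickness", "total_area")


def write_cohort_tables(
    cohort: Iterable[SubjectMorphometry],
    measures_csv: Union[str, Path],
    subjects_csv: Union[str, Path],
) -> None:
    """Write the two-table cohort interchange (per-ROI measures + subjects)."""
    m_rows, s_rows = [], []
    for s in cohort:
        s_rows.append(
            {
                "subject_id": s.subject_id,
                "label": s.label,
                "tiv": s.tiv,
                "mean_thickness": s.mean_thickness,
                "total_area": s.total_area,
            }
        )
        block = s.data.sort_index().rename_axis("roi_index").reset_index()
        block.insert(0, "subject_id", s.subject_id)
        m_rows.append(block)
    pd.concat(m_rows, ignore_index=True)[list(_MEASURE_COLUMNS)].to_csv(
        measures_csv, index=False
    )
    pd.DataFrame(s_rows, columns=list(_SUBJECT_COLUMNS)).to_csv(subjects_csv, index=False)


def read_cohort_tables(
    measures_csv: Union[str, Path],
    subjects_csv: Union[str, Path],
    n_rois: int | None = None,
) -> list[SubjectMorphometry]:
    """Read the two-table cohort interchange back into subject records.

    Schema violations raise :class:`MorphometryError` naming the column
    (and, for per-ROI gaps, the subject and ROI).
    """
    measures = pd.read_csv(measures_csv)
    subjects = pd.read_csv(subjects_csv)
    for frame, cols, path in (
        (measures, _MEASURE_COLUMNS, measures_csv),
        (subjects, _SUBJECT_COLUMNS, subjects_csv),
    ):
        missing = set(cols) - set(frame.columns)
        if missing:
            raise MorphometryError(f"{path}: missing column {sorted(missing)[0]!r}")
    out = []
    grouped = dict(tuple(measures.groupby("subject_id", sort=False)))
    for row in subjects.itertuples(index=False):
        if row.subject_id not in grouped:
            raise MorphometryError(f"subject {row.subject_id}: no measure rows")
        block = grouped[row.subject_id].set_index("roi_index")[list(ROI_COLUMNS)]
        subj = SubjectMorphometry(
            subject_id=str(row.subject_id),
            label=str(row.label),
            data=block,
            tiv=float(row.tiv),
            mean_thickness=float(row.mean_thickness),
            total_area=float(row.total_area),
        ).validate(n_rois=n_rois)
        out.append(subj)
    return out
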