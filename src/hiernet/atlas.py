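"""Multi-resolution cortical parcellation hierarchy.

The package analyses regional morphometry on a four-layer hierarchy of
regions of interest (ROIs).  The bottom layer (layer 4) is the cortical
subset of the Automated Anatomical Labeling (AAL) parcellation: the 90
AAL regions with the 12 subcortical structures removed, renumbered 1-78.
Layer 3 merges these gyral regions into 36 lobar surfaces (lateral,
medial, orbital/inferior), layer 2 into 14 lobes (central region,
frontal, temporal, parietal, occipital, limbic, insula; one per
hemisphere), and layer 1 treats the cortex as a single whole-brain
region.

A hierarchy is interchanged as a flat TSV with one row per bottom-layer
ROI carrying its index and name at every coarser layer, which makes the
encoding directly auditable.  Odd indices are left-hemisphere, even
indices right-hemisphere, following the AAL convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

__all__ = [
    "AAL_TOTAL_REGIONS",
    "AtlasError",
    "RoiDef",
    "AtlasHierarchy",
    "load_atlas",
    "count_layer_edges",
]

#: Number of regions in the full AAL parcellation (cortical + subcortical).
AAL_TOTAL_REGIONS = 90

#: Layer indices, coarsest (whole brain) to finest (gyral).
LAYERS = (1, 2, 3, 4)

_DEFAULT_ATLAS = "aal78"

_TSV_COLUMNS = (
    "layer4_index",
    "layer4_name",
    "hemisphere",
    "layer3_index",
    "layer3_name",
    "layer2_index",
    "layer2_name",
)


class AtlasError(ValueError):
    """Raised when a hierarchy definition is structurally invalid."""


@dataclass(frozen=True)
class RoiDef:
    """One region of interest within a single layer of the hierarchy."""

    index: int  # 1-based within its layer
    name: str
    hemisphere: str  # "L", "R" or "whole"
    layer: int

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise AtlasError(f"ROI {self.name!r}: invalid layer {self.layer}")
        if self.index < 1:
            raise AtlasError(f"ROI {self.name!r}: index must be >= 1, got {self.index}")
        if self.hemisphere not in ("L", "R", "whole"):
            raise AtlasError(
                f"ROI {self.name!r}: hemisphere must be L, R or whole, got {self.hemisphere!r}"
            )


@dataclass(frozen=True)
class AtlasHierarchy:
    """A validated four-layer ROI hierarchy with bottom-up merge maps.

    Parameters
    ----------
    layers
        Mapping from layer number (1..4) to the tuple of :class:`RoiDef`
        in that layer, ordered by index.
    merge_map
        For each coarse layer ``l`` in {1, 2, 3}, a mapping from every
        layer-4 ROI index to the index of the layer-``l`` ROI containing
        it.
    """

    layers: Mapping[int, tuple[RoiDef, ...]]
    merge_map: Mapping[int, Mapping[int, int]]

    # -- accessors ---------------------------------------------------------

    def n_rois(self, layer: int) -> int:
        self._check_layer(layer)
        return len(self.layers[layer])

    def rois(self, layer: int) -> tuple[RoiDef, ...]:
        self._check_layer(layer)
        return self.layers[layer]

    def roi(self, layer: int, index: int) -> RoiDef:
        self._check_layer(layer)
        try:
            roi = self.layers[layer][index - 1]
        except IndexError:
            raise AtlasError(f"layer {layer} has no ROI with index {index}") from None
        return roi

    def map_index(self, layer4_index: int, layer: int) -> int:
        """Index of the layer-``layer`` ROI containing a layer-4 ROI."""
        self._check_layer(layer)
        if layer == 4:
            return layer4_index
        try:
            return self.merge_map[layer][layer4_index]
        except KeyError:
            raise AtlasError(f"no layer-{layer} mapping for layer-4 ROI {layer4_index}") from None

    def preimage(self, layer: int, index: int) -> tuple[int, ...]:
        """Layer-4 ROI indices merged into ROI ``index`` of layer ``layer``."""
        self._check_layer(layer)
        if layer == 4:
            return (index,)
        members = tuple(
            i4 for i4, coarse in sorted(self.merge_map[layer].items()) if coarse == index
        )
        if not members:
            raise AtlasError(f"layer-{layer} ROI {index} has an empty preimage")
        return members

    @staticmethod
    def _check_layer(layer: int) -> None:
        if layer not in LAYERS:
            raise AtlasError(f"invalid layer {layer}; expected one of {LAYERS}")

    # -- validation --------------------------------------------------------

    def validate(self) -> "AtlasHierarchy":
        for layer in LAYERS:
            if layer not in self.layers:
                raise AtlasError(f"layer {layer} missing from hierarchy")
            rois = self.layers[layer]
            if not rois:
                raise AtlasError(f"layer {layer} is empty")
            indices = [r.index for r in rois]
            if len(set(indices)) != len(indices):
                dup = next(i for i in indices if indices.count(i) > 1)
                raise AtlasError(f"layer {layer}: duplicate ROI index {dup}")
            if indices != list(range(1, len(rois) + 1)):
                raise AtlasError(
                    f"layer {layer}: ROI indices must be contiguous from 1, got {indices}"
                )
            for r in rois:
                if r.layer != layer:
                    raise AtlasError(f"ROI {r.name!r} placed in layer {layer} but tagged {r.layer}")
        if self.n_rois(1) != 1:
            raise AtlasError(f"layer 1 must contain a single whole-brain ROI, got {self.n_rois(1)}")

        bottom = {r.index for r in self.layers[4]}
        for layer in (1, 2, 3):
            if layer not in self.merge_map:
                raise AtlasError(f"merge map for layer {layer} missing")
            mm = self.merge_map[layer]
            missing = bottom - set(mm)
            if missing:
                raise AtlasError(
                    f"layer-4 ROI {min(missing)} has no mapping onto layer {layer}"
                )
            extra = set(mm) - bottom
            if extra:
                raise AtlasError(f"merge map for layer {layer} refers to unknown ROI {min(extra)}")
            targets = set(mm.values())
            valid = {r.index for r in self.layers[layer]}
            if not targets <= valid:
                bad = min(targets - valid)
                raise AtlasError(f"merge map for layer {layer} targets unknown ROI {bad}")
            orphans = valid - targets
            if orphans:
                roi = self.roi(layer, min(orphans))
                raise AtlasError(
                    f"merge map for layer {layer} is not surjective: "
                    f"ROI {roi.index} ({roi.name!r}) has no members"
                )
        if set(self.merge_map[1].values()) != {1}:
            raise AtlasError("layer-1 map must send every ROI to the whole-brain ROI (index 1)")
        # the 4->2 map must factor through the 4->3 map
        l3_to_l2: dict[int, int] = {}
        for i4 in sorted(bottom):
            i3, i2 = self.merge_map[3][i4], self.merge_map[2][i4]
            if l3_to_l2.setdefault(i3, i2) != i2:
                raise AtlasError(
                    f"inconsistent merge maps: layer-3 ROI {i3} maps to both layer-2 ROIs "
                    f"{l3_to_l2[i3]} and {i2} (via layer-4 ROI {i4})"
                )
        return self

    # -- interchange -------------------------------------------------------

    def to_rows(self) -> list[dict[str, object]]:
        """Flat-table form: one row per layer-4 ROI (the TSV interchange shape)."""
        rows = []
        for r4 in self.layers[4]:
            r3 = self.roi(3, self.merge_map[3][r4.index])
            r2 = self.roi(2, self.merge_map[2][r4.index])
            rows.append(
                {
                    "layer4_index": r4.index,
                    "layer4_name": r4.name,
                    "hemisphere": r4.hemisphere,
                    "layer3_index": r3.index,
                    "layer3_name": r3.name,
                    "layer2_index": r2.index,
                    "layer2_name": r2.name,
                }
            )
        return rows

    def write_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_TSV_COLUMNS, delimiter="\t")
            writer.writeheader()
            writer.writerows(self.to_rows())

    @classmethod
    def from_rows(cls, rows: list[dict[str, object]]) -> "AtlasHierarchy":
        if not rows:
            raise AtlasError("hierarchy table is empty")
        l4: list[RoiDef] = []
        names: dict[int, dict[int, str]] = {2: {}, 3: {}}
        mm: dict[int, dict[int, int]] = {1: {}, 2: {}, 3: {}}
        for row in rows:
            try:
                i4 = int(row["layer4_index"])
                i3 = int(row["layer3_index"])
                i2 = int(row["layer2_index"])
                n4 = str(row["layer4_name"]).strip()
                n3 = str(row["layer3_name"]).strip()
                n2 = str(row["layer2_name"]).strip()
                hemi = str(row["hemisphere"]).strip()
            except (KeyError, TypeError, ValueError) as exc:
                raise AtlasError(f"malformed hierarchy row {row!r}: {exc}") from exc
            l4.append(RoiDef(index=i4, name=n4, hemisphere=hemi, layer=4))
            for layer, idx, name in ((3, i3, n3), (2, i2, n2)):
                if names[layer].setdefault(idx, name) != name:
                    raise AtlasError(
                        f"layer-{layer} ROI {idx} named both "
                        f"{names[layer][idx]!r} and {name!r}"
                    )
                mm[layer][i4] = idx
            mm[1][i4] = 1

        l4.sort(key=lambda r: r.index)

        def _coarse(layer: int) -> tuple[RoiDef, ...]:
            return tuple(
                RoiDef(
                    index=i,
                    name=names[layer][i],
                    hemisphere="L" if i % 2 == 1 else "R",
                    layer=layer,
                )
                for i in sorted(names[layer])
            )

        layers = {
            1: (RoiDef(index=1, name="Whole brain", hemisphere="whole", layer=1),),
            2: _coarse(2),
            3: _coarse(3),
            4: tuple(l4),
        }
        return cls(layers=layers, merge_map=mm).validate()

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "AtlasHierarchy":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = set(_TSV_COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise AtlasError(f"hierarchy TSV {path} lacks columns {sorted(missing)}")
            return cls.from_rows(list(reader))


def load_atlas(source: Union[str, Path, None] = None) -> AtlasHierarchy:
    """Load and validate an ROI hierarchy.

    Parameters
    ----------
    source
        ``None`` or ``"aal78"`` for the bundled 78-region cortical AAL
        hierarchy; otherwise a path to a hierarchy TSV.

    Returns
    -------
    AtlasHierarchy
        A fully validated hierarchy; structural defects raise
        :class:`AtlasError`.
    """
    if source is None or source == _DEFAULT_ATLAS:
        ref = resources.files("hiernet") / "data" / "aal78_hierarchy.tsv"
        with resources.as_file(ref) as path:
            return AtlasHierarchy.read_tsv(path)
    return AtlasHierarchy.read_tsv(source)


def count_layer_edges(atlas: AtlasHierarchy, layer: int) -> int:
    """Number of distinct ROI pairs (network edge features) in a layer."""
    n = atlas.n_rois(layer)
    return n * (n - 1) // 2
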