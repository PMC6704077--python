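"""Exchange data types and file I/O for per-node cortical field data.

A field simulator emits a cloud of cortical nodes (XYZ coordinates in mm)
and, per montage, one non-negative scalar per node: the magnitude of
current density (MCD) or of the electric field (MEF).  Downstream analysis
groups those scalars by anatomical label (hemisphere / lobe / gyrus) in a
standardized atlas space, so this module also carries the native-to-atlas
affine mapping and the node labeling step.

All tables are UTF-8, tab-delimited text with a header row and '.' decimal
separator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("mscope")

SPACE_NATIVE = "native"
SPACE_TALAIRACH = "talairach"
SPACES = (SPACE_NATIVE, SPACE_TALAIRACH)

HEMISPHERES = ("left", "right")
LOBES = ("frontal", "parietal", "temporal", "occipital", "limbic", "sublobar")
#: the 12 (hemisphere, lobe) categories of the parcellation
CATEGORIES = tuple((h, lb) for h in HEMISPHERES for lb in LOBES)

FIELD_KINDS = ("MCD", "MEF")


class MscopeError(ValueError):
    """Base error for invalid inputs to the analysis."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class NodeCloud:
    """Per-node 3D coordinates (mm) with stable integer node identifiers."""

    node_id: np.ndarray
    coords: np.ndarray
    space: str = SPACE_NATIVE

    def __post_init__(self) -> None:
        self.node_id = np.asarray(self.node_id, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.node_id.ndim != 1 or self.node_id.size == 0:
            raise MscopeError("NodeCloud needs at least one node")
        if self.coords.shape != (self.node_id.size, 3):
            raise MscopeError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.node_id.size} node ids"
            )
        if np.unique(self.node_id).size != self.node_id.size:
            raise MscopeError("duplicate node_id in NodeCloud")
        if not np.all(np.isfinite(self.coords)):
            raise MscopeError("non-finite coordinates in NodeCloud")
        if self.space not in SPACES:
            raise MscopeError(f"unknown space {self.space!r}")

    def __len__(self) -> int:
        return int(self.node_id.size)


@dataclass
class FieldVector:
    """One non-negative scalar (MCD or MEF) per node of a NodeCloud."""

    node_id: np.ndarray
    value: np.ndarray
    kind: str = "MCD"
    montage_name: str = ""

    def __post_init__(self) -> None:
        self.node_id = np.asarray(self.node_id, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=float)
        if self.node_id.shape != self.value.shape or self.node_id.ndim != 1:
            raise MscopeError("node_id and value must be aligned 1-D arrays")
        if np.unique(self.node_id).size != self.node_id.size:
            raise MscopeError("duplicate node_id in FieldVector")
        if not np.all(np.isfinite(self.value)):
            raise MscopeError("non-finite field value")
        if np.any(self.value < 0):
            raise MscopeError("negative field value")
        if self.kind not in FIELD_KINDS:
            raise MscopeError(f"unknown field kind {self.kind!r}")

    def __len__(self) -> int:
        return int(self.node_id.size)

    def restrict(self, node_ids: np.ndarray) -> "FieldVector":
        """Field restricted to ``node_ids`` (order of self preserved)."""
        keep = np.isin(self.node_id, np.asarray(node_ids, dtype=np.int64))
        return replace(self, node_id=self.node_id[keep], value=self.value[keep])

    def scaled(self, factor: float) -> "FieldVector":
        return replace(self, value=self.value * float(factor))


@dataclass
class AtlasLabelTable:
    """Per-node (hemisphere, lobe, gyrus) labels.

    Unlabeled nodes never appear here; they are dropped (with a logged
    count) at labeling time, mirroring how out-of-atlas coordinates are
    silently excluded by atlas lookup services.
    """

    table: pd.DataFrame

    REQUIRED = ("node_id", "hemisphere", "lobe", "gyrus")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise MscopeError(f"label table missing columns {missing}")
        t = self.table.reset_index(drop=True).copy()
        t["node_id"] = t["node_id"].astype(np.int64)
        if t["node_id"].duplicated().any():
            raise MscopeError("duplicate node_id in label table")
        bad_h = set(t["hemisphere"].unique()) - set(HEMISPHERES)
        if bad_h:
            raise MscopeError(f"unknown hemisphere labels {bad_h}")
        bad_l = set(t["lobe"].unique()) - set(LOBES)
        if bad_l:
            raise MscopeError(f"unknown lobe labels {bad_l}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def node_id(self) -> np.ndarray:
        return self.table["node_id"].to_numpy()

    def categories_present(self) -> list[tuple[str, str]]:
        got = self.table.groupby(["hemisphere", "lobe"], observed=True).size()
        return [c for c in CATEGORIES if c in got.index]


@dataclass
class BoundingBox:
    """Axis-aligned box in mm; used as the atlas-coverage stand-in."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float).reshape(3)
        self.hi = np.asarray(self.hi, dtype=float).reshape(3)
        if np.any(self.lo > self.hi):
            raise MscopeError("bounding box lo > hi")

    def contains(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return np.all((coords >= self.lo) & (coords <= self.hi), axis=1)


@dataclass
class AffineTransform:
    """4x4 homogeneous transform, native mm -> atlas (Talairach) mm."""

    matrix: np.ndarray = field(
        default_factory=lambda: np.eye(4)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(4, 4)
        if not np.allclose(self.matrix[3], [0.0, 0.0, 0.0, 1.0]):
            raise MscopeError("affine bottom row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise MscopeError("singular affine")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.matrix[:3, :3].T + self.matrix[:3, 3]


# ---------------------------------------------------------------------------
# readers / writers (tab-delimited, header row)
# ---------------------------------------------------------------------------

def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise MscopeError(f"empty file {path}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MscopeError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise MscopeError(f"{path}: no data rows")
    return df


def read_node_cloud(path, space: str = SPACE_NATIVE) -> NodeCloud:
    """Read a node table (columns node_id, x, y, z); order preserved."""
    df = _read_tsv(path, ("node_id", "x", "y", "z"))
    try:
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
        ids = df["node_id"].to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise MscopeError(f"{path}: non-numeric node data") from exc
    return NodeCloud(node_id=ids, coords=coords, space=space)


def write_node_cloud(cloud: NodeCloud, path) -> None:
    pd.DataFrame(
        {"node_id": cloud.node_id,
         "x": cloud.coords[:, 0],
         "y": cloud.coords[:, 1],
         "z": cloud.coords[:, 2]}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_field_vector(path, cloud: NodeCloud | None = None,
                      kind: str = "MCD", montage_name: str = "") -> FieldVector:
    """Read a field table (columns node_id, value), optionally checking
    that its node-id set matches ``cloud``'s."""
    df = _read_tsv(path, ("node_id", "value"))
    try:
        ids = df["node_id"].to_numpy(dtype=np.int64)
        values = df["value"].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise MscopeError(f"{path}: non-numeric field data") from exc
    fv = FieldVector(node_id=ids, value=values, kind=kind,
                     montage_name=montage_name)
    if cloud is not None and set(ids.tolist()) != set(cloud.node_id.tolist()):
        raise MscopeError(f"{path}: node ids do not match the node cloud")
    return fv


def write_field_vector(fv: FieldVector, path) -> None:
    pd.DataFrame({"node_id": fv.node_id, "value": fv.value}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_label_table(path) -> AtlasLabelTable:
    df = _read_tsv(path, AtlasLabelTable.REQUIRED)
    return AtlasLabelTable(df[list(AtlasLabelTable.REQUIRED)])


def write_label_table(labels: AtlasLabelTable, path) -> None:
    labels.table.to_csv(path, sep="\t", index=False)


def read_affine(path) -> tuple[AffineTransform, BoundingBox]:
    """Read affine.json: 16 row-major numbers plus bounds {lo, hi} in mm."""
    with open(path) as fh:
        blob = json.load(fh)
    matrix = np.asarray(blob["matrix"], dtype=float).reshape(4, 4)
    bounds = BoundingBox(lo=blob["bounds"]["lo"], hi=blob["bounds"]["hi"])
    return AffineTransform(matrix=matrix), bounds


def write_affine(affine: AffineTransform, bounds: BoundingBox, path) -> None:
    blob = {
        "matrix": [float(v) for v in affine.matrix.ravel()],
        "bounds": {"lo": bounds.lo.tolist(), "hi": bounds.hi.tolist()},
    }
    with open(path, "w") as fh:
        json.dump(blob, fh, indent=1)


# ---------------------------------------------------------------------------
# native -> atlas mapping and node labeling
# ---------------------------------------------------------------------------

def map_to_atlas_space(cloud: NodeCloud, affine: AffineTransform,
                       bounds: BoundingBox) -> NodeCloud:
    """Transform a native-space cloud into atlas space.

    Nodes whose transformed coordinates fall outside ``bounds`` are dropped,
    emulating coordinates that fail atlas mapping (the survivor count is
    logged).  Node ids of survivors are unchanged.
    """
    if cloud.space != SPACE_NATIVE:
        raise MscopeError("map_to_atlas_space expects a native-space cloud")
    mapped = affine.apply(cloud.coords)
    keep = bounds.contains(mapped)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("atlas mapping dropped %d/%d nodes outside bounds",
                    n_drop, len(cloud))
    if not keep.any():
        raise MscopeError("no nodes survive atlas mapping")
    return NodeCloud(node_id=cloud.node_id[keep], coords=mapped[keep],
                     space=SPACE_TALAIRACH)


def label_nodes(cloud: NodeCloud, atlas) -> AtlasLabelTable:
    """Assign (hemisphere, lobe, gyrus) to every node of an atlas-space cloud.

    ``atlas`` is one of
      * a path to a labels.tsv file,
      * an :class:`AtlasLabelTable` / DataFrame covering (a superset of) the
        cloud's node ids,
      * an object with a ``label(coords) -> DataFrame`` method (the synthetic
        partition of :mod:`mscope.synth`).

    Nodes absent from the lookup source are excluded from the returned table;
    the exclusion count is logged.
    """
    if cloud.space != SPACE_TALAIRACH:
        raise MscopeError("label_nodes expects an atlas-space cloud")
    if hasattr(atlas, "label") and not isinstance(atlas, AtlasLabelTable):
        lab = atlas.label(cloud.coords)
        lab = lab.assign(node_id=cloud.node_id)
        return AtlasLabelTable(lab[list(AtlasLabelTable.REQUIRED)])
    if isinstance(atlas, (str,)) or hasattr(atlas, "__fspath__"):
        atlas = read_label_table(atlas)
    if isinstance(atlas, AtlasLabelTable):
        source = atlas.table
    elif isinstance(atlas, pd.DataFrame):
        source = AtlasLabelTable(atlas).table
    else:
        raise MscopeError(f"unsupported atlas lookup source {type(atlas)!r}")
    merged = pd.DataFrame({"node_id": cloud.node_id}).merge(
        source, on="node_id", how="left"
    )
    unlabeled = merged["lobe"].isna()
    if unlabeled.any():
        logger.info("labeling excluded %d/%d nodes absent from the atlas",
                    int(unlabeled.sum()), len(cloud))
    kept = merged.loc[~unlabeled]
    if len(kept) == 0:
        raise MscopeError("no node of the cloud is covered by the atlas")
    return AtlasLabelTable(kept[list(AtlasLabelTable.REQUIRED)])
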