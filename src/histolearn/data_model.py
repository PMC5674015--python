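"""Domain types and file formats for whole-slide object tables.

A slide's segmented nuclei live in two stores: a text-delimited boundary
file (one polygon per line) and an HDF5 feature store holding the K x F
feature matrix together with object ids, slide ids and pixel centroids.
Expert labels are kept in small CSV files. All learning and phenotype
operations run off the feature store; boundaries are only needed for
export and visualization.

Coordinate convention: 0-based pixel coordinates, x rightward, y downward
(image convention). Conversion to microns happens only where a physical
radius is needed, via each slide's microns-per-pixel (mpp).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "IGNORE",
    "LABEL_SOURCES",
    "DataValidationError",
    "SlideMeta",
    "HistObject",
    "FeatureStore",
    "LabelSet",
    "read_boundary_file",
    "write_boundary_file",
    "load_feature_store",
    "save_feature_store",
    "load_labels",
    "save_labels",
    "load_slide_table",
    "save_slide_table",
    "centroids_to_microns",
]

#: Class encoding: positive class (e.g. vascular endothelial nuclei) is +1,
#: negative is -1, matching the tree-vote convention t_j in {-1, +1}.
POSITIVE = 1
NEGATIVE = -1
#: Sentinel for objects an annotator placed in the ignore category; they are
#: excluded from all training and evaluation.
IGNORE = 0

LABEL_SOURCES = ("seed", "instance", "heatmap", "review", "truth")


class DataValidationError(ValueError):
    """Raised when an input file or in-memory container violates a contract."""


@dataclass(frozen=True)
class SlideMeta:
    """Metadata for one whole-slide image (its derived object table)."""

    slide_id: str
    width_px: int
    height_px: int
    mpp: float  # microns per pixel at base resolution
    patient_id: str = ""

    def __post_init__(self) -> None:
        if not self.slide_id:
            raise DataValidationError("slide_id must be non-empty")
        if self.width_px <= 0 or self.height_px <= 0:
            raise DataValidationError(
                f"slide {self.slide_id}: dimensions must be positive"
            )
        if not (self.mpp > 0):
            raise DataValidationError(f"slide {self.slide_id}: mpp must be > 0")


@dataclass
class HistObject:
    """One segmented nucleus: ids, pixel centroid, boundary polygon, features."""

    object_id: int
    slide_id: str
    centroid: tuple[float, float]
    boundary: np.ndarray  # (V, 2) pixel vertices, closed implicitly
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.object_id < 0:
            raise DataValidationError("object_id must be non-negative")
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2:
            raise DataValidationError(
                f"object {self.object_id}: boundary must be a (V, 2) array"
            )
        if len(self.boundary) < 3:
            raise DataValidationError(
                f"object {self.object_id}: degenerate polygon "
                f"({len(self.boundary)} vertices, need >= 3)"
            )


class FeatureStore:
    """Columnar K x F feature matrix with object/slide indices.

    The unit all learning operates on. Rows are objects; ``object_ids``,
    ``slide_ids`` and ``centroids`` are row-aligned with ``features``.
    """

    def __init__(
        self,
        features: np.ndarray,
        object_ids: np.ndarray,
        slide_ids: np.ndarray,
        centroids: np.ndarray,
        feature_names: Sequence[str],
    ) -> None:
        self.features = np.asarray(features, dtype=np.float64)
        self.object_ids = np.asarray(object_ids, dtype=np.int64)
        self.slide_ids = np.asarray(slide_ids, dtype=object).astype(str)
        self.centroids = np.asarray(centroids, dtype=np.float64)
        self.feature_names = [str(n) for n in feature_names]
        self._validate()
        self._row_of: dict[int, int] | None = None

    def _validate(self) -> None:
        if self.features.ndim != 2:
            raise DataValidationError("features must be a 2-D matrix")
        k, f = self.features.shape
        for name, arr, expect in (
            ("object_ids", self.object_ids, (k,)),
            ("slide_ids", self.slide_ids, (k,)),
            ("centroids", self.centroids, (k, 2)),
        ):
            if arr.shape != expect:
                raise DataValidationError(
                    f"{name} has shape {arr.shape}, expected {expect} "
                    f"(length mismatch with K={k})"
                )
        if len(self.feature_names) != f:
            raise DataValidationError(
                f"feature_names has length {len(self.feature_names)}, expected {f}"
            )
        if len(set(self.feature_names)) != f:
            raise DataValidationError("feature_names must be unique")
        if not np.isfinite(self.features).all():
            bad = int(np.count_nonzero(~np.isfinite(self.features)))
            raise DataValidationError(
                f"features contain {bad} non-finite values; refusing to load"
            )
        if len(np.unique(self.object_ids)) != k:
            raise DataValidationError("object_ids must be unique")

    @property
    def n_objects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def rows_of(self, object_ids: Iterable[int]) -> np.ndarray:
        """Row indices for the given object ids (error on unknown id)."""
        if self._row_of is None:
            self._row_of = {int(o): i for i, o in enumerate(self.object_ids)}
        try:
            return np.array([self._row_of[int(o)] for o in object_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"object_id {exc.args[0]} not in feature store") from None

    def slide_mask(self, slide_id: str) -> np.ndarray:
        return self.slide_ids == slide_id

    def feature_columns(self, names: Sequence[str]) -> np.ndarray:
        """Sub-matrix of the named feature columns, in the order given."""
        idx = []
        for n in names:
            try:
                idx.append(self.feature_names.index(n))
            except ValueError:
                raise KeyError(f"feature {n!r} not in store") from None
        return self.features[:, idx]


class LabelSet:
    """Expert labels (training or validation) with per-entry provenance.

    One entry per object_id; label is +1, -1 or IGNORE. IGNORE entries are
    excluded from training and evaluation but still tracked so that the
    object is never re-presented for labeling.
    """

    def __init__(self, role: str = "training") -> None:
        if role not in ("training", "validation"):
            raise DataValidationError(f"role must be training/validation, got {role!r}")
        self.role = role
        self.entries: dict[int, int] = {}
        self.source: dict[int, str] = {}
        self.iteration: dict[int, int] = {}

    def add(self, object_id: int, label: int, source: str, iteration: int = 0) -> None:
        if label not in (POSITIVE, NEGATIVE, IGNORE):
            raise DataValidationError(f"label must be +1/-1/IGNORE, got {label!r}")
        if source not in LABEL_SOURCES:
            raise DataValidationError(f"unknown label source {source!r}")
        oid = int(object_id)
        self.entries[oid] = int(label)
        self.source[oid] = source
        self.iteration[oid] = int(iteration)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, object_id: int) -> bool:
        return int(object_id) in self.entries

    def labeled_ids(self) -> list[int]:
        """Object ids with an effective (non-IGNORE) label, sorted."""
        return sorted(o for o, l in self.entries.items() if l != IGNORE)

    def labels_for(self, object_ids: Iterable[int]) -> np.ndarray:
        return np.array([self.entries[int(o)] for o in object_ids], dtype=np.int64)

    def n_effective(self) -> int:
        return sum(1 for l in self.entries.values() if l != IGNORE)

    def copy(self) -> "LabelSet":
        out = LabelSet(role=self.role)
        out.entries = dict(self.entries)
        out.source = dict(self.source)
        out.iteration = dict(self.iteration)
        return out

    def to_frame(self) -> pd.DataFrame:
        oids = sorted(self.entries)
        return pd.DataFrame(
            {
                "object_id": oids,
                "label": ["ignore" if self.entries[o] == IGNORE else self.entries[o] for o in oids],
                "source": [self.source[o] for o in oids],
                "iteration": [self.iteration[o] for o in oids],
            }
        )

    def validate_against(self, store: FeatureStore) -> None:
        known = set(int(o) for o in store.object_ids)
        missing = [o for o in self.entries if o not in known]
        if missing:
            raise DataValidationError(
                f"{len(missing)} labeled object_ids not in feature store "
                f"(first: {missing[:5]})"
            )


# ---------------------------------------------------------------------------
# Boundary file format
#
# UTF-8, tab-separated, one object per line:
#   slide_id <TAB> object_id <TAB> centroid_x <TAB> centroid_y <TAB> vertices
# where vertices is a space-separated list of "x,y" pairs. A 3-field
# variant (slide_id, object_id, vertices) omits the centroid, which is then
# computed as the vertex mean. Lines starting with '#' are comments.
# ---------------------------------------------------------------------------

_BOUNDARY_HEADER = "# slide_id\tobject_id\tcentroid_x\tcentroid_y\tboundary(x,y ...)"


def _parse_vertices(text: str, lineno: int) -> np.ndarray:
    verts = []
    for pair in text.split():
        parts = pair.split(",")
        if len(parts) != 2:
            raise DataValidationError(
                f"line {lineno}: malformed vertex {pair!r} (expected 'x,y')"
            )
        try:
            verts.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise DataValidationError(
                f"line {lineno}: non-numeric vertex {pair!r}"
            ) from None
    return np.array(verts, dtype=float).reshape(-1, 2)


def read_boundary_file(path, slide: SlideMeta | None = None) -> list[HistObject]:
    """Parse a text-delimited boundary file into HistObjects (no features).

    If ``slide`` is given, centroids are checked against its bounds and
    slide ids must match. Line order is preserved.
    """
    objects: list[HistObject] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 5:
                slide_id, oid_s, cx_s, cy_s, verts_s = fields
                try:
                    centroid = (float(cx_s), float(cy_s))
                except ValueError:
                    raise DataValidationError(
                        f"line {lineno}: non-numeric centroid ({cx_s!r}, {cy_s!r})"
                    ) from None
            elif len(fields) == 3:
                slide_id, oid_s, verts_s = fields
                centroid = None
            else:
                raise DataValidationError(
                    f"line {lineno}: expected 3 or 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                object_id = int(oid_s)
            except ValueError:
                raise DataValidationError(
                    f"line {lineno}: non-integer object_id {oid_s!r}"
                ) from None
            verts = _parse_vertices(verts_s, lineno)
            if len(verts) < 3:
                raise DataValidationError(
                    f"line {lineno}: degenerate polygon ({len(verts)} vertices)"
                )
            if centroid is None:
                centroid = (float(verts[:, 0].mean()), float(verts[:, 1].mean()))
            if slide is not None:
                if slide_id != slide.slide_id:
                    raise DataValidationError(
                        f"line {lineno}: slide_id {slide_id!r} does not match "
                        f"{slide.slide_id!r}"
                    )
                x, y = centroid
                if not (0 <= x < slide.width_px and 0 <= y < slide.height_px):
                    raise DataValidationError(
                        f"line {lineno}: centroid {centroid} outside slide bounds"
                    )
            objects.append(
                HistObject(
                    object_id=object_id,
                    slide_id=slide_id,
                    centroid=centroid,
                    boundary=verts,
                )
            )
    return objects


def write_boundary_file(objects: Sequence[HistObject], path) -> None:
    """Write objects to the text-delimited boundary format (one slide per file)."""
    slide_ids = {o.slide_id for o in objects}
    if len(slide_ids) > 1:
        raise DataValidationError(
            f"boundary file holds a single slide; got {sorted(slide_ids)}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_BOUNDARY_HEADER + "\n")
        for o in objects:
            verts = " ".join(f"{x:.10g},{y:.10g}" for x, y in o.boundary)
            fh.write(
                f"{o.slide_id}\t{o.object_id}\t{o.centroid[0]:.10g}"
                f"\t{o.centroid[1]:.10g}\t{verts}\n"
            )


# ---------------------------------------------------------------------------
# HDF5 feature store
# ---------------------------------------------------------------------------

_H5_DATASETS = ("features", "object_ids", "slide_ids", "centroids", "feature_names")


def save_feature_store(store: FeatureStore, path) -> None:
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=store.features.astype(np.float32))
        f.create_dataset("object_ids", data=store.object_ids)
        f.create_dataset("slide_ids", data=np.asarray(store.slide_ids, dtype=str_dt))
        f.create_dataset("centroids", data=store.centroids.astype(np.float32))
        f.create_dataset(
            "feature_names", data=np.asarray(store.feature_names, dtype=str_dt)
        )


def load_feature_store(path) -> FeatureStore:
    """Load and validate an HDF5 feature store.

    Distinct errors for a missing dataset, a row-length mismatch, and
    non-finite feature values; the returned store always satisfies the
    container invariants.
    """
    with h5py.File(path, "r") as f:
        for name in _H5_DATASETS:
            if name not in f:
                raise DataValidationError(f"feature store missing dataset /{name}")
        features = f["features"][()]
        object_ids = f["object_ids"][()]
        slide_ids = np.array([s.decode() if isinstance(s, bytes) else str(s)
                              for s in f["slide_ids"][()]])
        centroids = f["centroids"][()]
        feature_names = [s.decode() if isinstance(s, bytes) else str(s)
                         for s in f["feature_names"][()]]
    return FeatureStore(features, object_ids, slide_ids, centroids, feature_names)


# ---------------------------------------------------------------------------
# Label CSV: object_id,label,source,iteration with label in {1,-1,ignore}
# ---------------------------------------------------------------------------


def save_labels(labels: LabelSet, path) -> None:
    labels.to_frame().to_csv(path, index=False)


def load_labels(path, role: str = "training") -> LabelSet:
    out = LabelSet(role=role)
    df = pd.read_csv(path, dtype={"label": str})
    required = {"object_id", "label", "source", "iteration"}
    if not required.issubset(df.columns):
        raise DataValidationError(
            f"label file missing columns {sorted(required - set(df.columns))}"
        )
    for row in df.itertuples(index=False):
        raw = str(row.label).strip().lower()
        if raw == "ignore":
            label = IGNORE
        else:
            try:
                label = int(raw)
            except ValueError:
                raise DataValidationError(f"bad label value {row.label!r}") from None
        out.add(int(row.object_id), label, str(row.source), int(row.iteration))
    return out


# ---------------------------------------------------------------------------
# Slide metadata CSV: slide_id,patient_id,width_px,height_px,mpp
# ---------------------------------------------------------------------------


def save_slide_table(slides: Sequence[SlideMeta], path) -> None:
    pd.DataFrame(
        {
            "slide_id": [s.slide_id for s in slides],
            "patient_id": [s.patient_id for s in slides],
            "width_px": [s.width_px for s in slides],
            "height_px": [s.height_px for s in slides],
            "mpp": [s.mpp for s in slides],
        }
    ).to_csv(path, index=False)


def load_slide_table(path) -> dict[str, SlideMeta]:
    df = pd.read_csv(path, dtype={"slide_id": str, "patient_id": str})
    slides = {}
    for row in df.itertuples(index=False):
        meta = SlideMeta(
            slide_id=str(row.slide_id),
            width_px=int(row.width_px),
            height_px=int(row.height_px),
            mpp=float(row.mpp),
            patient_id=str(row.patient_id),
        )
        if meta.slide_id in slides:
            raise DataValidationError(f"duplicate slide_id {meta.slide_id!r}")
        slides[meta.slide_id] = meta
    return slides


def centroids_to_microns(
    store: FeatureStore, slides: Mapping[str, SlideMeta]
) -> np.ndarray:
    """Convert pixel centroids to microns using each slide's mpp.

    Positions remain in per-slide coordinate frames: coordinates on
    different slides are never compared directly.
    """
    out = np.empty_like(store.centroids)
    for sid in np.unique(store.slide_ids):
        if sid not in slides:
            raise KeyError(f"slide_id {sid!r} not in slide metadata")
        mask = store.slide_ids == sid
        out[mask] = store.centroids[mask] * slides[sid].mpp
    return out
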