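"""Voxel volume-conductor models and their conductivity assignment.

A volume conductor is represented as a 3-D array of integer tissue labels on a
regular grid of cubic voxels (pitch in mm), together with a table mapping each
label to a tissue name and a quasi-static electrical conductivity in S/m.
Voxel ``(i, j, k)`` occupies the half-open cube
``[i, i+1) x [j, j+1) x [k, k+1)`` in pitch units from the model origin
(0-based indices; array axes 0/1/2 are x/y/z, z is the anatomical
rotation axis).

The module also implements the two geometric manipulations used in
sensitivity studies: whole-body homogenization (every non-air voxel replaced
by a single tissue with conductivity 2/3 that of muscle) and rigid
rotation/isotropic scaling of the cardiac compartment about its centroid,
with vacated volume back-filled with lung-like tissue.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TissueTable",
    "VoxelModel",
    "ConductivityGrid",
    "load_tissue_table",
    "default_tissue_table",
    "load_model",
    "save_model",
    "assign_conductivity",
    "homogenize",
    "transform_heart",
    "model_hash",
]

#: Tissue names treated as non-conducting empty space (sigma must be 0).
AIR_NAMES = frozenset({"air", "internal air"})

#: Conductivity assigned to skin regardless of the shipped table value, S/m.
SKIN_SIGMA = 0.1


class ModelFormatError(ValueError):
    """Raised when a model file is malformed or inconsistent with its metadata."""


class UnknownLabelError(ValueError):
    """Raised when the label array contains a label absent from the tissue table."""


@dataclass(frozen=True)
class TissueTable:
    """Mapping from integer tissue label to (name, conductivity in S/m)."""

    entries: Mapping[int, tuple[str, float]]

    def __post_init__(self) -> None:
        names = [n.lower() for n, _ in self.entries.values()]
        if len(set(self.entries)) != len(self.entries):  # pragma: no cover
            raise ValueError("duplicate tissue labels")
        del names
        for label, (name, sigma) in self.entries.items():
            if sigma < 0:
                raise ValueError(f"tissue {name!r} (label {label}): sigma {sigma} < 0")
            if name.lower() in AIR_NAMES and sigma != 0.0:
                raise ValueError(f"air-type tissue {name!r} must have sigma = 0")

    def sigma(self, label: int) -> float:
        return self.entries[label][1]

    def name(self, label: int) -> str:
        return self.entries[label][0]

    def label_of(self, name: str) -> int:
        """Label of the tissue with the given (case-insensitive) name."""
        target = name.lower()
        for label, (n, _) in self.entries.items():
            if n.lower() == target:
                return label
        raise KeyError(f"no tissue named {name!r} in table")

    @property
    def air_labels(self) -> frozenset[int]:
        return frozenset(
            label for label, (n, _) in self.entries.items() if n.lower() in AIR_NAMES
        )

    def lookup_array(self, *, force_skin: bool = True) -> np.ndarray:
        """Dense label -> sigma lookup vector (index = label).

        Skin is pinned to :data:`SKIN_SIGMA` when ``force_skin`` is set, which
        is the convention used throughout: table variants with very low
        stratum-corneum values are overridden.
        """
        max_label = max(self.entries)
        lut = np.full(max_label + 1, np.nan)
        for label, (name, sigma) in self.entries.items():
            lut[label] = SKIN_SIGMA if (force_skin and name.lower() == "skin") else sigma
        return lut

    @classmethod
    def from_csv(cls, path) -> "TissueTable":
        df = pd.read_csv(path)
        required = {"label", "name", "sigma_S_per_m"}
        if not required.issubset(df.columns):
            raise ModelFormatError(f"tissue CSV must have columns {sorted(required)}")
        return cls(
            {int(r.label): (str(r.name), float(r.sigma_S_per_m)) for r in df.itertuples()}
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [(label, n, s) for label, (n, s) in sorted(self.entries.items())],
            columns=["label", "name", "sigma_S_per_m"],
        ).to_csv(path, index=False)


def load_tissue_table(path) -> TissueTable:
    return TissueTable.from_csv(path)


def default_tissue_table() -> TissueTable:
    """The packaged 52-entry whole-body tissue table (1 Hz quasi-static values)."""
    with resources.files("ecgloc.data").joinpath("tissue_conductivities.csv").open() as f:
        return TissueTable.from_csv(f)


@dataclass(frozen=True)
class VoxelModel:
    """A labeled voxel volume conductor.

    Parameters
    ----------
    labels : (nx, ny, nz) integer array of tissue labels.
    pitch_mm : cubic voxel edge length, mm (2.0 for whole-body-scale models).
    origin_mm : physical coordinate of the corner of voxel (0, 0, 0).
    tissues : label -> (name, sigma) table.
    heart_label, blood_label, lung_label : labels of the cardiac tissue, the
        intracardiac blood and the lung fill tissue; ``None`` when the model
        has no such compartment (e.g. after homogenization).
    """

    labels: np.ndarray
    pitch_mm: float
    tissues: TissueTable
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    heart_label: Optional[int] = None
    blood_label: Optional[int] = None
    lung_label: Optional[int] = None

    def __post_init__(self) -> None:
        labels = np.ascontiguousarray(np.asarray(self.labels))
        if labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ModelFormatError("labels must be integer-valued")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "origin_mm", np.asarray(self.origin_mm, float))
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be > 0")
        present = np.unique(labels)
        missing = sorted(set(present.tolist()) - set(self.tissues.entries))
        if missing:
            raise UnknownLabelError(
                f"label(s) {missing} present in model but absent from tissue table"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def heart_mask(self) -> np.ndarray:
        if self.heart_label is None:
            raise ValueError("model has no heart label")
        return self.labels == self.heart_label

    def heart_voxel_count(self) -> int:
        return int(self.heart_mask.sum())

    def voxel_centers_mm(self, idx: np.ndarray) -> np.ndarray:
        """Physical centers (mm) of voxels given (n, 3) integer indices."""
        return self.origin_mm + (np.asarray(idx, float) + 0.5) * self.pitch_mm


@dataclass(frozen=True)
class ConductivityGrid:
    """Element-wise conductivity field sigma(i, j, k), S/m."""

    sigma: np.ndarray
    pitch_mm: float


def assign_conductivity(model: VoxelModel) -> ConductivityGrid:
    """Look up per-voxel conductivity from the model's tissue table.

    Skin, if present in the table, is mapped to 0.1 S/m (the whole-tissue
    value; lower stratum-corneum figures are not appropriate at ECG
    frequencies).
    """
    lut = model.tissues.lookup_array(force_skin=True)
    sigma = lut[model.labels]
    return ConductivityGrid(sigma=sigma, pitch_mm=model.pitch_mm)


def homogenize(model: VoxelModel) -> VoxelModel:
    """Replace every non-air voxel with a single homogeneous tissue.

    The homogeneous conductivity is 2/3 of the muscle conductivity from the
    model's own table. The body-surface geometry (air/non-air mask) is
    preserved exactly. Compartment labels (heart/blood/lung) are cleared since
    the homogenized model no longer distinguishes them.
    """
    try:
        muscle_sigma = model.tissues.sigma(model.tissues.label_of("muscle"))
    except KeyError as exc:
        raise ValueError("cannot homogenize: no muscle entry in tissue table") from exc
    homo_label = max(model.tissues.entries) + 1
    homo_sigma = 2.0 / 3.0 * muscle_sigma

    air = np.isin(model.labels, list(model.tissues.air_labels))
    labels = np.where(air, model.labels, homo_label)
    entries = dict(model.tissues.entries)
    entries[homo_label] = ("Homogenized tissue", homo_sigma)
    return VoxelModel(
        labels=labels.astype(model.labels.dtype),
        pitch_mm=model.pitch_mm,
        origin_mm=model.origin_mm,
        tissues=TissueTable(entries),
        heart_label=None,
        blood_label=None,
        lung_label=None,
    )


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def transform_heart(
    model: VoxelModel,
    rotation_deg_z: float = 0.0,
    scale_pct: float = 100.0,
    include_blood: bool = False,
) -> VoxelModel:
    """Rigidly rotate (about z) and/or isotropically scale the cardiac tissue.

    The transform is centered on the cardiac-voxel centroid and resampled by
    nearest neighbor: an output voxel is cardiac iff its center, mapped back
    through the inverse transform, falls inside a cardiac voxel of the input.
    Voxels vacated by the heart are filled with the lung label; voxels newly
    claimed by the heart overwrite their previous (non-air) label.

    Parameters
    ----------
    rotation_deg_z : rotation angle about the z axis, degrees
        (study range -10..10; larger values warn).
    scale_pct : isotropic scale, percent (study range 90..110; outside warns).
    include_blood : also move intracardiac blood voxels with the heart.
        Default moves the heart tissue only.
    """
    if not -10.0 <= rotation_deg_z <= 10.0:
        warnings.warn(f"rotation {rotation_deg_z} deg outside the nominal +/-10 deg range")
    if not 90.0 <= scale_pct <= 110.0:
        warnings.warn(f"scale {scale_pct}% outside the nominal 90-110% range")
    if model.heart_label is None:
        raise ValueError("model has no heart label")
    if model.lung_label is None:
        raise ValueError("model has no lung label to back-fill vacated volume")

    cardiac_labels = [model.heart_label]
    if include_blood and model.blood_label is not None:
        cardiac_labels.append(model.blood_label)
    cardiac = np.isin(model.labels, cardiac_labels)
    if not cardiac.any():
        raise ValueError("no cardiac voxels to transform")

    if rotation_deg_z == 0.0 and scale_pct == 100.0:
        return model

    idx = np.argwhere(cardiac)
    centroid = idx.mean(axis=0) + 0.5  # voxel-center coordinates, pitch units

    nx, ny, nz = model.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    centers = np.stack([ii, jj, kk], axis=-1) + 0.5
    rel = centers.reshape(-1, 3) - centroid
    scale = scale_pct / 100.0
    src = centroid + rel @ _rot_z(-rotation_deg_z).T / scale
    src_idx = np.floor(src).astype(int)

    inside = np.all((src_idx >= 0) & (src_idx < model.shape), axis=1)
    claimed = np.zeros(rel.shape[0], dtype=bool)
    src_flat = np.ravel_multi_index(src_idx[inside].T, model.shape)
    claimed[inside] = cardiac.ravel()[src_flat]
    claimed = claimed.reshape(model.shape)

    air = np.isin(model.labels, list(model.tissues.air_labels))
    if np.any(claimed & air):
        raise ValueError("transform pushes cardiac tissue outside the body surface")

    out = model.labels.copy()
    out[cardiac & ~claimed] = model.lung_label
    new_vals = np.empty(rel.shape[0], dtype=out.dtype)
    new_vals[inside] = model.labels.ravel()[src_flat]
    out[claimed] = new_vals.reshape(model.shape)[claimed]
    return replace(model, labels=out)


def model_hash(model: VoxelModel) -> str:
    """Stable content hash of labels, pitch and tissue table (provenance key)."""
    import hashlib

    h = hashlib.sha256()
    h.update(np.ascontiguousarray(model.labels).tobytes())
    h.update(str(model.labels.shape).encode())
    h.update(f"{model.pitch_mm:.9g}".encode())
    for label, (name, sigma) in sorted(model.tissues.entries.items()):
        h.update(f"{label}:{name}:{sigma:.9g};".encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Model I/O: raw little-endian + JSON sidecar, NIfTI + JSON sidecar, and a
# single-file JSON text format for small fixtures.
# ---------------------------------------------------------------------------

def _meta_dict(model: VoxelModel) -> dict:
    return {
        "shape": list(model.shape),
        "pitch_mm": model.pitch_mm,
        "origin_mm": model.origin_mm.tolist(),
        "heart_label": model.heart_label,
        "blood_label": model.blood_label,
        "lung_label": model.lung_label,
        "tissues": {
            str(label): {"name": name, "sigma_S_per_m": sigma}
            for label, (name, sigma) in sorted(model.tissues.entries.items())
        },
    }


def _model_from_meta(labels: np.ndarray, meta: dict) -> VoxelModel:
    tissues = TissueTable(
        {
            int(label): (entry["name"], float(entry["sigma_S_per_m"]))
            for label, entry in meta["tissues"].items()
        }
    )
    if tuple(meta["shape"]) != labels.shape:
        raise ModelFormatError(
            f"metadata shape {tuple(meta['shape'])} != data shape {labels.shape}"
        )
    return VoxelModel(
        labels=labels,
        pitch_mm=float(meta["pitch_mm"]),
        origin_mm=np.asarray(meta.get("origin_mm", [0, 0, 0]), float),
        tissues=tissues,
        heart_label=meta.get("heart_label"),
        blood_label=meta.get("blood_label"),
        lung_label=meta.get("lung_label"),
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.json") if path.suffix == ".gz" \
        else path.with_suffix(".meta.json")


def save_model(model: VoxelModel, path, format: Optional[str] = None) -> None:
    """Write a model. Format inferred from the extension when not given:
    ``.json`` (single-file text), ``.raw`` (little-endian uint8/uint16 +
    ``.meta.json`` sidecar), ``.nii``/``.nii.gz`` (NIfTI + sidecar for the
    tissue table)."""
    path = Path(path)
    fmt = format or {".json": "text", ".raw": "raw", ".nii": "nifti", ".gz": "nifti"}.get(
        path.suffix
    )
    if fmt == "text":
        meta = _meta_dict(model)
        meta["labels"] = model.labels.ravel().tolist()
        path.write_text(json.dumps(meta))
    elif fmt == "raw":
        dtype = np.uint8 if model.labels.max() < 256 else np.uint16
        arr = model.labels.astype(f"<{dtype().dtype.str[1:]}")
        arr.tofile(path)
        meta = _meta_dict(model)
        meta["dtype"] = arr.dtype.str
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif fmt == "nifti":
        import nibabel as nib

        affine = np.diag([model.pitch_mm] * 3 + [1.0])
        affine[:3, 3] = model.origin_mm
        img = nib.Nifti1Image(model.labels.astype(np.int16), affine)
        img.header.set_zooms((model.pitch_mm,) * 3)
        nib.save(img, str(path))
        _sidecar_path(path).write_text(json.dumps(_meta_dict(model), indent=1))
    else:
        raise ModelFormatError(f"cannot infer model format for {path.name!r}")


def load_model(path, format: Optional[str] = None) -> VoxelModel:
    """Load a model saved by :func:`save_model` (or compatible files)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or {".json": "text", ".raw": "raw", ".nii": "nifti", ".gz": "nifti"}.get(
        path.suffix
    )
    if fmt == "text":
        meta = json.loads(path.read_text())
        labels = np.asarray(meta.pop("labels"), dtype=np.int64).reshape(meta["shape"])
        return _model_from_meta(labels, meta)
    if fmt == "raw":
        meta = json.loads(_sidecar_path(path).read_text())
        dtype = np.dtype(meta.get("dtype", "<u1"))
        labels = np.fromfile(path, dtype=dtype)
        expected = int(np.prod(meta["shape"]))
        if labels.size != expected:
            raise ModelFormatError(
                f"raw file holds {labels.size} voxels, metadata promises {expected}"
            )
        return _model_from_meta(labels.reshape(meta["shape"]).astype(np.int64), meta)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(np.int64)
        meta = json.loads(_sidecar_path(path).read_text())
        meta.setdefault("pitch_mm", float(img.header.get_zooms()[0]))
        return _model_from_meta(labels, meta)
    raise ModelFormatError(f"cannot infer model format for {path.name!r}")
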