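"""Volumetric containers and operations: NIfTI IO, mask-constrained smoothing,
nuisance regression, and time-series extraction.

All spatial math downstream uses world coordinates in millimetres obtained from
the NIfTI affine (RAS expected but not enforced). Voxel indices are 0-based.
Masked voxels are enumerated in a fixed, documented order: ascending flattened
index with the first (x) axis fastest, i.e. sorted lexicographically by
(k, j, i) with i varying fastest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

LEFT, RIGHT = 1, 2  # hemisphere codes used in RoiMask.hemisphere volumes

__all__ = [
    "BoldVolume",
    "RoiMask",
    "AtlasLabels",
    "CoordinateTable",
    "CompatibilityError",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_atlas",
    "save_atlas",
    "check_compatible",
    "regress_nuisance",
    "smooth_within_mask",
    "extract_parcel_timeseries",
    "extract_roi_timeseries",
]


class CompatibilityError(ValueError):
    """Raised when two volumes do not share a grid/affine."""


def _validate_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    return affine


@dataclass
class BoldVolume:
    """A 4D BOLD series: data is (x, y, z, time), affine maps voxel -> mm."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = _validate_affine(self.affine)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got ndim={self.data.ndim}")
        if self.data.shape[3] < 3:
            raise ValueError("need at least 3 timepoints")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data contains NaN or Inf")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class RoiMask:
    """A bilateral ROI mask with per-voxel hemisphere labels (1=left, 2=right)."""

    data: np.ndarray
    affine: np.ndarray
    hemisphere: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.affine = _validate_affine(self.affine)
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.hemisphere is None:
            if arr.dtype != bool and set(np.unique(arr)) - {0} == {LEFT, RIGHT}:
                self.hemisphere = arr.astype(np.int8)
            else:
                self.hemisphere = self._infer_hemispheres(arr.astype(bool))
        else:
            self.hemisphere = np.asarray(self.hemisphere, dtype=np.int8)
            if self.hemisphere.shape != arr.shape:
                raise ValueError("hemisphere labels must match mask shape")
        self.data = np.asarray(arr, dtype=bool) if arr.dtype == bool else arr != 0
        for code, name in ((LEFT, "left"), (RIGHT, "right")):
            n = int(((self.hemisphere == code) & self.data).sum())
            if n < 4:
                raise ValueError(
                    f"{name} hemisphere has {n} voxels; at least 4 required"
                )

    def _infer_hemispheres(self, mask: np.ndarray) -> np.ndarray:
        # Split a plain binary mask at the midline of the mask's world-x extent.
        idx = np.argwhere(mask)
        if idx.size == 0:
            raise ValueError("empty mask")
        world_x = (self.affine[:3, :3] @ idx.T)[0] + self.affine[0, 3]
        mid = world_x.mean()
        hemi = np.zeros(mask.shape, dtype=np.int8)
        hemi[tuple(idx[world_x < mid].T)] = LEFT
        hemi[tuple(idx[world_x >= mid].T)] = RIGHT
        return hemi

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class AtlasLabels:
    """Integer parcellation volume; 0 is background.

    ``labels`` maps every nonzero label to a name; ``tags`` optionally marks
    parcels (e.g. phantom "rostral"/"caudal" targets).
    """

    data: np.ndarray
    affine: np.ndarray
    labels: dict[int, str]
    tags: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = _validate_affine(self.affine)
        if self.data.ndim != 3:
            raise ValueError("atlas must be 3D")
        present = set(int(v) for v in np.unique(self.data)) - {0}
        unknown = sorted(present - set(self.labels))
        if unknown:
            raise ValueError(f"atlas contains labels absent from the table: {unknown}")

    def exclude_roi_overlap(self, mask: RoiMask) -> int:
        """Zero out parcel voxels that overlap the ROI (warn); returns count."""
        overlap = (self.data != 0) & mask.data
        n = int(overlap.sum())
        if n:
            logger.warning("atlas overlaps ROI in %d voxels; excluding them", n)
            self.data = self.data.copy()
            self.data[overlap] = 0
        return n


def _mask_order(mask3d: np.ndarray) -> np.ndarray:
    """Indices of True voxels, ascending flat index with x fastest."""
    k, j, i = np.nonzero(np.transpose(mask3d, (2, 1, 0)))
    return np.stack([i, j, k], axis=1)


@dataclass
class CoordinateTable:
    """Per masked voxel: 0-based index triple, world mm coordinates, hemisphere.

    Row order is the canonical masked-voxel order (x-fastest ascending flat
    index); every voxel-wise vector downstream uses this order.
    """

    indices: np.ndarray
    world: np.ndarray
    hemisphere: np.ndarray
    affine: np.ndarray

    @classmethod
    def from_mask(cls, mask: RoiMask) -> "CoordinateTable":
        idx = _mask_order(mask.data)
        world = idx @ mask.affine[:3, :3].T + mask.affine[:3, 3]
        hemi = mask.hemisphere[tuple(idx.T)]
        return cls(indices=idx, world=world, hemisphere=hemi, affine=mask.affine)

    def __len__(self) -> int:
        return self.indices.shape[0]

    def hemi_rows(self, hemisphere: str | int) -> np.ndarray:
        code = {"left": LEFT, "right": RIGHT, LEFT: LEFT, RIGHT: RIGHT}[hemisphere]
        return np.flatnonzero(self.hemisphere == code)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "i": self.indices[:, 0],
                "j": self.indices[:, 1],
                "k": self.indices[:, 2],
                "x_mm": self.world[:, 0],
                "y_mm": self.world[:, 1],
                "z_mm": self.world[:, 2],
                "hemisphere": np.where(self.hemisphere == LEFT, "left", "right"),
            }
        )


# ---------------------------------------------------------------------------
# IO


def save_volume(vol: BoldVolume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    zooms = list(img.header.get_zooms())
    if len(zooms) == 4:
        zooms[3] = vol.tr_seconds
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_volume(path, tr_seconds: float | None = None) -> BoldVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BoldVolume(data=data, affine=np.asarray(img.affine), tr_seconds=tr_seconds)


def save_mask(mask: RoiMask, path) -> None:
    # hemisphere-coded (1=left, 2=right) so the split round-trips
    nib.save(nib.Nifti1Image(mask.hemisphere.astype(np.int16), mask.affine), str(path))


def load_mask(path) -> RoiMask:
    img = nib.load(str(path))
    arr = np.asarray(img.get_fdata()).round().astype(np.int16)
    return RoiMask(data=arr, affine=np.asarray(img.affine))


def save_atlas(atlas: AtlasLabels, path, table_path=None) -> None:
    nib.save(nib.Nifti1Image(atlas.data.astype(np.int32), atlas.affine), str(path))
    if table_path is not None:
        with open(table_path, "w") as fh:
            fh.write("label\tname\ttag\n")
            for lab in sorted(atlas.labels):
                fh.write(f"{lab}\t{atlas.labels[lab]}\t{atlas.tags.get(lab, '')}\n")


def load_atlas(path, table) -> AtlasLabels:
    """Load a parcellation. ``table`` is a {label: name} dict or a TSV path."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata()).round().astype(np.int32)
    tags: dict[int, str] = {}
    if not isinstance(table, dict):
        import pandas as pd

        df = pd.read_csv(table, sep="\t")
        labels = dict(zip(df["label"].astype(int), df["name"].astype(str)))
        if "tag" in df.columns:
            tags = {
                int(l): str(t)
                for l, t in zip(df["label"], df["tag"].fillna(""))
                if str(t)
            }
    else:
        labels = {int(k): str(v) for k, v in table.items()}
    return AtlasLabels(data=data, affine=np.asarray(img.affine), labels=labels, tags=tags)


def check_compatible(a, b, atol_mm: float = 1e-4) -> None:
    """Same 3D grid and affine (within ``atol_mm``); mismatch is a hard error."""
    shape_a = a.data.shape[:3]
    shape_b = b.data.shape[:3]
    if shape_a != shape_b:
        raise CompatibilityError(f"grid shapes differ: {shape_a} vs {shape_b}")
    if not np.allclose(a.affine, b.affine, atol=atol_mm):
        raise CompatibilityError(
            f"affines differ beyond {atol_mm} mm:\n{a.affine}\nvs\n{b.affine}"
        )


# ---------------------------------------------------------------------------
# Operations


def regress_nuisance(bold: BoldVolume, regressors: np.ndarray | None) -> BoldVolume:
    """Replace every voxel series by its residual after regressing on
    [intercept, regressors]. With no regressors this is temporal demeaning.
    """
    T = bold.n_timepoints
    if regressors is None or np.size(regressors) == 0:
        X = np.ones((T, 1))
    else:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != T:
            raise ValueError(
                f"regressors have {regressors.shape[0]} rows, series has {T} timepoints"
            )
        if regressors.shape[1] >= T:
            raise ValueError("more regressors than timepoints")
        X = np.column_stack([np.ones(T), regressors])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("regressor matrix is rank deficient (with intercept)")
    flat = bold.data.reshape(-1, T).T  # time x voxels
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    out = resid.T.reshape(bold.data.shape)
    return BoldVolume(data=out, affine=bold.affine, tr_seconds=bold.tr_seconds)


def smooth_within_mask(bold: BoldVolume, mask, fwhm_mm: float) -> BoldVolume:
    """Gaussian smoothing restricted to the mask (RoiMask or boolean array).

    Kernel weights are renormalized over in-mask voxels at every location, so
    no signal leaks across the mask boundary and a constant field is preserved
    exactly. Voxels outside the mask are returned unchanged (bit-identical).
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if isinstance(mask, RoiMask):
        check_compatible(bold, mask)
        m = mask.data
    else:
        m = np.asarray(mask, dtype=bool)
        if m.shape != bold.shape3d:
            raise CompatibilityError("mask grid does not match volume")
    if not m.any():
        raise ValueError("empty mask")
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    voxel_sizes = np.sqrt((bold.affine[:3, :3] ** 2).sum(axis=0))
    sigma_vox = sigma_mm / voxel_sizes
    mf = m.astype(float)
    norm = ndimage.gaussian_filter(mf, sigma_vox, mode="constant")
    out = bold.data.copy()
    for t in range(bold.n_timepoints):
        num = ndimage.gaussian_filter(bold.data[..., t] * mf, sigma_vox, mode="constant")
        frame = out[..., t]
        frame[m] = num[m] / norm[m]
    return BoldVolume(data=out, affine=bold.affine, tr_seconds=bold.tr_seconds)


def extract_parcel_timeseries(
    bold: BoldVolume, atlas: AtlasLabels
) -> tuple[np.ndarray, list[int]]:
    """Mean time series per parcel, rows ordered by ascending label.

    Empty parcels (in the table but absent from the volume) are dropped with a
    warning. Returns (parcels x time matrix, ordered label list).
    """
    check_compatible(bold, atlas)
    rows, kept = [], []
    for lab in sorted(atlas.labels):
        sel = atlas.data == lab
        if not sel.any():
            logger.warning("parcel %d (%s) is empty; dropped", lab, atlas.labels[lab])
            continue
        rows.append(bold.data[sel].mean(axis=0))
        kept.append(lab)
    if not rows:
        raise ValueError("all parcels are empty")
    return np.asarray(rows), kept


def extract_roi_timeseries(
    bold: BoldVolume, mask: RoiMask
) -> tuple[np.ndarray, CoordinateTable]:
    """ROI voxel series (voxels x time) in canonical CoordinateTable order.

    Zero-variance voxel series are flagged with a warning; they are retained
    here and handled by the gradient pipeline (excluded from correlations,
    imputed from in-mask neighbours).
    """
    check_compatible(bold, mask)
    coords = CoordinateTable.from_mask(mask)
    ts = bold.data[tuple(coords.indices.T)]
    flat = np.flatnonzero(ts.std(axis=1) == 0)
    if flat.size:
        logger.warning("%d ROI voxel(s) have zero temporal variance", flat.size)
    return ts, coords
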