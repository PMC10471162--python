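"""Connectopic model of a single gradient estimation problem.

`ConnectopicModel` is built from ROI voxel series and parcel mean series (or
directly from volumes via `from_volumes`); `fit()` runs fingerprints ->
eta-squared similarity -> per-hemisphere connected graph -> Laplacian
eigenmap -> oriented gradient -> bilateral trend-surface fit, and returns a
`ConnectopicResults` carrying every intermediate along with a text summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from . import connectopic, trend
from .volumes import (
    AtlasLabels,
    BoldVolume,
    CoordinateTable,
    RoiMask,
    extract_parcel_timeseries,
    extract_roi_timeseries,
    regress_nuisance,
    smooth_within_mask,
)

logger = logging.getLogger(__name__)

__all__ = ["ConnectopicModel", "ConnectopicResults", "save_gradient"]


class ConnectopicModel:
    """Estimate the dominant functional-connectivity gradient within an ROI.

    Parameters
    ----------
    roi_ts : (voxels, time) array in CoordinateTable order.
    parcel_ts : (parcels, time) array of target parcel mean series.
    coords : CoordinateTable for the ROI voxels.
    parcel_labels : optional parcel label list matching parcel_ts rows.
    """

    def __init__(self, roi_ts, parcel_ts, coords: CoordinateTable,
                 parcel_labels=None):
        self.roi_ts = np.asarray(roi_ts, dtype=float)
        self.parcel_ts = np.asarray(parcel_ts, dtype=float)
        if self.roi_ts.shape[0] != len(coords):
            raise ValueError("roi_ts rows must match the coordinate table")
        self.coords = coords
        self.parcel_labels = parcel_labels

    @classmethod
    def from_volumes(cls, bold: BoldVolume, mask: RoiMask, atlas: AtlasLabels,
                     fwhm_mm: float | None = 3.0,
                     nuisance: np.ndarray | None = None) -> "ConnectopicModel":
        """Standard preprocessing path: optional nuisance regression, then
        mask-constrained smoothing, then time-series extraction."""
        atlas.exclude_roi_overlap(mask)
        if nuisance is not None:
            bold = regress_nuisance(bold, nuisance)
        if fwhm_mm:
            bold = smooth_within_mask(bold, mask, fwhm_mm)
        roi_ts, coords = extract_roi_timeseries(bold, mask)
        parcel_ts, labels = extract_parcel_timeseries(bold, atlas)
        return cls(roi_ts, parcel_ts, coords, parcel_labels=labels)

    def _impute_flat_voxels(self, values: np.ndarray, flat: np.ndarray) -> np.ndarray:
        """Gradient value of a zero-variance voxel = mean over in-mask
        6-neighbours (repeated until assigned)."""
        values = values.copy()
        idx = {tuple(v): i for i, v in enumerate(self.coords.indices)}
        todo = list(flat)
        offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                            [0, -1, 0], [0, 0, 1], [0, 0, -1]])
        for _ in range(len(self.coords)):
            if not todo:
                break
            remaining = []
            for i in todo:
                nb = [idx.get(tuple(self.coords.indices[i] + o)) for o in offsets]
                nb = [j for j in nb if j is not None and np.isfinite(values[j])]
                if nb:
                    values[i] = float(np.mean([values[j] for j in nb]))
                    logger.warning("imputed gradient at zero-variance voxel %s "
                                   "from %d neighbours",
                                   tuple(self.coords.indices[i]), len(nb))
                else:
                    remaining.append(i)
            if len(remaining) == len(todo):
                values[remaining] = 0.5
                break
            todo = remaining
        return values

    def fit(self, n_components: int = 1) -> "ConnectopicResults":
        flat = np.flatnonzero(self.roi_ts.std(axis=1) == 0)
        if flat.size:
            keep = np.setdiff1d(np.arange(len(self.coords)), flat)
            sub = CoordinateTable(self.coords.indices[keep],
                                  self.coords.world[keep],
                                  self.coords.hemisphere[keep],
                                  self.coords.affine)
            F_sub = connectopic.fingerprints(self.roi_ts[keep], self.parcel_ts)
            S_sub = connectopic.similarity_matrix(F_sub)
            g_sub = connectopic.compute_gradient(S_sub, sub)
            values = np.full(len(self.coords), np.nan)
            values[keep] = g_sub.values
            values = self._impute_flat_voxels(values, flat)
            gradient = connectopic.GradientMap(
                values=values, coords=self.coords,
                thresholds=g_sub.thresholds, eigenvalues=g_sub.eigenvalues,
                flipped=g_sub.flipped, source=g_sub.source)
            F = np.full((len(self.coords), self.parcel_ts.shape[0]), np.nan)
            F[keep] = F_sub
            S = None
        else:
            F = connectopic.fingerprints(self.roi_ts, self.parcel_ts)
            S = connectopic.similarity_matrix(F)
            gradient = connectopic.compute_gradient(S, self.coords)
        left, right = trend.fit_bilateral(gradient.values, self.coords)
        return ConnectopicResults(model=self, fingerprints=F, similarity=S,
                                  gradient=gradient, tsm_left=left,
                                  tsm_right=right)


@dataclass
class ConnectopicResults:
    model: ConnectopicModel
    fingerprints: np.ndarray
    similarity: np.ndarray | None
    gradient: connectopic.GradientMap
    tsm_left: trend.TrendSurfaceResults
    tsm_right: trend.TrendSurfaceResults

    @property
    def asymmetry(self) -> trend.AsymmetryProfile:
        return trend.asymmetry(self.tsm_left, self.tsm_right)

    @property
    def partition(self) -> np.ndarray:
        return connectopic.partition_rostral_caudal(self.gradient)

    def projection(self) -> dict:
        return connectopic.projection_map(self.fingerprints, self.partition,
                                          parcel_ids=self.model.parcel_labels)

    def tsm_params(self) -> np.ndarray:
        """The 18 bilateral trend-surface coefficients (left 9, right 9)."""
        return np.concatenate([self.tsm_left.params, self.tsm_right.params])

    def summary(self) -> str:
        g = self.gradient
        lines = [
            "Connectopic gradient fit",
            "=" * 60,
            f"voxels: {len(g.coords)}   parcels: {self.model.parcel_ts.shape[0]}"
            f"   timepoints: {self.model.roi_ts.shape[1]}",
        ]
        for h in ("left", "right"):
            lam = g.eigenvalues.get(h, [])
            lam_s = ", ".join(f"{v:.5f}" for v in lam)
            lines.append(
                f"{h:>6}: graph threshold {g.thresholds.get(h, float('nan')):.4f}"
                f"   lambda1 {lam_s}   flipped: {g.flipped.get(h)}"
            )
        lines.append("-" * 60)
        lines.append(f"{'term':>6} {'left':>10} {'right':>10} {'|L-R|':>10}")
        asym = self.asymmetry
        for i, t in enumerate(trend.TSM_TERMS):
            lines.append(f"{t:>6} {self.tsm_left.params[i]:>10.5f} "
                         f"{self.tsm_right.params[i]:>10.5f} {asym.diffs[i]:>10.5f}")
        lines.append(f"{'R2':>6} {self.tsm_left.r2:>10.4f} {self.tsm_right.r2:>10.4f}"
                     f" {asym.index:>10.5f}  (asymmetry index)")
        return "\n".join(lines)


def save_gradient(gradient: connectopic.GradientMap, shape, path,
                  sidecar_path=None) -> None:
    """Write a GradientMap as a scalar NIfTI plus a JSON sidecar."""
    import nibabel as nib

    vol = gradient.to_volume(tuple(shape))
    nib.save(nib.Nifti1Image(vol.astype(np.float32), gradient.coords.affine),
             str(path))
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"thresholds": gradient.thresholds,
                       "eigenvalues": gradient.eigenvalues,
                       "flipped": gradient.flipped,
                       "source": gradient.source}, fh, indent=1)
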