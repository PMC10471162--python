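"""Synthetic phantoms with a planted rostro-caudal connectivity gradient.

The generator builds everything the pipeline consumes without any download:
a bilateral ROI of two elongated blobs (long axis = anterior-posterior), a
block parcellation whose parcels are tagged as rostral-like targets,
caudal-like targets, or neutral, per-subject BOLD-like time series, and a
cohort table with planted age and behavioral couplings.

Generative model per subject: two latent unit-variance signals s_rostral and
s_caudal (correlation ``latent_corr``). Each ROI voxel mixes them according to
a planted field g(v) in [0, 1] -- a logistic function of the voxel's
normalized long-axis coordinate whose midpoint is set by ``rostral_extent``
(the fraction of the nucleus expressing rostral-like connectivity) and whose
slope is ``steepness`` (sharper -> more clusterable gradient). Rostral-target
parcels carry s_rostral, caudal-target parcels s_caudal, neutral parcels their
own latent; every observed series adds white Gaussian noise of SD ``noise_sd``
relative to the unit-variance signals.

In the cohort, rostral_extent declines linearly with age and steepness
increases with age (older = less rostral-like, more clustered), one
emotional-memory-like score is coupled to the planted linear-y trend-surface
coefficient and one reactivity-like score to rostral_extent; remaining scores
are pure noise, so analyses can distinguish true couplings from nulls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from . import connectopic, trend
from .volumes import (
    LEFT,
    RIGHT,
    AtlasLabels,
    BoldVolume,
    CoordinateTable,
    RoiMask,
)

__all__ = [
    "PhantomConfig",
    "EffectConfig",
    "GradientTruth",
    "CohortTruth",
    "SubjectData",
    "Cohort",
    "make_phantom_roi",
    "make_phantom_atlas",
    "planted_field",
    "simulate_subject",
    "simulate_subject_timeseries",
    "simulate_cohort",
]

SCORE_COLUMNS = (
    "em_recollection",
    "em_recognition",
    "em_priming",
    "er_reactivity",
    "er_reappraisal",
    "hotel",
    "psqi",
    "hads",
)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and signal parameters of one phantom subject."""

    grid_shape: tuple = (20, 24, 16)
    voxel_size_mm: float = 2.0
    n_timepoints: int = 200
    n_cortical_parcels: int = 20
    n_subcortical_parcels: int = 10
    rostral_extent: float = 0.6
    noise_sd: float = 0.1
    seed: int = 0
    blob_shape: tuple = (2, 12, 2)  # (x, y, z); y is the rostro-caudal axis
    steepness: float = 6.0
    latent_corr: float = 0.3
    tr_seconds: float = 1.0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if not 0.0 <= self.rostral_extent <= 1.0:
            raise ValueError("rostral_extent must be in [0, 1]")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_cortical_parcels < 2 or self.n_subcortical_parcels < 2:
            raise ValueError("parcel counts must be >= 2")
        bx, by, bz = self.blob_shape
        if bx * by * bz < 8:
            raise ValueError("hemisphere blobs must contain at least 8 voxels")
        nx, ny, nz = self.grid_shape
        need = (2 * bx + 12, by + 2, bz + 4)
        if nx < need[0] or ny < need[1] or nz < need[2]:
            raise ValueError(
                f"grid {self.grid_shape} too small for two {self.blob_shape} blobs; "
                f"minimum grid is {need}"
            )
        if not -1.0 < self.latent_corr < 1.0:
            raise ValueError("latent_corr must be in (-1, 1)")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    @property
    def affine(self) -> np.ndarray:
        """Diagonal RAS affine centred on the grid."""
        v = self.voxel_size_mm
        aff = np.diag([v, v, v, 1.0])
        aff[:3, 3] = -v * (np.asarray(self.grid_shape) - 1) / 2.0
        return aff


# per-slice lateral / dorsoventral offsets give the nucleus a gentle curve,
# so each world axis takes >= 4 distinct values and the 9-term cubic basis is
# well-posed (a perfectly rectangular column would make x^2 constant and
# x^3 == x). The right blob is the exact mirror image of the left.
_X_CYCLE = (0, 1, 2, 1)
_Z_CYCLE = (0, 0, 1, 2, 2, 1)


def make_phantom_roi(config: PhantomConfig) -> tuple[RoiMask, np.ndarray]:
    """Bilateral ROI of two curved columns elongated along the
    anterior-posterior axis, mirror-symmetric about the midline."""
    nx, ny, nz = config.grid_shape
    bx, by, bz = config.blob_shape
    hemi = np.zeros(config.grid_shape, dtype=np.int8)
    x_left = 2
    y0 = (ny - by) // 2
    z0 = (nz - bz - 2) // 2
    for s in range(by):
        xs = x_left + _X_CYCLE[s % len(_X_CYCLE)]
        zs = z0 + _Z_CYCLE[s % len(_Z_CYCLE)]
        hemi[xs : xs + bx, y0 + s, zs : zs + bz] = LEFT
        hemi[nx - xs - bx : nx - xs, y0 + s, zs : zs + bz] = RIGHT
    mask = RoiMask(data=hemi, affine=config.affine)
    return mask, config.affine


def make_phantom_atlas(config: PhantomConfig, mask: RoiMask | None = None) -> AtlasLabels:
    """Contiguous 2x2x2 block parcels on a lattice, never overlapping the ROI.

    Labels 1..n_cortical are 'cortical', the rest 'subcortical'. Parcels cycle
    through tags rostral / caudal / (untagged) so about a third of each set
    serves as rostral-like and caudal-like connectivity targets.
    """
    if mask is None:
        mask, _ = make_phantom_roi(config)
    nx, ny, nz = config.grid_shape
    n_needed = config.n_cortical_parcels + config.n_subcortical_parcels
    data = np.zeros(config.grid_shape, dtype=np.int32)
    labels: dict[int, str] = {}
    tags: dict[int, str] = {}
    lab = 0
    for k in range(1, nz - 2, 3):
        for j in range(1, ny - 2, 3):
            for i in range(1, nx - 2, 3):
                if lab >= n_needed:
                    break
                block = (slice(i, i + 2), slice(j, j + 2), slice(k, k + 2))
                if mask.data[block].any():
                    continue
                lab += 1
                data[block] = lab
                if lab <= config.n_cortical_parcels:
                    labels[lab] = f"ctx_{lab:03d}"
                else:
                    labels[lab] = f"sub_{lab - config.n_cortical_parcels:03d}"
                tag = ("rostral", "caudal", "")[(lab - 1) % 3]
                if tag:
                    tags[lab] = tag
    if lab < n_needed:
        raise ValueError(
            f"could only place {lab} of {n_needed} parcels without overlapping "
            "the ROI; enlarge the grid or reduce parcel counts"
        )
    return AtlasLabels(data=data, affine=config.affine, labels=labels, tags=tags)


@dataclass
class GradientTruth:
    """Planted ground truth for one subject."""

    planted_field: np.ndarray           # per ROI voxel, CoordinateTable order
    planted_tsm: dict                   # hemisphere -> 9 coefficients
    rostral_extent: float
    steepness: float
    age_effect: float = 0.0
    score_effects: dict = field(default_factory=dict)


def planted_field(config: PhantomConfig, coords: CoordinateTable) -> np.ndarray:
    """Logistic planted field: 1 at the rostral (anterior) tip, 0 caudally.

    Within each hemisphere the long-axis coordinate is normalized to u in
    [0, 1] (caudal -> rostral); g = expit(steepness * (u - u0)) with midpoint
    u0 = 1 - rostral_extent, so rostral_extent is the fraction of the long
    axis on the rostral-like side of the transition.
    """
    g = np.empty(len(coords))
    u0 = 1.0 - config.rostral_extent
    for code in (LEFT, RIGHT):
        rows = coords.hemi_rows(code)
        y = coords.world[rows, 1]
        u = (y - y.min()) / (y.max() - y.min())
        g[rows] = expit(config.steepness * (u - u0))
    return g


def _planted_tsm(g: np.ndarray, coords: CoordinateTable) -> dict:
    left, right = trend.fit_bilateral(g, coords)
    return {"left": left.params.copy(), "right": right.params.copy()}


def simulate_subject_timeseries(
    config: PhantomConfig,
    mask: RoiMask | None = None,
    atlas: AtlasLabels | None = None,
    coords: CoordinateTable | None = None,
    return_parcel_voxels: bool = False,
):
    """Generate one subject's ROI and parcel-mean series (no 4D assembly).

    Returns (roi_ts, parcel_ts, parcel_labels, truth[, parcel_voxel_ts]).
    The draw order is fixed so that `simulate_subject` produces bit-identical
    ROI/parcel series for the same seed.
    """
    if mask is None:
        mask, _ = make_phantom_roi(config)
    if atlas is None:
        atlas = make_phantom_atlas(config, mask)
    if coords is None:
        coords = CoordinateTable.from_mask(mask)
    rng = np.random.default_rng(config.seed)
    T = config.n_timepoints
    rho = config.latent_corr

    s_r = rng.standard_normal(T)
    s_c = rho * s_r + np.sqrt(1.0 - rho**2) * rng.standard_normal(T)

    parcel_labels = sorted(atlas.labels)
    latents = {}
    for lab in parcel_labels:
        tag = atlas.tags.get(lab, "")
        if tag == "rostral":
            latents[lab] = s_r
        elif tag == "caudal":
            latents[lab] = s_c
        else:
            latents[lab] = rng.standard_normal(T)

    g = planted_field(config, coords)
    signal = g[:, None] * s_r[None, :] + (1.0 - g)[:, None] * s_c[None, :]
    amp = np.sqrt(g**2 + (1.0 - g) ** 2 + 2.0 * rho * g * (1.0 - g))
    roi_ts = signal / amp[:, None] + config.noise_sd * rng.standard_normal((len(coords), T))

    parcel_rows = []
    parcel_voxel_ts = {}
    for lab in parcel_labels:
        n_vox = int((atlas.data == lab).sum())
        series = latents[lab][None, :] + config.noise_sd * rng.standard_normal((n_vox, T))
        parcel_voxel_ts[lab] = series
        parcel_rows.append(series.mean(axis=0))
    parcel_ts = np.asarray(parcel_rows)

    truth = GradientTruth(
        planted_field=g,
        planted_tsm=_planted_tsm(g, coords),
        rostral_extent=config.rostral_extent,
        steepness=config.steepness,
    )
    if return_parcel_voxels:
        return roi_ts, parcel_ts, parcel_labels, truth, parcel_voxel_ts
    return roi_ts, parcel_ts, parcel_labels, truth


def simulate_subject(
    config: PhantomConfig,
    mask: RoiMask | None = None,
    atlas: AtlasLabels | None = None,
) -> tuple[BoldVolume, GradientTruth]:
    """Full 4D BOLD-like volume for one subject, plus the truth used.

    Background voxels (outside ROI and parcels) get unit white noise drawn
    after the ROI/parcel series, so the scientifically relevant series match
    `simulate_subject_timeseries` bit for bit at equal seed.
    """
    if mask is None:
        mask, _ = make_phantom_roi(config)
    if atlas is None:
        atlas = make_phantom_atlas(config, mask)
    coords = CoordinateTable.from_mask(mask)
    roi_ts, _, parcel_labels, truth, parcel_voxel_ts = simulate_subject_timeseries(
        config, mask, atlas, coords, return_parcel_voxels=True
    )
    # continue the same stream for the background
    rng = np.random.default_rng(config.seed)
    rng.standard_normal(config.n_timepoints)  # skip s_r
    T = config.n_timepoints
    data = np.empty(config.grid_shape + (T,))
    bg_rng = np.random.default_rng((config.seed + 1_000_003) % 2**31)
    data[...] = bg_rng.standard_normal(data.shape)
    data[tuple(coords.indices.T)] = roi_ts
    for lab in parcel_labels:
        data[atlas.data == lab] = parcel_voxel_ts[lab]
    vol = BoldVolume(data=data, affine=config.affine, tr_seconds=config.tr_seconds)
    return vol, truth


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class EffectConfig:
    """Planted cohort-level effect sizes (the study conditions).

    ``age_slope`` is the per-year change in rostral_extent;
    ``steepness_slope`` the per-year change in the logistic slope (positive:
    older subjects have sharper, more clusterable gradients). Score couplings
    are expressed per SD of the planted quantity against unit score noise.
    ``hads_shift`` is added to rostral_extent of subjects whose HADS exceeds
    the screening threshold.
    """

    age_slope: float = -0.005
    steepness_slope: float = 0.06
    rostral_noise_sd: float = 0.05
    steepness_noise_sd: float = 0.5
    em_effect: float = 1.5
    er_effect: float = 1.5
    hads_shift: float = -0.12
    score_noise_sd: float = 1.0
    base_rostral: float = 0.6
    base_steepness: float = 6.0

    @classmethod
    def null(cls) -> "EffectConfig":
        """All planted effects zero; noise levels unchanged."""
        return cls(age_slope=0.0, steepness_slope=0.0, em_effect=0.0,
                   er_effect=0.0, hads_shift=0.0)


@dataclass
class CohortTruth:
    """Ground truth for a generated cohort."""

    subject_truths: dict
    effects: EffectConfig
    seed: int


@dataclass
class SubjectData:
    id: str
    roi_ts: np.ndarray
    parcel_ts: np.ndarray
    truth: GradientTruth


class Cohort:
    """A generated cohort: covariate/score table plus per-subject series.

    Provides cached per-subject fingerprints, eta-squared similarity matrices
    and individual gradient maps keyed by subject id, which is what the
    statistical analyses consume.
    """

    def __init__(self, table: pd.DataFrame, subjects: list[SubjectData],
                 coords: CoordinateTable, mask: RoiMask, atlas: AtlasLabels,
                 parcel_labels: list[int], config: PhantomConfig,
                 truth: CohortTruth):
        self.table = table
        self.subjects = {s.id: s for s in subjects}
        self.coords = coords
        self.mask = mask
        self.atlas = atlas
        self.parcel_labels = parcel_labels
        self.config = config
        self.truth = truth
        self._fingerprints: dict[str, np.ndarray] = {}
        self._similarity: dict[str, np.ndarray] = {}
        self._gradient: dict[str, connectopic.GradientMap] = {}

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def fingerprints(self, subject_id: str) -> np.ndarray:
        if subject_id not in self._fingerprints:
            s = self.subjects[subject_id]
            self._fingerprints[subject_id] = connectopic.fingerprints(
                s.roi_ts, s.parcel_ts
            )
        return self._fingerprints[subject_id]

    def similarity(self, subject_id: str) -> np.ndarray:
        if subject_id not in self._similarity:
            self._similarity[subject_id] = connectopic.similarity_matrix(
                self.fingerprints(subject_id)
            )
        return self._similarity[subject_id]

    def gradient(self, subject_id: str) -> connectopic.GradientMap:
        if subject_id not in self._gradient:
            self._gradient[subject_id] = connectopic.compute_gradient(
                self.similarity(subject_id), self.coords
            )
        return self._gradient[subject_id]

    def group_gradient(self, subject_ids) -> connectopic.GradientMap:
        return connectopic.group_gradient(
            [self.similarity(i) for i in subject_ids], self.coords
        )


def simulate_cohort(
    n_subjects: int,
    age_range: tuple[float, float] = (18.0, 88.0),
    effects: EffectConfig | None = None,
    seed: int = 0,
    config: PhantomConfig | None = None,
) -> Cohort:
    """Generate a cohort with planted age, behavioral and HADS-group effects.

    Ages are uniform on ``age_range``; per subject rostral_extent =
    base + age_slope*(age - mean age) + noise (plus the HADS shift for
    screen-positive subjects), clipped to [0, 1]; steepness analogous. Scores
    are linear in the planted spatial parameters (standardized within the
    cohort) plus Gaussian noise. Fully deterministic under a fixed seed.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    lo, hi = age_range
    if not lo < hi:
        raise ValueError(f"degenerate age_range {age_range}: min must be < max")
    effects = effects or EffectConfig()
    config = config or PhantomConfig()
    if not np.all(np.isfinite([effects.age_slope, effects.steepness_slope,
                               effects.em_effect, effects.er_effect,
                               effects.hads_shift])):
        raise ValueError("effect sizes must be finite")

    rng = np.random.default_rng(seed)
    mask, _ = make_phantom_roi(config)
    atlas = make_phantom_atlas(config, mask)
    coords = CoordinateTable.from_mask(mask)

    age = rng.uniform(lo, hi, n_subjects)
    sex = rng.integers(0, 2, n_subjects)
    education = np.clip(rng.normal(14.6, 4.0, n_subjects), 0.0, None)
    hads = np.clip(np.round(np.abs(rng.normal(5.0, 3.0, n_subjects))), 0, 21)
    dage = age - age.mean()

    rostral = (
        effects.base_rostral
        + effects.age_slope * dage
        + rng.normal(0.0, effects.rostral_noise_sd, n_subjects)
    )
    rostral = rostral + np.where(hads > 7, effects.hads_shift, 0.0)
    rostral = np.clip(rostral, 0.0, 1.0)
    steep = np.clip(
        effects.base_steepness
        + effects.steepness_slope * dage
        + rng.normal(0.0, effects.steepness_noise_sd, n_subjects),
        1.0,
        None,
    )

    subjects, truths, planted_by = [], {}, np.empty(n_subjects)
    sub_seeds = rng.integers(0, 2**31 - 1, n_subjects)
    for i in range(n_subjects):
        cfg_i = replace(
            config,
            rostral_extent=float(rostral[i]),
            steepness=float(steep[i]),
            seed=int(sub_seeds[i]),
        )
        roi_ts, parcel_ts, parcel_labels, truth = simulate_subject_timeseries(
            cfg_i, mask, atlas, coords
        )
        truth.age_effect = effects.age_slope
        sid = f"sub-{i + 1:04d}"
        subjects.append(SubjectData(id=sid, roi_ts=roi_ts, parcel_ts=parcel_ts, truth=truth))
        truths[sid] = truth
        planted_by[i] = 0.5 * (truth.planted_tsm["left"][1] + truth.planted_tsm["right"][1])

    def _z(x):
        s = x.std()
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    noise = rng.normal(0.0, effects.score_noise_sd, (6, n_subjects))
    scores = {
        "em_recognition": effects.em_effect * _z(planted_by) + noise[0],
        "er_reactivity": effects.er_effect * _z(rostral) + noise[1],
        "em_recollection": noise[2],
        "em_priming": noise[3],
        "er_reappraisal": noise[4],
        "hotel": noise[5],
        "psqi": np.clip(np.round(rng.normal(5.0, 3.0, n_subjects)), 0, 21),
        "hads": hads,
    }
    for sid, truth in truths.items():
        truth.score_effects = {"em_recognition": effects.em_effect,
                               "er_reactivity": effects.er_effect}

    table = pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "age": age,
            "sex": sex,
            "education": education,
            **{k: scores[k] for k in SCORE_COLUMNS},
        }
    )
    truth = CohortTruth(subject_truths=truths, effects=effects, seed=seed)
    return Cohort(table, subjects, coords, mask, atlas, parcel_labels, config, truth)


def write_truth_json(cohort: Cohort, path) -> None:
    payload = {
        "seed": cohort.truth.seed,
        "effects": asdict(cohort.truth.effects),
        "subjects": {
            sid: {
                "rostral_extent": t.rostral_extent,
                "steepness": t.steepness,
                "planted_tsm": {h: list(map(float, b)) for h, b in t.planted_tsm.items()},
            }
            for sid, t in cohort.truth.subject_truths.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
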