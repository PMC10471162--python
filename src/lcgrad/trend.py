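"""Third-order trend-surface modelling of a gradient's spatial layout.

A gradient is summarized per hemisphere by regressing its voxel values on the
nine pure-power coordinate terms x, y, z, x^2, y^2, z^2, x^3, y^3, z^3 (no
cross-terms), built from per-hemisphere z-scored world coordinates. The fit is
Bayesian linear regression with an isotropic Gaussian prior on the slopes and
an unpenalized intercept; the prior precision alpha and noise precision tau
are set by evidence maximization (MacKay fixed-point updates on the effective
degrees of freedom), which reduces to ordinary least squares when the data
dominate. Left-hemisphere x is sign-flipped before z-scoring so "lateral" is
positive on both sides and coefficients are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import LEFT, CoordinateTable

__all__ = [
    "TSM_TERMS",
    "TsmBasis",
    "tsm_basis",
    "TrendSurfaceModel",
    "TrendSurfaceResults",
    "fit_tsm",
    "fit_bilateral",
    "AsymmetryProfile",
    "asymmetry",
]

TSM_TERMS = ("x", "y", "z", "x2", "y2", "z2", "x3", "y3", "z3")
_AXES = ("x", "y", "z")


@dataclass
class TsmBasis:
    """Design matrix (voxels x 9) of pure coordinate powers.

    Column order is fixed: x, y, z, x^2, y^2, z^2, x^3, y^3, z^3, each a power
    of the per-hemisphere z-scored (and, on the left, x-flipped) mm
    coordinate. The z-scoring parameters are stored for reproducibility.
    """

    X: np.ndarray
    hemisphere: str
    center: np.ndarray
    scale: np.ndarray
    flip_x: bool
    names: tuple = TSM_TERMS


def tsm_basis(coords: CoordinateTable, hemisphere: str) -> TsmBasis:
    rows = coords.hemi_rows(hemisphere)
    if rows.size < 10:
        raise ValueError(
            f"{hemisphere} hemisphere has {rows.size} voxels; >= 10 required for a 9-term fit"
        )
    w = coords.world[rows].astype(float).copy()
    flip = hemisphere in ("left", LEFT)
    if flip:
        w[:, 0] = -w[:, 0]  # lateral positive on both sides
    center = w.mean(axis=0)
    scale = w.std(axis=0)
    for ax, s in zip(_AXES, scale):
        if s == 0:
            raise ValueError(f"zero spatial variance along {ax} axis; cannot build basis")
    zc = (w - center) / scale
    X = np.column_stack([zc, zc**2, zc**3])
    return TsmBasis(X=X, hemisphere=hemisphere, center=center, scale=scale, flip_x=flip)


@dataclass
class TrendSurfaceResults:
    """Posterior-mean TSM coefficients and fit diagnostics."""

    params: np.ndarray          # 9 slope coefficients, TSM_TERMS order
    intercept: float
    alpha: float                # prior precision on the slopes
    noise_precision: float
    r2: float
    converged: bool
    n_iter: int
    hemisphere: str
    evidence: np.ndarray = field(default_factory=lambda: np.empty(0))
    basis: TsmBasis | None = None

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        if X is None:
            X = self.basis.X
        return self.intercept + X @ self.params

    def summary(self) -> str:
        lines = [
            f"Trend surface fit ({self.hemisphere} hemisphere)",
            f"  n voxels: {self.basis.X.shape[0] if self.basis is not None else '?'}"
            f"    R2: {self.r2:.4f}    converged: {self.converged} ({self.n_iter} it)",
            f"  prior precision alpha: {self.alpha:.4g}"
            f"    noise precision: {self.noise_precision:.4g}",
            f"  intercept: {self.intercept:+.4f}",
        ]
        for name, b in zip(TSM_TERMS, self.params):
            lines.append(f"  beta_{name:<3s} {b:+.5f}")
        return "\n".join(lines)


class TrendSurfaceModel:
    """Evidence-maximized Bayesian ridge regression of gradient values on a
    third-order coordinate basis.

    Parameters
    ----------
    values : array, one gradient value per basis row.
    basis : TsmBasis for the matching hemisphere.
    """

    ALPHA_MAX = 1e12
    ALPHA_MIN = 1e-10
    TAU_MAX = 1e12

    def __init__(self, values: np.ndarray, basis: TsmBasis):
        y = np.asarray(values, dtype=float).ravel()
        if y.size != basis.X.shape[0]:
            raise ValueError("values and basis rows do not match")
        self.y = y
        self.basis = basis

    def fit(self, tol: float = 1e-6, max_iter: int = 200) -> TrendSurfaceResults:
        X = self.basis.X
        n, p = X.shape
        xm = X.mean(axis=0)
        Xc = X - xm
        ym = self.y.mean()
        yc = self.y - ym
        tss = float(yc @ yc)

        # one eigendecomposition serves every fixed-point iteration
        XtX = Xc.T @ Xc
        Xty = Xc.T @ yc
        evals, evecs = np.linalg.eigh(XtX)
        evals = np.clip(evals, 0.0, None)
        Pty = evecs.T @ Xty

        alpha = 1.0
        tau = 1.0 / tss * n if tss > 0 else 1.0
        converged = False
        evidence = []
        beta = np.zeros(p)
        rss = tss
        for it in range(1, max_iter + 1):
            denom = alpha + tau * evals
            beta = evecs @ (tau * Pty / denom)
            resid = yc - Xc @ beta
            rss = float(resid @ resid)
            gamma = float(np.sum(tau * evals / denom))
            b2 = float(beta @ beta)
            alpha_new = gamma / b2 if b2 > 0 else self.ALPHA_MAX
            alpha_new = float(np.clip(alpha_new, self.ALPHA_MIN, self.ALPHA_MAX))
            tau_new = (n - gamma) / rss if rss > 0 else self.TAU_MAX
            tau_new = float(np.clip(tau_new, 1e-12, self.TAU_MAX))
            evidence.append(self._log_evidence(alpha, tau, evals, rss, b2, n, p))
            if abs(alpha_new - alpha) <= tol * alpha:
                alpha, tau = alpha_new, tau_new
                converged = True
                break
            alpha, tau = alpha_new, tau_new
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        intercept = float(ym - xm @ beta)
        return TrendSurfaceResults(
            params=beta,
            intercept=intercept,
            alpha=alpha,
            noise_precision=tau,
            r2=float(r2),
            converged=converged,
            n_iter=it,
            hemisphere=self.basis.hemisphere,
            evidence=np.asarray(evidence),
            basis=self.basis,
        )

    @staticmethod
    def _log_evidence(alpha, tau, evals, rss, b2, n, p) -> float:
        logdet_A = float(np.sum(np.log(alpha + tau * evals)))
        return 0.5 * (
            p * np.log(alpha)
            + n * np.log(tau)
            - tau * rss
            - alpha * b2
            - logdet_A
            - n * np.log(2 * np.pi)
        )


def fit_tsm(values: np.ndarray, basis: TsmBasis, **kwargs) -> TrendSurfaceResults:
    """Functional wrapper around TrendSurfaceModel(...).fit()."""
    return TrendSurfaceModel(values, basis).fit(**kwargs)


def fit_bilateral(values: np.ndarray, coords: CoordinateTable, **kwargs):
    """Independent TSM fit per hemisphere; returns (left, right)."""
    values = np.asarray(values, dtype=float)
    out = []
    for hemisphere in ("left", "right"):
        rows = coords.hemi_rows(hemisphere)
        basis = tsm_basis(coords, hemisphere)
        out.append(TrendSurfaceModel(values[rows], basis).fit(**kwargs))
    return tuple(out)


@dataclass
class AsymmetryProfile:
    """Entrywise |beta_L - beta_R| and its Euclidean norm."""

    diffs: np.ndarray
    index: float
    names: tuple = TSM_TERMS


def asymmetry(left: TrendSurfaceResults, right: TrendSurfaceResults) -> AsymmetryProfile:
    d = np.abs(np.asarray(left.params) - np.asarray(right.params))
    return AsymmetryProfile(diffs=d, index=float(np.linalg.norm(d)))
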