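"""Statistical core of the multi-parametric screen analysis.

Per plate: compute the Z'-factor of every feature between active-control
(AC, +DOX) and negative-control (NC, -DOX) wells, keep the most separating
features, fit a Gaussian model (mean + shrunk covariance) to each control
population, and score every well by its Mahalanobis distance (MHD) to both
models.  Plate quality is the Z'-factor between the AC and NC wells'
MHD-to-AC distributions.

Z' = 1 - 3(sigma_+ + sigma_-) / |mu_+ - mu_-|   (bounded above by 1;
values above ~0.5 indicate an excellent assay window).

Covariance shrinkage uses the trace-identity target,
Sigma = (1-lambda) S + lambda tr(S)/d I, which keeps the model positive
definite even when the number of control wells is close to (or below) the
number of selected features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .plate_model import WellRole


class DegenerateSeparationError(ValueError):
    """Control means coincide; the Z'-factor is undefined."""


class NoSeparatingFeaturesError(ValueError):
    """No feature's Z'-factor clears the selection floor."""


class SingularCovarianceError(ValueError):
    """Control covariance is not positive definite after shrinkage."""


@dataclass(frozen=True)
class ZPrimeResult:
    zprime: float
    n_plus: int
    n_minus: int


def zprime(plus_values, minus_values) -> ZPrimeResult:
    """Z'-factor between two control populations (sample SDs, ddof=1).

    Symmetric in its arguments; equals 1 exactly when both SDs vanish and
    the means differ; raises :class:`DegenerateSeparationError` when the
    means coincide.
    """
    plus = np.asarray(plus_values, dtype=float)
    minus = np.asarray(minus_values, dtype=float)
    if plus.size < 2 or minus.size < 2:
        raise ValueError(
            f"need >= 2 values per side, got {plus.size} and {minus.size}"
        )
    if not (np.isfinite(plus).all() and np.isfinite(minus).all()):
        raise ValueError("non-finite control values")
    gap = abs(plus.mean() - minus.mean())
    if gap == 0:
        raise DegenerateSeparationError("control means are equal")
    z = 1.0 - 3.0 * (plus.std(ddof=1) + minus.std(ddof=1)) / gap
    return ZPrimeResult(zprime=float(z), n_plus=int(plus.size), n_minus=int(minus.size))


@dataclass(frozen=True)
class FeatureSubset:
    """Selected feature names (catalog order broken only by Z' rank)."""

    names: tuple[str, ...]
    per_feature_zprime: dict[str, float]


def per_feature_zprime(
    features: pd.DataFrame, roles: pd.Series
) -> dict[str, float]:
    """Z' of each feature column between AC and NC wells.

    Degenerate features (equal control means, e.g. constant columns) are
    omitted from the result.
    """
    roles = pd.Series(roles).reset_index(drop=True)
    ac = roles == WellRole.ACTIVE_CONTROL.value
    nc = roles == WellRole.NEGATIVE_CONTROL.value
    if ac.sum() < 2 or nc.sum() < 2:
        raise ValueError("need >= 2 AC and >= 2 NC wells for feature selection")
    out: dict[str, float] = {}
    X = features.reset_index(drop=True)
    for name in X.columns:
        col = X[name].to_numpy(float)
        if not np.isfinite(col).all():
            raise ValueError(f"non-finite values in feature {name!r}")
        try:
            out[name] = zprime(col[ac.to_numpy()], col[nc.to_numpy()]).zprime
        except DegenerateSeparationError:
            continue
    return out


def select_features(
    features: pd.DataFrame,
    roles: pd.Series,
    zprime_floor: float = 0.0,
    max_features: int = 10,
) -> FeatureSubset:
    """Keep features whose AC-vs-NC Z' clears the floor, best first.

    Ranked by descending Z'; ties broken by column (catalog) order; truncated
    to ``max_features``.  Raises :class:`NoSeparatingFeaturesError` when the
    floor eliminates everything.
    """
    zp = per_feature_zprime(features, roles)
    cols = list(features.columns)
    candidates = [c for c in cols if c in zp and zp[c] >= zprime_floor]
    if not candidates:
        raise NoSeparatingFeaturesError(
            f"no feature reaches Z' >= {zprime_floor} between controls"
        )
    ranked = sorted(candidates, key=lambda c: (-zp[c], cols.index(c)))
    kept = tuple(ranked[:max_features])
    return FeatureSubset(names=kept, per_feature_zprime={c: zp[c] for c in kept})


@dataclass
class ControlModel:
    """Gaussian model of one control population over the selected features."""

    mu: np.ndarray
    sigma: np.ndarray
    lam: float
    n: int
    feature_names: tuple[str, ...]
    _chol: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        try:
            self._chol = cho_factor(self.sigma, lower=True)
        except LinAlgError:
            raise SingularCovarianceError(
                f"covariance not positive definite (n={self.n}, "
                f"d={len(self.mu)}, lambda={self.lam})"
            ) from None

    @property
    def dim(self) -> int:
        return int(self.mu.size)

    def mahalanobis(self, X: np.ndarray) -> np.ndarray:
        """MHD of each row of X to this model, via a Cholesky solve."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise ValueError(f"dimension mismatch: x has {X.shape[1]}, model {self.dim}")
        if not np.isfinite(X).all():
            raise ValueError("non-finite input to mahalanobis")
        diff = X - self.mu
        solved = cho_solve(self._chol, diff.T)
        return np.sqrt(np.einsum("ij,ji->i", diff, solved))


def fit_control_model(
    X: np.ndarray | pd.DataFrame,
    lam: float = 0.1,
    feature_names: tuple[str, ...] | None = None,
) -> ControlModel:
    """Fit mean and shrunk covariance to a control-well feature matrix."""
    if isinstance(X, pd.DataFrame):
        if feature_names is None:
            feature_names = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if n < 2:
        raise ValueError(f"need >= 2 control wells, got {n}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values in control matrix")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"shrinkage lambda {lam} outside [0, 1]")
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(d))

    mu = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1).reshape(d, d)
    sigma = (1.0 - lam) * S + lam * (np.trace(S) / d) * np.eye(d)
    return ControlModel(mu=mu, sigma=sigma, lam=lam, n=n, feature_names=feature_names)


def mahalanobis_score(x: np.ndarray, model: ControlModel) -> float:
    """MHD of a single feature vector to a control model."""
    return float(model.mahalanobis(np.asarray(x, dtype=float).reshape(1, -1))[0])


@dataclass
class PlateScores:
    """Per-well MHD scores plus the plate-level QC statistic."""

    scores: pd.DataFrame  # columns: well, role, [compound_id,] mhd_ac, mhd_nc
    qc: ZPrimeResult
    subset: FeatureSubset
    lam: float


def score_plate(
    features: pd.DataFrame,
    subset: FeatureSubset | None = None,
    lam: float = 0.1,
    zscale: bool = True,
    zprime_floor: float = 0.0,
    max_features: int = 10,
) -> PlateScores:
    """Score every well of one plate against its own control models.

    ``features`` carries ``well`` and ``role`` columns plus feature columns
    (extra metadata columns like ``compound_id`` are carried through).
    Features are optionally z-scaled with the pooled control mean/SD before
    model fitting — irrelevant at lambda = 0 (affine invariance of the MHD)
    but numerically safer, and documented as affecting lambda > 0 results.
    Plate QC is the Z' between AC and NC wells' MHD-to-AC values.
    """
    meta_cols = [c for c in ("well", "role", "compound_id", "concentration_uM", "no_objects") if c in features.columns]
    if "role" not in meta_cols:
        raise ValueError("features table needs a 'role' column")
    feat_cols = [c for c in features.columns if c not in meta_cols]
    roles = features["role"].reset_index(drop=True)
    if subset is None:
        subset = select_features(
            features[feat_cols], roles, zprime_floor=zprime_floor, max_features=max_features
        )
    missing = [n for n in subset.names if n not in features.columns]
    if missing:
        raise ValueError(f"subset features absent from table: {missing}")

    X = features[list(subset.names)].to_numpy(dtype=float)
    ac_mask = (roles == WellRole.ACTIVE_CONTROL.value).to_numpy()
    nc_mask = (roles == WellRole.NEGATIVE_CONTROL.value).to_numpy()
    if ac_mask.sum() < 2 or nc_mask.sum() < 2:
        raise ValueError("need >= 2 AC and >= 2 NC wells to score a plate")

    if zscale:
        ctrl = X[ac_mask | nc_mask]
        center = ctrl.mean(axis=0)
        scale = ctrl.std(ddof=1, axis=0)
        scale[scale == 0] = 1.0
        X = (X - center) / scale

    ac_model = fit_control_model(X[ac_mask], lam=lam, feature_names=subset.names)
    nc_model = fit_control_model(X[nc_mask], lam=lam, feature_names=subset.names)
    mhd_ac = ac_model.mahalanobis(X)
    mhd_nc = nc_model.mahalanobis(X)

    out = features[meta_cols].copy().reset_index(drop=True)
    out["mhd_ac"] = mhd_ac
    out["mhd_nc"] = mhd_nc
    qc = zprime(mhd_ac[ac_mask], mhd_ac[nc_mask])
    return PlateScores(scores=out, qc=qc, subset=subset, lam=lam)
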