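"""Pointwise group statistics on deformation markers.

At each template point k the Jacobian marker J_k(s) of subject s is
modelled by ordinary least squares,

    J_k(s) = beta_k0 + beta_k1 * group(s) + a_age*age + a_sex*sex + a_tiv*tiv + eps,

with a binary group indicator and nuisance covariates age, sex and total
intracranial volume.  The group effect is reported as -beta_k1 so that,
with the disease group coded 1, positive values mean local atrophy of the
disease group relative to controls and negative values mean expansion.

Significance is assessed by permutation: the per-point statistic is the
two-sided |t| for beta_k1, the null ensemble permutes subjects under the
Freedman–Lane scheme (residuals of the covariate-only reduced model are
permuted and the full model refit), and the family-wise error rate across
points is controlled by the single-step max-statistic (Westfall–Young)
correction.  Naive label permutation is available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    InvalidGroupingError,
    LengthMismatchError,
    SingularDesignError,
    TooFewPermutationsError,
    UndefinedErrorMetric,
)

__all__ = [
    "GroupDifferenceResult",
    "design_matrix",
    "fit_pointwise_model",
    "permutation_fwer",
    "upsample_result",
    "overall_error",
    "detection_scores",
]

COVARIATE_COLUMNS = ["group", "age", "sex", "tiv"]


@dataclass
class GroupDifferenceResult:
    """Per-point group-difference estimates with FWER-corrected p-values."""

    minus_beta1: np.ndarray  # (n_points,) atrophy-positive effect
    t_obs: np.ndarray  # (n_points,) observed |t| statistic basis (signed t)
    p_fwer: np.ndarray  # (n_points,) max-statistic corrected p-values
    significant: np.ndarray  # boolean, p_fwer <= alpha
    global_p: float
    n_perm: int
    seed: int
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "point": np.arange(len(self.minus_beta1)),
            "minus_beta1": self.minus_beta1,
            "t": self.t_obs,
            "p_fwer": self.p_fwer,
            "significant": self.significant,
        })


def _validate_covariates(cov: pd.DataFrame, n_subjects: int) -> pd.DataFrame:
    missing = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing:
        raise InvalidGroupingError(f"covariate table lacks columns {missing}")
    if len(cov) != n_subjects:
        raise InvalidGroupingError(
            f"covariate rows ({len(cov)}) != marker-matrix subjects ({n_subjects})"
        )
    g = np.unique(np.asarray(cov["group"]))
    if len(g) < 2:
        raise InvalidGroupingError("group variable has a single level")
    return cov


def design_matrix(cov: pd.DataFrame) -> np.ndarray:
    """Full design [1, group, age, sex, tiv] as an (n, 5) float array."""
    X = np.column_stack([
        np.ones(len(cov)),
        np.asarray(cov["group"], float),
        np.asarray(cov["age"], float),
        np.asarray(cov["sex"], float),
        np.asarray(cov["tiv"], float),
    ])
    return X


def _check_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the dependent columns via the null space
        _, s, Vt = np.linalg.svd(X)
        null = Vt[rank:]
        names = ["intercept"] + COVARIATE_COLUMNS
        bad = sorted({names[j] for row in null for j in np.nonzero(np.abs(row) > 1e-8)[0]})
        raise SingularDesignError(bad)


def fit_pointwise_model(J: np.ndarray, cov: pd.DataFrame
                        ) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit of every template point's marker on [1, group, age, sex, tiv].

    Returns ``(betas, residuals)`` with betas of shape (n_points, 5) and
    residuals of shape (n_subjects, n_points).
    """
    J = np.asarray(J, float)
    cov = _validate_covariates(cov, J.shape[0])
    X = design_matrix(cov)
    if J.shape[0] <= X.shape[1] + 1:
        raise InvalidGroupingError(
            f"need more subjects ({J.shape[0]}) than regressors + 1 ({X.shape[1] + 1})"
        )
    _check_rank(X)
    beta, *_ = np.linalg.lstsq(X, J, rcond=None)
    resid = J - X @ beta
    return beta.T, resid


def _t_stats(X: np.ndarray, pinv: np.ndarray, c11: float, Y: np.ndarray
             ) -> np.ndarray:
    """t statistics for the group coefficient, vectorized over points."""
    beta = pinv @ Y  # (p, n_points)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * c11, 1e-300))
    return beta[1] / se


def permutation_fwer(J: np.ndarray, cov: pd.DataFrame, n_perm: int = 10_000,
                     seed: int = 0, alpha: float = 0.05,
                     scheme: str = "freedman-lane") -> GroupDifferenceResult:
    """Max-statistic permutation test of the group effect at every point.

    The observed statistic at point k is |t_k| for beta_k1.  The null
    ensemble permutes subjects (Freedman–Lane by default: residuals of the
    covariate-only reduced model are permuted, the full model refit); the
    corrected p-value is

        p_fwer(k) = (1 + #{perm : max_j |t_j*| >= |t_k|}) / (1 + n_perm),

    which controls the family-wise error rate under exchangeability and is
    bounded below by 1/(n_perm + 1).  ``global_p`` is the corrected p of
    the largest observed statistic.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise TooFewPermutationsError(f"n_perm must be >= 100, got {n_perm}")
    if scheme not in ("freedman-lane", "labels"):
        raise InvalidGroupingError(f"unknown permutation scheme {scheme!r}")
    J = np.asarray(J, float)
    cov = _validate_covariates(cov, J.shape[0])
    X = design_matrix(cov)
    _check_rank(X)
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    c11 = float(np.linalg.inv(X.T @ X)[1, 1])

    t_obs = _t_stats(X, pinv, c11, J)
    abs_obs = np.abs(t_obs)
    beta = pinv @ J
    minus_beta1 = -beta[1]

    rng = np.random.default_rng(seed)
    if scheme == "freedman-lane":
        Xr = np.delete(X, 1, axis=1)  # covariate-only reduced model
        pr = np.linalg.pinv(Xr)
        fitted_r = Xr @ (pr @ J)
        resid_r = J - fitted_r
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        if scheme == "freedman-lane":
            Yb = fitted_r + resid_r[perm]
            tb = _t_stats(X, pinv, c11, Yb)
        else:
            Xb = X.copy()
            Xb[:, 1] = X[perm, 1]
            pb = np.linalg.pinv(Xb)
            c11b = float(np.linalg.inv(Xb.T @ Xb)[1, 1])
            tb = _t_stats(Xb, pb, c11b, J)
        max_null[b] = np.max(np.abs(tb))

    exceed = (max_null[None, :] >= abs_obs[:, None]).sum(axis=1)
    p_fwer = (1.0 + exceed) / (1.0 + n_perm)
    global_p = float((1.0 + np.sum(max_null >= abs_obs.max())) / (1.0 + n_perm))
    return GroupDifferenceResult(
        minus_beta1=minus_beta1,
        t_obs=t_obs,
        p_fwer=p_fwer,
        significant=p_fwer <= alpha,
        global_p=global_p,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
    )


def upsample_result(values: np.ndarray, factor: int, target_len: int
                    ) -> np.ndarray:
    """Periodic linear interpolation of a per-point result along the curve.

    Down-sampled index j corresponds to full-resolution index j*factor;
    the value at full index i interpolates between down-sampled neighbours
    floor(i/f) and ceil(i/f) (mod n).
    """
    values = np.asarray(values, float)
    n = len(values)
    if factor == 1:
        if target_len != n:
            raise LengthMismatchError(
                f"factor 1 requires target_len == len(values) ({target_len} != {n})"
            )
        return values.copy()
    if not (n * factor >= target_len >= n):
        raise LengthMismatchError(
            f"need len*factor >= target_len >= len ({n}*{factor} vs {target_len})"
        )
    pos = np.arange(target_len) / factor
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    hi = (lo + 1) % n
    lo = lo % n
    return (1.0 - frac) * values[lo] + frac * values[hi]


def overall_error(r: np.ndarray, r1: np.ndarray) -> float:
    """sum_i (r_i - r1_i)^2 / sum_i (r_i + r1_i)^2.

    Ranges in [0, 1] whenever r_i * r1_i >= 0 for all i; with mixed signs
    the ratio can exceed 1 and is returned as-is (documented, not
    clipped).  A zero denominator raises :class:`UndefinedErrorMetric`.
    """
    r = np.asarray(r, float)
    r1 = np.asarray(r1, float)
    if r.shape != r1.shape:
        raise LengthMismatchError(f"length mismatch: {r.shape} vs {r1.shape}")
    denom = float(np.sum((r + r1) ** 2))
    if denom == 0.0:
        raise UndefinedErrorMetric("sum of squared sums is zero")
    return float(np.sum((r - r1) ** 2)) / denom


def detection_scores(significant: np.ndarray, truth: np.ndarray,
                     blur: int = 3) -> tuple[float, float]:
    """Sensitivity / specificity of a detected point set vs. a truth arc.

    Tolerates ``blur`` points of boundary uncertainty on the closed curve:
    sensitivity is scored on the truth arc eroded by ``blur`` points and
    specificity on the complement of the truth arc dilated by ``blur``.
    """
    significant = np.asarray(significant, bool)
    truth = np.asarray(truth, bool)
    n = len(truth)
    idx = np.arange(n)
    eroded = truth.copy()
    dilated = truth.copy()
    for s in range(1, blur + 1):
        eroded &= np.roll(truth, s) & np.roll(truth, -s)
        dilated |= np.roll(truth, s) | np.roll(truth, -s)
    core = idx[eroded]
    outside = idx[~dilated]
    sens = float(significant[core].mean()) if len(core) else float("nan")
    spec = float((~significant[outside]).mean()) if len(outside) else float("nan")
    return sens, spec
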