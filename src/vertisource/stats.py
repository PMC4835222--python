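"""Permutation-corrected voxelwise statistics and behavioral correlations.

Voxelwise group contrasts use the nonparametric max-statistic recipe:
the unpaired t-map is recomputed under random relabelings of the group
memberships, the maximum |t| over voxels is recorded per permutation,
and a voxel is familywise-significant when its observed |t| reaches the
upper tail of that max-null.  Correlation maps are corrected the same
way by permuting the behavioral vector.  Corrected p-values use the
standard (1 + exceedances) / (1 + n_perm) estimator, which controls the
FWER at the nominal level without distributional assumptions.

ROI-level group differences are tested with a per-ROI one-way ANOVA on
log-power values (two groups, F with (1, nA+nB-2) df); behavioral
associations with plain Pearson correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class StatMap:
    """Voxelwise statistic with max-statistic permutation correction."""

    stat: np.ndarray          # (voxels,) t or r; NaN where undefined
    p_corrected: np.ndarray   # (voxels,) FWER-corrected p
    significant: np.ndarray   # (voxels,) bool at the stated alpha
    max_null: np.ndarray      # (n_perm,) permutation max-|stat| distribution
    kind: str                 # "t" or "r"
    alpha: float
    n_perm: int
    seed: int

    @property
    def threshold(self) -> float:
        """Critical |stat| at the stated alpha (max-null upper quantile)."""
        srt = np.sort(self.max_null)
        k = int(np.ceil((1.0 - self.alpha) * (self.n_perm + 1))) - 1
        return float(srt[min(max(k, 0), self.n_perm - 1)])


def _t_from_indicator(ind: np.ndarray, X: np.ndarray, X2: np.ndarray,
                      nA: int, nB: int) -> np.ndarray:
    """Unpaired t-maps for many group assignments at once.

    ``ind`` is (n_perm, n) with 1 marking group A membership; returns
    (n_perm, voxels).
    """
    n = nA + nB
    sumA = ind @ X
    sumB = X.sum(axis=0)[None, :] - sumA
    ssA = ind @ X2
    ssB = X2.sum(axis=0)[None, :] - ssA
    mA, mB = sumA / nA, sumB / nB
    ssw = (ssA - nA * mA**2) + (ssB - nB * mB**2)
    varp = ssw / (n - 2)
    denom = np.sqrt(varp * (1.0 / nA + 1.0 / nB))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mA - mB) / denom
    t[~np.isfinite(t)] = np.nan
    return t


def snpm_group_compare(mapsA: np.ndarray, mapsB: np.ndarray,
                       n_perm: int = 5000, alpha: float = 0.05,
                       seed: int = 0) -> StatMap:
    """Voxelwise unpaired t with max-|t| permutation FWER correction.

    ``mapsA``/``mapsB`` are subjects x voxels.  Voxels with zero pooled
    variance get NaN statistics and are never significant.
    """
    A = np.atleast_2d(np.asarray(mapsA, float))
    B = np.atleast_2d(np.asarray(mapsB, float))
    if A.shape[1] != B.shape[1]:
        raise ParameterError("groups must share the voxel dimension")
    nA, nB = A.shape[0], B.shape[0]
    if min(nA, nB) < 3:
        raise ParameterError("need at least 3 subjects per group")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is too small for stable thresholds")
    X = np.vstack([A, B])
    X2 = X**2
    obs = _t_from_indicator(np.r_[np.ones(nA), np.zeros(nB)][None, :],
                            X, X2, nA, nB)[0]
    rng = np.random.default_rng(seed)
    n = nA + nB
    ind = np.zeros((n_perm, n))
    for p in range(n_perm):
        ind[p, rng.permutation(n)[:nA]] = 1.0
    t_null = _t_from_indicator(ind, X, X2, nA, nB)
    max_null = np.nanmax(np.abs(t_null), axis=1)
    absobs = np.abs(obs)
    p_corr = (1.0 + (max_null[None, :] >= absobs[:, None]).sum(axis=1)) / (n_perm + 1.0)
    p_corr[~np.isfinite(obs)] = np.nan
    sig = np.where(np.isfinite(obs), p_corr <= alpha, False)
    return StatMap(stat=obs, p_corrected=p_corr, significant=sig,
                   max_null=max_null, kind="t", alpha=alpha,
                   n_perm=n_perm, seed=seed)


def voxelwise_correlation(maps: np.ndarray, behavior: np.ndarray,
                          n_perm: int = 5000, alpha: float = 0.05,
                          seed: int = 0) -> StatMap:
    """Voxelwise Pearson r vs a behavioral score, max-|r| corrected."""
    X = np.atleast_2d(np.asarray(maps, float))
    b = np.asarray(behavior, float).ravel()
    n = X.shape[0]
    if n != b.size:
        raise ParameterError("behavior length must match subject count")
    if n < 5:
        raise ParameterError("need at least 5 subjects")
    if np.ptp(b) == 0:
        raise ParameterError("behavior vector is constant")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is too small for stable thresholds")
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = Xc / sd
    zb = (b - b.mean()) / b.std()
    obs = (zb @ Z) / n
    obs[sd == 0] = np.nan
    rng = np.random.default_rng(seed)
    perms = np.stack([zb[rng.permutation(n)] for _ in range(n_perm)])
    r_null = (perms @ np.nan_to_num(Z)) / n
    finite_cols = sd > 0
    max_null = np.abs(r_null[:, finite_cols]).max(axis=1) if finite_cols.any() \
        else np.zeros(n_perm)
    absobs = np.abs(obs)
    p_corr = (1.0 + (max_null[None, :] >= absobs[:, None]).sum(axis=1)) / (n_perm + 1.0)
    p_corr[~np.isfinite(obs)] = np.nan
    sig = np.where(np.isfinite(obs), p_corr <= alpha, False)
    return StatMap(stat=obs, p_corrected=p_corr, significant=sig,
                   max_null=max_null, kind="r", alpha=alpha,
                   n_perm=n_perm, seed=seed)


def roi_band_anova(values: pd.DataFrame, groups: np.ndarray,
                   permutation: bool = False, n_perm: int = 5000,
                   seed: int = 0) -> pd.DataFrame:
    """One-way ANOVA per ROI between two groups.

    ``values`` is subjects x ROIs (one band's log power); ``groups`` is a
    vector of two labels.  Returns a frame with F and p per ROI;
    ``permutation=True`` adds a permutation p-value.
    """
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ParameterError("exactly two groups required")
    maskA = g == labels[0]
    if min(maskA.sum(), (~maskA).sum()) < 3:
        raise ParameterError("need at least 3 subjects per group")
    out = []
    rng = np.random.default_rng(seed)
    for roi in values.columns:
        a = values.loc[maskA, roi].to_numpy(float)
        b = values.loc[~maskA, roi].to_numpy(float)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ParameterError(f"ROI {roi!r}: zero within-group variance")
        F, p = sps.f_oneway(a, b)
        row = {"roi": roi, "F": float(F), "p": float(p)}
        if permutation:
            pooled = np.concatenate([a, b])
            nA = a.size
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                Fp, _ = sps.f_oneway(perm[:nA], perm[nA:])
                count += Fp >= F
            row["p_perm"] = (1.0 + count) / (n_perm + 1.0)
        out.append(row)
    return pd.DataFrame(out).set_index("roi")


def pearson_with_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p (t transform with n-2 df)."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size or a.size < 3:
        raise ParameterError("need equal-length vectors with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ParameterError("constant input; correlation undefined")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
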