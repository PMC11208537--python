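"""Environment-community association statistics.

Covers the regression/correlation toolbox relating soil variables and
pollution indices to bacterial diversity and community structure:

* polynomial (degree 1 or 2) least-squares fits with an overall F-test;
* a Spearman taxon x environment correlation grid with Benjamini-
  Hochberg adjustment;
* Mantel and partial Mantel permutation tests between distance
  matrices (one-tailed, ``p = (1 + #{r_perm >= r_obs}) / (B + 1)``);
* variation partitioning (partial RDA on Hellinger-transformed
  abundances, Ezekiel-adjusted R-squared);
* random-forest predictor importance as out-of-bag permutation
  increase in MSE (the %IncMSE convention).

All randomised procedures are deterministic given their seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    degree: int
    coefficients: list[float]  # highest power first
    r_squared: float
    p_value: float
    vertex_x: float | None = None


@dataclass
class MantelResult:
    r: float
    p_value: float
    permutations: int
    method: str
    partial: bool = False


@dataclass
class VPAResult:
    """Fractions of community variation: X1-unique (a), shared (b),
    X2-unique (c), residual; on the adjusted-R-squared scale."""

    a: float
    b: float
    c: float
    residual: float
    adjusted: bool = True


def fit_polynomial(x, y, degree: int = 1) -> FitResult:
    """Least-squares polynomial fit with R^2 and overall F-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if len(x) < degree + 2:
        raise ValueError("need at least degree + 2 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: constant x")
    design = np.vander(x, degree + 1)
    if np.linalg.matrix_rank(design) < degree + 1:
        raise ValueError("degenerate design: collinear columns")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df_model, df_resid = degree, len(x) - degree - 1
    if r2 >= 1.0:
        p = 0.0
    else:
        f = (r2 / df_model) / ((1 - r2) / df_resid)
        p = float(stats.f.sf(f, df_model, df_resid))
    vertex = None
    if degree == 2 and coef[0] != 0:
        vertex = float(-coef[1] / (2 * coef[0]))
    return FitResult(degree=degree, coefficients=[float(c) for c in coef],
                     r_squared=float(np.clip(r2, 0, 1)), p_value=p,
                     vertex_x=vertex)


def spearman_grid(taxa_abundance: pd.DataFrame,
                  env: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho/p for every taxon x environment-variable pair.

    Returns a long-format frame (taxon, variable, rho, p, p_adjusted);
    constant columns yield NA with a warning.  BH adjustment is applied
    across the whole grid; raw p is kept alongside.
    """
    common = taxa_abundance.index.intersection(env.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 shared samples")
    ta = taxa_abundance.loc[common]
    ev = env.loc[common]
    records = []
    for taxon in ta.columns:
        for var in ev.columns:
            pair = pd.concat([ta[taxon], ev[var]], axis=1).dropna()
            if pair.iloc[:, 0].nunique() < 2 or pair.iloc[:, 1].nunique() < 2:
                warnings.warn(f"constant column for ({taxon}, {var}); "
                              "rho undefined", stacklevel=2)
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            records.append((taxon, var, rho, p))
    out = pd.DataFrame(records, columns=["taxon", "variable", "rho", "p"])
    out["p_adjusted"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_adjusted"] = multipletests(
            out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def _condensed(d: DistanceMatrix) -> np.ndarray:
    return squareform(np.asarray(d.data, dtype=float), checks=False)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("constant distance matrix")
    return (v - v.mean()) / sd


def _check_labels(*ds: DistanceMatrix) -> None:
    ids = ds[0].ids
    for d in ds[1:]:
        if tuple(d.ids) != tuple(ids):
            raise ValueError("distance matrices have mismatched labels")


def mantel(dA: DistanceMatrix, dB: DistanceMatrix, method: str = "spearman",
           permutations: int = 999, seed: int = 0) -> MantelResult:
    """One-tailed Mantel test between two distance matrices.

    The statistic is the Pearson (or Spearman, via ranks) correlation of
    the upper-triangle entries; the null distribution permutes the rows
    and columns of ``dB`` jointly.
    """
    _check_labels(dA, dB)
    if permutations < 99:
        raise ValueError("need at least 99 permutations")
    n = dA.shape[0]
    a, b = _condensed(dA), _condensed(dB)
    if method == "spearman":
        a, b = stats.rankdata(a), stats.rankdata(b)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    za = _zscore(a)
    b_sq = squareform(b, checks=False)
    r_obs = float(np.mean(za * _zscore(b)))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        bp = squareform(b_sq[np.ix_(perm, perm)], checks=False)
        if np.mean(za * _zscore(bp)) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (permutations + 1)
    return MantelResult(r=r_obs, p_value=p, permutations=permutations,
                        method=method)


def _partial_r(r_ab: float, r_ac: float, r_bc: float) -> float:
    numer = r_ab - r_ac * r_bc
    denom = math.sqrt(max((1 - r_ac ** 2) * (1 - r_bc ** 2), 0.0))
    if denom == 0:
        if abs(numer) < 1e-12:  # removable case, e.g. controlling for B
            return 0.0
        raise ValueError("degenerate partial correlation (|r| = 1)")
    return numer / denom


def partial_mantel(dA: DistanceMatrix, dB: DistanceMatrix,
                   dC: DistanceMatrix, method: str = "spearman",
                   permutations: int = 999, seed: int = 0) -> MantelResult:
    """Partial Mantel test of A vs B controlling for C.

    ``r_AB.C = (r_AB - r_AC r_BC) / sqrt((1-r_AC^2)(1-r_BC^2))``; the
    permutation scheme permutes ``dB`` and recomputes the statistic.
    """
    _check_labels(dA, dB, dC)
    if permutations < 99:
        raise ValueError("need at least 99 permutations")
    n = dA.shape[0]
    a, b, c = _condensed(dA), _condensed(dB), _condensed(dC)
    if method == "spearman":
        a, b, c = (stats.rankdata(v) for v in (a, b, c))
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    za, zc = _zscore(a), _zscore(c)
    zb = _zscore(b)
    r_ac = float(np.mean(za * zc))
    r_obs = _partial_r(float(np.mean(za * zb)), r_ac,
                       float(np.mean(zb * zc)))
    b_sq = squareform(b, checks=False)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        zbp = _zscore(squareform(b_sq[np.ix_(perm, perm)], checks=False))
        r_perm = _partial_r(float(np.mean(za * zbp)), r_ac,
                            float(np.mean(zbp * zc)))
        if r_perm >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (permutations + 1)
    return MantelResult(r=r_obs, p_value=p, permutations=permutations,
                        method=method, partial=True)


def hellinger(abundance: np.ndarray) -> np.ndarray:
    """Hellinger transform: sqrt of row-wise relative abundance."""
    abundance = np.asarray(abundance, dtype=float)
    totals = abundance.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("zero-total sample")
    return np.sqrt(abundance / totals)


def _rda_r2(Y: np.ndarray, X: np.ndarray, block: str,
            allow_rank_deficient: bool = False) -> tuple[float, int]:
    """Redundancy-analysis R^2 of multivariate Y on predictor block X.

    The combined block of a partition may be collinear (e.g. shared
    variables in both blocks); its effective rank then serves as the
    predictor count for the adjustment.
    """
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        if not allow_rank_deficient:
            raise ValueError(f"rank-deficient predictor block: {block}")
        Xc = Xc  # lstsq handles the deficiency; adjustment uses rank
    Yc = Y - Y.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ coef
    ss_tot = float((Yc ** 2).sum())
    r2 = float((fitted ** 2).sum()) / ss_tot
    return r2, int(rank)


def _ezekiel(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variation_partition(community: pd.DataFrame, X1: pd.DataFrame,
                        X2: pd.DataFrame, adjusted: bool = True) -> VPAResult:
    """Partition community variation between two predictor blocks.

    The community matrix is Hellinger-transformed, each block's RDA
    R-squared is Ezekiel-adjusted, and the fractions are
    ``a = adj(X1+X2) - adj(X2)``, ``c = adj(X1+X2) - adj(X1)``,
    ``b = adj(X1) + adj(X2) - adj(X1+X2)``, residual ``1 - adj(X1+X2)``.
    Negative adjusted fractions are reported as computed (standard for
    varpart-style output).
    """
    n = community.shape[0]
    p_both = X1.shape[1] + X2.shape[1]
    if n <= p_both + 1:
        raise ValueError("need n > combined predictor count + 1")
    Y = hellinger(community.to_numpy())
    x1 = X1.to_numpy(dtype=float)
    x2 = X2.to_numpy(dtype=float)
    r2_1, p1 = _rda_r2(Y, x1, "X1")
    r2_2, p2 = _rda_r2(Y, x2, "X2")
    r2_12, p12 = _rda_r2(Y, np.hstack([x1, x2]), "X1+X2",
                         allow_rank_deficient=True)
    if adjusted:
        r2_1, r2_2, r2_12 = (_ezekiel(r2_1, n, p1), _ezekiel(r2_2, n, p2),
                             _ezekiel(r2_12, n, p12))
    a = r2_12 - r2_2
    c = r2_12 - r2_1
    b = r2_1 + r2_2 - r2_12
    return VPAResult(a=a, b=b, c=c, residual=1.0 - r2_12, adjusted=adjusted)


def forest_importance(X: pd.DataFrame, y, trees: int = 500,
                      seed: int = 0) -> pd.DataFrame:
    """Random-forest %IncMSE importance of each predictor.

    Fits a regression forest (``mtry = ceil(p/3)``) and measures, per
    tree, the increase in out-of-bag MSE when one predictor is permuted;
    %IncMSE is 100 x the mean increase over trees relative to the mean
    un-permuted OOB MSE, and ``raw_increase`` keeps the unnormalised
    mean increase (comparable across models).  Returns a frame sorted
    by rank.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 samples")
    if trees < 100:
        raise ValueError("need at least 100 trees")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    rng = np.random.default_rng(seed)
    forest = RandomForestRegressor(
        n_estimators=trees, max_features=math.ceil(p / 3),
        bootstrap=True, random_state=int(seed))
    Xv = X.to_numpy(dtype=float)
    forest.fit(Xv, y)
    base_mse = np.zeros(trees)
    inc = np.zeros((trees, p))
    for t, (tree, inbag) in enumerate(
            zip(forest.estimators_, forest.estimators_samples_)):
        oob = np.setdiff1d(np.arange(n), inbag)
        if len(oob) < 2:
            continue
        pred = tree.predict(Xv[oob])
        base_mse[t] = np.mean((y[oob] - pred) ** 2)
        for j in range(p):
            Xp = Xv[oob].copy()
            Xp[:, j] = Xp[rng.permutation(len(oob)), j]
            mse = np.mean((y[oob] - tree.predict(Xp)) ** 2)
            inc[t, j] = mse - base_mse[t]
    denom = base_mse.mean()
    raw = inc.mean(axis=0)
    out = pd.DataFrame({"importance": 100.0 * raw / denom,
                        "raw_increase": raw}, index=list(X.columns))
    out.index.name = "variable"
    out["rank"] = out["importance"].rank(ascending=False,
                                         method="first").astype(int)
    return out.sort_values("rank")
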