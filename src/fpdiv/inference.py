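"""Regression layer: covariate screening, model selection, the a-scan,
relative importance, and spatial autocorrelation.

The central step is the scan over the phylogeny weight ``a``: for each
value, SES.MFPD (against a shared null stream) and FPDve (COMP) are
recomputed from FPDist(a) and regressed on the environmental covariates
plus COMP; the ``a`` maximizing adjusted R^2 is the optimal weight — the
mix of functional and phylogenetic information that environment and
competition explain best.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from skbio import DistanceMatrix

from .containers import CommunityMatrix, ValidationError
from .distance import FPDistSpec, RetentionRule, fpdist, rescale_to_unit
from .evenness import fpdve_per_site
from .null import NullSpec, mpd_per_site, null_matrices, ses_mfpd

__all__ = [
    "spearman_screen",
    "fit_ols",
    "backward_select",
    "lmg_importance",
    "scan_a",
    "morans_i",
    "RegressionResult",
    "AScanResult",
    "MoranResult",
    "ScreenResult",
]

EARTH_RADIUS_M = 6_378_137.0


@dataclass
class ScreenResult:
    correlations: pd.DataFrame  # Spearman rho among covariates
    flagged_pairs: list[tuple[str, str, float]]
    removal_proposals: list[str]


def spearman_screen(covariates: pd.DataFrame, threshold: float = 0.7) -> ScreenResult:
    """Spearman collinearity screen among covariate columns.

    Pairs with ``|rho| >= threshold`` are flagged; within each flagged pair
    the covariate with more high-correlation partners (ties: larger mean
    absolute rho) is proposed for removal.  Constant covariates yield
    undefined (NaN) correlations for their pairs.
    """
    if len(covariates) < 3:
        raise ValidationError("need at least 3 sites for the collinearity screen")
    cols = list(covariates.columns)
    n = len(cols)
    rho = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    for i, j in combinations(range(n), 2):
        xi = covariates.iloc[:, i].to_numpy(dtype=float)
        xj = covariates.iloc[:, j].to_numpy(dtype=float)
        if np.ptp(xi) == 0 or np.ptp(xj) == 0:
            r = np.nan
        else:
            r = stats.spearmanr(xi, xj).statistic
        rho.iloc[i, j] = rho.iloc[j, i] = r
    flagged = [
        (cols[i], cols[j], float(rho.iloc[i, j]))
        for i, j in combinations(range(n), 2)
        if np.isfinite(rho.iloc[i, j]) and abs(rho.iloc[i, j]) >= threshold
    ]
    high_count = {c: 0 for c in cols}
    mean_abs = {c: [] for c in cols}
    for a, b, r in flagged:
        high_count[a] += 1
        high_count[b] += 1
        mean_abs[a].append(abs(r))
        mean_abs[b].append(abs(r))
    proposals: list[str] = []
    for a, b, _ in flagged:
        key = lambda c: (high_count[c], float(np.mean(mean_abs[c])) if mean_abs[c] else 0.0)
        worse = a if key(a) > key(b) else b
        if worse not in proposals:
            proposals.append(worse)
    return ScreenResult(correlations=rho, flagged_pairs=flagged, removal_proposals=proposals)


@dataclass
class RegressionResult:
    """OLS fit summary with the backward-selection removal trace."""

    covariates: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float
    rsquared_adj: float
    nobs: int
    removal_trace: list[tuple[str, float]] = field(default_factory=list)
    model: object = None  # underlying statsmodels results

    def summary(self) -> str:
        lines = [
            f"OLS: n={self.nobs}, k={len(self.covariates)}, "
            f"R2={self.rsquared:.4f}, adj R2={self.rsquared_adj:.4f}",
            f"{'term':>12} {'coef':>12} {'se':>12} {'p':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:>12} {self.params[name]:>12.5g} "
                f"{self.bse[name]:>12.5g} {self.pvalues[name]:>10.4g}"
            )
        for name, p in self.removal_trace:
            lines.append(f"  removed {name} (p={p:.4g})")
        return "\n".join(lines)


def _design(x: pd.DataFrame) -> pd.DataFrame:
    return sm.add_constant(x.astype(float), has_constant="add")


def fit_ols(y: pd.Series | np.ndarray, x: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares of SES on covariates, with intercept."""
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValidationError("response contains undefined values; drop flagged sites first")
    n, k = len(y), x.shape[1]
    if n <= k + 1:
        raise ValidationError(f"n={n} too small for k={k} covariates")
    design = _design(x)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        collinear = _collinear_columns(design)
        raise ValidationError(f"rank-deficient design; collinear columns: {collinear}")
    res = sm.OLS(y, design).fit()
    return RegressionResult(
        covariates=list(x.columns),
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        nobs=int(res.nobs),
        model=res,
    )


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    cols = list(design.columns)
    bad = []
    arr = design.to_numpy()
    full_rank = np.linalg.matrix_rank(arr)
    for i, c in enumerate(cols):
        reduced = np.delete(arr, i, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            bad.append(c)
    return [c for c in bad if c != "const"]


def backward_select(
    y: pd.Series | np.ndarray, x: pd.DataFrame, alpha: float = 0.05
) -> RegressionResult:
    """Drop the least-significant covariate until all p-values <= alpha.

    The intercept is never removed.  If every covariate is dropped, the
    intercept-only model is returned with a warning.
    """
    kept = list(x.columns)
    trace: list[tuple[str, float]] = []
    while kept:
        res = fit_ols(y, x[kept])
        pv = res.pvalues.drop("const")
        worst = pv.idxmax()
        if pv[worst] <= alpha:
            res.removal_trace = trace
            return res
        trace.append((worst, float(pv[worst])))
        kept.remove(worst)
    warnings.warn("backward selection removed every covariate; intercept-only model")
    y = np.asarray(y, dtype=float)
    res = sm.OLS(y, np.ones((len(y), 1))).fit()
    out = RegressionResult(
        covariates=[],
        params=pd.Series({"const": float(res.params[0])}),
        bse=pd.Series({"const": float(res.bse[0])}),
        pvalues=pd.Series({"const": float(res.pvalues[0])}),
        rsquared=0.0,
        rsquared_adj=0.0,
        nobs=int(res.nobs),
        removal_trace=trace,
        model=res,
    )
    return out


def _subset_r2(y: np.ndarray, x: np.ndarray, subset: tuple[int, ...]) -> float:
    n = len(y)
    if not subset:
        return 0.0
    design = np.column_stack([np.ones(n), x[:, list(subset)]])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return float(1 - resid @ resid / tss) if tss > 0 else 0.0


def lmg_importance(y: pd.Series | np.ndarray, x: pd.DataFrame) -> pd.DataFrame:
    """LMG relative importance: average sequential R^2 over all orderings.

    Computed by the subset-averaging identity (weights ``s!(k-1-s)!/k!``
    over the ``2^(k-1)`` subsets not containing the focal covariate), which
    equals the mean over all ``k!`` orderings of the covariate's increment
    to R^2.  Shares sum to the full model's R^2; the normalized column
    rescales them to percent of R^2.
    """
    cols = list(x.columns)
    k = len(cols)
    if k > 10:
        raise ValidationError("LMG limited to k <= 10 covariates")
    y = np.asarray(y, dtype=float)
    arr = x.to_numpy(dtype=float)
    r2_cache: dict[tuple[int, ...], float] = {}
    for size in range(k + 1):
        for subset in combinations(range(k), size):
            r2_cache[subset] = _subset_r2(y, arr, subset)
    shares = np.zeros(k)
    for j in range(k):
        others = [i for i in range(k) if i != j]
        for size in range(k):
            w = math.factorial(size) * math.factorial(k - 1 - size) / math.factorial(k)
            for subset in combinations(others, size):
                inc = r2_cache[tuple(sorted(subset + (j,)))] - r2_cache[subset]
                shares[j] += w * inc
    full_r2 = r2_cache[tuple(range(k))]
    normalized = 100 * shares / full_r2 if full_r2 > 0 else np.full(k, np.nan)
    return pd.DataFrame(
        {"covariate": cols, "lmg_share": shares, "lmg_percent_of_r2": normalized}
    ).set_index("covariate")


@dataclass
class AScanResult:
    """Adjusted-R^2 profile over the a-grid and the selected optimum."""

    a_grid: np.ndarray
    adj_r2: np.ndarray
    a_star: float
    max_adj_r2: float
    ses_by_a: pd.DataFrame  # sites x a values
    comp_by_a: pd.DataFrame
    ses_at_star: object  # SESResult at a_star
    fits: list[RegressionResult]

    def profile(self) -> pd.DataFrame:
        return pd.DataFrame({"a": self.a_grid, "adj_r2": self.adj_r2})


def scan_a(
    comm: CommunityMatrix,
    fd: DistanceMatrix,
    pd_: DistanceMatrix,
    covariates: pd.DataFrame,
    null_spec: NullSpec,
    a_grid: np.ndarray | None = None,
    p: float = 2.0,
    retention: RetentionRule | None = None,
) -> AScanResult:
    """Scan the phylogeny weight, refitting the full model at each ``a``.

    The same null-randomization stream (from ``null_spec.seed``) is reused
    for every ``a`` so that differences in adjusted R^2 reflect the weight,
    not Monte-Carlo noise.  Sites flagged undefined (SES or COMP) at a given
    ``a`` are dropped from that fit.
    """
    a_grid = np.round(np.arange(0, 1.0001, 0.01), 10) if a_grid is None else np.asarray(a_grid, float)
    if a_grid.min() < 0 or a_grid.max() > 1:
        raise ValidationError("a_grid must lie within [0, 1]")
    if list(covariates.index) != list(comm.sites):
        covariates = covariates.loc[comm.sites]
    m = comm.values()
    nulls = null_matrices(m, null_spec)
    fd_r = rescale_to_unit(fd)
    pd_r = rescale_to_unit(pd_)
    adj = np.full(len(a_grid), np.nan)
    fits: list[RegressionResult] = []
    ses_cols, comp_cols = {}, {}
    ses_results = []
    for ai, a in enumerate(a_grid):
        d_a = fpdist(fd_r, pd_r, FPDistSpec(a=a, p=p))
        ses_res = ses_mfpd(comm, d_a, null_spec, nulls=nulls)
        ev = fpdve_per_site(comm, d_a, retention)
        ses_cols[a] = ses_res.table["ses"].to_numpy()
        comp_cols[a] = ev.table["fpdve"].to_numpy()
        ok = (~ses_res.table["undefined"].to_numpy()) & (~ev.table["undefined"].to_numpy())
        if ok.sum() == 0:
            raise ValidationError(f"all sites flagged undefined at a={a}")
        y = ses_cols[a][ok]
        design = covariates.loc[ok].copy()
        design["COMP"] = comp_cols[a][ok]
        fit = fit_ols(y, design)
        adj[ai] = fit.rsquared_adj
        fits.append(fit)
        ses_results.append(ses_res)
    best = int(np.nanargmax(adj))
    return AScanResult(
        a_grid=a_grid,
        adj_r2=adj,
        a_star=float(a_grid[best]),
        max_adj_r2=float(adj[best]),
        ses_by_a=pd.DataFrame(ses_cols, index=comm.sites),
        comp_by_a=pd.DataFrame(comp_cols, index=comm.sites),
        ses_at_star=ses_results[best],
        fits=fits,
    )


@dataclass
class MoranResult:
    observed: float
    expected: float
    sd: float
    p: float

    def __repr__(self) -> str:
        return (
            f"MoranResult(I={self.observed:.4f}, E[I]={self.expected:.4f}, "
            f"sd={self.sd:.4f}, p={self.p:.4f})"
        )


def haversine_matrix(lon: np.ndarray, lat: np.ndarray, radius: float = EARTH_RADIUS_M) -> np.ndarray:
    """Great-circle distances (m) between all site pairs."""
    lon_r, lat_r = np.radians(lon), np.radians(lat)
    dlat = lat_r[:, None] - lat_r[None, :]
    dlon = lon_r[:, None] - lon_r[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat_r)[:, None] * np.cos(lat_r)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def morans_i(values: pd.Series | np.ndarray, coords: pd.DataFrame) -> MoranResult:
    """Moran's I with inverse great-circle-distance weights.

    ``coords`` holds decimal-degree ``longitude``/``latitude`` per site.
    The expectation is ``-1/(n-1)``; the variance follows the normality
    assumption and the two-tailed p the normal approximation.  Constant
    values give an undefined (NaN) statistic.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 4:
        raise ValidationError("Moran's I needs at least 4 sites")
    if not np.isfinite(v).all():
        raise ValidationError("undefined values passed to Moran's I")
    lon = coords["longitude"].to_numpy(dtype=float)
    lat = coords["latitude"].to_numpy(dtype=float)
    dist = haversine_matrix(lon, lat)
    off = ~np.eye(n, dtype=bool)
    if (dist[off] == 0).any():
        raise ValidationError("coincident site coordinates; jitter or exclude duplicates")
    w = np.zeros_like(dist)
    w[off] = 1.0 / dist[off]
    z = v - v.mean()
    denom = z @ z
    expected = -1.0 / (n - 1)
    s0 = w.sum()
    s1 = ((w + w.T) ** 2).sum() / 2
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - expected**2
    sd = math.sqrt(max(var, 0.0))
    if denom == 0:
        return MoranResult(observed=float("nan"), expected=expected, sd=sd, p=float("nan"))
    observed = n / s0 * (z @ w @ z) / denom
    pval = 2 * stats.norm.sf(abs(observed - expected) / sd) if sd > 0 else float("nan")
    return MoranResult(observed=float(observed), expected=expected, sd=sd, p=float(min(pval, 1.0)))
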