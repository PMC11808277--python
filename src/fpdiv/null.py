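"""Mean pairwise distance, null-model randomization, and SES.

The observed statistic per site is the mean functional-phylogenetic
pairwise distance (MFPD): the average of the distance matrix over all
unordered pairs of species present at the site.  The standardized effect
size compares it with a null distribution obtained by randomizing the
community matrix; the default *frequency* algorithm permutes each species'
presences across sites independently, preserving every species' occurrence
frequency exactly.  Negative SES indicates clustering (co-occurring species
more similar than chance), positive SES over-dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .containers import CommunityMatrix, ValidationError

__all__ = ["NullSpec", "mpd", "mpd_per_site", "randomize", "null_matrices", "ses_mfpd", "SESResult"]

ALGORITHMS = ("frequency", "richness", "independentswap")


@dataclass(frozen=True)
class NullSpec:
    """Null-model configuration.

    ``frequency`` permutes each species column across sites (occurrence
    frequencies preserved); ``richness`` permutes each site row across
    species (site richness preserved); ``independentswap`` preserves both
    margins via repeated checkerboard swaps.
    """

    algorithm: str = "frequency"
    n_iterations: int = 999
    seed: int = 0
    n_swaps_per_species: int = 20  # independentswap thinning

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(
                f"unknown null algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")


def mpd(presence: np.ndarray, d: np.ndarray) -> float:
    """Mean pairwise distance among present species; NaN if richness < 2."""
    idx = np.flatnonzero(presence)
    s = len(idx)
    if s < 2:
        return float("nan")
    sub = d[np.ix_(idx, idx)]
    return float(sub.sum() / (s * (s - 1)))


def mpd_per_site(m: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorized MPD for every row of a site x species matrix."""
    m = m.astype(float)
    rich = m.sum(axis=1)
    pair_sums = np.einsum("ij,jk,ik->i", m, d, m)
    denom = rich * (rich - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = pair_sums / denom
    out[rich < 2] = np.nan
    return out


def mpd_stream(nulls: np.ndarray, d: np.ndarray, chunk_elems: int = 40_000_000) -> np.ndarray:
    """MPD for every (iteration, site) of a randomization stream.

    Flattens iterations x sites into one matrix product per chunk so the
    work runs as large BLAS calls; returns (n_iterations, n_sites).
    """
    n_it, n_sites, n_sp = nulls.shape
    rows_per_chunk = max(1, chunk_elems // (n_sites * n_sp))
    out = np.empty((n_it, n_sites))
    for start in range(0, n_it, rows_per_chunk):
        block = nulls[start : start + rows_per_chunk].astype(float)
        flat = block.reshape(-1, n_sp)
        pair_sums = ((flat @ d) * flat).sum(axis=1).reshape(block.shape[0], n_sites)
        rich = block.sum(axis=2)
        denom = rich * (rich - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = pair_sums / denom
        vals[rich < 2] = np.nan
        out[start : start + rows_per_chunk] = vals
    return out


def _permute_columns(m: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    keys = rng.random(m.shape)
    perms = np.argsort(keys, axis=0)
    return np.take_along_axis(m, perms, axis=0)


def _permute_rows(m: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    keys = rng.random(m.shape)
    perms = np.argsort(keys, axis=1)
    return np.take_along_axis(m, perms, axis=1)


def _independent_swap(m: np.ndarray, rng: np.random.Generator, n_swaps: int) -> np.ndarray:
    out = m.copy()
    n_sites, n_sp = out.shape
    done = 0
    attempts = 0
    max_attempts = 200 * max(n_swaps, 1)
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        r = rng.integers(0, n_sites, size=2)
        c = rng.integers(0, n_sp, size=2)
        if r[0] == r[1] or c[0] == c[1]:
            continue
        a, b = out[r[0], c[0]], out[r[0], c[1]]
        c_, d_ = out[r[1], c[0]], out[r[1], c[1]]
        if a == d_ and b == c_ and a != b:  # checkerboard
            out[r[0], c[0]], out[r[0], c[1]] = b, a
            out[r[1], c[0]], out[r[1], c[1]] = d_, c_
            done += 1
    return out


def randomize(comm: CommunityMatrix, spec: NullSpec) -> CommunityMatrix:
    """One randomized community matrix under the chosen algorithm."""
    rng = np.random.default_rng(spec.seed)
    m = comm.values()
    if spec.algorithm == "frequency":
        shuffled = _permute_columns(m, rng)
    elif spec.algorithm == "richness":
        shuffled = _permute_rows(m, rng)
    else:
        shuffled = _independent_swap(m, rng, spec.n_swaps_per_species * m.shape[1])
    df = pd.DataFrame(shuffled, index=comm.sites, columns=comm.species)
    out = object.__new__(CommunityMatrix)
    out.data = df.astype(np.int8)
    return out


def null_matrices(m: np.ndarray, spec: NullSpec) -> np.ndarray:
    """The full randomization stream: (n_iterations, n_sites, n_species).

    Regenerating this from the same :class:`NullSpec` gives the identical
    stream, which is what lets the a-scan and the envelope reuse one set of
    randomized matrices across all values of ``a``.
    """
    rng = np.random.default_rng(spec.seed)
    out = np.empty((spec.n_iterations, *m.shape), dtype=np.int8)
    for i in range(spec.n_iterations):
        if spec.algorithm == "frequency":
            out[i] = _permute_columns(m, rng)
        elif spec.algorithm == "richness":
            out[i] = _permute_rows(m, rng)
        else:
            out[i] = _independent_swap(m, rng, spec.n_swaps_per_species * m.shape[1])
    return out


@dataclass
class SESResult:
    """Per-site SES table plus the null configuration that produced it."""

    table: pd.DataFrame  # site, richness, observed_mfpd, null_mean, null_sd, ses, rank_quantile, p, undefined
    spec: NullSpec

    @property
    def ses(self) -> pd.Series:
        return self.table["ses"]

    def defined(self) -> pd.DataFrame:
        return self.table[~self.table["undefined"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def ses_mfpd(
    comm: CommunityMatrix,
    d: DistanceMatrix,
    spec: NullSpec,
    nulls: np.ndarray | None = None,
) -> SESResult:
    """SES of MFPD per site against the randomization stream.

    ``nulls`` may be a precomputed stream from :func:`null_matrices` (to
    share one stream across several distance matrices); otherwise it is
    generated from ``spec``.  SES uses the sample (n-1) standard deviation;
    the two-tailed p is ``2 * min(q, 1-q)`` for the mid-rank quantile ``q``,
    clipped to (0, 1].  Sites whose null SD is zero are flagged undefined.
    """
    if list(comm.species) != list(d.ids):
        raise ValidationError("community and distance matrix species order differ")
    m = comm.values()
    dvals = d.data
    observed = mpd_per_site(m, dvals)
    if nulls is None:
        nulls = null_matrices(m, spec)
    null_mpd = mpd_stream(nulls, dvals)
    with np.errstate(invalid="ignore"):
        null_mean = np.nanmean(null_mpd, axis=0)
        null_sd = np.nanstd(null_mpd, axis=0, ddof=1)
    ses = np.full_like(observed, np.nan)
    # degenerate nulls: sd exactly zero up to float accumulation noise
    sd_floor = 1e-12 * np.maximum(np.abs(null_mean), 1.0)
    ok = np.isfinite(observed) & np.isfinite(null_sd) & (null_sd > sd_floor)
    ses[ok] = (observed[ok] - null_mean[ok]) / null_sd[ok]
    n_it = nulls.shape[0]
    with np.errstate(invalid="ignore"):
        less = np.nansum(null_mpd < observed[None, :], axis=0)
        equal = np.nansum(null_mpd == observed[None, :], axis=0)
    quantile = (less + 0.5 * equal + 0.5) / (n_it + 1)
    p = np.clip(2 * np.minimum(quantile, 1 - quantile), np.finfo(float).tiny, 1.0)
    undefined = ~ok
    quantile[undefined] = np.nan
    p[undefined] = np.nan
    table = pd.DataFrame(
        {
            "site": comm.sites,
            "richness": m.sum(axis=1),
            "observed_mfpd": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "ses": ses,
            "rank_quantile": quantile,
            "p": p,
            "undefined": undefined,
        }
    )
    return SESResult(table=table, spec=spec)
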