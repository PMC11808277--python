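"""MFPD-vs-a null envelopes and per-site assembly-regime classification.

For each site the observed MFPD is traced across the phylogeny-weight grid
together with quantile bands of the null MFPD distribution (95%, 50% and a
1% band around the median).  Where the observed curve sits relative to the
bands at the functional end (small ``a``) versus the phylogenetic end
(large ``a``) separates four regimes:

* significant at both ends — the traits driving assembly carry
  phylogenetic signal and were measured (``matched_with_signal``);
* significant only at small ``a`` — measured traits match assembly but
  their signal is weak (``trait_matched_weak_signal``);
* significant only at large ``a`` — a conserved but unmeasured trait
  drives assembly (``signal_but_trait_mismatch``);
* never significant — ``random``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .containers import CommunityMatrix, ValidationError
from .distance import FPDistSpec, fpdist, rescale_to_unit
from .null import NullSpec, mpd_per_site, mpd_stream, null_matrices

__all__ = ["envelope", "classify_regime", "EnvelopeCurve", "REGIME_LABELS", "plot_envelope"]

QUANTILES = (0.025, 0.25, 0.495, 0.505, 0.75, 0.975)
QCOLS = ["q025", "q25", "q495", "q505", "q75", "q975"]

REGIME_LABELS = (
    "matched_with_signal",
    "trait_matched_weak_signal",
    "signal_but_trait_mismatch",
    "random",
)


@dataclass
class EnvelopeCurve:
    """Long-format observed-vs-null curves: one row per (site, a)."""

    table: pd.DataFrame  # site, a, observed, q025, q25, q495, q505, q75, q975
    n_null: int
    seed: int

    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.table["site"]))

    def for_site(self, site: str) -> pd.DataFrame:
        return self.table[self.table["site"] == site]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def envelope(
    comm: CommunityMatrix,
    fd: DistanceMatrix,
    pd_: DistanceMatrix,
    a_grid: np.ndarray | None = None,
    n_null: int = 1000,
    seed: int = 0,
    p: float = 2.0,
    null_algorithm: str = "frequency",
) -> EnvelopeCurve:
    """Observed MFPD and null quantile bands across the a-grid.

    One stream of ``n_null`` randomized matrices is generated once and
    reused at every ``a``, so each site's curve and its bands vary smoothly
    in ``a``.  Sites with richness < 2 are omitted with a warning.
    """
    a_grid = np.round(np.arange(0, 1.0001, 0.01), 10) if a_grid is None else np.asarray(a_grid, float)
    spec = NullSpec(algorithm=null_algorithm, n_iterations=n_null, seed=seed)
    m = comm.values()
    rich = m.sum(axis=1)
    if (rich < 2).any():
        dropped = [s for s, r in zip(comm.sites, rich) if r < 2]
        warnings.warn(f"omitting sites with richness < 2: {dropped}")
    keep = rich >= 2
    nulls = null_matrices(m, spec)
    fd_r = rescale_to_unit(fd)
    pd_r = rescale_to_unit(pd_)
    records = []
    sites = np.array(comm.sites)[keep]
    for a in a_grid:
        d_a = fpdist(fd_r, pd_r, FPDistSpec(a=a, p=p)).data
        obs = mpd_per_site(m, d_a)[keep]
        null_mpd = mpd_stream(nulls, d_a)[:, keep]
        with np.errstate(invalid="ignore"):
            qs = np.nanquantile(null_mpd, QUANTILES, axis=0)
        for si, site in enumerate(sites):
            records.append((site, a, obs[si], *qs[:, si]))
    table = pd.DataFrame(records, columns=["site", "a", "observed", *QCOLS])
    return EnvelopeCurve(table=table, n_null=n_null, seed=seed)


def classify_regime(
    curve: EnvelopeCurve,
    frac_threshold: float = 0.8,
    low_window: tuple[float, float] = (0.0, 0.25),
    high_window: tuple[float, float] = (0.75, 1.0),
) -> pd.DataFrame:
    """Label each site's assembly regime from its envelope curve.

    A grid point is significant when the observed MFPD falls outside the
    95% band.  ``frac_low``/``frac_high`` are the significant fractions of
    the grid inside the two windows; an end counts as significant when its
    fraction reaches ``frac_threshold``.
    """
    if not 0 < frac_threshold <= 1:
        raise ValidationError("frac_threshold must be in (0, 1]")
    rows = []
    for site in curve.sites():
        sub = curve.for_site(site)
        sig = (sub["observed"] < sub["q025"]) | (sub["observed"] > sub["q975"])
        a = sub["a"].to_numpy()
        low = (a >= low_window[0]) & (a <= low_window[1])
        high = (a >= high_window[0]) & (a <= high_window[1])
        frac_low = float(sig[low].mean()) if low.any() else np.nan
        frac_high = float(sig[high].mean()) if high.any() else np.nan
        low_sig = frac_low >= frac_threshold
        high_sig = frac_high >= frac_threshold
        if low_sig and high_sig:
            label = "matched_with_signal"
        elif low_sig:
            label = "trait_matched_weak_signal"
        elif high_sig:
            label = "signal_but_trait_mismatch"
        else:
            label = "random"
        rows.append((site, frac_low, frac_high, label))
    return pd.DataFrame(rows, columns=["site", "frac_low", "frac_high", "label"])


def plot_envelope(curve: EnvelopeCurve, site: str, ax=None):
    """Observed MFPD curve with shaded null bands for one site (optional)."""
    import matplotlib.pyplot as plt

    sub = curve.for_site(site)
    if sub.empty:
        raise ValidationError(f"unknown site {site!r}")
    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(sub["a"], sub["q025"], sub["q975"], color="0.85", label="95% null")
    ax.fill_between(sub["a"], sub["q25"], sub["q75"], color="0.7", label="50% null")
    ax.fill_between(sub["a"], sub["q495"], sub["q505"], color="0.3", label="null median")
    ax.plot(sub["a"], sub["observed"], "k:", lw=2, label="observed")
    ax.set_xlabel("phylogeny weight a")
    ax.set_ylabel("MFPD")
    ax.set_title(site)
    ax.legend(frameon=False, fontsize="small")
    return ax
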