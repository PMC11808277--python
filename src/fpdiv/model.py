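"""Model/Results front for the whole analysis.

``CommunityAssemblyModel`` bundles the aligned inputs (phylogeny, traits,
community, environment) and precomputes the functional and phylogenetic
distance matrices; ``fit()`` runs collinearity screening, the adjusted-R^2
scan over the phylogeny weight ``a``, backward selection at the optimum,
LMG relative importance and Moran's I, returning an
:class:`AssemblyResults` with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .containers import CommunityMatrix, EnvTable, TraitTable, ValidationError
from .diagnostics import EnvelopeCurve, classify_regime, envelope
from .distance import RetentionRule, functional_distance, patristic_distances
from .inference import (
    AScanResult,
    MoranResult,
    RegressionResult,
    ScreenResult,
    backward_select,
    lmg_importance,
    morans_i,
    scan_a,
    spearman_screen,
)
from .io import align_labels, read_community, read_env, read_newick, read_traits
from .null import NullSpec

__all__ = ["CommunityAssemblyModel", "AssemblyResults"]


class CommunityAssemblyModel:
    """Functional-phylogenetic community assembly model.

    Parameters
    ----------
    tree, traits, community, env
        The four aligned inputs; species shared by tree/traits/community
        are used, sites must match between community and env.
    p
        FPDist combination exponent.
    retention
        PCoA axis-retention rule for the functional embedding and the
        per-site evenness embeddings.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        traits: TraitTable,
        community: CommunityMatrix,
        env: EnvTable,
        p: float = 2.0,
        retention: RetentionRule | None = None,
    ) -> None:
        tree, traits, community = align_labels(tree, traits, community)
        missing = set(community.sites) - set(env.sites)
        if missing:
            raise ValidationError(f"sites missing from environment table: {sorted(missing)}")
        self.tree = tree
        self.traits = traits
        self.community = community
        self.env = env
        self.p = p
        self.retention = retention or RetentionRule()
        self.fdist, self.ordination = functional_distance(traits, self.retention)
        self.pdist = patristic_distances(tree)

    @classmethod
    def from_files(
        cls,
        tree_path: str | Path,
        traits_path: str | Path,
        community_path: str | Path,
        env_path: str | Path,
        trait_types: dict[str, str],
        **kwargs,
    ) -> "CommunityAssemblyModel":
        return cls(
            read_newick(Path(tree_path)),
            read_traits(traits_path, trait_types),
            read_community(community_path),
            read_env(env_path),
            **kwargs,
        )

    def fit(
        self,
        a_grid: np.ndarray | None = None,
        null_spec: NullSpec | None = None,
        alpha: float = 0.05,
        screen_threshold: float = 0.7,
        auto_screen: bool = True,
        spatial: bool = True,
    ) -> "AssemblyResults":
        """Run the full inference pipeline and return the results object."""
        null_spec = null_spec or NullSpec()
        covariates = self.env.covariates.loc[self.community.sites]
        screen = spearman_screen(covariates, threshold=screen_threshold)
        kept = [c for c in covariates.columns if not (auto_screen and c in screen.removal_proposals)]
        scan = scan_a(
            self.community,
            self.fdist,
            self.pdist,
            covariates[kept],
            null_spec,
            a_grid=a_grid,
            p=self.p,
            retention=self.retention,
        )
        ses_tab = scan.ses_at_star.table
        comp = scan.comp_by_a[scan.a_star].to_numpy()
        ok = (~ses_tab["undefined"].to_numpy()) & np.isfinite(comp)
        y = ses_tab["ses"].to_numpy()[ok]
        design = covariates[kept].loc[ok].copy()
        design["COMP"] = comp[ok]
        selected = backward_select(y, design, alpha=alpha)
        lmg = (
            lmg_importance(y, design[selected.covariates])
            if selected.covariates
            else None
        )
        moran = None
        if spatial:
            coords = self.env.coordinates().loc[self.community.sites].loc[ok]
            moran = morans_i(y, coords)
        return AssemblyResults(
            model=self,
            scan=scan,
            screen=screen,
            screened_covariates=kept,
            selected=selected,
            lmg=lmg,
            moran=moran,
            null_spec=null_spec,
            alpha=alpha,
        )


@dataclass
class AssemblyResults:
    """Fitted results: optimal weight, selected model, importances, SES."""

    model: CommunityAssemblyModel
    scan: AScanResult
    screen: ScreenResult
    screened_covariates: list[str]
    selected: RegressionResult
    lmg: pd.DataFrame | None
    moran: MoranResult | None
    null_spec: NullSpec
    alpha: float
    _envelope: EnvelopeCurve | None = field(default=None, repr=False)

    @property
    def a_star(self) -> float:
        return self.scan.a_star

    @property
    def ses_table(self) -> pd.DataFrame:
        return self.scan.ses_at_star.table

    def envelope(self, n_null: int = 1000, seed: int | None = None, a_grid=None) -> EnvelopeCurve:
        if self._envelope is None:
            self._envelope = envelope(
                self.model.community,
                self.model.fdist,
                self.model.pdist,
                a_grid=a_grid,
                n_null=n_null,
                seed=self.null_spec.seed if seed is None else seed,
                p=self.model.p,
            )
        return self._envelope

    def regimes(self, frac_threshold: float = 0.8) -> pd.DataFrame:
        return classify_regime(self.envelope(), frac_threshold=frac_threshold)

    def summary(self) -> str:
        ses = self.ses_table
        defined = ses[~ses["undefined"]]
        lines = [
            "Community assembly model (functional-phylogenetic distances)",
            "=" * 62,
            f"species: {len(self.model.community.species)}   sites: {len(self.model.community.sites)}"
            f"   null: {self.null_spec.algorithm} x {self.null_spec.n_iterations}"
            f" (seed {self.null_spec.seed})",
            f"functional axes retained: {self.model.ordination.retained_axes}"
            f" ({100 * self.model.ordination.proportion_explained:.1f}% of positive eigenvalue mass)",
            "",
            f"optimal phylogeny weight a* = {self.a_star:.2f}"
            f"   max adjusted R2 = {self.scan.max_adj_r2:.4f}",
            f"mean SES.MFPD = {defined['ses'].mean():.3f} (sd {defined['ses'].std():.3f},"
            f" range {defined['ses'].min():.2f} to {defined['ses'].max():.2f})",
            "",
            "screened covariates: " + ", ".join(self.screened_covariates),
        ]
        if self.screen.removal_proposals:
            lines.append("removed as collinear: " + ", ".join(self.screen.removal_proposals))
        lines += ["", "selected model (backward elimination):", self.selected.summary()]
        if self.lmg is not None:
            lines += ["", "relative importance (LMG):"]
            for cov, row in self.lmg.iterrows():
                lines.append(
                    f"  {cov:>8}: share {row['lmg_share']:.4f}"
                    f" ({row['lmg_percent_of_r2']:.1f}% of R2)"
                )
        if self.moran is not None:
            lines += [
                "",
                f"Moran's I on SES: I = {self.moran.observed:.4f}"
                f" (E[I] = {self.moran.expected:.4f}, p = {self.moran.p:.3f})",
            ]
        return "\n".join(lines)

    def to_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scan.profile().to_csv(outdir / "a_scan.csv", index=False)
        self.ses_table.to_csv(outdir / "ses_at_a_star.csv", index=False)
        if self.lmg is not None:
            self.lmg.to_csv(outdir / "lmg.csv")
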