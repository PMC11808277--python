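# fpdiv

Functional–phylogenetic analysis of community assembly: which process —
environmental filtering, interspecific competition, or chance — shapes the
species composition of ecological communities, and is that process visible
through measured traits, through phylogeny, or both?

The package is aimed at community ecologists working with a species pool
(a phylogeny plus a mixed-type trait table), a site × species
presence/absence matrix, and per-site environmental covariates — the
standard output of, for example, a bird transect survey.

## The method

Two interspecific distance matrices are built over the pool:

- **FDist** — Gower dissimilarity over mixed traits (continuous, ordinal,
  nominal, binary), embedded by principal coordinates analysis, with
  Euclidean distances recomputed on the retained axes;
- **PDist** — patristic distance (summed branch lengths between tips).

They are blended with a phylogeny weight *a* ∈ [0, 1] after max-rescaling
each to [0, 1]:

    FPDist(a) = ( a · PDist′^p + (1 − a) · FDist′^p )^(1/p),   p = 2

so *a* = 0 is a purely functional distance and *a* = 1 purely phylogenetic.

Per site, the mean pairwise FPDist among the species present (MFPD) is
compared against a frequency-preserving null model (each species' presences
permuted across sites; 999 randomizations by default), giving a
standardized effect size

    SES.MFPD = (MFPD_obs − mean(MFPD_null)) / sd(MFPD_null).

Negative SES means co-occurring species are more similar than chance
(clustering, the signature of filtering); positive SES means
over-dispersion (the signature of limiting similarity).

The phylogeny weight is chosen by data: for each *a* on a grid, SES.MFPD
and the functional–phylogenetic evenness FPDve (a minimum-spanning-tree
evenness used as the competition-intensity covariate COMP) are regressed
on the environmental covariates plus COMP, and *a\** is the weight
maximizing adjusted R². Backward elimination then selects significant
drivers, LMG decomposition attributes shares of R² to each, and Moran's I
(inverse great-circle-distance weights) checks for residual spatial
structure. Per-site MFPD-vs-*a* curves against null envelopes classify
each site's regime: whether the measured traits match assembly and whether
they carry phylogenetic signal.

A synthetic-data module generates complete studies — birth–death trees,
traits with controllable Pagel-λ signal, assemblages built by filtering /
limiting similarity / neutral draws, covariates coupled to process
strength — so the whole pipeline is testable offline with known truth.

## Worked example

```python
import numpy as np
import fpdiv

study = fpdiv.generate_study(
    n_sites=40, pool_size=80, seed=7,
    process_mix={"filtering": 1.0},
    covariate_coupling="filtering",
    driver="measured_all", n_continuous=12, n_nominal=0,
    richness_range=(15, 30),
)
model = fpdiv.CommunityAssemblyModel(
    study.tree, study.traits, study.community, study.env
)
res = model.fit(
    a_grid=np.round(np.arange(0, 1.01, 0.05), 10),
    null_spec=fpdiv.NullSpec(n_iterations=199, seed=7),
)
print(res.summary())
```

prints

```
Community assembly model (functional-phylogenetic distances)
==============================================================
species: 71   sites: 40   null: frequency x 199 (seed 7)
functional axes retained: 11 (81.2% of positive eigenvalue mass)

optimal phylogeny weight a* = 0.15   max adjusted R2 = 0.7020
mean SES.MFPD = -0.247 (sd 2.107, range -3.88 to 6.56)

screened covariates: TEMP, PREC, NDVI, NPP, HII, ALT

selected model (backward elimination):
OLS: n=40, k=2, R2=0.7074, adj R2=0.6916
        term         coef           se          p
       const      -4.2271       3.6746     0.2574
        TEMP      0.37351      0.15092    0.01803
         HII      -1.2985      0.13789  2.298e-11
  removed ALT (p=0.8205)
  removed NDVI (p=0.6627)
  removed PREC (p=0.6202)
  removed COMP (p=0.1185)
  removed NPP (p=0.06762)

relative importance (LMG):
      TEMP: share 0.0272 (3.9% of R2)
       HII: share 0.6801 (96.1% of R2)

Moran's I on SES: I = 0.0155 (E[I] = -0.0256, p = 0.218)
```

Read it as follows. The simulated truth is trait-driven filtering whose
strength rises with the HII covariate, and the fit recovers exactly that:
the optimal weight sits near the functional end (*a\** = 0.15 — measured
traits, not phylogeny, carry the assembly signal), HII is retained with a
strongly negative coefficient (stronger filtering → more clustered
communities → lower SES) and takes 96% of the explained variance, and
Moran's I finds no spatial autocorrelation (none was simulated).
`res.regimes()` labels each site's envelope curve; `res.envelope()` returns
the curves themselves for plotting.

The same workflow runs from the shell on CSV/Newick inputs:

```sh
fpdiv simulate --out bundle --n-sites 40 --pool-size 80 --seed 7
fpdiv fit --tree bundle/tree.nwk --traits bundle/traits.csv \
          --community bundle/community.csv --env bundle/env.csv \
          --out results --a-step 0.05 --n-null 199 --seed 7
```

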