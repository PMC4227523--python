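# ige — indirect genetic effects in group-housed populations

When animals live in groups, each individual's phenotype is shaped not
only by its own genes but by the genes of its group mates: survival of a
laying hen depends on how much her cage mates peck, growth of a pig on
how much its pen mates fight over feed.  Classical selection ignores
these *indirect (social) genetic effects* and can move a trait the
wrong way — the best-surviving hens may simply be the best peckers.
`ige` is a toolkit for breeders and quantitative geneticists who design
selection schemes for such socially affected traits.

## The model

The phenotype of individual *i* in a group of *n* is

    P_i = A_D,i + E_D,i + Σ_{j≠i} (A_S,j + E_S,j) + g_group

with direct effects (A_D, E_D) on the individual's own phenotype and
social effects (A_S, E_S) on each group mate.  The total breeding value
`TBV_i = A_D,i + (n−1) A_S,i` carries all heritable influence of *i* on
the population mean, with variance

    σ²_TBV = σ²_AD + 2(n−1) σ_ADS + (n−1)² σ²_AS

and response to selection `ΔG = ι ρ σ_TBV`, where ρ is the correlation
between a scheme's selection criterion and the TBV.

The package provides:

* **`ige.variance_theory`** — all derived (co)variances (σ²_P,
  Cov(P_i,P_j), σ²_TPV, T², …) and closed-form accuracies of five
  schemes: individual selection (IS), group selection (GS), multilevel
  selection (MS, weight g), selection on group-housed relatives (SR),
  and classical-BLUP selection;
* **`ige.pedigree_blup`** — pedigree A-matrix, Henderson MME for the
  classical and the direct–social model (genetic covariance C ⊗ A,
  group effects, within-group-correlated residuals), REML variance
  components with analytic gradients, and identifiability diagnostics
  for group compositions;
* **`ige.breeding_sim`** — a forward stochastic simulator (discrete
  generations, separate sexes, unrelated/half-sib/full-sib/two-family
  groups, all five schemes) that doubles as the Monte-Carlo oracle for
  every closed form;
* **`ige.validation`** — scripted experiments: the laying-hen worked
  example, Monte-Carlo accuracy checks, REML parameter recovery and
  design identifiability, and direct-EBV vs total-EBV selection;
* **`ige` CLI** — `predict`, `simulate`, `blup`, `reml`, `validate`,
  `fixture`.

## Worked example

Accuracy and predicted response of group selection for crossbred
laying-hen survival time, full-sib cages of 4 (bundled reconstructed
parameter set; trait unit = days of survival):

```python
from ige import GroupDesign, accuracy_group, predict_response
from ige.io_cli import bundled_layer_parameters
import math

table = bundled_layer_parameters()
params = table["populations"]["crossbred"][0]
design = GroupDesign(group_size=4, relatedness_within_group=0.5)

rho = accuracy_group(params, design)
sd_tbv = math.sqrt(
    params.var_direct_genetic
    + 2 * 3 * params.cov_direct_social_genetic
    + 9 * params.var_social_genetic
)
print(f"accuracy {rho:.3f}, sd(TBV) {sd_tbv:.1f} days, "
      f"dG {predict_response(1.0, rho, sd_tbv).delta_g:.1f} days/generation")
```

prints

```
accuracy 0.408, sd(TBV) 57.7 days, dG 23.5 days/generation
```

so one generation of group selection at unit intensity is predicted to
add about 23.5 days of survival — even though the direct–social genetic
correlation is strongly negative (r_A ≈ −0.82) and plain individual
selection on the same population with unrelated cage mates would *lose*
about 8 days per generation (run `ige validate --experiment table3` for
the full table of all scheme × relatedness combinations).

The same contrast at the EBV level:

```bash
ige validate --experiment dblup --quick
```

simulates selection on direct EBVs (D-BLUP) versus total EBVs (C-BLUP)
under heritable competition; D-BLUP responses are negative, C-BLUP
responses positive.

A note on the bundled parameter file: the original supplementary
estimates behind the published response table were not available, so
`src/ige/data/layer_survival_params.json` holds sets *reconstructed* by
inverting that table through the package's formulas.  The published
table is not exactly representable by any valid parameter configuration
(docs/methods.md quantifies this), so the reproduction is exact for the
individual-selection rows and within ~0.9 days elsewhere, with all
signs and orderings preserved.

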