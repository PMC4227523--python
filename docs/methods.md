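# Methods

## The model

When animals are housed in groups of `n`, the phenotype of individual
`i` is modelled as

    P_i = A_D,i + E_D,i + Σ_{j≠i} (A_S,j + E_S,j) + g_group

where `A_D` and `E_D` are the direct genetic and non-genetic effects of
the individual on its own phenotype, `A_S` and `E_S` the social
(indirect) effects it exerts on each group mate, and `g_group` an
optional non-genetic effect common to the group (a pen or cage effect).
The pair `(A_D, A_S)` follows a bivariate normal with covariance matrix

    C = [[σ²_AD, σ_ADS], [σ_ADS, σ²_AS]]

and `(E_D, E_S)` likewise with `[[σ²_ED, σ_EDS], [σ_EDS, σ²_ES]]`;
residuals are independent between individuals.  The total breeding
value `TBV_i = A_D,i + (n−1) A_S,i` measures the whole heritable impact
of `i` on the population mean; its variance

    σ²_TBV = σ²_AD + 2(n−1) σ_ADS + (n−1)² σ²_AS

is the heritable variance available to selection, and `T² = σ²_TBV/σ²_P`
is the group-housed analogue of heritability (not bounded by 1).  A
negative direct–social correlation `r_A = σ_ADS/(σ_AD σ_AS)` expresses
heritable competition: genotypes that do well themselves depress their
group mates.

## Derived (co)variances

`σ²_P` follows the standard decomposition with within-group relatedness
`r` pulling part of the social (co)variance into the individual
phenotype.  The group-mate covariance is derived from the phenotype
model itself:

    Cov(P_i,P_j) = r σ²_AD + 2[1+(n−2)r] σ_ADS
                 + [(n−2) + r(n²−3n+3)] σ²_AS
                 + 2 σ_EDS + (n−2) σ²_ES + σ²_g

Every derived quantity is verified against sample moments of simulated
populations (the simulator stores all four effect components per
individual and assembles phenotypes exactly, so closed form and
simulation share no code path).

A useful exact identity, used in the tests and in the reproduction
analysis below:

    σ²_P + (n−1) Cov(P_i,P_j) = σ²_TPV + (n−1) r σ²_TBV + n σ²_g

with `σ²_TPV = σ²_PD + 2(n−1)σ_PDS + (n−1)²σ²_PS` the variance of total
phenotypic values.  It shows that the phenotypic variance, the group-mate
covariance and the total phenotypic variance cannot be chosen
independently once the model holds.

## Accuracies of the five selection schemes

Accuracy is `ρ = corr(SC, TBV)` for a scheme's selection criterion SC;
predicted response per generation is `ΔG = ι ρ σ_TBV`.

* individual selection, SC = own phenotype:
  `ρ = {r σ²_TBV + (1−r)[σ²_AD + (n−1)σ_ADS]}/(σ_TBV σ_P)` — can be
  negative under heritable competition with unrelated groups;
* group selection, SC = group mean:
  `ρ = [(n−1)r + 1] σ_TBV/(n σ_P̄grp)` — never negative;
* multilevel selection, SC = P_i + g·Σ_{j≠i}P_j, which interpolates the
  two (`g = 0` individual, `g = 1` group selection);
* selection on relatives: individually housed candidates scored on the
  mean phenotype of `m` groups of `n` relatives,
  `ρ = r_rel σ_TBV / sd(relatives' mean)` with
  `Var(mean) = r σ²_TBV + (σ²_TPV − r σ²_TBV)/(mn) + σ²_g/m`.
  When `σ²_g = 0` this equals the textbook form
  `r_rel η/√(τ + (1−τ)/mn)` with `η = σ_TBV/σ_TPV`, `τ = r η²`; the
  `σ²_g/m` term is kept because the simulation oracle shows the
  textbook form is biased upward when a common group environment
  exists;
* classical BLUP with unrelated groups:
  `ρ ≈ ρ_MME · [σ²_AD + (n−1)σ_ADS]/(σ_AD σ_TBV)` — the bracket is
  corr(DBV, TBV), so direct-only EBV selection inherits the sign
  problem of individual selection.

All five are tested two ways: against an independent exact-covariance
oracle (explicit joint covariance matrix of all effect components,
machine precision) and against Monte-Carlo correlations in simulated
populations (3 jackknife SE).  A delete-one-block jackknife over groups
is used for the Monte-Carlo standard errors because group mates'
criteria are correlated and the i.i.d. formula understates the error.

## Mixed models and REML

The classical animal model and the direct–social model are solved by
Henderson's mixed-model equations.  The direct–social model uses
genetic covariance `C ⊗ A` (A = pedigree numerator relationship matrix,
tabular method), an incidence matrix that links each record to the
social effects of its `n−1` group mates, an optional random group
effect, and a residual that is correlated within groups exactly as the
phenotype model implies (diagonal `σ²_ED + (n−1)σ²_ES`, off-diagonal
`2σ_EDS + (n−2)σ²_ES`).  Solutions are checked against brute-force
joint-covariance GLS to 1e-8 on small instances.  Reliabilities come
from prediction error variances via the inverse coefficient matrix;
the total-EBV reliability uses the contrast vector (1, n−1).

REML maximises the dense restricted likelihood with analytic gradients
(L-BFGS-B, multi-start).  The genetic matrix is parameterised by its
log-Cholesky factors, so estimates are positive semidefinite by
construction; the within-group residual covariance is mapped through a
sigmoid to the interval that keeps the residual block positive
definite.  Only the aggregated within-group residual variance and
covariance are identifiable; the reported `σ²_ED/σ²_ES` decomposition
assumes `σ_EDS = 0` and no separate group variance, and is labelled as
such.  Convergence is declared at ~1e-6 relative likelihood change; a
dense-covariance guard rejects data sets above 3000 records.

### Identifiability and design

With every group drawn from a single family (all members equally
related), the three genetic (co)variances enter the likelihood only
through confounded combinations.  The package flags this structurally
(all groups single-family) and numerically (condition number of the
scaled expected Fisher information in (σ²_AD, σ_ADS, σ²_AS); ~1e16 on
single-family designs versus ~10 on two-family designs).  Two-family
groups are built by *ring pairing*: group `k` holds half of family `k`
and half of family `k+1`.  Pairing both halves of two families into the
same two groups looks like a two-family design but is exactly singular
(the social kernel becomes a linear combination of the direct and
covariance kernels); the ring breaks this.  The group count is compared
with the ~250–500 range that design studies recommend for usable
component precision.

## Simulator

Discrete generations, separate sexes, hierarchical sire–dam matings
(each dam nested in one sire), offspring effects = parent average plus
Mendelian deviation drawn from C/2 (an optional `1−F̄` correction exists
but is off by default; horizons here are short).  Group compositions:
unrelated (at most one member per family and sire per group), half-sib
(one sire, distinct dams), full-sib, and two-family (ring-paired).
Relatives-based schemes house candidates individually with `m` groups
of `n` sib relatives (half sibs all from distinct dams so candidate–
relative and relative–relative relatedness are exactly 1/4).  The
phenotype is reconstructed exactly from stored components, which makes
the simulator a valid oracle for every closed form.  Realized selection
intensity is computed from the realized truncation differential, not
the nominal fraction.  Traits are Gaussian; censored or binary survival
is out of scope.

## The laying-hen worked example

The bundled parameter file
(`src/ige/data/layer_survival_params.json`) carries one direct–social
parameter set each for purebred and crossbred laying-hen survival time
(days, 4-bird cages).  The original supplementary estimates were not
available, so the sets were **reconstructed** by least-squares inversion
of the published predicted-response table (unit selection intensity)
through this package's formulas, constrained to valid parameter
configurations and to the published ranges of `σ_TBV` (50–65 days
purebred), `T²` (0.15–0.19 purebred, 0.17–0.26 crossbred) and `r_A`
(≈−0.3 purebred, strongly negative crossbred).

The published table turns out not to be exactly representable: by the
identity above, `σ²_TPV` is pinned once `σ²_P`, `Cov(P_i,P_j)` and
`σ²_TBV` are chosen, but the published relatives-selection rows require
`σ²_TPV` about 18% larger (crossbred) than the value implied by the
individual- and group-selection rows — equivalent to a negative group
variance.  The purebred individual-selection row is exactly linear in
`r`, which forces `σ²_AS ≈ −σ_ADS` and then over-constrains the
group-selection row.  Both patterns are consistent with the original
predictions having been computed per line (three purebred lines, two
reciprocal crosses) with intermediate rounding, and then averaged.  The
bundled reconstruction therefore reproduces the individual-selection
rows to <0.01 days and every other cell to within 0.6 days (purebred) /
0.9 days (crossbred), with all signs and orderings correct; the
corresponding full-precision acceptance check is expected to fail and
documents this.

## Default problem sizes

Monte-Carlo accuracy checks use ~2×10⁵ individuals per cell; response
checks 30–50 replicates of cohorts of ~1200–1600; REML recovery 6–8
replicates of 200–400 two-family groups of 4 (800–1600 records).  These
sizes give jackknife/replicate standard errors small enough for the
3-SE and 2-SE checks while keeping a full run in the tens of minutes on
one core.

## Known limitations

* Constant group size; one group per individual (no regrouping).
* Dilution of social effects with group size is not modelled.
* No genomic relationships, maternal effects, repeated records, or
  kin/non-kin differential social effects.
* Classical-model REML assumes i.i.d. residuals; applying it to
  socially affected data estimates a misspecified model (by design —
  that is the comparison of interest).
* The selection-experiment reproductions are sign/ordering tests, not
  quantitative reproductions of field responses.
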