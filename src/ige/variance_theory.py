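"""Closed-form variance and accuracy theory for socially affected traits.

When animals are housed in groups of *n*, the phenotype of individual *i*
is modelled as the sum of its own direct effect and the social effects
contributed by each of its *n* - 1 group mates::

    P_i = A_D,i + E_D,i + sum_{j != i} (A_S,j + E_S,j)  (+ group effect)

Each individual carries two breeding values: a direct breeding value
(DBV, effect on its own phenotype) and a social breeding value (SBV,
effect on each group mate's phenotype).  The total breeding value

    TBV_i = A_D,i + (n - 1) A_S,i

summarises the full heritable impact of the individual on the population
mean, and its variance sigma2_TBV is the heritable variance available for
response to selection.  This module provides the derived (co)variances,
the accuracies of the five classical selection schemes for such traits
(individual, group, multilevel, relatives-based, and classical-EBV
selection), and the response predictor dG = iota * rho * sd(TBV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "GeneticParameterSet",
    "GroupDesign",
    "DerivedVariances",
    "ResponsePrediction",
    "derived_variances",
    "accuracy_individual",
    "accuracy_group",
    "accuracy_multilevel",
    "accuracy_relatives",
    "accuracy_classical_blup",
    "predict_response",
    "intensity_from_selected_fraction",
]

#: tolerance on the smallest eigenvalue when enforcing positive
#: semidefiniteness; slightly negative eigenvalues from round-off are
#: accepted so that degenerate cases (rA = -1, "one winner one loser")
#: remain representable.
PSD_TOL = 1e-10


def _check_psd(matrix: np.ndarray, name: str) -> None:
    eigvals = np.linalg.eigvalsh(matrix)
    scale = max(abs(matrix).max(), 1.0)
    if eigvals.min() < -PSD_TOL * scale:
        raise ValueError(
            f"{name} covariance matrix is not positive semidefinite "
            f"(smallest eigenvalue {eigvals.min():.6g}): {matrix.tolist()}"
        )


@dataclass
class GeneticParameterSet:
    """Genetic and residual (co)variances of the direct-social model.

    All entries are in squared trait units.  ``var_group_env`` is the
    variance of a non-genetic effect common to all members of a group
    (a pen or cage effect); it may be zero.
    """

    var_direct_genetic: float
    var_social_genetic: float
    cov_direct_social_genetic: float
    var_direct_residual: float
    var_social_residual: float
    cov_direct_social_residual: float = 0.0
    var_group_env: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        _check_psd(self.genetic_matrix(), "genetic")
        _check_psd(self.residual_matrix(), "residual")
        if self.var_group_env < 0:
            raise ValueError("var_group_env must be >= 0")

    def genetic_matrix(self) -> np.ndarray:
        """The 2x2 direct-social genetic covariance matrix C."""
        return np.array(
            [
                [self.var_direct_genetic, self.cov_direct_social_genetic],
                [self.cov_direct_social_genetic, self.var_social_genetic],
            ]
        )

    def residual_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.var_direct_residual, self.cov_direct_social_residual],
                [self.cov_direct_social_residual, self.var_social_residual],
            ]
        )

    @property
    def genetic_correlation(self) -> Optional[float]:
        """Direct-social genetic correlation rA, or None when undefined.

        Undefined (not zero) when either genetic variance vanishes.
        """
        denom = self.var_direct_genetic * self.var_social_genetic
        if denom <= 0:
            return None
        return self.cov_direct_social_genetic / math.sqrt(denom)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneticParameterSet":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class GroupDesign:
    """Housing design: group size, relatedness, and scheme parameters.

    ``relatedness_within_group`` (r) is the additive relationship between
    any two group mates.  ``multilevel_weight`` (g) weights group-mate
    phenotypes in the multilevel criterion (g=0 individual selection,
    g=1 group selection).  For relatives-based schemes,
    ``relatedness_candidate_to_relatives`` (r_rel) and
    ``groups_per_candidate`` (m) describe the m groups of n relatives on
    which an individually housed candidate is evaluated.
    """

    group_size: int
    relatedness_within_group: float = 0.0
    multilevel_weight: float = 0.0
    relatedness_candidate_to_relatives: float = 0.5
    groups_per_candidate: int = 1

    def __post_init__(self) -> None:
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2 (social effects need group mates)")
        for name in ("relatedness_within_group", "relatedness_candidate_to_relatives"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.multilevel_weight <= 1.0:
            raise ValueError("multilevel_weight must lie in [0, 1]")
        if self.groups_per_candidate < 1:
            raise ValueError("groups_per_candidate must be >= 1")


@dataclass
class DerivedVariances:
    """All scalar (co)variances derived from a parameter set and a design."""

    var_tbv: float
    t2: float
    var_phenotype: float
    cov_groupmates: float
    var_group_mean: float
    var_criterion: float
    var_total_phenotypic: float
    eta: float
    tau: float
    var_phen_direct: float
    var_phen_social: float
    cov_phen_direct_social: float


@dataclass
class ResponsePrediction:
    scheme: str
    intensity: float
    accuracy: float
    sd_tbv: float
    delta_g: float = field(init=False)

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.accuracy <= 1.0 + 1e-12:
            raise ValueError(f"accuracy must lie in [-1, 1], got {self.accuracy}")
        self.delta_g = self.intensity * self.accuracy * self.sd_tbv


def total_breeding_variance(params: GeneticParameterSet, n: int) -> float:
    """sigma2_TBV = sigma2_AD + 2(n-1) sigma_ADS + (n-1)^2 sigma2_AS."""
    return (
        params.var_direct_genetic
        + 2 * (n - 1) * params.cov_direct_social_genetic
        + (n - 1) ** 2 * params.var_social_genetic
    )


def phenotypic_variance(params: GeneticParameterSet, n: int, r: float) -> float:
    """Var(P_i) in a group of n with pairwise relatedness r.

    Relatedness puts part of the direct-social covariance and of the
    social variance into the individual phenotype, because group mates'
    social effects then co-vary with the individual's own effects.
    The residual direct-social covariance does not enter: an
    individual's own E_S never appears in its own phenotype.
    """
    p = params
    return (
        p.var_direct_genetic
        + p.var_direct_residual
        + (n - 1) * (p.var_social_genetic + p.var_social_residual)
        + r
        * (
            2 * (n - 1) * p.cov_direct_social_genetic
            + (n - 1) * (n - 2) * p.var_social_genetic
        )
        + p.var_group_env
    )


def groupmate_covariance(params: GeneticParameterSet, n: int, r: float) -> float:
    """Cov(P_i, P_j) for two members of the same group.

    Derived from the phenotype model assuming residuals independent
    between individuals: each member's phenotype contains the other's
    social effect (giving the 2*sigma_ADS and 2*sigma_EDS terms and the
    (n-2) shared third-party social effects), while relatedness r links
    every genetic effect of one member to every genetic effect of the
    other.  Verified against simulated populations in the test suite.
    """
    p = params
    return (
        r * p.var_direct_genetic
        + 2 * (1 + (n - 2) * r) * p.cov_direct_social_genetic
        + ((n - 2) + r * ((n - 1) ** 2 - (n - 2))) * p.var_social_genetic
        + 2 * p.cov_direct_social_residual
        + (n - 2) * p.var_social_residual
        + p.var_group_env
    )


def derived_variances(params: GeneticParameterSet, design: GroupDesign) -> DerivedVariances:
    """Compute every derived (co)variance for one parameter set and design."""
    n = design.group_size
    r = design.relatedness_within_group
    g = design.multilevel_weight
    p = params

    var_tbv = total_breeding_variance(p, n)
    var_p = phenotypic_variance(p, n, r)
    cov_ij = groupmate_covariance(p, n, r)
    var_group_mean = (var_p + (n - 1) * cov_ij) / n
    # criterion SC_i = P_i + g * sum of the n-1 group mates' phenotypes
    var_sc = (
        var_p
        + 2 * g * (n - 1) * cov_ij
        + g**2 * ((n - 1) * var_p + (n - 1) * (n - 2) * cov_ij)
    )
    var_pd = p.var_direct_genetic + p.var_direct_residual
    var_ps = p.var_social_genetic + p.var_social_residual
    cov_pds = p.cov_direct_social_genetic + p.cov_direct_social_residual
    var_tpv = var_pd + 2 * (n - 1) * cov_pds + (n - 1) ** 2 * var_ps
    eta = math.sqrt(max(var_tbv, 0.0) / var_tpv) if var_tpv > 0 else float("nan")
    tau = r * eta**2
    return DerivedVariances(
        var_tbv=var_tbv,
        t2=var_tbv / var_p,
        var_phenotype=var_p,
        cov_groupmates=cov_ij,
        var_group_mean=var_group_mean,
        var_criterion=var_sc,
        var_total_phenotypic=var_tpv,
        eta=eta,
        tau=tau,
        var_phen_direct=var_pd,
        var_phen_social=var_ps,
        cov_phen_direct_social=cov_pds,
    )


def accuracy_individual(
    params: GeneticParameterSet, design: GroupDesign
) -> Optional[float]:
    """Accuracy (corr with TBV) of selection on own phenotype.

    rho = {r var_TBV + (1-r)[var_AD + (n-1) cov_ADS]} / (sd_TBV sd_P).
    Returns None when var_TBV = 0 (accuracy undefined).
    """
    n = design.group_size
    r = design.relatedness_within_group
    dv = derived_variances(params, design)
    if dv.var_tbv <= 0:
        return None
    num = r * dv.var_tbv + (1 - r) * (
        params.var_direct_genetic + (n - 1) * params.cov_direct_social_genetic
    )
    return num / math.sqrt(dv.var_tbv * dv.var_phenotype)


def accuracy_group(params: GeneticParameterSet, design: GroupDesign) -> Optional[float]:
    """Accuracy of selection on the group mean phenotype (always >= 0)."""
    n = design.group_size
    r = design.relatedness_within_group
    dv = derived_variances(params, design)
    if dv.var_tbv <= 0:
        return None
    return ((n - 1) * r + 1) * math.sqrt(dv.var_tbv) / (n * math.sqrt(dv.var_group_mean))


def accuracy_multilevel(
    params: GeneticParameterSet, design: GroupDesign
) -> Optional[float]:
    """Accuracy of selection on SC_i = P_i + g * sum_{j != i} P_j.

    Reduces to individual selection at g = 0 and to group selection at
    g = 1 (where SC = n * group mean, a monotone rescaling).
    """
    n = design.group_size
    r = design.relatedness_within_group
    g = design.multilevel_weight
    dv = derived_variances(params, design)
    if dv.var_tbv <= 0:
        return None
    num = (g + r + (n - 2) * g * r) * dv.var_tbv + (1 - g) * (1 - r) * (
        params.var_direct_genetic + (n - 1) * params.cov_direct_social_genetic
    )
    return num / math.sqrt(dv.var_tbv * dv.var_criterion)


def accuracy_relatives(
    params: GeneticParameterSet, design: GroupDesign
) -> Optional[float]:
    """Accuracy of selecting individually housed candidates on the mean
    phenotype of m groups of n relatives.

    rho = r_rel * eta / sqrt(tau + (1 - tau) / (m n)) with
    eta = sd_TBV / sd_TPV and tau = r * eta^2, where r is the
    relatedness among the relatives within their groups and r_rel the
    relatedness of the candidate to its relatives.  As m n -> infinity
    with full sibs (r = r_rel = 1/2) the accuracy tends to sqrt(1/2).

    A non-genetic group effect inflates the variance of the relatives'
    mean by var_group_env / m without adding candidate-TBV covariance;
    the first-principles denominator used here includes that term and
    collapses to the expression above when var_group_env = 0.
    """
    n = design.group_size
    m = design.groups_per_candidate
    if m * n == 0:
        raise ValueError("m * n must be positive")
    dv = derived_variances(params, design)
    if dv.var_tbv <= 0 or not math.isfinite(dv.eta):
        return None
    r = design.relatedness_within_group
    # Var(mean of m groups of n relatives), relatives equally related r:
    var_rel_mean = (
        r * dv.var_tbv
        + (dv.var_total_phenotypic - r * dv.var_tbv) / (m * n)
        + params.var_group_env / m
    )
    return (
        design.relatedness_candidate_to_relatives
        * math.sqrt(dv.var_tbv)
        / math.sqrt(var_rel_mean)
    )


def accuracy_classical_blup(
    params: GeneticParameterSet, design: GroupDesign, rho_mme: float
) -> Optional[float]:
    """Approximate TBV-accuracy of selection on classical (direct-only)
    BLUP EBVs with unrelated group members.

    rho ~= rho_MME * [var_AD + (n-1) cov_ADS] / (sd_AD * sd_TBV); the
    bracket is corr(DBV, TBV), so the sign of the response equals the
    sign of var_AD + (n-1) cov_ADS, matching individual selection.
    ``rho_mme`` is the ordinary accuracy of the EBV as computed from the
    mixed-model equations.  Returns None when undefined.
    """
    n = design.group_size
    var_tbv = total_breeding_variance(params, n)
    if params.var_direct_genetic <= 0 or var_tbv <= 0:
        return None
    bracket = (
        params.var_direct_genetic + (n - 1) * params.cov_direct_social_genetic
    ) / math.sqrt(params.var_direct_genetic * var_tbv)
    return rho_mme * bracket


def predict_response(
    intensity: float, accuracy: float, sd_tbv: float, scheme: str = ""
) -> ResponsePrediction:
    """Predicted response per generation, dG = iota * rho * sd_TBV."""
    for name, v in (("intensity", intensity), ("accuracy", accuracy), ("sd_tbv", sd_tbv)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    return ResponsePrediction(
        scheme=scheme, intensity=intensity, accuracy=accuracy, sd_tbv=sd_tbv
    )


def intensity_from_selected_fraction(p: float) -> float:
    """Selection intensity of truncating a standard normal at fraction p.

    iota = phi(z_p) / p where z_p is the upper-tail truncation point.
    Monotone decreasing in p; iota -> 0 as p -> 1.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"selected fraction must lie in (0, 1), got {p}")
    z = stats.norm.isf(p)
    return stats.norm.pdf(z) / p
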