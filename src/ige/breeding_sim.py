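"""Forward stochastic simulation of group-housed populations with direct
and social genetic effects.

Every individual carries four latent components: direct and social
genetic effects (A_D, A_S), drawn jointly from the 2x2 genetic matrix C,
and direct and social residuals (E_D, E_S) from the residual matrix.
Phenotypes are assembled exactly as

    P_i = A_D,i + E_D,i + sum_{j in group, j != i} (A_S,j + E_S,j) + g_grp

so every closed-form (co)variance of the theory layer can be checked
against sample moments.  The simulator supports the five selection
schemes (own phenotype, group mean, multilevel, relatives' mean, and
BLUP EBVs via the pedigree module), discrete generations, separate
sexes, and hierarchical sire-dam matings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .variance_theory import GeneticParameterSet

__all__ = [
    "SimConfig",
    "GenerationSummary",
    "sample_founders",
    "make_groups",
    "realize_phenotypes",
    "compute_criterion",
    "truncation_select",
    "breed_offspring",
    "run_scheme",
    "structured_population",
    "relatives_design",
    "mean_within_group_relatedness",
]

POP_COLUMNS = [
    "id", "sire", "dam", "sex", "a_d", "a_s", "e_d", "e_s",
    "group", "phenotype", "generation",
]

GROUP_MODES = ("unrelated", "half-sib", "full-sib", "two-family")


@dataclass
class SimConfig:
    """Configuration of a forward breeding simulation.

    ``composition`` controls the family structure of groups (and hence
    the within-group relatedness r: unrelated 0, half-sib 0.25,
    full-sib 0.5, two-family mixed).  ``scheme`` is one of IS, GS, MS,
    SR, EBV-D (selection on direct EBVs from the direct-social model),
    EBV-TBV (selection on total EBVs), EBV-C (classical-model EBVs) or
    random.  A seed is mandatory: every run is replayable.
    """

    params: GeneticParameterSet
    group_size: int
    composition: str
    scheme: str
    seed: int
    n_sires: int = 20
    dams_per_sire: int = 4
    offspring_per_dam: int = 8
    selected_fraction: float = 0.25
    multilevel_weight: float = 0.5
    groups_per_candidate: int = 1
    generations: int = 1
    mendelian_inbreeding_correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.selected_fraction <= 1.0:
            raise ValueError("selected_fraction must lie in (0, 1]")
        if self.composition not in GROUP_MODES:
            raise ValueError(f"unknown composition {self.composition!r}")
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")


@dataclass
class GenerationSummary:
    generation: int
    mean_tbv: float
    mean_phenotype: float
    realized_intensity: float
    empirical_accuracy: float
    var_tbv: float
    var_phenotype: float
    n: int


def _mvn(cov: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Bivariate normal draws tolerant of singular covariance matrices."""
    if not np.any(cov):
        return np.zeros((size, 2))
    return rng.multivariate_normal(
        np.zeros(2), cov, size=size, method="eigh", check_valid="ignore"
    )


def sample_founders(
    n_individuals: int,
    params: GeneticParameterSet,
    rng: np.random.Generator,
    generation: int = 0,
    start_id: int = 1,
) -> pd.DataFrame:
    """Unrelated, non-inbred base individuals with all four components."""
    gen = _mvn(params.genetic_matrix(), n_individuals, rng)
    res = _mvn(params.residual_matrix(), n_individuals, rng)
    sex = np.zeros(n_individuals, dtype=np.int8)
    sex[rng.permutation(n_individuals)[: n_individuals // 2]] = 1
    return pd.DataFrame(
        {
            "id": np.arange(start_id, start_id + n_individuals, dtype=np.int64),
            "sire": 0,
            "dam": 0,
            "sex": sex,  # 1 = male
            "a_d": gen[:, 0],
            "a_s": gen[:, 1],
            "e_d": res[:, 0],
            "e_s": res[:, 1],
            "group": -1,
            "phenotype": np.nan,
            "generation": generation,
        }
    )


def total_breeding_values(pop: pd.DataFrame, n: int) -> np.ndarray:
    return (pop["a_d"] + (n - 1) * pop["a_s"]).to_numpy()


def _family_key(pop: pd.DataFrame, mode: str) -> pd.Series:
    if mode == "half-sib":
        return pop["sire"].astype(str)
    return pop["sire"].astype(str) + "x" + pop["dam"].astype(str)


def make_groups(
    pop: pd.DataFrame, mode: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign every individual to one group of size n.

    unrelated  -- at most one member per full-sib family and per sire
                  in any group;
    half-sib   -- groups drawn from one sire family, one offspring per
                  dam (so every pair shares the sire only, r = 1/4);
    full-sib   -- groups drawn entirely from one full-sib family (r = 1/2);
    two-family -- n/2 members from each of two unrelated full-sib
                  families (identifiability design).
    """
    if mode not in GROUP_MODES:
        raise ValueError(f"unknown group mode {mode!r}")
    if len(pop) % n:
        raise ValueError(f"population size {len(pop)} not divisible by group size {n}")
    pop = pop.copy()
    n_groups = len(pop) // n
    group = np.full(len(pop), -1, dtype=np.int64)

    if mode == "unrelated":
        # spread sire families across groups: sort by sire with random
        # tie-break, then deal round-robin
        order = np.lexsort((rng.random(len(pop)), pop["sire"].to_numpy()))
        group[order] = np.arange(len(pop)) % n_groups
    elif mode == "full-sib":
        fams = _family_key(pop, mode)
        if (fams.value_counts() % n).any():
            raise ValueError("full-sib family sizes must be divisible by group size")
        gid = 0
        for _, idx in pop.groupby(fams.to_numpy()).indices.items():
            idx = rng.permutation(idx)
            for start in range(0, len(idx), n):
                group[idx[start : start + n]] = gid
                gid += 1
    elif mode == "half-sib":
        # per sire: deal offspring so that no two members of a group
        # share a dam
        gid = 0
        for _, idx in pop.groupby(pop["sire"].to_numpy()).indices.items():
            sub = pop.iloc[idx]
            if len(idx) % n:
                raise ValueError("sire family sizes must be divisible by group size")
            order = np.lexsort((rng.random(len(sub)), sub["dam"].to_numpy()))
            n_sub = len(idx) // n
            dams_per_group = pd.Series(idx[order]).groupby(np.arange(len(idx)) % n_sub)
            for _, block in dams_per_group:
                members = block.to_numpy()
                dams = pop["dam"].to_numpy()[members]
                if len(set(dams.tolist())) != len(members):
                    raise ValueError(
                        "not enough distinct dams per sire for half-sib groups"
                    )
                group[members] = gid
                gid += 1
    else:  # two-family
        if n % 2:
            raise ValueError("two-family groups need an even group size")
        fams = _family_key(pop, mode)
        half = n // 2
        by_family = []  # list of half-group index arrays per family
        for _, idx in pop.groupby(fams.to_numpy()).indices.items():
            if len(idx) % half:
                raise ValueError(
                    "family sizes must be divisible by half the group size"
                )
            idx = rng.permutation(idx)
            by_family.append([idx[s : s + half] for s in range(0, len(idx), half)])
        if len(by_family) < 3:
            raise ValueError(
                "two-family groups need at least 3 families (with only 2, "
                "every family shares all its groups with the same partner "
                "and direct/social components stay confounded)"
            )
        # ring pairing: group k is made of one half-group of family k and
        # one of family k+1 (mod K), so every family shares its two
        # groups with two *different* partner families.  Pairing both
        # halves of a family with the same partner would leave the
        # direct and social components confounded.
        order = rng.permutation(len(by_family))
        halves = [list(by_family[k]) for k in order]
        gid = 0
        K = len(halves)
        if all(len(h) == 2 for h in halves):
            for k in range(K):
                group[halves[k][1]] = gid
                group[halves[(k + 1) % K][0]] = gid
                gid += 1
        else:
            # unequal family sizes: walk the ring repeatedly, always
            # joining consecutive families that still have halves left
            remaining = [list(h) for h in halves]
            while any(remaining):
                progress = False
                for k in range(K):
                    nxt = next(
                        (j for j in range(1, K)
                         if remaining[(k + j) % K]),
                        None,
                    )
                    if remaining[k] and nxt is not None and remaining[(k + nxt) % K]:
                        group[remaining[k].pop()] = gid
                        group[remaining[(k + nxt) % K].pop()] = gid
                        gid += 1
                        progress = True
                if not progress:
                    raise ValueError(
                        "cannot pair two half-groups of the same family"
                    )
    pop["group"] = group
    return pop


def realize_phenotypes(
    pop: pd.DataFrame,
    params: GeneticParameterSet,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assemble phenotypes from the stored components (exact, no extra noise).

    Requires every individual to belong to a group; all groups must have
    equal size.  A common group environmental effect is added when
    var_group_env > 0.
    """
    if (pop["group"] < 0).any():
        raise ValueError("unassigned individuals: run make_groups first")
    sizes = pop.groupby("group").size()
    if sizes.nunique() != 1:
        raise ValueError("groups must have equal size")
    pop = pop.copy()
    social = pop["a_s"] + pop["e_s"]
    group_social = social.groupby(pop["group"]).transform("sum")
    phen = pop["a_d"] + pop["e_d"] + (group_social - social)
    if params.var_group_env > 0:
        groups = pop["group"].to_numpy()
        uniq, inv = np.unique(groups, return_inverse=True)
        eff = rng.normal(0.0, math.sqrt(params.var_group_env), size=len(uniq))
        phen = phen + eff[inv]
    pop["phenotype"] = phen.to_numpy()
    return pop


def compute_criterion(
    pop: pd.DataFrame,
    scheme: str,
    multilevel_weight: float = 0.5,
    ebv: Optional[pd.Series] = None,
) -> np.ndarray:
    """Per-candidate selection score for group-housed schemes.

    IS: own phenotype; GS: group mean (every member of a group scores
    the same); MS: P_i + g * sum of group mates' phenotypes.  EBV-based
    schemes pass the EBV series directly.  SR scores are computed by
    :func:`relatives_design`, which owns the candidate/relative split.
    """
    if scheme == "IS":
        return pop["phenotype"].to_numpy()
    if scheme == "GS":
        return pop.groupby("group")["phenotype"].transform("mean").to_numpy()
    if scheme == "MS":
        g = multilevel_weight
        total = pop.groupby("group")["phenotype"].transform("sum")
        return (pop["phenotype"] + g * (total - pop["phenotype"])).to_numpy()
    if scheme in ("EBV-D", "EBV-TBV", "EBV-C"):
        if ebv is None:
            raise ValueError(f"scheme {scheme} needs EBVs")
        return ebv.loc[pop["id"]].to_numpy()
    raise ValueError(f"unknown scheme {scheme!r}")


def truncation_select(
    pop: pd.DataFrame, scores: np.ndarray, n_males: int, n_females: int
) -> pd.DataFrame:
    """Top-scoring individuals within each sex."""
    pop = pop.assign(_score=scores)
    males = pop[pop["sex"] == 1].nlargest(n_males, "_score")
    females = pop[pop["sex"] == 0].nlargest(n_females, "_score")
    if len(males) < n_males or len(females) < n_females:
        raise ValueError(
            f"not enough candidates: need {n_males} males / {n_females} females, "
            f"have {int((pop['sex']==1).sum())} / {int((pop['sex']==0).sum())}"
        )
    return pd.concat([males, females]).drop(columns="_score")


def breed_offspring(
    selected: pd.DataFrame,
    params: GeneticParameterSet,
    rng: np.random.Generator,
    offspring_per_dam: int,
    start_id: int,
    generation: int,
    mean_inbreeding: float = 0.0,
) -> pd.DataFrame:
    """Hierarchical random mating: each dam is nested within one sire.

    Offspring genetic effects are the parent average plus a Mendelian
    deviation drawn from C/2 (optionally scaled by 1 - mean parental F).
    """
    sires = selected[selected["sex"] == 1]
    dams = selected[selected["sex"] == 0]
    if not len(sires) or not len(dams):
        raise ValueError("need selected parents of both sexes")
    if len(dams) % len(sires):
        raise ValueError("number of dams must be a multiple of number of sires")
    d_per_s = len(dams) // len(sires)
    sire_of_dam = np.repeat(
        sires["id"].to_numpy()[rng.permutation(len(sires))], d_per_s
    )
    dam_ids = dams["id"].to_numpy()[rng.permutation(len(dams))]

    n_off = len(dams) * offspring_per_dam
    off_sire = np.repeat(sire_of_dam, offspring_per_dam)
    off_dam = np.repeat(dam_ids, offspring_per_dam)

    by_id = selected.set_index("id")
    parent_mean = 0.5 * (
        by_id.loc[off_sire, ["a_d", "a_s"]].to_numpy()
        + by_id.loc[off_dam, ["a_d", "a_s"]].to_numpy()
    )
    ms_scale = 0.5 * (1.0 - mean_inbreeding)
    mend = _mvn(params.genetic_matrix() * ms_scale, n_off, rng)
    res = _mvn(params.residual_matrix(), n_off, rng)
    sex = np.zeros(n_off, dtype=np.int8)
    sex[rng.permutation(n_off)[: n_off // 2]] = 1
    return pd.DataFrame(
        {
            "id": np.arange(start_id, start_id + n_off, dtype=np.int64),
            "sire": off_sire,
            "dam": off_dam,
            "sex": sex,
            "a_d": parent_mean[:, 0] + mend[:, 0],
            "a_s": parent_mean[:, 1] + mend[:, 1],
            "e_d": res[:, 0],
            "e_s": res[:, 1],
            "group": -1,
            "phenotype": np.nan,
            "generation": generation,
        }
    )


def _summary(pop: pd.DataFrame, n: int, scores: Optional[np.ndarray],
             realized_intensity: float) -> GenerationSummary:
    tbv = total_breeding_values(pop, n)
    acc = float("nan")
    if scores is not None and np.std(scores) > 0 and np.std(tbv) > 0:
        acc = float(np.corrcoef(scores, tbv)[0, 1])
    return GenerationSummary(
        generation=int(pop["generation"].iloc[0]),
        mean_tbv=float(np.mean(tbv)),
        mean_phenotype=float(pop["phenotype"].mean()),
        realized_intensity=realized_intensity,
        empirical_accuracy=acc,
        var_tbv=float(np.var(tbv)),
        var_phenotype=float(np.var(pop["phenotype"].to_numpy())),
        n=len(pop),
    )


def run_scheme(config: SimConfig, ebv_solver: Optional[Callable] = None):
    """Run a multi-generation selection scheme.

    Returns (summaries, final population, pedigree frame).  For EBV
    schemes a solver callback(records, pedigree_frame, params) -> Series
    of EBVs indexed by id must be supplied (the CLI wires this to the
    pedigree module; keeping it a callback avoids a circular import).
    """
    from .variance_theory import intensity_from_selected_fraction

    rng = np.random.default_rng(config.seed)
    n = config.group_size
    n_parents_m = config.n_sires
    n_parents_f = config.n_sires * config.dams_per_sire

    pop = sample_founders(
        2 * n_parents_f, config.params, rng, generation=0, start_id=1
    )
    pedigree_frames = [pop[["id", "sire", "dam"]]]
    next_id = int(pop["id"].max()) + 1
    summaries: list[GenerationSummary] = []

    parents = truncation_select(pop, rng.random(len(pop)), n_parents_m, n_parents_f)
    for gen in range(1, config.generations + 1):
        off = breed_offspring(
            parents, config.params, rng, config.offspring_per_dam, next_id, gen
        )
        next_id = int(off["id"].max()) + 1
        pedigree_frames.append(off[["id", "sire", "dam"]])
        off = make_groups(off, config.composition, n, rng)
        off = realize_phenotypes(off, config.params, rng)

        if config.scheme == "random":
            scores = rng.random(len(off))
        elif config.scheme in ("EBV-D", "EBV-TBV", "EBV-C"):
            if ebv_solver is None:
                raise ValueError("EBV schemes need an ebv_solver callback")
            ped_frame = pd.concat(pedigree_frames, ignore_index=True)
            ebv = ebv_solver(off, ped_frame, config.params, config.scheme)
            scores = compute_criterion(off, config.scheme, ebv=ebv)
        else:
            scores = compute_criterion(off, config.scheme, config.multilevel_weight)

        n_m = max(int(round((off["sex"] == 1).sum() * config.selected_fraction)), 1)
        n_f = max(int(round((off["sex"] == 0).sum() * config.selected_fraction)), 1)
        n_m = min(n_m, int((off["sex"] == 1).sum()))
        n_f = min(n_f, int((off["sex"] == 0).sum()))
        if config.scheme == "random":
            realized_int = 0.0
        else:
            sd = scores.std() if hasattr(scores, "std") else np.std(scores)
            sel_idx = truncation_select(off, scores, n_m, n_f).index
            mean_sel = np.mean(np.asarray(scores)[off.index.get_indexer(sel_idx)])
            realized_int = (
                float((mean_sel - np.mean(scores)) / sd) if sd > 0 else 0.0
            )
        summaries.append(_summary(off, n, np.asarray(scores), realized_int))

        want_m = min(n_parents_m, n_m)
        want_f = min(n_parents_f, n_f)
        parents = truncation_select(off, scores, want_m, want_f)
        # keep the hierarchical structure: dams multiple of sires
        want_f -= want_f % max(want_m, 1)
        parents = pd.concat(
            [
                parents[parents["sex"] == 1].head(want_m),
                parents[parents["sex"] == 0].head(want_f),
            ]
        )
        pop = off
    ped = pd.concat(pedigree_frames, ignore_index=True)
    return summaries, pop, ped


# ---------------------------------------------------------------------------
# structured single-cohort populations (the simulation oracle)
# ---------------------------------------------------------------------------

def structured_population(
    params: GeneticParameterSet,
    n: int,
    mode: str,
    n_groups: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One cohort of grouped, phenotyped individuals with exact nominal
    within-group relatedness (0, 1/4, 1/2, or the two-family mosaic).

    Families are produced from unrelated, non-inbred founder parents in
    one round of breeding, so half sibs have relatedness exactly 1/4 and
    full sibs exactly 1/2.  Returns (population, pedigree frame).
    """
    if mode not in GROUP_MODES:
        raise ValueError(f"unknown group mode {mode!r}")
    total = n_groups * n
    if mode == "unrelated":
        pop = sample_founders(total, params, rng)
        pop = make_groups(pop, "unrelated", n, rng)
        pop = realize_phenotypes(pop, params, rng)
        return pop, pop[["id", "sire", "dam"]].copy()

    if mode == "full-sib":
        n_fams = n_groups
        sires, dams = n_fams, n_fams
        per_dam = n
    elif mode == "half-sib":
        n_fams = n_groups  # sire families
        sires, dams = n_fams, n_fams * n
        per_dam = 1
    else:  # two-family
        if n % 2:
            raise ValueError("two-family groups need an even group size")
        n_fams = n_groups  # one full-sib family contributes to 2 groups... see below
        sires, dams = n_fams, n_fams
        per_dam = n  # family of n split over two groups
    founders = sample_founders(sires + dams, params, rng)
    founders.loc[founders.index[:sires], "sex"] = 1
    founders.loc[founders.index[sires:], "sex"] = 0
    sire_ids = founders["id"].to_numpy()[:sires]
    dam_ids = founders["id"].to_numpy()[sires:]

    if mode == "half-sib":
        off_sire = np.repeat(sire_ids, n)
        off_dam = dam_ids
    else:
        off_sire = np.repeat(sire_ids, per_dam)
        off_dam = np.repeat(dam_ids, per_dam)

    by_id = founders.set_index("id")
    pm = 0.5 * (
        by_id.loc[off_sire, ["a_d", "a_s"]].to_numpy()
        + by_id.loc[off_dam, ["a_d", "a_s"]].to_numpy()
    )
    n_off = len(off_sire)
    mend = _mvn(params.genetic_matrix() * 0.5, n_off, rng)
    res = _mvn(params.residual_matrix(), n_off, rng)
    start = int(founders["id"].max()) + 1
    pop = pd.DataFrame(
        {
            "id": np.arange(start, start + n_off, dtype=np.int64),
            "sire": off_sire,
            "dam": off_dam,
            "sex": rng.integers(0, 2, n_off).astype(np.int8),
            "a_d": pm[:, 0] + mend[:, 0],
            "a_s": pm[:, 1] + mend[:, 1],
            "e_d": res[:, 0],
            "e_s": res[:, 1],
            "group": -1,
            "phenotype": np.nan,
            "generation": 1,
        }
    )
    pop = make_groups(pop, mode, n, rng)
    pop = realize_phenotypes(pop, params, rng)
    ped = pd.concat(
        [founders[["id", "sire", "dam"]], pop[["id", "sire", "dam"]]],
        ignore_index=True,
    )
    return pop, ped


def relatives_design(
    params: GeneticParameterSet,
    n: int,
    m: int,
    relative_kind: str,  # 'full-sib' | 'half-sib'
    n_candidates: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Individually housed candidates scored on m groups of n sib relatives.

    full-sib: candidate and relatives share both parents (r_rel = 1/2,
    and relatives are full sibs of each other, r = 1/2).  half-sib: all
    share the sire only, every individual from a distinct dam (r_rel =
    r = 1/4).  Candidates have no own phenotype.  Returns
    (candidates with 'criterion' and 'tbv' columns, relatives frame).
    """
    if relative_kind not in ("full-sib", "half-sib"):
        raise ValueError("relative_kind must be 'full-sib' or 'half-sib'")
    rel_per_cand = m * n
    per_fam = 1 + rel_per_cand  # candidate + relatives
    dams_per_fam = 1 if relative_kind == "full-sib" else per_fam
    sires = n_candidates
    n_dams = n_candidates * dams_per_fam
    founders = sample_founders(sires + n_dams, params, rng)
    sire_ids = founders["id"].to_numpy()[:sires]
    dam_ids = founders["id"].to_numpy()[sires:]
    sire_gen = founders[["a_d", "a_s"]].to_numpy()[:sires]
    dam_gen = founders[["a_d", "a_s"]].to_numpy()[sires:]

    # offspring laid out family-major: [cand, rel_1 .. rel_mn] per family
    off_sire = np.repeat(sire_ids, per_fam)
    sire_mean = np.repeat(sire_gen, per_fam, axis=0)
    if relative_kind == "full-sib":
        off_dam = np.repeat(dam_ids, per_fam)
        dam_mean = np.repeat(dam_gen, per_fam, axis=0)
    else:  # one offspring per dam so all pairs share the sire only
        off_dam = dam_ids
        dam_mean = dam_gen
    n_off = n_candidates * per_fam
    gen_eff = 0.5 * (sire_mean + dam_mean) + _mvn(
        params.genetic_matrix() * 0.5, n_off, rng
    )
    res = _mvn(params.residual_matrix(), n_off, rng)
    start = int(founders["id"].max()) + 1
    ids = np.arange(start, start + n_off, dtype=np.int64)

    is_cand = np.zeros(n_off, dtype=bool)
    is_cand[::per_fam] = True
    # groups: relatives of family k fill groups [k*m, (k+1)*m)
    within = np.tile(np.arange(per_fam), n_candidates)
    group = np.repeat(np.arange(n_candidates) * m, per_fam) + (within - 1) // n

    cands = pd.DataFrame(
        {
            "id": ids[is_cand],
            "sire": off_sire[is_cand],
            "dam": off_dam[is_cand],
            "a_d": gen_eff[is_cand, 0],
            "a_s": gen_eff[is_cand, 1],
        }
    )
    rel = pd.DataFrame(
        {
            "id": ids[~is_cand],
            "sire": off_sire[~is_cand],
            "dam": off_dam[~is_cand],
            "a_d": gen_eff[~is_cand, 0],
            "a_s": gen_eff[~is_cand, 1],
            "e_d": res[~is_cand, 0],
            "e_s": res[~is_cand, 1],
            "group": group[~is_cand],
            "phenotype": np.nan,
            "sex": 0,
            "generation": 1,
        }
    )
    rel = realize_phenotypes(rel, params, rng)
    # criterion: mean phenotype over the candidate's m*n relatives
    rel["candidate"] = np.repeat(cands["id"].to_numpy(), rel_per_cand)
    cands["criterion"] = (
        rel.groupby("candidate")["phenotype"].mean().loc[cands["id"]].to_numpy()
    )
    cands["tbv"] = cands["a_d"] + (n - 1) * cands["a_s"]
    return cands, rel


def mean_within_group_relatedness(pop: pd.DataFrame, ped_frame: pd.DataFrame) -> float:
    """Mean pairwise additive relationship within groups, from the A-matrix."""
    from .pedigree_blup import Pedigree

    ped = Pedigree.from_frame(ped_frame)
    A = ped.amatrix()
    idx = ped.index_of(pop["id"].to_numpy())
    total, count = 0.0, 0
    groups = pop.groupby("group").indices
    for _, rows in groups.items():
        ii = idx[rows]
        sub = A[np.ix_(ii, ii)]
        k = len(ii)
        total += sub.sum() - np.trace(sub)
        count += k * (k - 1)
    return total / count
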