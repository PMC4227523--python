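"""Scripted experiments tying theory, BLUP/REML, and simulation together.

Four experiments are provided:

* :func:`reproduce_table3` -- the laying-hen worked example: predicted
  responses for survival time under individual selection (IS), group
  selection (GS), and selection on relatives (SR) in purebred and
  crossbred populations, at unit selection intensity, for unrelated,
  half-sib and full-sib group compositions.
* :func:`mc_accuracy_suite` -- Monte-Carlo verification of every
  closed-form accuracy against the empirical correlation between the
  selection criterion and the true total breeding value.
* :func:`recovery_experiment` -- REML parameter recovery on two-family
  group designs, and the expected identifiability failure on
  single-family designs.
* :func:`dblup_vs_cblup_experiment` -- realized response to one
  generation of selection on total EBVs versus direct EBVs under
  heritable competition.

Every experiment is seeded and re-runs bit-identically; tolerances are
fixed in the experiment definitions, not chosen per run.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .variance_theory import (
    GeneticParameterSet,
    GroupDesign,
    accuracy_group,
    accuracy_individual,
    accuracy_multilevel,
    accuracy_relatives,
    predict_response,
    total_breeding_variance,
)
from . import breeding_sim as sim
from . import pedigree_blup as blup
from .io_cli import FIXTURE_REGIMES, bundled_layer_parameters

__all__ = [
    "ExperimentReport",
    "TABLE3_REFERENCE",
    "table3_predictions",
    "reproduce_table3",
    "mc_accuracy_suite",
    "response_suite",
    "recovery_experiment",
    "dblup_vs_cblup_experiment",
    "classical_blup_grouping_experiment",
]


@dataclass
class ExperimentReport:
    name: str
    table: pd.DataFrame
    passed: bool
    seed: Optional[int]
    runtime_s: float
    notes: str = ""

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        head = f"[{status}] {self.name} (seed={self.seed}, {self.runtime_s:.1f}s)"
        if self.notes:
            head += f"\n{self.notes}"
        return head + "\n" + self.table.to_string(index=False)


# ---------------------------------------------------------------------------
# worked example: predicted responses for laying-hen survival time
# ---------------------------------------------------------------------------

#: published predicted responses (days per generation, iota = 1) used as
#: the regression reference for the worked example.  Keys:
#: (population, scheme, relatedness-label, m).
TABLE3_REFERENCE = {
    ("purebred", "IS", "unrelated", 1): 9.7,
    ("purebred", "IS", "HS", 1): 12.6,
    ("purebred", "IS", "FS", 1): 15.5,
    ("purebred", "GS", "unrelated", 1): 9.6,
    ("purebred", "GS", "HS", 1): 16.1,
    ("purebred", "GS", "FS", 1): 22.1,
    ("purebred", "SR", "HS", 1): 8.8,
    ("purebred", "SR", "FS", 1): 16.7,
    ("purebred", "SR", "HS", 10): 19.1,
    ("purebred", "SR", "FS", 10): 30.4,
    ("crossbred", "IS", "unrelated", 1): -8.1,
    ("crossbred", "IS", "HS", 1): 0.0,
    ("crossbred", "IS", "FS", 1): 8.1,
    ("crossbred", "GS", "unrelated", 1): 10.5,
    ("crossbred", "GS", "HS", 1): 17.5,
    ("crossbred", "GS", "FS", 1): 24.1,
    ("crossbred", "SR", "HS", 1): 9.3,
    ("crossbred", "SR", "FS", 1): 18.0,
    ("crossbred", "SR", "HS", 10): 21.5,
    ("crossbred", "SR", "FS", 10): 35.0,
}

_REL = {"unrelated": 0.0, "HS": 0.25, "FS": 0.5}


def _cell_prediction(
    lines: Sequence[GeneticParameterSet],
    n: int,
    scheme: str,
    rel_label: str,
    m: int,
    intensity: float = 1.0,
) -> float:
    """Mean predicted response over the population's lines for one cell."""
    r = _REL[rel_label]
    values = []
    for params in lines:
        if scheme == "IS":
            design = GroupDesign(n, r)
            rho = accuracy_individual(params, design)
        elif scheme == "GS":
            design = GroupDesign(n, r)
            rho = accuracy_group(params, design)
        elif scheme == "SR":
            design = GroupDesign(
                n, r, relatedness_candidate_to_relatives=r, groups_per_candidate=m
            )
            rho = accuracy_relatives(params, design)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        sd_tbv = math.sqrt(total_breeding_variance(params, n))
        values.append(predict_response(intensity, rho, sd_tbv, scheme).delta_g)
    return float(np.mean(values))


def table3_predictions(
    parameter_table: Optional[dict] = None, intensity: float = 1.0
) -> pd.DataFrame:
    """Predicted responses for every cell of the worked example.

    ``parameter_table`` follows the layout of
    :func:`ige.io_cli.load_parameter_table`; by default the bundled
    laying-hen sets are used.  Per-population predictions are the mean
    over that population's lines.
    """
    table = parameter_table if parameter_table is not None else bundled_layer_parameters()
    n = table["group_size"]
    rows = []
    for (pop, scheme, rel, m), reference in TABLE3_REFERENCE.items():
        lines = table["populations"][pop]
        pred = _cell_prediction(lines, n, scheme, rel, m, intensity)
        rows.append(
            {
                "population": pop,
                "scheme": scheme,
                "relatedness": rel,
                "m": m,
                "predicted_dG": pred,
                "reference_dG": reference,
                "abs_dev": abs(pred - reference),
            }
        )
    return pd.DataFrame(rows)


def reproduce_table3(
    parameter_table: Optional[dict] = None,
    tolerance: float = 0.05,
) -> ExperimentReport:
    """Reproduce the predicted-response table for laying-hen survival.

    Tolerance +-0.05 days: the reference values are printed rounded to
    one decimal.  Without a parameter file the bundled reconstructed
    sets are used; a caller-supplied table is run as-is (fixture mode is
    flagged in the notes when the supplied table carries
    ``fixture=True``).
    """
    t0 = time.time()
    notes = ""
    if parameter_table is None:
        table = bundled_layer_parameters()
    else:
        table = parameter_table
        if table.get("fixture"):
            notes = (
                "ILLUSTRATIVE ONLY: running with fixture parameter values, "
                "predictions will not match the reference column"
            )
    df = table3_predictions(table)
    passed = bool((df["abs_dev"] <= tolerance).all())
    return ExperimentReport(
        name="table3-predicted-responses",
        table=df,
        passed=passed,
        seed=None,
        runtime_s=time.time() - t0,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo accuracy suite
# ---------------------------------------------------------------------------

def _block_corr(x, y, blocks, n_blocks=50):
    """Correlation and its Monte-Carlo SE by delete-one-block jackknife.

    Group mates' criteria and breeding values are correlated, so the
    i.i.d. formula understates the sampling error; clusters (groups or
    candidate families) are collected into ``n_blocks`` blocks and the
    jackknife over blocks gives the SE.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    codes = pd.factorize(np.asarray(blocks))[0] % n_blocks
    # sufficient statistics per block -> exact delete-one-block corr
    stats_all = np.array([x.sum(), y.sum(), (x * x).sum(), (y * y).sum(),
                          (x * y).sum(), float(len(x))])
    per_block = np.zeros((n_blocks, 6))
    for col, arr in enumerate((x, y, x * x, y * y, x * y, np.ones_like(x))):
        per_block[:, col] = np.bincount(codes, weights=arr, minlength=n_blocks)

    def corr_from(s):
        sx, sy, sxx, syy, sxy, m = s
        cov = sxy / m - (sx / m) * (sy / m)
        vx = sxx / m - (sx / m) ** 2
        vy = syy / m - (sy / m) ** 2
        return cov / math.sqrt(vx * vy)

    emp = corr_from(stats_all)
    loo = np.array([corr_from(stats_all - per_block[b]) for b in range(n_blocks)])
    se = math.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum())
    return float(emp), float(se)


def mc_accuracy_suite(
    regimes: Optional[Sequence[str]] = None,
    r_values: Sequence[float] = (0.0, 0.25, 0.5),
    n_individuals: int = 200_000,
    seed: int = 1,
    multilevel_weight: float = 0.5,
    sr_groups: Sequence[int] = (1, 10),
    se_multiple: float = 3.0,
) -> ExperimentReport:
    """Empirical corr(criterion, TBV) versus each closed-form accuracy.

    For every (regime, r, scheme) cell a fresh cohort of about
    ``n_individuals`` is simulated with the exact nominal relatedness and
    the sample correlation is compared with the formula within
    ``se_multiple`` Monte-Carlo standard errors.
    """
    t0 = time.time()
    regimes = list(regimes or FIXTURE_REGIMES)
    rng = np.random.default_rng(seed)
    rows = []
    modes = {0.0: "unrelated", 0.25: "half-sib", 0.5: "full-sib"}
    for regime_name in regimes:
        regime = FIXTURE_REGIMES[regime_name]
        params = regime.params
        n = regime.design.group_size
        for r in r_values:
            mode = modes[r]
            n_groups = max(n_individuals // n, 10)
            pop, _ = sim.structured_population(params, n, mode, n_groups, rng)
            tbv = sim.total_breeding_values(pop, n)
            schemes = {
                "IS": accuracy_individual(params, GroupDesign(n, r)),
                "GS": accuracy_group(params, GroupDesign(n, r)),
                "MS": accuracy_multilevel(
                    params, GroupDesign(n, r, multilevel_weight=multilevel_weight)
                ),
            }
            for scheme, analytic in schemes.items():
                crit = sim.compute_criterion(pop, scheme, multilevel_weight)
                emp, se = _block_corr(crit, tbv, pop["group"].to_numpy())
                rows.append(
                    dict(
                        regime=regime_name, scheme=scheme, r=r, m=1,
                        analytic=analytic, empirical=emp, se=se,
                        ok=abs(emp - analytic) <= se_multiple * se,
                    )
                )
            if r in (0.25, 0.5):  # SR needs sib relatives
                kind = mode
                for m in sr_groups:
                    n_cand = max(n_individuals // (m * n + 1), 10)
                    cands, _ = sim.relatives_design(params, n, m, kind, n_cand, rng)
                    design = GroupDesign(
                        n, r, relatedness_candidate_to_relatives=r,
                        groups_per_candidate=m,
                    )
                    analytic = accuracy_relatives(params, design)
                    emp, se = _block_corr(
                        cands["criterion"], cands["tbv"], cands["id"].to_numpy()
                    )
                    rows.append(
                        dict(
                            regime=regime_name, scheme="SR", r=r, m=m,
                            analytic=analytic, empirical=emp, se=se,
                            ok=abs(emp - analytic) <= se_multiple * se,
                        )
                    )
    df = pd.DataFrame(rows)
    return ExperimentReport(
        name="mc-accuracy-suite",
        table=df,
        passed=bool(df["ok"].all()),
        seed=seed,
        runtime_s=time.time() - t0,
        notes=f"{int(df['ok'].sum())}/{len(df)} cells within "
              f"{se_multiple} SE",
    )


# ---------------------------------------------------------------------------
# one-generation realized response vs iota * rho * sd(TBV)
# ---------------------------------------------------------------------------

def response_suite(
    schemes: Sequence[str] = ("IS", "GS", "MS", "SR"),
    replicates: int = 50,
    seed: int = 1,
    params: Optional[GeneticParameterSet] = None,
    group_size: int = 4,
    relatedness: float = 0.25,
    selected_fraction: float = 0.2,
    n_groups: int = 400,
    multilevel_weight: float = 0.5,
    sr_m: int = 1,
    se_multiple: float = 3.0,
) -> ExperimentReport:
    """Realized selection differential on TBV versus iota * rho * sd(TBV).

    For each scheme and replicate, a cohort is simulated, the top
    fraction is truncation-selected on the scheme's criterion, and the
    mean TBV advantage of the selected parents is compared with the
    breeder's-equation prediction using the realized intensity and the
    closed-form accuracy.  Pass: the mean deviation over replicates is
    within ``se_multiple`` empirical standard errors of zero, per scheme.
    """
    t0 = time.time()
    if params is None:
        params = FIXTURE_REGIMES["positive-rA"].params
    n = group_size
    r = relatedness
    mode = {0.0: "unrelated", 0.25: "half-sib", 0.5: "full-sib"}[r]
    rng = np.random.default_rng(seed)
    rows = []
    for scheme in schemes:
        if scheme == "MS":
            design = GroupDesign(n, r, multilevel_weight=multilevel_weight)
            rho = accuracy_multilevel(params, design)
        elif scheme == "IS":
            rho = accuracy_individual(params, GroupDesign(n, r))
        elif scheme == "GS":
            rho = accuracy_group(params, GroupDesign(n, r))
        elif scheme == "SR":
            design = GroupDesign(
                n, r, relatedness_candidate_to_relatives=r,
                groups_per_candidate=sr_m,
            )
            rho = accuracy_relatives(params, design)
        else:
            raise ValueError(scheme)
        sd_tbv = math.sqrt(total_breeding_variance(params, n))
        for rep in range(replicates):
            if scheme == "SR":
                n_cand = max(n_groups * n // (sr_m * n + 1), 50)
                cands, _ = sim.relatives_design(
                    params, n, sr_m, mode, n_cand, rng
                )
                scores = cands["criterion"].to_numpy()
                tbv = cands["tbv"].to_numpy()
            else:
                pop, _ = sim.structured_population(params, n, mode, n_groups, rng)
                scores = sim.compute_criterion(pop, scheme, multilevel_weight)
                tbv = sim.total_breeding_values(pop, n)
            k = max(int(round(len(scores) * selected_fraction)), 1)
            sel = np.argpartition(scores, -k)[-k:]
            iota = (scores[sel].mean() - scores.mean()) / scores.std()
            realized = tbv[sel].mean() - tbv.mean()
            predicted = iota * rho * sd_tbv
            rows.append(
                dict(scheme=scheme, replicate=rep, realized=realized,
                     predicted=predicted, iota=iota)
            )
    df = pd.DataFrame(rows)
    checks = []
    for scheme, sub in df.groupby("scheme"):
        dev = sub["realized"] - sub["predicted"]
        se = dev.std(ddof=1) / math.sqrt(len(dev))
        checks.append(
            dict(scheme=scheme, mean_realized=sub["realized"].mean(),
                 mean_predicted=sub["predicted"].mean(),
                 mean_deviation=dev.mean(), se=se,
                 ok=abs(dev.mean()) <= se_multiple * se)
        )
    summary = pd.DataFrame(checks)
    return ExperimentReport(
        name="one-generation-response",
        table=summary,
        passed=bool(summary["ok"].all()),
        seed=seed,
        runtime_s=time.time() - t0,
    )


# ---------------------------------------------------------------------------
# REML recovery / identifiability
# ---------------------------------------------------------------------------

def recovery_experiment(
    design: str = "two-family",
    n_groups: int = 400,
    replicates: int = 50,
    seed: int = 1,
    params: Optional[GeneticParameterSet] = None,
    group_size: int = 4,
    n_starts: int = 2,
) -> ExperimentReport:
    """Simulate-and-re-estimate: does REML recover the generating values?

    two-family designs should give unbiased recovery (mean estimate
    within 2 empirical standard errors of truth); single-family
    (all full-sib groups) designs are structurally non-identifiable and
    must be flagged as such.
    """
    t0 = time.time()
    if params is None:
        params = GeneticParameterSet(
            1.0, 0.5, -0.4, 3.0, 0.4, 0.0, 0.3, "recovery-truth"
        )
    mode = "two-family" if design == "two-family" else "full-sib"
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        pop, pedf = sim.structured_population(
            params, group_size, mode, n_groups, rng
        )
        rec = pop.rename(columns={"phenotype": "value"})[["id", "group", "value"]]
        ped = blup.Pedigree.from_frame(pedf)
        ident = blup.identifiability_check(rec, ped)
        row = dict(
            replicate=rep,
            identifiable=ident.identifiable,
            single_family=ident.all_single_family,
            n_groups=ident.n_groups,
        )
        if ident.identifiable:
            est = blup.reml_estimate(
                rec, ped, "direct-social", n_starts=n_starts, seed=seed + rep,
                check_identifiability=False,
            )
            row.update(
                var_direct=est.params.var_direct_genetic,
                cov_ds=est.params.cov_direct_social_genetic,
                var_social=est.params.var_social_genetic,
                loglik=est.loglik,
                converged=est.converged,
            )
        rows.append(row)
    df = pd.DataFrame(rows)

    if design == "two-family":
        truth = {
            "var_direct": params.var_direct_genetic,
            "cov_ds": params.cov_direct_social_genetic,
            "var_social": params.var_social_genetic,
        }
        checks = {}
        for k, v in truth.items():
            est_mean = df[k].mean()
            se = df[k].std(ddof=1) / math.sqrt(len(df))
            checks[k] = abs(est_mean - v) <= 2 * max(se, 1e-12)
        passed = all(checks.values()) and bool(df["identifiable"].all())
        notes = "; ".join(
            f"{k}: mean {df[k].mean():.3f} vs truth {truth[k]:.3f} "
            f"(SE {df[k].std(ddof=1)/math.sqrt(len(df)):.3f})"
            for k in truth
        )
    else:
        flagged = (~df["identifiable"]).mean()
        passed = flagged >= 0.95
        notes = f"non-identifiability flagged in {flagged:.0%} of replicates"
    return ExperimentReport(
        name=f"reml-recovery-{design}",
        table=df,
        passed=passed,
        seed=seed,
        runtime_s=time.time() - t0,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# selection on total vs direct EBVs
# ---------------------------------------------------------------------------

def _one_generation_response(
    params: GeneticParameterSet,
    scheme: str,
    composition: str,
    seed: int,
    n_sires: int = 10,
    dams_per_sire: int = 4,
    offspring_per_dam: int = 6,
    group_size: int = 4,
    selected_fraction: float = 0.25,
) -> float:
    """Mean TBV of selected parents minus cohort mean (one cycle)."""
    rng = np.random.default_rng(seed)
    founders = sim.sample_founders(2 * n_sires * dams_per_sire, params, rng)
    parents = sim.truncation_select(
        founders, rng.random(len(founders)), n_sires, n_sires * dams_per_sire
    )
    pop = sim.breed_offspring(
        parents, params, rng, offspring_per_dam,
        start_id=int(founders["id"].max()) + 1, generation=1,
    )
    pop = sim.make_groups(pop, composition, group_size, rng)
    pop = sim.realize_phenotypes(pop, params, rng)
    if scheme in ("EBV-D", "EBV-TBV", "EBV-C"):
        pedf = pd.concat(
            [founders[["id", "sire", "dam"]], pop[["id", "sire", "dam"]]],
            ignore_index=True,
        )
        ebv = _ebv_solver(pop, pedf, params, scheme)
        scores = ebv.loc[pop["id"]].to_numpy()
    else:
        scores = sim.compute_criterion(pop, scheme)
    tbv = sim.total_breeding_values(pop, group_size)
    n_m = max(int(round((pop["sex"] == 1).sum() * selected_fraction)), 1)
    n_f = max(int(round((pop["sex"] == 0).sum() * selected_fraction)), 1)
    sel = sim.truncation_select(pop, scores, n_m, n_f)
    return float(sim.total_breeding_values(sel, group_size).mean() - tbv.mean())


def _ebv_solver(records, ped_frame, params, scheme) -> pd.Series:
    """EBVs for the simulator's EBV schemes (classical or direct-social)."""
    ped = blup.Pedigree.from_frame(ped_frame)
    rec = records.rename(columns={"phenotype": "value"})[["id", "group", "value"]]
    if scheme == "EBV-C":
        n = int(rec.groupby("group").size().iloc[0])
        sol = blup.solve_classical(
            rec, ped,
            params.var_direct_genetic,
            params.var_direct_residual
            + (n - 1) * params.var_social_residual
            + params.var_group_env,
            compute_reliability=False,
        )
        values = sol.ebv_total
    else:
        sol = blup.solve_direct_social(rec, ped, params, compute_reliability=False)
        values = sol.ebv_direct if scheme == "EBV-D" else sol.ebv_total
    return pd.Series(values, index=sol.ids)


def classical_blup_grouping_experiment(
    params: Optional[GeneticParameterSet] = None,
    replicates: int = 30,
    seed: int = 1,
) -> ExperimentReport:
    """Classical (direct-only) BLUP selection: full-sib vs unrelated groups.

    With family groups the classical EBV absorbs the social contribution
    of the family and becomes an estimate of the total breeding value, so
    the realized TBV response is larger than with unrelated groups.
    """
    t0 = time.time()
    if params is None:
        params = FIXTURE_REGIMES["negative-rA-crossbred-like"].params
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        fam = _one_generation_response(
            params, "EBV-C", "full-sib", rep_seed, offspring_per_dam=8
        )
        unrel = _one_generation_response(
            params, "EBV-C", "unrelated", rep_seed, offspring_per_dam=8
        )
        rows.append(dict(replicate=rep, family_groups=fam, unrelated_groups=unrel))
    df = pd.DataFrame(rows)
    diff = df["family_groups"] - df["unrelated_groups"]
    t_stat = diff.mean() / (diff.std(ddof=1) / math.sqrt(len(df)))
    passed = bool(diff.mean() > 0 and t_stat > 1.645)
    notes = (
        f"family groups {df['family_groups'].mean():.2f} vs unrelated "
        f"{df['unrelated_groups'].mean():.2f}, one-sided t={t_stat:.2f}"
    )
    return ExperimentReport(
        name="classical-blup-grouping",
        table=df,
        passed=passed,
        seed=seed,
        runtime_s=time.time() - t0,
        notes=notes,
    )


def dblup_vs_cblup_experiment(
    params: Optional[GeneticParameterSet] = None,
    replicates: int = 30,
    seed: int = 1,
    composition: str = "unrelated",
) -> ExperimentReport:
    """Response to selection on total EBVs (C-BLUP) vs direct EBVs (D-BLUP).

    Under a strongly negative direct-social covariance with unrelated
    groups, selection on direct EBVs moves the trait the wrong way while
    selection on total EBVs achieves positive gain -- the sign pattern
    observed in selection experiments with group-housed quail.
    """
    t0 = time.time()
    if params is None:
        params = FIXTURE_REGIMES["negative-rA-crossbred-like"].params
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        # paired: both schemes see the same simulated population
        rep_seed = int(rng.integers(0, 2**31 - 1))
        d = _one_generation_response(params, "EBV-D", composition, rep_seed)
        c = _one_generation_response(params, "EBV-TBV", composition, rep_seed)
        rows.append(dict(replicate=rep, dblup=d, cblup=c))
    df = pd.DataFrame(rows)
    mean_d, mean_c = df["dblup"].mean(), df["cblup"].mean()
    se_d = df["dblup"].std(ddof=1) / math.sqrt(len(df))
    se_c = df["cblup"].std(ddof=1) / math.sqrt(len(df))
    diff = df["cblup"] - df["dblup"]
    sd_diff = diff.std(ddof=1)
    # identical schemes (e.g. null social variance) give zero paired sd
    t_stat = (
        diff.mean() / (sd_diff / math.sqrt(len(df))) if sd_diff > 0 else 0.0
    )
    passed = bool(mean_c > mean_d and t_stat > 1.645)
    notes = (
        f"D-BLUP {mean_d:.2f} (SE {se_d:.2f}), C-BLUP {mean_c:.2f} "
        f"(SE {se_c:.2f}), one-sided t={t_stat:.2f}"
    )
    return ExperimentReport(
        name="dblup-vs-cblup",
        table=df,
        passed=passed,
        seed=seed,
        runtime_s=time.time() - t0,
        notes=notes,
    )
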