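"""Relationship matrices, Henderson MME vs dense GLS, REML, identifiability."""

import numpy as np
import pandas as pd
import pytest

from ige.variance_theory import GeneticParameterSet
from ige.pedigree_blup import (
    Pedigree,
    additive_relationship_matrix,
    identifiability_check,
    reml_estimate,
    solve_classical,
    solve_direct_social,
    _incidence,
    _residual_block,
)
from ige.breeding_sim import structured_population

from conftest import kinship_oracle


class TestPedigree:
    def test_founders_give_identity(self):
        ped = Pedigree([1, 2], [0, 0], [0, 0])
        assert np.allclose(ped.amatrix(), np.eye(2))

    def test_full_sibs_half_related(self):
        ped = Pedigree([1, 2, 3, 4], [0, 0, 1, 1], [0, 0, 2, 2])
        A = ped.amatrix()
        assert A[2, 3] == pytest.approx(0.5)
        assert A[2, 2] == pytest.approx(1.0)

    def test_three_generations_match_path_counting(self, toy_pedigree_frame):
        ped = Pedigree.from_frame(toy_pedigree_frame)
        A = additive_relationship_matrix(ped)
        oracle = kinship_oracle(
            toy_pedigree_frame["id"], toy_pedigree_frame["sire"],
            toy_pedigree_frame["dam"],
        )
        assert np.allclose(A, oracle, atol=1e-12)

    def test_inbred_animal_diagonal(self, toy_pedigree_frame):
        # animal 9: parents 5 and 6 are full sibs -> F = 0.25
        ped = Pedigree.from_frame(toy_pedigree_frame)
        f = dict(zip(ped.ids, ped.inbreeding()))
        assert f[9] == pytest.approx(0.25)

    def test_cycle_rejected_with_id(self):
        with pytest.raises(ValueError, match="ancestor"):
            Pedigree([1, 2, 3], [2, 3, 1], [0, 0, 0])

    def test_out_of_order_pedigree_reordered_with_warning(self):
        with pytest.warns(UserWarning, match="reordered"):
            ped = Pedigree([3, 1, 2], [1, 0, 0], [2, 0, 0])
        assert list(ped.ids)[-1] == 3

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Pedigree([1, 1], [0, 0], [0, 0])


def _toy_records(rng, ped, n_groups=2, n=3, mu=10.0, sd=2.0):
    phenotyped = ped.ids[-n_groups * n :]
    return pd.DataFrame(
        {
            "id": phenotyped,
            "group": np.repeat(np.arange(1, n_groups + 1), n),
            "value": rng.normal(mu, sd, n_groups * n),
        }
    )


def _gls_direct_social(records, ped, params, X):
    """Joint-covariance GLS/BLUP oracle, brute force."""
    A = ped.amatrix()
    ZD, ZS = _incidence(records, ped)
    n = int(records.groupby("group").size().iloc[0])
    G = np.kron(params.genetic_matrix(), A)
    W = np.hstack([ZD, ZS])
    blocks = []
    R = np.zeros((len(records), len(records)))
    blk = _residual_block(params, n)
    for _, idx in records.groupby("group").indices.items():
        R[np.ix_(idx, idx)] = blk
    groups = pd.unique(records["group"])
    V_inc = (records["group"].to_numpy()[:, None] == groups[None, :]).astype(float)
    V = W @ G @ W.T + R + params.var_group_env * V_inc @ V_inc.T
    Vi = np.linalg.inv(V)
    y = records["value"].to_numpy()
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    a = G @ W.T @ Vi @ (y - X @ b)
    return b, a[: len(ped)], a[len(ped) :]


class TestMMEvsGLS:
    def test_zero_genetic_variance_gives_ols_and_null_ebvs(self, rng,
                                                           toy_pedigree_frame):
        ped = Pedigree.from_frame(toy_pedigree_frame)
        rec = _toy_records(rng, ped)
        sol = solve_classical(rec, ped, 0.0, 2.5)
        assert np.allclose(sol.ebv_direct, 0.0)
        assert sol.fixed_effects[0] == pytest.approx(rec["value"].mean())

    def test_classical_matches_dense_gls(self, rng, toy_pedigree_frame):
        ped = Pedigree.from_frame(toy_pedigree_frame)
        rec = _toy_records(rng, ped)
        sol = solve_classical(rec, ped, 1.7, 3.1)
        A = ped.amatrix()
        rows = ped.index_of(rec["id"])
        Z = np.zeros((len(rec), len(ped)))
        Z[np.arange(len(rec)), rows] = 1.0
        V = Z @ (1.7 * A) @ Z.T + 3.1 * np.eye(len(rec))
        Vi = np.linalg.inv(V)
        X = np.ones((len(rec), 1))
        y = rec["value"].to_numpy()
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        a = 1.7 * A @ Z.T @ Vi @ (y - X @ b)
        assert np.allclose(sol.ebv_direct, a, atol=1e-8)
        assert np.allclose(sol.fixed_effects, b, atol=1e-8)

    def test_direct_social_matches_dense_gls(self, rng, toy_pedigree_frame):
        ped = Pedigree.from_frame(toy_pedigree_frame)
        rec = _toy_records(rng, ped)
        params = GeneticParameterSet(2.0, 0.8, -0.5, 3.0, 0.6, 0.1, 0.7, "toy")
        sol = solve_direct_social(rec, ped, params)
        X = np.ones((len(rec), 1))
        b, a_d, a_s = _gls_direct_social(rec, ped, params, X)
        assert np.allclose(sol.fixed_effects, b, atol=1e-8)
        assert np.allclose(sol.ebv_direct, a_d, atol=1e-8)
        assert np.allclose(sol.ebv_social, a_s, atol=1e-8)

    def test_null_social_nests_classical(self, rng, toy_pedigree_frame):
        ped = Pedigree.from_frame(toy_pedigree_frame)
        rec = _toy_records(rng, ped)
        p0 = GeneticParameterSet(2.0, 0.0, 0.0, 3.0, 0.0, 0.0, 0.0, "null")
        s_ds = solve_direct_social(rec, ped, p0)
        s_cl = solve_classical(rec, ped, 2.0, 3.0)
        assert np.allclose(s_ds.ebv_direct, s_cl.ebv_direct, atol=1e-8)

    def test_singular_fixed_design_rejected(self, rng, toy_pedigree_frame):
        ped = Pedigree.from_frame(toy_pedigree_frame)
        rec = _toy_records(rng, ped)
        rec["dup1"] = ["a", "a", "b", "b", "c", "c"]
        rec["dup2"] = rec["dup1"]
        with pytest.raises(ValueError, match="confounded|singular"):
            solve_classical(rec, ped, 1.0, 1.0, ["dup1", "dup2"])

    def test_group_of_one_rejected(self, rng, toy_pedigree_frame):
        ped = Pedigree.from_frame(toy_pedigree_frame)
        rec = _toy_records(rng, ped)
        rec.loc[rec.index[-1], "group"] = 99
        params = GeneticParameterSet(2.0, 0.8, -0.5, 3.0, 0.6)
        with pytest.raises(ValueError, match="size 1"):
            solve_direct_social(rec, ped, params)

    def test_classical_ebv_estimates_tbv_in_family_groups(self, rng):
        # with full-sib groups the classical EBV tracks the total, not the
        # direct, breeding value
        params = GeneticParameterSet(1.0, 0.6, -0.2, 2.0, 0.5, 0.0, 0.2, "fam")
        pop, pedf = structured_population(params, 4, "full-sib", 120, rng)
        ped = Pedigree.from_frame(pedf)
        rec = pop.rename(columns={"phenotype": "value"})[["id", "group", "value"]]
        sol = solve_classical(rec, ped, 1.0, 2.0, compute_reliability=False)
        ebv = pd.Series(sol.ebv_direct, index=sol.ids).loc[pop["id"]].to_numpy()
        tbv = (pop["a_d"] + 3 * pop["a_s"]).to_numpy()
        dbv = pop["a_d"].to_numpy()
        assert np.corrcoef(ebv, tbv)[0, 1] > np.corrcoef(ebv, dbv)[0, 1]


class TestREML:
    def test_optimum_at_least_as_good_as_truth(self, rng):
        params = GeneticParameterSet(1.0, 0.5, -0.4, 3.0, 0.4, 0.0, 0.3, "t")
        pop, pedf = structured_population(params, 4, "two-family", 60, rng)
        rec = pop.rename(columns={"phenotype": "value"})[["id", "group", "value"]]
        ped = Pedigree.from_frame(pedf)
        est = reml_estimate(rec, ped, "direct-social", n_starts=2, seed=3,
                            check_identifiability=False)
        # evaluate the restricted likelihood at the generating values
        from ige.pedigree_blup import (_genetic_kernels, _restricted_loglik)
        K_dd, K_ds, K_ss = _genetic_kernels(rec, ped)
        g = rec["group"].to_numpy()
        same = (g[:, None] == g[None, :]).astype(float)
        np.fill_diagonal(same, 0.0)
        v_e = 3.0 + 3 * 0.4 + 0.3
        c_e = 2 * 0.4 + 0.3
        V = (1.0 * K_dd - 0.4 * K_ds + 0.5 * K_ss
             + v_e * np.eye(len(rec)) + c_e * same)
        ll_truth = _restricted_loglik(V, np.ones((len(rec), 1)),
                                      rec["value"].to_numpy())
        assert est.loglik >= ll_truth - 1e-6

    def test_classical_reml_recovers_heritability_scale(self, rng):
        params = GeneticParameterSet(1.0, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0, "h2")
        pop, pedf = structured_population(params, 4, "full-sib", 150, rng)
        rec = pop.rename(columns={"phenotype": "value"})[["id", "group", "value"]]
        est = reml_estimate(rec, Pedigree.from_frame(pedf), "classical")
        assert est.params.var_direct_genetic == pytest.approx(1.0, abs=0.6)
        assert est.var_residual_within == pytest.approx(2.0, abs=0.8)

    def test_record_guard(self, rng, toy_pedigree_frame):
        ped = Pedigree.from_frame(toy_pedigree_frame)
        rec = _toy_records(rng, ped)
        with pytest.raises(ValueError, match="guard"):
            reml_estimate(rec, ped, max_records=3)


class TestIdentifiability:
    def test_single_family_groups_flagged(self, rng):
        params = GeneticParameterSet(1.0, 0.5, -0.4, 3.0, 0.4, 0.0, 0.3, "t")
        pop, pedf = structured_population(params, 4, "full-sib", 40, rng)
        rec = pop.rename(columns={"phenotype": "value"})[["id", "group", "value"]]
        rep = identifiability_check(rec, Pedigree.from_frame(pedf))
        assert rep.all_single_family and not rep.identifiable

    def test_single_family_fisher_information_singular(self, rng):
        params = GeneticParameterSet(1.0, 0.5, -0.4, 3.0, 0.4, 0.0, 0.3, "t")
        pop, pedf = structured_population(params, 4, "full-sib", 40, rng)
        rec = pop.rename(columns={"phenotype": "value"})[["id", "group", "value"]]
        rep = identifiability_check(
            rec, Pedigree.from_frame(pedf), params, compute_fisher=True
        )
        assert rep.fisher_condition > 1e10

    def test_two_family_groups_identifiable_with_sane_information(self, rng):
        params = GeneticParameterSet(1.0, 0.5, -0.4, 3.0, 0.4, 0.0, 0.3, "t")
        pop, pedf = structured_population(params, 4, "two-family", 40, rng)
        rec = pop.rename(columns={"phenotype": "value"})[["id", "group", "value"]]
        rep = identifiability_check(
            rec, Pedigree.from_frame(pedf), params, compute_fisher=True
        )
        assert rep.identifiable
        assert rep.fisher_condition < 1e6

    def test_too_few_groups_reported(self, rng):
        params = GeneticParameterSet(1.0, 0.5, -0.4, 3.0, 0.4, 0.0, 0.3, "t")
        pop, pedf = structured_population(params, 4, "two-family", 3, rng)
        rec = pop.rename(columns={"phenotype": "value"})[["id", "group", "value"]]
        rep = identifiability_check(rec, Pedigree.from_frame(pedf))
        assert not rep.adequate_groups
        assert "groups" in rep.reason
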