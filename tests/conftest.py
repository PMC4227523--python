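import numpy as np
import pandas as pd
import pytest

from ige.variance_theory import GeneticParameterSet, GroupDesign


@pytest.fixture
def hen_like_params():
    """Survival-time-like magnitudes with moderate negative rA."""
    return GeneticParameterSet(
        var_direct_genetic=1200.0,
        var_social_genetic=300.0,
        cov_direct_social_genetic=-250.0,
        var_direct_residual=8000.0,
        var_social_residual=900.0,
        cov_direct_social_residual=0.0,
        var_group_env=400.0,
        label="hen-like",
    )


@pytest.fixture
def null_social_params():
    return GeneticParameterSet(0.4, 0.0, 0.0, 0.6, 0.0, 0.0, 0.0, "null-social")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_psd_params(rng, scale=1.0):
    """A random admissible parameter set (PSD genetic and residual blocks)."""
    a_d = rng.uniform(0.05, 2.0) * scale
    a_s = rng.uniform(0.01, 1.0) * scale
    r_a = rng.uniform(-0.99, 0.99)
    e_d = rng.uniform(0.1, 4.0) * scale
    e_s = rng.uniform(0.01, 1.5) * scale
    r_e = rng.uniform(-0.9, 0.9)
    return GeneticParameterSet(
        a_d, a_s, r_a * np.sqrt(a_d * a_s),
        e_d, e_s, r_e * np.sqrt(e_d * e_s),
        rng.uniform(0.0, 0.5) * scale, "random",
    )


def exact_accuracy_oracle(params, n, r, scheme, g=0.5, m=1, r_rel=None):
    """Accuracy corr(criterion, TBV) by explicit joint-covariance algebra.

    Builds the covariance matrix of all 4n effect components in a group
    (or of m groups of relatives plus a candidate) from the relatedness
    matrix and the parameter blocks, maps to phenotypes linearly, and
    returns the exact correlation.  Shares no code with the closed-form
    layer.
    """
    C = params.genetic_matrix()
    E = params.residual_matrix()
    g2 = params.var_group_env

    if scheme in ("IS", "GS", "MS"):
        R = np.full((n, n), r)
        np.fill_diagonal(R, 1.0)
        cov_gen = np.kron(C, R)           # (A_D block, A_S block)
        cov_res = np.kron(E, np.eye(n))
        # effect vector x = (A_D 1..n, A_S 1..n, E_D 1..n, E_S 1..n)
        cov_x = np.zeros((4 * n, 4 * n))
        cov_x[: 2 * n, : 2 * n] = cov_gen
        cov_x[2 * n :, 2 * n :] = cov_res
        # P_i = A_D,i + E_D,i + sum_{j != i}(A_S,j + E_S,j) (+ shared env)
        M = np.zeros((n, 4 * n))
        for i in range(n):
            M[i, i] = 1.0
            M[i, 2 * n + i] = 1.0
            for j in range(n):
                if j != i:
                    M[i, n + j] = 1.0
                    M[i, 3 * n + j] = 1.0
        cov_p = M @ cov_x @ M.T + g2  # shared group effect adds g2 everywhere
        if scheme == "IS":
            w = np.zeros(n); w[0] = 1.0
        elif scheme == "GS":
            w = np.full(n, 1.0 / n)
        else:
            w = np.full(n, g); w[0] = 1.0
        # TBV_1 = A_D,1 + (n-1) A_S,1
        k = np.zeros(4 * n)
        k[0] = 1.0
        k[n] = n - 1.0
        var_crit = w @ cov_p @ w
        var_tbv = k @ cov_x @ k
        cov_ct = w @ (M @ cov_x @ k)
        return cov_ct / np.sqrt(var_crit * var_tbv)

    assert scheme == "SR"
    r_rel = r if r_rel is None else r_rel
    total = m * n + 1  # candidate is index 0, relatives 1..mn
    R = np.full((total, total), r)
    R[0, 1:] = R[1:, 0] = r_rel
    np.fill_diagonal(R, 1.0)
    cov_gen = np.kron(C, R)
    cov_res = np.kron(E, np.eye(total))
    cov_x = np.zeros((4 * total, 4 * total))
    cov_x[: 2 * total, : 2 * total] = cov_gen
    cov_x[2 * total :, 2 * total :] = cov_res
    groups = [list(range(1 + q * n, 1 + (q + 1) * n)) for q in range(m)]
    M = np.zeros((m * n, 4 * total))
    for row, i in enumerate(i for grp in groups for i in grp):
        M[row, i] = 1.0
        M[row, 2 * total + i] = 1.0
        grp = next(gg for gg in groups if i in gg)
        for j in grp:
            if j != i:
                M[row, total + j] = 1.0
                M[row, 3 * total + j] = 1.0
    cov_p = M @ cov_x @ M.T
    # shared cage effect within each group of relatives
    for q in range(m):
        cov_p[q * n : (q + 1) * n, q * n : (q + 1) * n] += g2
    w = np.full(m * n, 1.0 / (m * n))
    k = np.zeros(4 * total)
    k[0] = 1.0
    k[total] = n - 1.0
    var_crit = w @ cov_p @ w
    var_tbv = k @ cov_x @ k
    cov_ct = w @ (M @ cov_x @ k)
    return cov_ct / np.sqrt(var_crit * var_tbv)


def kinship_oracle(ids, sires, dams):
    """Brute-force recursive kinship -> additive relationship matrix."""
    idx = {i: (s, d) for i, s, d in zip(ids, sires, dams)}
    order = {i: k for k, i in enumerate(ids)}
    cache = {}

    def phi(a, b):
        if a == 0 or b == 0:
            return 0.0
        if order[a] < order[b]:
            a, b = b, a
        if (a, b) in cache:
            return cache[(a, b)]
        s, d = idx[a]
        if a == b:
            val = 0.5 * (1.0 + phi(s, d))
        else:
            val = 0.5 * (phi(s, b) + phi(d, b))
        cache[(a, b)] = val
        return val

    n = len(ids)
    A = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            A[i, j] = 2.0 * phi(a, b)
    return A


@pytest.fixture
def toy_pedigree_frame():
    """Three generations, 10 animals, includes inbreeding."""
    return pd.DataFrame(
        {
            "id": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
            "sire": [0, 0, 0, 0, 1, 1, 3, 3, 5, 5],
            "dam": [0, 0, 0, 0, 2, 2, 4, 4, 6, 7],
        }
    )
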