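"""Pedigree relationship matrices, mixed-model equations, and REML for the
direct-social animal model.

Two models are supported.  The classical animal model

    y = X b + Z a + e,        var(a) = A * sigma2_A,  var(e) = I * sigma2_E

predicts one breeding value per animal.  The direct-social model adds a
second genetic effect per animal (the social effect expressed in group
mates' phenotypes), a non-genetic random group effect, and a residual
that is correlated within a group::

    y = X b + Z_D a_D + Z_S a_S + V g + e,
    var([a_D; a_S]) = C (x) A     (Kronecker product)

where row i of Z_S carries ones in the columns of i's n-1 group mates.
The within-group residual correlation arises because each phenotype
contains the non-heritable social effects of the same group mates; it is
parameterised here directly by the variance of, and covariance between,
group mates' residuals.

Solutions are obtained from Henderson's mixed-model equations; for data
sets small enough to invert the coefficient matrix, prediction error
variances (and hence reliabilities) are returned as well.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .variance_theory import GeneticParameterSet

__all__ = [
    "Pedigree",
    "MMESolution",
    "VarianceEstimate",
    "additive_relationship_matrix",
    "solve_classical",
    "solve_direct_social",
    "reml_estimate",
    "identifiability_check",
    "IdentifiabilityReport",
]

UNKNOWN = 0  # parent code for "unknown", treated as an unrelated founder

# guideline from design studies of the direct-social model: the number of
# groups, not the number of records, drives the precision of the social
# variance components, and a few hundred groups are needed in practice.
RECOMMENDED_GROUPS = (250, 500)


class Pedigree:
    """An ordered pedigree: (individual, sire, dam) with 0 = unknown parent.

    Records are topologically sorted on construction so that parents
    always precede offspring; a cycle (an individual that is its own
    ancestor) is rejected.
    """

    def __init__(self, ids: Sequence[int], sires: Sequence[int], dams: Sequence[int]):
        ids = np.asarray(ids, dtype=np.int64)
        sires = np.asarray(sires, dtype=np.int64)
        dams = np.asarray(dams, dtype=np.int64)
        if len(set(ids.tolist())) != len(ids):
            dup = pd.Series(ids).loc[pd.Series(ids).duplicated()].iloc[0]
            raise ValueError(f"duplicate individual id in pedigree: {dup}")
        known = set(ids.tolist())
        for arr, what in ((sires, "sire"), (dams, "dam")):
            missing = set(arr.tolist()) - known - {UNKNOWN}
            if missing:
                raise ValueError(f"{what} ids not in pedigree: {sorted(missing)[:5]}")
        order = self._toposort(ids, sires, dams)
        if not np.array_equal(order, np.arange(len(ids))):
            warnings.warn("pedigree reordered so parents precede offspring")
        self.ids = ids[order]
        self.sires = sires[order]
        self.dams = dams[order]
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        self._amatrix: Optional[np.ndarray] = None

    @staticmethod
    def _toposort(ids, sires, dams) -> np.ndarray:
        index = {int(i): k for k, i in enumerate(ids)}
        state = np.zeros(len(ids), dtype=np.int8)  # 0 new, 1 visiting, 2 done
        order: list[int] = []

        for start in range(len(ids)):
            if state[start]:
                continue
            stack = [(start, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 2
                    order.append(node)
                    continue
                if state[node] == 2:
                    continue
                if state[node] == 1:
                    raise ValueError(
                        f"pedigree cycle: individual {int(ids[node])} is its own ancestor"
                    )
                state[node] = 1
                stack.append((node, True))
                for parent in (sires[node], dams[node]):
                    if parent != UNKNOWN:
                        p = index[int(parent)]
                        if state[p] == 1:
                            raise ValueError(
                                f"pedigree cycle: individual {int(ids[p])} is its own ancestor"
                            )
                        if state[p] == 0:
                            stack.append((p, False))
        return np.array(order)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Sequence[int]) -> np.ndarray:
        try:
            return np.array([self._index[int(i)] for i in ids])
        except KeyError as e:
            raise KeyError(f"id {e} not in pedigree") from None

    def amatrix(self) -> np.ndarray:
        """Numerator relationship matrix A by the tabular method.

        A_ii = 1 + F_i with F_i the inbreeding coefficient; symmetric PSD.
        """
        if self._amatrix is None:
            n = len(self)
            A = np.zeros((n, n))
            sidx = np.array([self._index[int(s)] if s != UNKNOWN else -1 for s in self.sires])
            didx = np.array([self._index[int(d)] if d != UNKNOWN else -1 for d in self.dams])
            for i in range(n):
                s, d = sidx[i], didx[i]
                if s >= 0 and d >= 0:
                    A[i, i] = 1.0 + 0.5 * A[s, d]
                else:
                    A[i, i] = 1.0
                row = np.zeros(i)
                if s >= 0:
                    row += 0.5 * A[s, :i]
                if d >= 0:
                    row += 0.5 * A[d, :i]
                A[i, :i] = row
                A[:i, i] = row
            self._amatrix = A
        return self._amatrix

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.amatrix()) - 1.0

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls(df["id"].to_numpy(), df["sire"].to_numpy(), df["dam"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "sire": self.sires, "dam": self.dams})


def additive_relationship_matrix(ped: Pedigree) -> np.ndarray:
    """A-matrix in the pedigree's (topological) id order."""
    return ped.amatrix()


@dataclass
class MMESolution:
    """Solutions of the mixed-model equations."""

    model: str  # 'classical' | 'direct-social'
    ids: np.ndarray
    fixed_effects: np.ndarray
    ebv_direct: np.ndarray
    ebv_social: Optional[np.ndarray]
    ebv_total: Optional[np.ndarray]
    group_effects: Optional[np.ndarray]
    reliability: Optional[np.ndarray]
    accuracy_mme: Optional[np.ndarray]

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.ids, "ebv_direct": self.ebv_direct})
        out["ebv_social"] = self.ebv_social if self.ebv_social is not None else np.nan
        out["ebv_total"] = (
            self.ebv_total if self.ebv_total is not None else out["ebv_direct"]
        )
        out["reliability"] = (
            self.reliability if self.reliability is not None else np.nan
        )
        return out


def _design_matrices(records: pd.DataFrame, fixed_effects: Sequence[str]):
    """Fixed-effect design matrix: intercept plus dummy-coded factors."""
    nrec = len(records)
    blocks = [np.ones((nrec, 1))]
    names = ["intercept"]
    for col in fixed_effects:
        levels = pd.unique(records[col])
        if len(levels) < 2:
            continue
        # drop first level: reference coding
        for lev in levels[1:]:
            blocks.append((records[col] == lev).to_numpy(float).reshape(-1, 1))
            names.append(f"{col}={lev}")
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"singular fixed-effect design; confounded levels among {names}"
        )
    return X, names


def _check_groups(records: pd.DataFrame) -> np.ndarray:
    if records["group"].isna().any():
        raise ValueError("records with missing group id")
    sizes = records.groupby("group").size()
    bad = sizes[sizes < 2]
    if len(bad):
        raise ValueError(
            f"groups of size 1 cannot carry social effects: {list(bad.index[:5])}"
        )
    return sizes.to_numpy()


def _incidence(records: pd.DataFrame, ped: Pedigree):
    """Z_D (own effect) and Z_S (group mates' effects) incidence matrices."""
    nrec = len(records)
    nanim = len(ped)
    rows = ped.index_of(records["id"].to_numpy())
    ZD = np.zeros((nrec, nanim))
    ZD[np.arange(nrec), rows] = 1.0
    ZS = np.zeros((nrec, nanim))
    for _, idx in records.groupby("group").indices.items():
        cols = rows[idx]
        for k in idx:
            ZS[k, cols] = 1.0
            ZS[k, rows[k]] = 0.0
    return ZD, ZS


def solve_classical(
    records: pd.DataFrame,
    ped: Pedigree,
    var_genetic: float,
    var_residual: float,
    fixed_effects: Sequence[str] = (),
    compute_reliability: bool = True,
) -> MMESolution:
    """BLUP under the classical animal model via Henderson's MME.

    ``records`` needs columns id and value (group is ignored here).
    With ``var_genetic = 0`` all EBVs are zero and the fixed effects are
    the GLS (here OLS) estimates.
    """
    X, _ = _design_matrices(records, fixed_effects)
    y = records["value"].to_numpy(float)
    nanim = len(ped)
    rows = ped.index_of(records["id"].to_numpy())
    Z = np.zeros((len(records), nanim))
    Z[np.arange(len(records)), rows] = 1.0

    if var_genetic <= 0:
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        zero = np.zeros(nanim)
        return MMESolution(
            "classical", ped.ids, b, zero, None, zero.copy(), None,
            np.zeros(nanim), np.zeros(nanim),
        )

    Ainv = np.linalg.inv(ped.amatrix())
    lam = var_residual / var_genetic
    top = np.hstack([X.T @ X, X.T @ Z])
    bottom = np.hstack([Z.T @ X, Z.T @ Z + lam * Ainv])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    nfix = X.shape[1]
    sol = _solve_mme(lhs, rhs)
    a_hat = sol[nfix:]

    reliability = accuracy = None
    if compute_reliability:
        Cinv = np.linalg.pinv(lhs)
        pev = np.diag(Cinv)[nfix:] * var_residual
        denom = np.diag(ped.amatrix()) * var_genetic
        rel = np.clip(1.0 - pev / denom, 0.0, 1.0)
        reliability = rel
        accuracy = np.sqrt(rel)
    return MMESolution(
        "classical", ped.ids, sol[:nfix], a_hat, None, a_hat.copy(), None,
        reliability, accuracy,
    )


def _solve_mme(lhs: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve possibly rank-deficient MME (pinv fallback)."""
    try:
        return linalg.solve(lhs, rhs, assume_a="sym")
    except linalg.LinAlgError:
        return np.linalg.pinv(lhs) @ rhs


def _residual_block(params: GeneticParameterSet, n: int) -> np.ndarray:
    """Within-group covariance of the aggregated residual
    e_i = E_D,i + sum_{j != i} E_S,j (group effect excluded)."""
    var = params.var_direct_residual + (n - 1) * params.var_social_residual
    cov = 2 * params.cov_direct_social_residual + (n - 2) * params.var_social_residual
    block = np.full((n, n), cov)
    np.fill_diagonal(block, var)
    return block


def solve_direct_social(
    records: pd.DataFrame,
    ped: Pedigree,
    params: GeneticParameterSet,
    fixed_effects: Sequence[str] = (),
    compute_reliability: bool = True,
) -> MMESolution:
    """BLUP under the direct-social model with genetic covariance C (x) A.

    Requires a constant group size (total EBVs need a single n).  The
    residual is correlated within groups as implied by the phenotype
    model; the non-genetic group effect is fitted when var_group_env > 0.
    When the social variance and covariance are both zero the social
    block is dropped and the solution reduces to the classical model.
    """
    sizes = _check_groups(records)
    if len(set(sizes.tolist())) != 1:
        raise ValueError("group size must be constant for total-EBV assembly")
    n = int(sizes[0])

    has_social = (
        params.var_social_genetic > 0 or params.cov_direct_social_genetic != 0
    )
    if not has_social:
        base = solve_classical(
            records, ped, params.var_direct_genetic,
            params.var_direct_residual, fixed_effects, compute_reliability,
        )
        return MMESolution(
            "direct-social", base.ids, base.fixed_effects, base.ebv_direct,
            np.zeros_like(base.ebv_direct), base.ebv_direct.copy(), None,
            base.reliability, base.accuracy_mme,
        )

    X, _ = _design_matrices(records, fixed_effects)
    y = records["value"].to_numpy(float)
    ZD, ZS = _incidence(records, ped)
    nanim = len(ped)
    nfix = X.shape[1]

    # R: block diagonal over groups
    Rinv = np.zeros((len(records), len(records)))
    block_inv = np.linalg.inv(_residual_block(params, n))
    for _, idx in records.groupby("group").indices.items():
        Rinv[np.ix_(idx, idx)] = block_inv

    C = params.genetic_matrix()
    eigval = np.linalg.eigvalsh(C)
    if eigval.min() <= 1e-12 * max(eigval.max(), 1.0):
        # near-singular C: ridge the correlation slightly to keep C invertible
        C = C + np.eye(2) * max(1e-8 * C.trace(), 1e-12)
    Ainv = np.linalg.inv(ped.amatrix())
    Ginv = np.kron(np.linalg.inv(C), Ainv)

    W = [X, ZD, ZS]
    use_group = params.var_group_env > 0
    if use_group:
        groups = pd.unique(records["group"])
        V = (records["group"].to_numpy()[:, None] == np.array(groups)[None, :]).astype(float)
        W.append(V)
    Wmat = np.hstack(W)
    lhs = Wmat.T @ Rinv @ Wmat
    lo = nfix
    lhs[lo : lo + 2 * nanim, lo : lo + 2 * nanim] += Ginv
    if use_group:
        gslice = slice(nfix + 2 * nanim, None)
        lhs[gslice, gslice] += np.eye(len(groups)) / params.var_group_env
    rhs = Wmat.T @ Rinv @ y
    sol = _solve_mme(lhs, rhs)

    a_d = sol[nfix : nfix + nanim]
    a_s = sol[nfix + nanim : nfix + 2 * nanim]
    tbv = a_d + (n - 1) * a_s
    g_hat = sol[nfix + 2 * nanim :] if use_group else None

    reliability = accuracy = None
    if compute_reliability:
        Cfull = np.linalg.pinv(lhs)
        k = np.array([1.0, n - 1.0])
        var_tbv_prior = float(k @ params.genetic_matrix() @ k) * np.diag(ped.amatrix())
        pev = np.empty(nanim)
        for i in range(nanim):
            idx = [nfix + i, nfix + nanim + i]
            pev[i] = float(k @ Cfull[np.ix_(idx, idx)] @ k)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(var_tbv_prior > 0, 1.0 - pev / var_tbv_prior, 0.0)
        reliability = np.clip(rel, 0.0, 1.0)
        accuracy = np.sqrt(reliability)

    return MMESolution(
        "direct-social", ped.ids, sol[:nfix], a_d, a_s, tbv, g_hat,
        reliability, accuracy,
    )


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

@dataclass
class VarianceEstimate:
    """REML point estimates with convergence and identifiability diagnostics.

    The residual side of the direct-social model is only identifiable as
    the within-group residual variance/covariance pair; the reported
    var_direct_residual / var_social_residual decomposition assumes no
    residual direct-social covariance and no separate group variance.
    """

    model: str
    params: GeneticParameterSet
    var_residual_within: float
    cov_residual_within: float
    loglik: float
    converged: bool
    n_records: int
    n_groups: int
    boundary: bool = False
    identifiable: Optional[bool] = None
    message: str = ""


def _restricted_loglik(Vy: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    try:
        cf = linalg.cho_factor(Vy, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv_X = linalg.cho_solve(cf, X, check_finite=False)
    Vinv_y = linalg.cho_solve(cf, y, check_finite=False)
    XtVX = X.T @ Vinv_X
    sign, logdetXVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
    resid_quad = float(y @ Vinv_y - (X.T @ Vinv_y) @ beta)
    return -0.5 * (logdetV + logdetXVX + resid_quad)


def _restricted_loglik_and_py(Vy, X, y):
    """(loglik, P y, V^-1, V^-1 X, (X'V^-1X)^-1) for gradient evaluations."""
    try:
        cf = linalg.cho_factor(Vy, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf, None, None, None, None
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv = linalg.cho_solve(cf, np.eye(len(y)), check_finite=False)
    Vinv_X = Vinv @ X
    XtVX = X.T @ Vinv_X
    sign, logdetXVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf, None, None, None, None
    XtVX_inv = np.linalg.inv(XtVX)
    Vinv_y = Vinv @ y
    beta = XtVX_inv @ (X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    ll = -0.5 * (logdetV + logdetXVX + float(y @ Py))
    return ll, Py, Vinv, Vinv_X, XtVX_inv


def _genetic_kernels(records: pd.DataFrame, ped: Pedigree):
    """Fixed N x N kernels so V(theta) is a linear combination per eval."""
    ZD, ZS = _incidence(records, ped)
    A = ped.amatrix()
    ZDA = ZD @ A
    K_dd = ZDA @ ZD.T
    K_ds = ZDA @ ZS.T
    K_ds = K_ds + K_ds.T
    K_ss = ZS @ A @ ZS.T
    return K_dd, K_ds, K_ss


def _theta_to_components(theta: np.ndarray, n: int):
    """Map unconstrained optimizer coordinates to admissible components.

    Genetic C via log-Cholesky (PSD by construction); residual within-
    group (variance, covariance) with the covariance bounded so the
    group block stays positive definite.
    """
    l11 = math.exp(theta[0])
    l21 = theta[1]
    l22 = math.exp(theta[2])
    c11 = l11 * l11
    c12 = l11 * l21
    c22 = l21 * l21 + l22 * l22
    v_e = math.exp(theta[3])
    s = 1.0 / (1.0 + math.exp(-theta[4]))
    c_e = v_e * (n * s - 1.0) / (n - 1.0)  # in (-v_e/(n-1), v_e)
    return c11, c12, c22, v_e, c_e


def _moment_start(records: pd.DataFrame, n: int) -> np.ndarray:
    """Crude ANOVA-flavoured starting values."""
    y = records["value"].to_numpy(float)
    var_tot = float(np.var(y))
    dev = records["value"] - records.groupby("group")["value"].transform("mean")
    var_within = float(np.var(dev.to_numpy())) * n / max(n - 1, 1)
    cov_within = max(var_tot - var_within, 0.0)
    gen0 = max(0.15 * var_tot, 1e-3 * var_tot + 1e-9)
    theta = np.zeros(5)
    theta[0] = 0.5 * math.log(gen0)
    theta[1] = 0.0
    theta[2] = 0.5 * math.log(max(0.05 * gen0, 1e-12))
    theta[3] = math.log(max(0.7 * var_tot, 1e-9))
    frac = (cov_within / max(var_tot, 1e-12) * (n - 1.0) + 1.0) / n
    theta[4] = math.log(max(frac, 1e-3) / max(1 - frac, 1e-3))
    return theta


def reml_estimate(
    records: pd.DataFrame,
    ped: Pedigree,
    model: str = "direct-social",
    fixed_effects: Sequence[str] = (),
    n_starts: int = 3,
    seed: int = 0,
    max_records: int = 3000,
    check_identifiability: bool = True,
) -> VarianceEstimate:
    """Restricted maximum likelihood for the classical or direct-social model.

    Dense implementation: the phenotypic covariance matrix is formed
    explicitly, so the number of records is capped (default 3000).  The
    genetic 2x2 matrix is optimised in a log-Cholesky parameterisation
    (PSD guaranteed); the within-group residual covariance is bounded so
    the residual stays positive definite.  Multiple starts reduce the
    local-optimum risk; non-convergence is flagged, not raised.
    """
    if len(records) > max_records:
        raise ValueError(
            f"{len(records)} records exceed the dense-REML guard ({max_records})"
        )
    sizes = _check_groups(records)
    if len(set(sizes.tolist())) != 1:
        raise ValueError("REML requires constant group size")
    n = int(sizes[0])
    n_groups = int(len(sizes))
    X, _ = _design_matrices(records, fixed_effects)
    y = records["value"].to_numpy(float)

    if model == "classical":
        return _reml_classical(records, ped, X, y, n, n_groups)
    if model != "direct-social":
        raise ValueError(f"unknown model: {model}")

    K_dd, K_ds, K_ss = _genetic_kernels(records, ped)
    groups = records["group"].to_numpy()
    same_group = (groups[:, None] == groups[None, :]).astype(float)
    np.fill_diagonal(same_group, 0.0)
    eye = np.eye(len(records))
    kernels = (K_dd, K_ds, K_ss, eye, same_group)

    def negll_grad(theta):
        c11, c12, c22, v_e, c_e = _theta_to_components(theta, n)
        comps = (c11, c12, c22, v_e, c_e)
        Vy = sum(c * K for c, K in zip(comps, kernels))
        ll, Py, Vinv, Vinv_X, XtVX_inv = _restricted_loglik_and_py(Vy, X, y)
        if not np.isfinite(ll):
            return 1e12, np.zeros(5)
        # d ll / d component = -0.5 [tr(P M) - (Py)' M (Py)]
        grad_c = np.empty(5)
        for j, M in enumerate(kernels):
            tr_PM = float(np.sum(Vinv * M)) - float(
                np.sum(XtVX_inv * (Vinv_X.T @ M @ Vinv_X))
            )
            grad_c[j] = -0.5 * (tr_PM - float(Py @ M @ Py))
        # chain rule through the PSD parameterisation
        l11 = math.exp(theta[0])
        s = 1.0 / (1.0 + math.exp(-theta[4]))
        J = np.zeros((5, 5))  # d components / d theta
        J[0, 0] = 2 * c11
        J[1, 0] = c12
        J[1, 1] = l11
        J[2, 1] = 2 * theta[1]
        J[2, 2] = 2 * math.exp(2 * theta[2])
        J[3, 3] = v_e
        J[4, 3] = c_e
        J[4, 4] = v_e * n / (n - 1.0) * s * (1 - s)
        return -ll, -(J.T @ grad_c)

    rng = np.random.default_rng(seed)
    theta0 = _moment_start(records, n)
    best = None
    converged = False
    for start in range(n_starts):
        t0 = theta0 if start == 0 else theta0 + rng.normal(0, 0.7, size=5)
        res = optimize.minimize(
            negll_grad, t0, method="L-BFGS-B", jac=True,
            # ftol is relative: matches the 1e-6 relative-likelihood rule
            options={"maxiter": 200, "ftol": 1e-9, "gtol": 1e-5},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        converged = converged or bool(res.success)

    c11, c12, c22, v_e, c_e = _theta_to_components(best.x, n)
    # decomposition convention: no residual D-S covariance, no group effect
    var_es = c_e / (n - 2) if n > 2 else max(c_e, 0.0)
    var_es = max(var_es, 0.0)
    var_ed = max(v_e - (n - 1) * var_es, 0.0)
    params = GeneticParameterSet(
        var_direct_genetic=c11,
        var_social_genetic=c22,
        cov_direct_social_genetic=c12,
        var_direct_residual=var_ed,
        var_social_residual=var_es,
        label="reml-estimate",
    )
    boundary = bool(
        c22 < 1e-6 * max(c11, 1.0)
        or (c11 * c22 > 0 and abs(c12) / math.sqrt(c11 * c22) > 0.999)
    )
    identifiable = None
    if check_identifiability:
        fams = _family_labels(records, ped)
        identifiable = not _all_single_family(records, fams)
    return VarianceEstimate(
        model="direct-social",
        params=params,
        var_residual_within=v_e,
        cov_residual_within=c_e,
        loglik=-best.fun,
        converged=converged,
        n_records=len(records),
        n_groups=n_groups,
        boundary=boundary,
        identifiable=identifiable,
        message=best.message if isinstance(best.message, str) else "",
    )


def _reml_classical(records, ped, X, y, n, n_groups) -> VarianceEstimate:
    rows = ped.index_of(records["id"].to_numpy())
    A = ped.amatrix()[np.ix_(rows, rows)]
    eye = np.eye(len(records))
    var_tot = float(np.var(y))

    def negll(theta):
        va, ve = np.exp(theta)
        return -_restricted_loglik(va * A + ve * eye, X, y)

    res = optimize.minimize(
        negll,
        np.log([0.3 * var_tot + 1e-9, 0.7 * var_tot + 1e-9]),
        method="Nelder-Mead",
        options={"maxiter": 1000, "fatol": 1e-6, "xatol": 1e-6},
    )
    va, ve = np.exp(res.x)
    params = GeneticParameterSet(
        var_direct_genetic=va, var_social_genetic=0.0,
        cov_direct_social_genetic=0.0, var_direct_residual=ve,
        var_social_residual=0.0, label="reml-classical",
    )
    return VarianceEstimate(
        model="classical", params=params, var_residual_within=ve,
        cov_residual_within=0.0, loglik=-res.fun, converged=bool(res.success),
        n_records=len(records), n_groups=n_groups,
        boundary=bool(va < 1e-8 * var_tot),
    )


# ---------------------------------------------------------------------------
# identifiability
# ---------------------------------------------------------------------------

@dataclass
class IdentifiabilityReport:
    identifiable: bool
    all_single_family: bool
    n_groups: int
    adequate_groups: bool
    fisher_condition: Optional[float] = None
    reason: str = ""


def _family_labels(records: pd.DataFrame, ped: Pedigree) -> pd.Series:
    idx = ped.index_of(records["id"].to_numpy())
    sires = ped.sires[idx]
    dams = ped.dams[idx]
    return pd.Series(
        [f"{s}x{d}" for s, d in zip(sires, dams)], index=records.index
    )


def _all_single_family(records: pd.DataFrame, fams: pd.Series) -> bool:
    return bool(
        records.assign(_fam=fams).groupby("group")["_fam"].nunique().eq(1).all()
    )


def identifiability_check(
    records: pd.DataFrame,
    ped: Pedigree,
    params: Optional[GeneticParameterSet] = None,
    compute_fisher: bool = False,
    seed: int = 0,
) -> IdentifiabilityReport:
    """Diagnose whether direct and social genetic (co)variances are
    separable given the group composition.

    When every group consists of a single family (all members equally
    related to each other), the direct and social components enter the
    likelihood only through confounded combinations and cannot be
    estimated separately; groups composed of two (or more) families make
    them identifiable.  Also reports whether the number of groups reaches
    the ~250-500 range recommended for usable precision.

    With ``compute_fisher=True`` a finite-difference Fisher information
    in (var_AD, cov_ADS, var_AS) is computed at ``params`` and its
    condition number reported (singular => non-identifiable).
    """
    fams = _family_labels(records, ped)
    single = _all_single_family(records, fams)
    n_groups = int(records["group"].nunique())
    adequate = n_groups >= RECOMMENDED_GROUPS[0]

    fisher_cond = None
    if compute_fisher and params is not None:
        fisher_cond = _fisher_condition(records, ped, params)
        identifiable = (not single) and (fisher_cond < 1e10)
    else:
        identifiable = not single
    reason = (
        "all groups are single-family: direct and social components are confounded"
        if single
        else "groups contain multiple families"
    )
    if not adequate:
        reason += (
            f"; only {n_groups} groups (roughly "
            f"{RECOMMENDED_GROUPS[0]}-{RECOMMENDED_GROUPS[1]} recommended)"
        )
    return IdentifiabilityReport(
        identifiable=identifiable,
        all_single_family=single,
        n_groups=n_groups,
        adequate_groups=adequate,
        fisher_condition=fisher_cond,
        reason=reason,
    )


def _fisher_condition(
    records: pd.DataFrame, ped: Pedigree, params: GeneticParameterSet
) -> float:
    """Condition number of the expected information in the genetic block.

    Uses I_jk = tr(V^-1 dV_j V^-1 dV_k) / 2 with the exact derivative
    kernels of (var_AD, cov_ADS, var_AS).
    """
    sizes = _check_groups(records)
    n = int(sizes[0])
    K_dd, K_ds, K_ss = _genetic_kernels(records, ped)
    groups = records["group"].to_numpy()
    same = (groups[:, None] == groups[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    block = _residual_block(params, n)
    Vy = (
        params.var_direct_genetic * K_dd
        + params.cov_direct_social_genetic * K_ds
        + params.var_social_genetic * K_ss
        + block[0, 0] * np.eye(len(records))
        + block[0, 1] * same
        + params.var_group_env * (same + np.eye(len(records)))
    )
    Vinv = np.linalg.inv(Vy)
    mats = [Vinv @ K_dd, Vinv @ K_ds, Vinv @ K_ss]
    info = np.empty((3, 3))
    for j in range(3):
        for k in range(j, 3):
            info[j, k] = info[k, j] = 0.5 * np.sum(mats[j] * mats[k].T)
    # normalise to a correlation-like matrix so the condition number
    # reflects confounding, not the different scales of the components
    d = np.sqrt(np.diag(info))
    info = info / np.outer(d, d)
    sv = np.linalg.svd(info, compute_uv=False)
    return float(sv[0] / max(sv[-1], 1e-300))
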