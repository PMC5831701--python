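"""Mixed-model solvers: SNP-BLUP, GBLUP and PC ridge regression.

All systems are ridge regressions differing in parameterization:

* SNP-BLUP: [X'X + lambda I] b = X'y, one effect per locus.
* GBLUP:    [I + lambda_g Ginv] g = y  (inverse form) or
            [G + lambda_g I] g = G y   (non-inverse form).
* PCRR:     [S^2 + lambda I] s = T'y on full SVD scores (diagonal),
            [C'C + lambda I] s = C'y on reduced scores (dense, small), or
            [S_C^2 + lambda I] t = T-hat'y after the two-stage SVD
            (diagonal again).

Individual genetic values follow by multiplying the coefficient vector back
through the relevant score matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.sparse.linalg import LinearOperator, cg

from .genotype_io import GenotypeMatrix, VarianceComponents, scaling_constant
from .svd_reduction import CoreBasis, ScoreMatrix, SVDFactors

__all__ = ["Solutions", "solve_snp_blup", "solve_gblup", "solve_pcrr",
           "back_transform_snp_effects", "fit_mean", "write_ebv",
           "write_snp_effects"]


@dataclass
class Solutions:
    g_hat: np.ndarray
    b_hat: np.ndarray | None = None
    s_hat: np.ndarray | None = None
    t_hat: np.ndarray | None = None
    mu_hat: float = 0.0
    n_iterations: int | None = None


def fit_mean(y: np.ndarray, strategy: str = "precenter"):
    """Handle the fixed mean: returns (mu_hat, adjusted y).

    'precenter' estimates mu as the phenotype mean and removes it; 'none'
    bypasses the mean (worked examples omit fixed effects).  The 'joint'
    strategy (mean absorbed in the normal equations) is handled inside the
    individual solvers via ``strategy='joint'``.
    """
    y = np.asarray(y, dtype=float)
    if strategy == "precenter":
        mu = float(y.mean())
        return mu, y - mu
    if strategy == "none":
        return 0.0, y
    raise ValueError(f"unknown mean strategy {strategy!r}")


def _spd_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    return sla.cho_solve(sla.cho_factor(A, lower=True), b)


def _solve_joint(M_build, rhs_build, design_row_sum, y):
    """Solve a ridge system jointly with an intercept column of ones.

    Augmented normal equations:
        [ n        1'W      ] [mu]   [1'y ]
        [ W'1   M (ridge)   ] [x ] = [rhs ]
    where W is the design (X, T, C or T-hat) and M its ridge LHS.
    """
    n = len(y)
    M = M_build()
    rhs = rhs_build()
    top = np.concatenate(([n], design_row_sum))
    A = np.zeros((len(rhs) + 1, len(rhs) + 1))
    A[0] = top
    A[:, 0] = top
    A[1:, 1:] = M
    b = np.concatenate(([y.sum()], rhs))
    sol = np.linalg.solve(A, b)
    return float(sol[0]), sol[1:]


def solve_snp_blup(
    gm: GenotypeMatrix,
    y: np.ndarray,
    vc: VarianceComponents,
    rho_val: float | None = None,
    mean: str = "none",
) -> Solutions:
    """Ridge solution for per-locus effects: [X'X + lambda I] b = X'y."""
    X = gm.dosages
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    lam = vc.lambda_snp(scaling_constant(gm) if rho_val is None else rho_val)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    k = X.shape[1]
    if mean == "joint":
        mu, b = _solve_joint(lambda: X.T @ X + lam * np.eye(k),
                             lambda: X.T @ y, X.sum(axis=0), y)
    else:
        mu, y = fit_mean(y, mean)
        b = _spd_solve(X.T @ X + lam * np.eye(k), X.T @ y)
    return Solutions(g_hat=X @ b, b_hat=b, mu_hat=mu)


def solve_gblup(
    G,
    y: np.ndarray,
    vc: VarianceComponents,
    form: str = "noninverse",
    theta: float | None = None,
    mean: str = "none",
    method: str = "direct",
    cg_rtol: float = 1e-10,
) -> Solutions:
    """Animal-model solve for genetic values.

    ``G`` is either a dense GRM (N x N) or a :class:`~svdgp.grm.
    GRMInverseOperator` already representing the regularized inverse.  The
    inverse form solves [I + lambda_g Ginv] g = y, the non-inverse form
    [G + lambda_g I] g = G y (no inverse needed).  ``method='pcg'`` uses a
    Jacobi-preconditioned conjugate gradient instead of a dense
    factorization.
    """
    from .grm import GRMInverseOperator  # local import to avoid a cycle

    y = np.asarray(y, dtype=float)
    lam = vc.lambda_g
    mu, y = fit_mean(y, "precenter" if mean == "joint" else mean)
    n = len(y)

    if isinstance(G, GRMInverseOperator):
        if form != "inverse":
            raise ValueError("an inverse operator supports only the inverse form")
        if method == "pcg":
            op = LinearOperator((n, n), matvec=lambda z: z + lam * G.matvec(z))
            g, info = cg(op, y, rtol=cg_rtol, atol=0.0)
            if info != 0:
                raise RuntimeError(f"PCG failed to converge (info={info})")
            return Solutions(g_hat=g, mu_hat=mu)
        A = lam * G.materialize()
        A[np.diag_indices(n)] += 1.0
        return Solutions(g_hat=np.linalg.solve(A, y), mu_hat=mu)

    G = np.asarray(G, dtype=float)
    if form == "noninverse":
        g = np.linalg.solve(G + lam * np.eye(n), G @ y)
        return Solutions(g_hat=g, mu_hat=mu)
    if form == "inverse":
        Gw = G if theta is None else G + theta * np.eye(n)
        try:
            c, low = sla.cho_factor(Gw, lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "GRM is singular; regularize with theta (G + I*theta) before "
                "using the inverse form") from exc
        Ginv = sla.cho_solve((c, low), np.eye(n))
        g = np.linalg.solve(np.eye(n) + lam * Ginv, y)
        return Solutions(g_hat=g, mu_hat=mu)
    raise ValueError(f"unknown form {form!r}")


def solve_pcrr(
    scores,
    y: np.ndarray,
    vc: VarianceComponents,
    rho_val: float,
    mean: str = "none",
) -> Solutions:
    """PC ridge regression, dispatching on the score representation.

    Full SVD factors and two-stage scores give diagonal systems; reduced
    scores C give a dense q x q system.
    """
    y = np.asarray(y, dtype=float)
    lam = vc.lambda_snp(rho_val)
    if lam <= 0:
        raise ValueError("lambda must be positive")

    if isinstance(scores, SVDFactors):
        T = scores.U * scores.S
        if mean == "joint":
            mu, coef = _solve_joint(lambda: np.diag(scores.S ** 2 + lam),
                                    lambda: T.T @ y, T.sum(axis=0), y)
        else:
            mu, y = fit_mean(y, mean)
            coef = (T.T @ y) / (scores.S ** 2 + lam)
        return Solutions(g_hat=T @ coef, s_hat=coef, mu_hat=mu)

    if not isinstance(scores, ScoreMatrix):
        raise TypeError("scores must be SVDFactors or ScoreMatrix")

    if scores.stage == "two_stage":
        T = scores.That
        if mean == "joint":
            mu, coef = _solve_joint(lambda: np.diag(scores.S_C ** 2 + lam),
                                    lambda: T.T @ y, T.sum(axis=0), y)
        else:
            mu, y = fit_mean(y, mean)
            coef = (T.T @ y) / (scores.S_C ** 2 + lam)
        return Solutions(g_hat=T @ coef, t_hat=coef, mu_hat=mu)

    C = scores.C
    q = C.shape[1]
    if mean == "joint":
        mu, coef = _solve_joint(lambda: C.T @ C + lam * np.eye(q),
                                lambda: C.T @ y, C.sum(axis=0), y)
    else:
        mu, y = fit_mean(y, mean)
        coef = _spd_solve(C.T @ C + lam * np.eye(q), C.T @ y)
    return Solutions(g_hat=C @ coef, s_hat=coef, mu_hat=mu)


def back_transform_snp_effects(sol: Solutions, basis) -> Solutions:
    """Recover per-locus effects from PC coefficients.

    With full SVD factors, b = V s.  With a core basis and two-stage
    coefficients, b = blockdiag(V_nq) V_C t.  The result satisfies the
    projection identity b = V V' b.
    """
    if isinstance(basis, SVDFactors):
        if sol.s_hat is None:
            raise ValueError("solutions carry no PC coefficients")
        if basis.V.shape[1] != len(sol.s_hat):
            raise ValueError("dimension mismatch between V and s_hat")
        sol.b_hat = basis.V @ sol.s_hat
        return sol
    if isinstance(basis, ScoreMatrix):
        score = basis
        if score.basis is None:
            raise ValueError("score matrix lacks its core basis")
        Vhat = score.basis.block_diag_V()
        if sol.t_hat is not None:
            if score.V_C is None:
                raise ValueError("two-stage factors missing V_C")
            sol.b_hat = Vhat @ (score.V_C @ sol.t_hat)
        elif sol.s_hat is not None:
            sol.b_hat = Vhat @ sol.s_hat
        else:
            raise ValueError("solutions carry no PC coefficients")
        return sol
    if isinstance(basis, CoreBasis):
        if sol.s_hat is None:
            raise ValueError("solutions carry no PC coefficients")
        Vhat = basis.block_diag_V()
        if Vhat.shape[1] != len(sol.s_hat):
            raise ValueError("dimension mismatch between basis and s_hat")
        sol.b_hat = Vhat @ sol.s_hat
        return sol
    raise TypeError("basis must be SVDFactors, CoreBasis or ScoreMatrix")


def write_ebv(path, ids, sol: Solutions) -> None:
    with open(path, "w") as fh:
        fh.write("id\tg_hat\tmu_hat\n")
        for i, g in zip(ids, sol.g_hat):
            fh.write(f"{i}\t{g:.10g}\t{sol.mu_hat:.10g}\n")


def write_snp_effects(path, snp_ids, sol: Solutions) -> None:
    if sol.b_hat is None:
        raise ValueError("no SNP effects in solutions")
    with open(path, "w") as fh:
        fh.write("snp_id\tb_hat\n")
        for s, b in zip(snp_ids, sol.b_hat):
            fh.write(f"{s}\t{b:.10g}\n")
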