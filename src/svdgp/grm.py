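"""Genomic relationship matrices and exact Woodbury inverses.

The regularized GRM is Gt = G + I*theta with G approximated by a low-rank
Gram product (1/rho) A A' (A = scores, genotypes, or QR factors).  Its exact
inverse has the Woodbury form

    Gt^-1 = (1/theta) (I - A (A'A + I rho theta)^-1 A'),

which requires inverting only the small inner system.  All operators expose
matrix-vector products and row extraction without materializing N x N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .genotype_io import GenotypeMatrix, rho as rho_of, vanraden2_weights
from .svd_reduction import CoreBasis, ScoreMatrix

__all__ = [
    "GRM", "GRMInverseOperator", "WoodburyInverseOperator",
    "APYInverseOperator", "build_grm", "pcig_inverse",
    "woodbury_inverse_markers", "qrig_inverse", "apy_inverse",
    "weighted_pcig_inverse", "inverse_row", "export_inverse",
]


@dataclass
class GRM:
    G: np.ndarray
    rho: float
    theta: float = 0.0
    weighted: bool = False
    D: np.ndarray | None = None

    @property
    def regularized(self) -> np.ndarray:
        return self.G + self.theta * np.eye(self.G.shape[0])


def build_grm(
    gm: GenotypeMatrix,
    method: str = "vanraden1",
    D: np.ndarray | None = None,
    theta: float = 0.0,
) -> GRM:
    """Dense GRM: G = X X'/rho (method 1) or X D X'/rho with locus weights."""
    if gm.coding == "raw":
        raise ValueError("raw dosages: center first")
    X = gm.dosages
    if method == "vanraden1":
        r = rho_of(gm)
        return GRM(G=(X @ X.T) / r, rho=r, theta=theta)
    if method == "weighted":
        if D is None:
            D = vanraden2_weights(gm.allele_freq)
        D = np.asarray(D, dtype=float)
        r = rho_of(gm, weights=D)
        return GRM(G=((X * D) @ X.T) / r, rho=r, theta=theta, weighted=True, D=D)
    raise ValueError(f"unknown GRM method {method!r}")


class GRMInverseOperator:
    """Implicit representation of the inverse regularized GRM."""

    algorithm: str
    theta: float
    rho: float
    n: int

    def matvec(self, z: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def row(self, i: int) -> np.ndarray:
        raise NotImplementedError

    def materialize(self) -> np.ndarray:
        return np.vstack([self.row(i) for i in range(self.n)])

    def approx_grm(self) -> np.ndarray:
        """The (dense) regularized GRM this operator inverts exactly."""
        raise NotImplementedError


class WoodburyInverseOperator(GRMInverseOperator):
    """(1/theta)(I - A M_inv A') with a diagonal or dense inner inverse.

    ``F`` optionally records a middle factor so that the approximated GRM is
    (1/rho) A F A' + I theta (weighted case); the inverse itself always has
    the plain Woodbury form above.
    """

    def __init__(self, A, M_inv, theta, rho, algorithm, F=None):
        if theta <= 0:
            raise ValueError("theta must be positive")
        self.A = np.asarray(A, dtype=float)
        self.M_inv = np.asarray(M_inv, dtype=float)
        self.diagonal_inner = self.M_inv.ndim == 1
        self.theta = float(theta)
        self.rho = float(rho)
        self.algorithm = algorithm
        self.F = F
        self.n = self.A.shape[0]

    def _inner(self, w: np.ndarray) -> np.ndarray:
        return self.M_inv * w if self.diagonal_inner else self.M_inv @ w

    def matvec(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return (z - self.A @ self._inner(self.A.T @ z)) / self.theta

    def row(self, i: int) -> np.ndarray:
        if not 0 <= i < self.n:
            raise IndexError(f"row {i} out of range for N={self.n}")
        out = -(self._inner(self.A[i]) @ self.A.T)
        out[i] += 1.0
        return out / self.theta

    def materialize(self) -> np.ndarray:
        out = -(self.A * self.M_inv) @ self.A.T if self.diagonal_inner \
            else -self.A @ self.M_inv @ self.A.T
        out[np.diag_indices(self.n)] += 1.0
        return out / self.theta

    def approx_grm(self) -> np.ndarray:
        if self.F is None:
            G = (self.A @ self.A.T) / self.rho
        else:
            G = (self.A @ self.F @ self.A.T) / self.rho
        G[np.diag_indices(self.n)] += self.theta
        return G


class APYInverseOperator(GRMInverseOperator):
    """Blockwise APY inverse: exact core block, diagonal non-core block.

    Non-core values are recursions on the core, g_i = G_ic Gcc^-1 g_c + eps_i
    with independent eps_i, giving
        Gt^-1 = [ Gcc^-1 + P Dinv P'   -P Dinv ]
                [ -Dinv P'              Dinv    ]
    with P = Gcc^-1 G_cn and D the conditional variances.
    """

    def __init__(self, Gcc_inv, P, d_inv, theta, rho):
        self.Gcc_inv = Gcc_inv
        self.P = P                      # (n_core, n_noncore)
        self.d_inv = d_inv              # (n_noncore,)
        self.theta = float(theta)
        self.rho = float(rho)
        self.algorithm = "apy"
        self.n_core = Gcc_inv.shape[0]
        self.n = self.n_core + P.shape[1]

    def matvec(self, z: np.ndarray) -> np.ndarray:
        zc, zn = z[:self.n_core], z[self.n_core:]
        w = self.d_inv * (zn - self.P.T @ zc)
        top = self.Gcc_inv @ zc - self.P @ w
        return np.concatenate([top, w])

    def row(self, i: int) -> np.ndarray:
        if not 0 <= i < self.n:
            raise IndexError(f"row {i} out of range for N={self.n}")
        e = np.zeros(self.n)
        e[i] = 1.0
        return self.matvec(e)

    def materialize(self) -> np.ndarray:
        nc = self.n_core
        out = np.zeros((self.n, self.n))
        PD = self.P * self.d_inv
        out[:nc, :nc] = self.Gcc_inv + PD @ self.P.T
        out[:nc, nc:] = -PD
        out[nc:, :nc] = -PD.T
        out[nc:, nc:] = np.diag(self.d_inv)
        return out


def pcig_inverse(scores: ScoreMatrix, rho: float, theta: float = 1e-3
                 ) -> WoodburyInverseOperator:
    """Exact inverse of the PC-approximated GRM (1/rho) A A' + I theta.

    Two-stage scores give a diagonal inner system (S_C^2 + I rho theta);
    reduced scores give a dense sum(q_i)-dimensional one.  Both represent
    the same operator since C C' = T-hat T-hat'.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if scores.stage == "two_stage":
        A = scores.That
        M_inv = 1.0 / (scores.S_C ** 2 + rho * theta)
    else:
        A = scores.C
        q = A.shape[1]
        M_inv = _spd_inv(A.T @ A + rho * theta * np.eye(q))
    return WoodburyInverseOperator(A, M_inv, theta, rho, "pcig")


def _spd_inv(M: np.ndarray) -> np.ndarray:
    c, low = sla.cho_factor(M, lower=True)
    return sla.cho_solve((c, low), np.eye(M.shape[0]))


def woodbury_inverse_markers(gm: GenotypeMatrix, rho: float | None = None,
                             theta: float = 1e-3) -> WoodburyInverseOperator:
    """Marker-side Woodbury inverse of Gt = (1/rho) X X' + I theta.

    Intended for k < N, where the k x k inner system beats inverting N x N.
    """
    if gm.coding == "raw":
        raise ValueError("raw dosages: center first")
    X = gm.dosages
    N, k = X.shape
    if k >= N:
        import warnings
        warnings.warn(f"k={k} >= N={N}: a dense N x N inverse would be cheaper")
    if rho is None:
        rho = rho_of(gm)
    M_inv = _spd_inv(X.T @ X + rho * theta * np.eye(k)) if k else \
        np.zeros((0, 0))
    return WoodburyInverseOperator(X, M_inv, theta, rho, "woodbury_markers")


def qrig_inverse(
    gm: GenotypeMatrix,
    core_ids,
    rho: float,
    theta: float = 1e-3,
    by_chromosome: bool = False,
) -> WoodburyInverseOperator:
    """QR-based inverse: QR of the core X_n', extension R-hat, Woodbury.

    Chromosome-wise mode factors each chromosome separately, then runs a
    second QR on the stacked per-chromosome R factors; the resulting
    operator is identical to the genome-wide one (same projection).
    Rank-deficient cores are handled by the theta term, never by dropping
    columns.
    """
    if gm.coding == "raw":
        raise ValueError("raw dosages: center first")
    if theta <= 0:
        raise ValueError("theta must be positive")
    core_ids = np.asarray(core_ids, dtype=object)
    pos = {v: i for i, v in enumerate(gm.ids)}
    core_rows = np.array([pos[c] for c in core_ids])
    nc = len(core_rows)
    noncore_rows = np.setdiff1d(np.arange(gm.n_individuals), core_rows)
    Xn = gm.dosages[core_rows]
    Xm = gm.dosages[noncore_rows]

    if not by_chromosome:
        Q, R = np.linalg.qr(Xn.T)            # Q: (k, n), R: (n, n)
        core_block = R.T                     # X_n Q = R'
        noncore_block = Xm @ Q
    else:
        chroms = gm.chromosomes
        Qs, Rs, idxs = [], [], []
        for lab in chroms:
            ix = np.flatnonzero(gm.chrom_of == lab)
            Qi, Ri = np.linalg.qr(Xn[:, ix].T)
            Qs.append(Qi)
            Rs.append(Ri)
            idxs.append(ix)
        Q2, Rn = np.linalg.qr(np.vstack(Rs))  # (c*n, n) -> Q2, R_n
        core_block = Rn.T
        noncore_block = np.zeros((len(noncore_rows), nc))
        for i, (Qi, ix) in enumerate(zip(Qs, idxs)):
            noncore_block += (Xm[:, ix] @ Qi) @ Q2[i * nc:(i + 1) * nc]

    A = np.zeros((gm.n_individuals, nc))
    A[core_rows] = core_block
    A[noncore_rows] = noncore_block
    M_inv = _spd_inv(A.T @ A + rho * theta * np.eye(nc))
    return WoodburyInverseOperator(A, M_inv, theta, rho, "qrig")


def apy_inverse(G_cc: np.ndarray, G_nc: np.ndarray, g_nn_diag: np.ndarray,
                theta: float = 1e-3, rho: float = 1.0) -> APYInverseOperator:
    """APY inverse of Gt = G + I theta with core block first.

    ``G_cc``: core x core GRM block (unregularized), ``G_nc``: non-core x
    core cross block, ``g_nn_diag``: non-core diagonal of G.  Conditional
    variances below theta are floored at theta.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    G_cc = np.asarray(G_cc, dtype=float)
    G_nc = np.asarray(G_nc, dtype=float)
    g_nn_diag = np.asarray(g_nn_diag, dtype=float)
    nc = G_cc.shape[0]
    Gcc_inv = _spd_inv(G_cc + theta * np.eye(nc))
    P = Gcc_inv @ G_nc.T                            # (n_core, n_noncore)
    d = (g_nn_diag + theta) - np.einsum("ij,ji->i", G_nc, P)
    d = np.maximum(d, theta)
    return APYInverseOperator(Gcc_inv, P, 1.0 / d, theta, rho)


def weighted_pcig_inverse(
    scores: ScoreMatrix,
    basis: CoreBasis,
    D: np.ndarray,
    rho: float,
    theta: float = 1e-3,
) -> WoodburyInverseOperator:
    """Inverse of the weighted PC-approximated GRM (1/rho) C F_n C' + I theta,
    with F_n = V_nq' D V_nq; inner system (C'C + F_n^-1 rho theta)."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("locus weights must be positive")
    # F_n is block diagonal: basis blocks occupy disjoint locus sets
    q = scores.C.shape[1]
    F = np.zeros((q, q))
    col = 0
    for ix, V in zip(basis.locus_indices, basis.V_blocks):
        qi = V.shape[1]
        F[col:col + qi, col:col + qi] = V.T @ (D[ix][:, None] * V)
        col += qi
    try:
        F_inv = _spd_inv(F)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "F_n = V'DV is singular: basis columns are not independent under "
            "the given weights") from exc
    C = scores.C
    M_inv = _spd_inv(C.T @ C + rho * theta * F_inv)
    return WoodburyInverseOperator(C, M_inv, theta, rho, "weighted_pcig", F=F)


def inverse_row(op: GRMInverseOperator, i: int) -> np.ndarray:
    """Row i of the materialized inverse, computed without forming N x N."""
    return op.row(i)


def export_inverse(op: GRMInverseOperator, path, min_abs: float = 0.0,
                   lower_triangle: bool = True) -> int:
    """Stream the inverse to text triplets `i j value` (1-based).

    Writes the lower triangle including the diagonal by default; entries
    with |value| <= min_abs are filtered (the diagonal is always kept).
    Returns the number of triplets written.
    """
    count = 0
    with open(path, "w") as fh:
        for i in range(op.n):
            row = op.row(i)
            cols = range(i + 1) if lower_triangle else range(op.n)
            for j in cols:
                v = row[j]
                if j == i or abs(v) > min_abs:
                    fh.write(f"{i + 1} {j + 1} {v:.12g}\n")
                    count += 1
    return count
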