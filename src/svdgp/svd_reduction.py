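"""Economy SVD, core-sample bases, score projection and two-stage SVD.

The reduction pipeline is: (1) economy SVD of a core subset of individuals,
optionally chromosome by chromosome; (2) projection of the whole population
onto the retained right singular vectors, giving a score matrix C; and
(3) an optional second-stage SVD of C producing scores T-hat with a diagonal
cross-product, so downstream ridge systems become diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genotype_io import GenotypeMatrix

__all__ = [
    "SVDFactors", "CoreBasis", "ScoreMatrix",
    "economy_svd", "select_rank", "core_svd", "project_scores",
    "two_stage_svd", "canonicalize_signs", "save_basis", "load_basis",
]


@dataclass
class SVDFactors:
    """Economy SVD X = U S V' truncated to numerical rank r."""

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    r: int

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.S) @ self.V.T


def _rank_cutoff(S: np.ndarray, shape) -> float:
    # standard numerical-rank rule: max(N, k) * eps * largest singular value
    if S.size == 0:
        return 0.0
    return max(shape) * np.finfo(float).eps * S[0]


def economy_svd(X: np.ndarray, rank_tol: float | None = None) -> SVDFactors:
    """Economy-sized SVD keeping only components with nonzero singular values.

    Singular values at or below ``rank_tol`` (default: the machine-precision
    rank cutoff) are treated as zero and dropped.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite entries")
    if X.size == 0:
        n, k = X.shape
        return SVDFactors(np.zeros((n, 0)), np.zeros(0), np.zeros((k, 0)), 0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = _rank_cutoff(S, X.shape) if rank_tol is None else rank_tol
    r = int(np.sum(S > tol))
    return SVDFactors(U[:, :r], S[:r], Vt[:r].T, r)


def canonicalize_signs(factors: SVDFactors) -> SVDFactors:
    """Flip each singular vector so its largest-magnitude V entry is positive.

    LAPACK signs are deterministic on one platform but not guaranteed across
    platforms; canonicalized factors serialize reproducibly.  Computation
    does not require it (all identities are sign-invariant).
    """
    if factors.r == 0:
        return factors
    idx = np.argmax(np.abs(factors.V), axis=0)
    signs = np.sign(factors.V[idx, np.arange(factors.r)])
    signs[signs == 0] = 1.0
    return replace(factors, U=factors.U * signs, V=factors.V * signs)


def select_rank(factors_or_S, threshold: float, strict: bool = False) -> int:
    """Smallest q whose leading squared singular values explain ``threshold``.

    Variance is measured on squared singular values.  With ``strict`` the
    cumulative fraction must strictly exceed the threshold.  Components tied
    (to machine precision) with the one at the boundary are all kept.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    S = factors_or_S.S if isinstance(factors_or_S, SVDFactors) else \
        np.asarray(factors_or_S, dtype=float)
    if S.size == 0:
        raise ValueError("empty factorization")
    ev = S ** 2
    frac = np.cumsum(ev) / ev.sum()
    if strict:
        ok = frac > threshold
    else:
        ok = frac >= threshold - 1e-12
    q = int(np.argmax(ok)) + 1 if ok.any() else len(S)
    # keep components tied with the boundary singular value
    while q < len(S) and np.isclose(S[q], S[q - 1], rtol=1e-12, atol=0.0):
        q += 1
    return q


@dataclass
class CoreBasis:
    """Right-singular-vector blocks estimated from a core sample.

    One block per chromosome (or a single genome-wide block); each block
    stores the column indices of its loci in the source matrix so that
    projection applies the right slice regardless of locus order.
    """

    chrom_labels: list
    locus_indices: list
    V_blocks: list
    sing_values: list
    variance_explained: list
    n_core: int
    core_ids: np.ndarray
    threshold: float
    by_chromosome: bool
    freq_source: str = "self"

    @property
    def q_per_chrom(self) -> list:
        return [V.shape[1] for V in self.V_blocks]

    @property
    def total_components(self) -> int:
        return int(sum(self.q_per_chrom))

    def block_diag_V(self) -> np.ndarray:
        """Dense block-diagonal V-hat factor, rows in source locus order."""
        k = sum(len(ix) for ix in self.locus_indices)
        out = np.zeros((k, self.total_components))
        col = 0
        for ix, V in zip(self.locus_indices, self.V_blocks):
            out[np.asarray(ix), col:col + V.shape[1]] = V
            col += V.shape[1]
        return out


def core_svd(
    gm: GenotypeMatrix,
    core_ids,
    threshold: float = 0.99,
    by_chromosome: bool = False,
    strict: bool = False,
) -> CoreBasis:
    """SVD of the core rows of ``gm``, retaining PC by explained variance.

    ``gm`` must already be centered or standardized with population-level
    frequencies (fixed before subsetting), so core and non-core rows share
    one coordinate system.
    """
    if gm.coding == "raw":
        raise ValueError("center or standardize genotypes before core_svd")
    core_ids = np.asarray(core_ids, dtype=object)
    if core_ids.size == 0:
        raise ValueError("core sample is empty")
    pos = {v: i for i, v in enumerate(gm.ids)}
    try:
        rows = np.array([pos[c] for c in core_ids])
    except KeyError as exc:
        raise ValueError(f"core id {exc.args[0]!r} not in population") from exc
    if rows.size > gm.n_individuals:
        raise ValueError("core sample larger than population")
    Xn = gm.dosages[rows]

    if by_chromosome:
        groups = [(lab, np.flatnonzero(gm.chrom_of == lab))
                  for lab in gm.chromosomes]
    else:
        groups = [("genome", np.arange(gm.n_loci))]

    labels, indices, blocks, svals, varexp = [], [], [], [], []
    for lab, ix in groups:
        fac = economy_svd(Xn[:, ix])
        if fac.r == 0:
            q = 0
            ve = 1.0
        else:
            q = select_rank(fac, threshold, strict=strict)
            ev = fac.S ** 2
            ve = float(ev[:q].sum() / ev.sum())
        labels.append(lab)
        indices.append(ix)
        blocks.append(fac.V[:, :q])
        svals.append(fac.S[:q])
        varexp.append(ve)
    return CoreBasis(labels, indices, blocks, svals, varexp,
                     n_core=int(rows.size), core_ids=core_ids,
                     threshold=threshold, by_chromosome=by_chromosome,
                     freq_source=gm.freq_source)


@dataclass
class ScoreMatrix:
    """Reduced scores C = X V_nq (chromosome blocks concatenated), and after
    the second-stage SVD the diagonalized scores T-hat = U_C S_C."""

    C: np.ndarray
    chrom_labels: list
    block_sizes: list
    stage: str = "reduced"
    That: np.ndarray | None = None
    S_C: np.ndarray | None = None
    V_C: np.ndarray | None = None
    basis: CoreBasis | None = None

    @property
    def n_components(self) -> int:
        return self.C.shape[1]

    @property
    def scores(self) -> np.ndarray:
        """The active score representation (T-hat when two-stage, else C)."""
        return self.That if self.stage == "two_stage" else self.C


def project_scores(gm: GenotypeMatrix, basis: CoreBasis) -> ScoreMatrix:
    """Project all individuals onto the core basis: C = X V_nq per block."""
    if gm.coding == "raw":
        raise ValueError("center or standardize genotypes before projection")
    if basis.by_chromosome:
        have = set(map(str, gm.chromosomes))
        want = set(map(str, basis.chrom_labels))
        if have != want:
            raise ValueError(f"chromosome mismatch: matrix has {sorted(have)}, "
                             f"basis has {sorted(want)}")
    blocks = []
    for ix, V in zip(basis.locus_indices, basis.V_blocks):
        if len(ix) and max(ix) >= gm.n_loci:
            raise ValueError("basis locus indices exceed matrix width")
        blocks.append(gm.dosages[:, ix] @ V)
    C = np.hstack(blocks) if blocks else np.zeros((gm.n_individuals, 0))
    return ScoreMatrix(C=C, chrom_labels=list(basis.chrom_labels),
                       block_sizes=basis.q_per_chrom, basis=basis)


def two_stage_svd(scores: ScoreMatrix) -> ScoreMatrix:
    """SVD of C without further rank reduction: C = U_C S_C V_C' = T-hat V_C'.

    T-hat has a diagonal cross-product (T-hat' T-hat = S_C^2), so the
    ridge system on T-hat is diagonal.  Only numerically-zero singular
    values are dropped.
    """
    if scores.stage != "reduced":
        raise ValueError("two_stage_svd expects stage='reduced' scores")
    fac = economy_svd(scores.C)
    return ScoreMatrix(
        C=scores.C, chrom_labels=scores.chrom_labels,
        block_sizes=scores.block_sizes, stage="two_stage",
        That=fac.U * fac.S, S_C=fac.S, V_C=fac.V, basis=scores.basis)


# ---------------------------------------------------------------------------
# serialization (single HDF5 container so SVD is computed once and reused)


def save_basis(path, basis: CoreBasis, scores: ScoreMatrix | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["threshold"] = basis.threshold
        f.attrs["by_chromosome"] = basis.by_chromosome
        f.attrs["n_core"] = basis.n_core
        f.attrs["freq_source"] = basis.freq_source
        f.create_dataset("core_ids",
                         data=np.asarray(basis.core_ids, dtype="S"))
        for lab, ix, V, S, ve in zip(basis.chrom_labels, basis.locus_indices,
                                     basis.V_blocks, basis.sing_values,
                                     basis.variance_explained):
            g = f.create_group(f"chrom/{lab}")
            g.create_dataset("loci", data=np.asarray(ix, dtype=np.int64))
            g.create_dataset("V", data=V)
            g.create_dataset("S", data=S)
            g.attrs["variance_explained"] = ve
        if scores is not None:
            g = f.create_group("scores")
            g.attrs["stage"] = scores.stage
            g.create_dataset("C", data=scores.C)
            g.create_dataset("block_sizes",
                             data=np.asarray(scores.block_sizes, dtype=np.int64))
            if scores.stage == "two_stage":
                g.create_dataset("That", data=scores.That)
                g.create_dataset("S_C", data=scores.S_C)
                g.create_dataset("V_C", data=scores.V_C)


def load_basis(path):
    import h5py

    with h5py.File(path, "r") as f:
        labels = sorted(f["chrom"].keys(), key=str)
        indices, blocks, svals, varexp = [], [], [], []
        for lab in labels:
            g = f[f"chrom/{lab}"]
            indices.append(g["loci"][...])
            blocks.append(g["V"][...])
            svals.append(g["S"][...])
            varexp.append(float(g.attrs["variance_explained"]))
        basis = CoreBasis(
            labels, indices, blocks, svals, varexp,
            n_core=int(f.attrs["n_core"]),
            core_ids=np.array([c.decode() for c in f["core_ids"][...]],
                              dtype=object),
            threshold=float(f.attrs["threshold"]),
            by_chromosome=bool(f.attrs["by_chromosome"]),
            freq_source=str(f.attrs["freq_source"]))
        scores = None
        if "scores" in f:
            g = f["scores"]
            scores = ScoreMatrix(
                C=g["C"][...], chrom_labels=labels,
                block_sizes=[int(b) for b in g["block_sizes"][...]],
                stage=str(g.attrs["stage"]),
                That=g["That"][...] if "That" in g else None,
                S_C=g["S_C"][...] if "S_C" in g else None,
                V_C=g["V_C"][...] if "V_C" in g else None,
                basis=basis)
    return basis, scores
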