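"""Desk-scale example data: two small centered genotype matrices.

Example 1: four individuals, five loci, rank 3, with phenotypes; used to
demonstrate SNP-BLUP / full PCRR equivalence and the b = V V' b identity.
Example 2 appends a fifth individual whose genotype duplicates the first,
and treats the first four individuals as the core sample.
"""

from __future__ import annotations

import numpy as np

from .genotype_io import GenotypeMatrix, PhenotypeVector

X_EXAMPLE1 = np.array([
    [0, 1, 0, 1, 0],
    [1, -1, -1, 1, 0],
    [-1, 1, 1, -1, 0],
    [0, 0, -1, -1, 1],
], dtype=float)

Y_EXAMPLE1 = np.array([-0.5, -0.5, 0.0, 1.0])

X_EXAMPLE2 = np.vstack([X_EXAMPLE1, X_EXAMPLE1[0]])

Y_EXAMPLE2 = np.array([-0.5, -0.5, 0.0, 1.0, -0.7])

CORE_IDS_EXAMPLE2 = np.array(["ind1", "ind2", "ind3", "ind4"], dtype=object)


def example1() -> tuple[GenotypeMatrix, PhenotypeVector]:
    gm = GenotypeMatrix(
        dosages=X_EXAMPLE1.copy(),
        ids=np.array([f"ind{i}" for i in range(1, 5)], dtype=object),
        snp_ids=np.array([f"snp{j}" for j in range(1, 6)], dtype=object),
        allele_freq=np.full(5, 0.5),
        chrom_of=np.full(5, "1", dtype=object),
        coding="centered",
    )
    return gm, PhenotypeVector(y=Y_EXAMPLE1.copy(), ids=gm.ids)


def example2() -> tuple[GenotypeMatrix, PhenotypeVector]:
    gm = GenotypeMatrix(
        dosages=X_EXAMPLE2.copy(),
        ids=np.array([f"ind{i}" for i in range(1, 6)], dtype=object),
        snp_ids=np.array([f"snp{j}" for j in range(1, 6)], dtype=object),
        allele_freq=np.full(5, 0.5),
        chrom_of=np.full(5, "1", dtype=object),
        coding="centered",
    )
    return gm, PhenotypeVector(y=Y_EXAMPLE2.copy(), ids=gm.ids)
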