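# svdgp

Reduced-dimension genomic prediction via singular value decomposition of the
genotype matrix:

* **PC ridge regression (PCRR)** — SNP-BLUP reparameterized on SVD scores, in
  full, core-sample-reduced, two-stage (diagonalized) and chromosome-wise
  variants.
* **Exact Woodbury inverses of PC-approximated GRMs** — PCIG (chromosome-wise
  or genome-wide), QRIG (QR-based), weighted GRMs, the marker-side Woodbury
  form for k < N, and an APY baseline. All operators support row-wise
  materialization and sparse-triplet export without forming the full N x N
  inverse.
* **A forward Wright–Fisher simulator** — infinite-sites mutation, Poisson
  recombination, burn-in to mutation–drift equilibrium, a bottleneck, QTL
  architecture and phenotypes at a target heritability.
* **A model-comparison harness** — core/validation sampling with masked
  phenotypes, EBV-vs-EBV correlations and EBV-vs-TBV accuracies across
  methods, core sizes and heritabilities.

## Library quick tour

```python
import numpy as np
from svdgp import (read_genotypes, standardize, core_svd, project_scores,
                   two_stage_svd, pcig_inverse, solve_pcrr,
                   VarianceComponents, scaling_constant)

gm = standardize(read_genotypes("genotypes.tsv", chrom_map="chrom_map.tsv"),
                 drop_monomorphic=True)
basis = core_svd(gm, core_ids, threshold=0.99, by_chromosome=True)
scores = two_stage_svd(project_scores(gm, basis))

vc = VarianceComponents.from_h2(0.5)
sol = solve_pcrr(scores, y, vc, rho_val=scaling_constant(gm))   # EBV in sol.g_hat

op = pcig_inverse(scores, rho=scaling_constant(gm), theta=1e-3)
row7 = op.row(7)              # one row of the inverse GRM, no N x N matrix
```

## CLI

```bash
svdgp simulate --preset scaled --seed 1 --out-dir sim/       # text outputs + manifest
svdgp svd --genotypes sim/genotypes.tsv --chrom-map sim/chrom_map.tsv \
      --core-ids core.txt --threshold 0.99 --by-chromosome --out basis.h5
svdgp ginverse --genotypes sim/genotypes.tsv --scores basis.h5 \
      --algorithm pcig --theta 1e-3 --out ginv.txt            # `i j value` triplets
svdgp predict --model pcrr --genotypes sim/genotypes.tsv \
      --phenotypes sim/phenotypes.tsv --h2 0.5 --out ebv.tsv
svdgp compare --seed 1 --core-sizes 200,400 --h2-levels 0.25,0.5 --out results.csv
```

The paper-scale simulation preset exists but is guarded
(`--preset paper --allow-large`); the default preset is desk-scale.

## Layout

```
src/svdgp/genotype_io.py    dosage matrices, centering/standardization, rho
src/svdgp/svd_reduction.py  economy/core/two-stage SVD, PC selection, scores
src/svdgp/predictors.py     SNP-BLUP, GBLUP, PCRR solvers, back-transforms
src/svdgp/grm.py            GRMs and Woodbury/QR/APY inverse operators
src/svdgp/simulator.py      forward Wright-Fisher simulator
src/svdgp/evaluation.py     comparison harness and metrics
src/svdgp/cli.py            `svdgp` command-line interface
src/svdgp/examples.py       packaged worked-example matrices
```
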