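"""Forward Wright-Fisher simulator with mutation, recombination, bottleneck.

Discrete generations, random mating, Poisson crossovers (no interference),
infinite-sites mutation at uniform positions along each chromosome (measured
in Morgans, so genetic and mutational coordinates coincide).  After burn-in
to mutation-drift equilibrium, the effective size declines linearly to the
final size over the bottleneck generations, and a large final cohort is
drawn for analysis.

The default configuration is deliberately desk-scale; the published-scale
parameterization is available via :meth:`SimConfig.paper` but takes hours.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix, PhenotypeVector, standardize

__all__ = ["SimConfig", "SimResult", "simulate_population",
           "assign_qtl_and_phenotypes", "effective_loci"]


@dataclass
class SimConfig:
    n_chromosomes: int = 2
    chrom_length_morgans: float = 1.0
    ne_historical: int = 100
    n_burnin_generations: int = 500
    ne_final: int = 50
    bottleneck_generations: int = 10
    mutation_rate: float = 1e-8          # per meiosis, per bp
    genome_bp: float = 1e7               # physical length per chromosome
    n_final_animals: int = 1000
    n_qtl_per_chrom: int = 20
    qtl_maf_min: float = 0.01
    h2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "ne_historical", "n_burnin_generations",
                     "ne_final", "bottleneck_generations", "n_final_animals",
                     "n_qtl_per_chrom"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ne_final > self.ne_historical:
            raise ValueError("ne_final must not exceed ne_historical")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if not 0 <= self.qtl_maf_min < 0.5:
            raise ValueError("qtl_maf_min must be in [0, 0.5)")
        if self.mutation_rate < 0 or self.chrom_length_morgans <= 0:
            raise ValueError("bad mutation rate or chromosome length")

    @classmethod
    def scaled(cls, **overrides) -> "SimConfig":
        """Desk-scale default: minutes on one CPU."""
        return cls(**overrides)

    @classmethod
    def paper(cls, **overrides) -> "SimConfig":
        """Published-scale parameters (hours of CPU; hundreds of thousands
        of segregating sites)."""
        params = dict(n_chromosomes=20, chrom_length_morgans=1.0,
                      ne_historical=1000, n_burnin_generations=10_000,
                      ne_final=100, bottleneck_generations=10,
                      mutation_rate=1e-8, genome_bp=1e8,
                      n_final_animals=10_000, n_qtl_per_chrom=200,
                      qtl_maf_min=0.01)
        params.update(overrides)
        return cls(**params)

    @property
    def sigma_e2(self) -> float:
        """Residual variance giving the target h2 at sigma_g2 = 1."""
        return (1.0 - self.h2) / self.h2

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class SimResult:
    genotypes: GenotypeMatrix              # raw dosages, final cohort
    positions: np.ndarray                  # per-locus position in Morgans
    qtl_indices: np.ndarray | None = None
    qtl_effects: np.ndarray | None = None  # length-k, zero off QTL
    alpha: float | None = None
    tbv: np.ndarray | None = None
    phenotypes: PhenotypeVector | None = None
    sigma_e2: float | None = None
    config: SimConfig | None = None
    n_segregating_burnin_end: int = 0
    n_burnin_sites_surviving: int = 0


# -- haplotype machinery -----------------------------------------------------
# a haplotype is a sorted float array of derived-mutation positions


def _recombine(rng, hapA, hapB, L):
    ncx = rng.poisson(L)
    if ncx == 0:
        return (hapA if rng.random() < 0.5 else hapB).copy()
    cuts = np.sort(rng.uniform(0.0, L, ncx))
    haps = (hapA, hapB) if rng.random() < 0.5 else (hapB, hapA)
    bounds = np.concatenate(([0.0], cuts, [L]))
    segs = []
    for i in range(len(bounds) - 1):
        h = haps[i % 2]
        segs.append(h[np.searchsorted(h, bounds[i]):
                      np.searchsorted(h, bounds[i + 1])])
    return np.concatenate(segs)


def _gamete(rng, ind, L, exp_mut):
    h = _recombine(rng, ind[0], ind[1], L)
    nm = rng.poisson(exp_mut)
    if nm:
        h = np.concatenate([h, rng.uniform(0.0, L, nm)])
        h.sort()
    return h


def _next_generation(rng, pop, n_children, L, exp_mut):
    n = len(pop)
    parents = rng.integers(0, n, size=(n_children, 2))
    return [(_gamete(rng, pop[a], L, exp_mut),
             _gamete(rng, pop[b], L, exp_mut)) for a, b in parents]


def _drop_fixed(pop):
    """Remove mutations carried by every haplotype (fixed, thus monomorphic)."""
    nh = 2 * len(pop)
    allpos = np.concatenate([h for ind in pop for h in ind])
    if allpos.size == 0:
        return pop
    pos, cnt = np.unique(allpos, return_counts=True)
    fixed = pos[cnt == nh]
    if fixed.size == 0:
        return pop
    return [(np.setdiff1d(h0, fixed), np.setdiff1d(h1, fixed))
            for h0, h1 in pop]


def _segregating_positions(pop):
    nh = 2 * len(pop)
    allpos = np.concatenate([h for ind in pop for h in ind]) if pop else \
        np.empty(0)
    if allpos.size == 0:
        return np.empty(0)
    pos, cnt = np.unique(allpos, return_counts=True)
    return pos[cnt < nh]


def simulate_population(cfg: SimConfig, with_phenotypes: bool = True
                        ) -> SimResult:
    """Run the full forward simulation and (optionally) the trait model.

    Returns the final cohort's segregating-site dosage matrix; with
    ``with_phenotypes`` the QTL architecture, true breeding values and
    phenotypes at the configured h2 are attached (requires at least one
    MAF-qualified locus).
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.chrom_length_morgans
    exp_mut = cfg.mutation_rate * cfg.genome_bp

    chrom_genos = []
    chrom_positions = []
    n_seg_burnin = 0
    n_surviving = 0
    for ci in range(cfg.n_chromosomes):
        pop = [(np.empty(0), np.empty(0)) for _ in range(cfg.ne_historical)]
        for g in range(cfg.n_burnin_generations):
            pop = _next_generation(rng, pop, cfg.ne_historical, L, exp_mut)
            if (g + 1) % 100 == 0:
                pop = _drop_fixed(pop)
        burnin_sites = _segregating_positions(pop)
        n_seg_burnin += burnin_sites.size
        # linear census decline over the bottleneck
        sizes = np.linspace(cfg.ne_historical, cfg.ne_final,
                            cfg.bottleneck_generations + 1).round().astype(int)
        for size in sizes[1:]:
            pop = _next_generation(rng, pop, int(size), L, exp_mut)
        final = _next_generation(rng, pop, cfg.n_final_animals, L, exp_mut)

        allpos = np.unique(np.concatenate(
            [h for ind in final for h in ind])) if cfg.n_final_animals else \
            np.empty(0)
        X = np.zeros((cfg.n_final_animals, allpos.size), dtype=np.int16)
        for i, (h0, h1) in enumerate(final):
            X[i, np.searchsorted(allpos, h0)] += 1
            X[i, np.searchsorted(allpos, h1)] += 1
        # keep only loci segregating in the final cohort
        dose = X.sum(axis=0)
        seg = (dose > 0) & (dose < 2 * cfg.n_final_animals)
        X, allpos = X[:, seg], allpos[seg]
        n_surviving += np.isin(burnin_sites, allpos).sum()
        chrom_genos.append(X)
        chrom_positions.append(allpos)

    k_per = [p.size for p in chrom_positions]
    dosages = np.hstack(chrom_genos).astype(float) if sum(k_per) else \
        np.zeros((cfg.n_final_animals, 0))
    chroms = np.concatenate([np.full(k, str(ci + 1), dtype=object)
                             for ci, k in enumerate(k_per)]) if sum(k_per) \
        else np.empty(0, dtype=object)
    positions = np.concatenate(chrom_positions) if sum(k_per) else np.empty(0)
    ids = np.array([f"ind{i + 1}" for i in range(cfg.n_final_animals)],
                   dtype=object)
    snp_ids = np.array([f"snp{c}_{j}" for c, p in
                        zip(range(1, cfg.n_chromosomes + 1), chrom_positions)
                        for j in range(p.size)], dtype=object)
    gm = GenotypeMatrix(dosages, ids, snp_ids,
                        dosages.mean(axis=0) / 2.0 if dosages.size else
                        np.empty(0), chroms, coding="raw")
    result = SimResult(genotypes=gm, positions=positions, config=cfg,
                       n_segregating_burnin_end=int(n_seg_burnin),
                       n_burnin_sites_surviving=int(n_surviving))
    if with_phenotypes and gm.n_loci > 0:
        assign_qtl_and_phenotypes(result, rng)
    return result


def assign_qtl_and_phenotypes(result: SimResult, rng=None) -> SimResult:
    """Sample QTL, scale effects to unit genetic variance, draw phenotypes.

    Per chromosome, QTL are drawn uniformly without replacement among loci
    with MAF above the configured minimum; effects are standard normal on
    the standardized genotype scale; alpha rescales them so the empirical
    variance of TBV in the reference cohort is exactly 1.  Residuals are
    N(0, sigma_e2) with sigma_e2 = (1 - h2)/h2.
    """
    import logging
    logger = logging.getLogger(__name__)
    cfg = result.config
    gm = result.genotypes
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    p = gm.allele_freq
    maf = np.minimum(p, 1.0 - p)
    qtl_idx = []
    for lab in gm.chromosomes:
        cand = np.flatnonzero((gm.chrom_of == lab) & (maf > cfg.qtl_maf_min))
        take = min(cfg.n_qtl_per_chrom, cand.size)
        if take < cfg.n_qtl_per_chrom:
            logger.warning("chromosome %s: only %d MAF-qualified loci for "
                           "%d requested QTL", lab, cand.size,
                           cfg.n_qtl_per_chrom)
        if take:
            qtl_idx.append(rng.choice(cand, size=take, replace=False))
    if not qtl_idx:
        raise ValueError("no loci qualify as QTL at the configured MAF minimum")
    qtl_idx = np.sort(np.concatenate(qtl_idx))

    b = np.zeros(gm.n_loci)
    b[qtl_idx] = rng.standard_normal(qtl_idx.size)
    Xs = standardize(gm, drop_monomorphic=False).dosages
    raw_tbv = Xs @ b
    var0 = raw_tbv.var()
    if var0 <= 0:
        raise ValueError("degenerate QTL architecture: zero genetic variance")
    alpha = 1.0 / np.sqrt(var0)
    tbv = alpha * raw_tbv
    sigma_e2 = cfg.sigma_e2
    y = tbv + rng.normal(0.0, np.sqrt(sigma_e2), size=gm.n_individuals)

    result.qtl_indices = qtl_idx
    result.qtl_effects = alpha * b
    result.alpha = float(alpha)
    result.tbv = tbv
    result.phenotypes = PhenotypeVector(y=y, ids=gm.ids)
    result.sigma_e2 = float(sigma_e2)
    return result


def effective_loci(Ne: float, L: float) -> float:
    """Effective number of loci: 2 Ne L / ln(2 Ne) (natural log)."""
    if Ne <= 0 or L <= 0:
        raise ValueError("Ne and L must be positive")
    if 2 * Ne == 1:
        raise ValueError("2*Ne = 1 gives a zero denominator")
    return 2.0 * Ne * L / np.log(2.0 * Ne)


# -- export ------------------------------------------------------------------


def export_sim(result: SimResult, out_dir) -> dict:
    """Write genotypes, phenotypes, truth, QTL and config to text files."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm = result.genotypes
    paths = {}

    paths["genotypes"] = out / "genotypes.tsv"
    with open(paths["genotypes"], "w") as fh:
        fh.write("ID\t" + "\t".join(map(str, gm.snp_ids)) + "\n")
        for i, row in zip(gm.ids, gm.dosages):
            fh.write(str(i) + "\t" +
                     "\t".join(str(int(v)) for v in row) + "\n")

    paths["chrom_map"] = out / "chrom_map.tsv"
    with open(paths["chrom_map"], "w") as fh:
        for s, c in zip(gm.snp_ids, gm.chrom_of):
            fh.write(f"{s}\t{c}\n")

    if result.phenotypes is not None:
        paths["phenotypes"] = out / "phenotypes.tsv"
        with open(paths["phenotypes"], "w") as fh:
            fh.write("id\tvalue\n")
            for i, v in zip(result.phenotypes.ids, result.phenotypes.y):
                fh.write(f"{i}\t{v:.10g}\n")
        paths["truth"] = out / "truth.tsv"
        with open(paths["truth"], "w") as fh:
            fh.write("id\ttbv\n")
            for i, v in zip(gm.ids, result.tbv):
                fh.write(f"{i}\t{v:.10g}\n")
        paths["qtl"] = out / "qtl.tsv"
        with open(paths["qtl"], "w") as fh:
            fh.write("locus\teffect\n")
            for j in result.qtl_indices:
                fh.write(f"{gm.snp_ids[j]}\t{result.qtl_effects[j]:.10g}\n")

    paths["config"] = out / "sim_config.json"
    with open(paths["config"], "w") as fh:
        fh.write(result.config.to_json())
    return paths
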