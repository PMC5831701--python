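import numpy as np
import pytest

from svdgp.genotype_io import (GenotypeMatrix, center, rho, standardize,
                               vanraden2_weights)
from svdgp.grm import (apy_inverse, build_grm, export_inverse, inverse_row,
                       pcig_inverse, qrig_inverse, weighted_pcig_inverse,
                       woodbury_inverse_markers)
from svdgp.svd_reduction import core_svd, project_scores, two_stage_svd

from conftest import random_genotypes

THETA = 1e-3


@pytest.fixture
def gm30():
    rng = np.random.default_rng(17)
    return center(random_genotypes(rng, 30, 200))


def dense_inverse_of(op):
    return np.linalg.inv(op.approx_grm())


class TestBuildGrm:
    def test_weighted_identity_reduces_to_vanraden1(self, gm30):
        g1 = build_grm(gm30, method="vanraden1")
        g2 = build_grm(gm30, method="weighted", D=np.ones(gm30.n_loci))
        np.testing.assert_allclose(g1.G, g2.G, atol=1e-12)
        assert g1.rho == pytest.approx(g2.rho)

    def test_identical_individuals_identical_rows(self):
        raw = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]], float)
        gm = center(GenotypeMatrix(raw, list("abc"),
                                   [f"s{i}" for i in range(4)],
                                   raw.mean(0) / 2, ["1"] * 4, "raw"))
        G = build_grm(gm).G
        np.testing.assert_allclose(G[0], G[1], atol=1e-12)

    def test_vanraden2_mean_diagonal_near_one(self):
        rng = np.random.default_rng(19)
        gm = random_genotypes(rng, 10, 100)
        gm = center(gm)
        keep = ~gm.monomorphic
        from dataclasses import replace
        gm = replace(gm, dosages=gm.dosages[:, keep],
                     snp_ids=gm.snp_ids[keep],
                     allele_freq=gm.allele_freq[keep],
                     chrom_of=gm.chrom_of[keep])
        D = vanraden2_weights(gm.allele_freq)
        G = build_grm(gm, method="weighted", D=D).G
        assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=0.3)

    def test_raw_coding_rejected(self):
        gm = random_genotypes(np.random.default_rng(0), 5, 5)
        with pytest.raises(ValueError, match="center"):
            build_grm(gm)

    def test_positive_semidefinite(self, gm30):
        G = build_grm(gm30).G
        rng = np.random.default_rng(0)
        for _ in range(5):
            z = rng.standard_normal(30)
            assert z @ G @ z >= -1e-10
        Gt = G + THETA * np.eye(30)
        assert np.linalg.eigvalsh(Gt).min() >= THETA - 1e-8


class TestPcigInverse:
    def test_against_dense_oracle(self, gm30):
        r = rho(gm30)
        basis = core_svd(gm30, gm30.ids[:20], threshold=0.95,
                         by_chromosome=True)
        sc = project_scores(gm30, basis)
        op = pcig_inverse(sc, rho=r, theta=THETA)
        dense = np.linalg.inv((sc.C @ sc.C.T) / r + THETA * np.eye(30))
        assert np.abs(op.materialize() - dense).max() <= 1e-9

    def test_zero_scores(self):
        from svdgp.svd_reduction import ScoreMatrix
        sc = ScoreMatrix(C=np.zeros((5, 2)), chrom_labels=["1"],
                         block_sizes=[2])
        op = pcig_inverse(sc, rho=1.0, theta=0.5)
        np.testing.assert_allclose(op.materialize(), np.eye(5) / 0.5)

    def test_c_path_equals_that_path(self, gm30):
        r = rho(gm30)
        basis = core_svd(gm30, gm30.ids[:20], threshold=0.95,
                         by_chromosome=True)
        sc = project_scores(gm30, basis)
        ts = two_stage_svd(sc)
        op_c = pcig_inverse(sc, rho=r, theta=THETA)
        op_t = pcig_inverse(ts, rho=r, theta=THETA)
        rng = np.random.default_rng(1)
        for _ in range(5):
            z = rng.standard_normal(30)
            np.testing.assert_allclose(op_c.matvec(z), op_t.matvec(z),
                                       atol=1e-10)

    def test_lossless_basis_equals_dense_grm_inverse(self, gm30):
        # approximation error lives in the basis, never in the inversion
        r = rho(gm30)
        basis = core_svd(gm30, gm30.ids, threshold=1.0, by_chromosome=True)
        ts = two_stage_svd(project_scores(gm30, basis))
        op = pcig_inverse(ts, rho=r, theta=THETA)
        dense = np.linalg.inv((gm30.dosages @ gm30.dosages.T) / r +
                              THETA * np.eye(30))
        assert np.abs(op.materialize() - dense).max() <= 1e-8

    def test_identity_product(self, gm30):
        r = rho(gm30)
        basis = core_svd(gm30, gm30.ids[:15], threshold=0.9)
        sc = project_scores(gm30, basis)
        op = pcig_inverse(sc, rho=r, theta=THETA)
        np.testing.assert_allclose(op.approx_grm() @ op.materialize(),
                                   np.eye(30), atol=1e-8)

    def test_theta_validation(self, gm30):
        basis = core_svd(gm30, gm30.ids[:10], threshold=0.9)
        sc = project_scores(gm30, basis)
        with pytest.raises(ValueError, match="theta"):
            pcig_inverse(sc, rho=1.0, theta=0.0)


class TestWoodburyMarkers:
    def test_against_dense_oracle(self):
        rng = np.random.default_rng(23)
        gm = center(random_genotypes(rng, 50, 10))
        op = woodbury_inverse_markers(gm, theta=THETA)
        assert np.abs(op.materialize() - dense_inverse_of(op)).max() <= 1e-9

    def test_zero_genotypes(self):
        gm = GenotypeMatrix(np.zeros((4, 2)), list("abcd"), ["s1", "s2"],
                            [0.0, 0.0], ["1", "1"], coding="centered")
        op = woodbury_inverse_markers(gm, rho=1.0, theta=0.25)
        np.testing.assert_allclose(op.materialize(), np.eye(4) / 0.25)

    def test_warns_when_k_large(self, gm30):
        with pytest.warns(UserWarning, match="cheaper"):
            woodbury_inverse_markers(gm30, theta=THETA)

    def test_gblup_theta_sensitivity_shrinks(self):
        from svdgp.genotype_io import VarianceComponents
        from svdgp.predictors import solve_gblup
        rng = np.random.default_rng(29)
        gm = center(random_genotypes(rng, 40, 10))
        y = rng.standard_normal(40)
        vc = VarianceComponents(1.0, 1.0)
        G = build_grm(gm).G
        ref = solve_gblup(G, y, vc, form="noninverse").g_hat
        diffs = []
        for theta in (1e-3, 1e-6):
            op = woodbury_inverse_markers(gm, theta=theta)
            got = solve_gblup(op, y, vc, form="inverse").g_hat
            diffs.append(np.abs(got - ref).max())
        assert diffs[1] < diffs[0]


class TestQrigInverse:
    def test_core_all_matches_dense(self, gm30):
        r = rho(gm30)
        op = qrig_inverse(gm30, gm30.ids, rho=r, theta=THETA)
        dense = np.linalg.inv((gm30.dosages @ gm30.dosages.T) / r +
                              THETA * np.eye(30))
        assert np.abs(op.materialize() - dense).max() <= 1e-9

    def test_duplicate_of_core_animal(self):
        rng = np.random.default_rng(31)
        gm = random_genotypes(rng, 10, 60)
        gm.dosages[9] = gm.dosages[0]  # non-core clone of core animal 0
        gm = center(GenotypeMatrix(gm.dosages, gm.ids, gm.snp_ids,
                                   gm.dosages.mean(0) / 2, gm.chrom_of, "raw"))
        op = qrig_inverse(gm, gm.ids[:5], rho=rho(gm), theta=THETA)
        np.testing.assert_allclose(op.A[9], op.A[0], atol=1e-10)

    def test_chromosome_wise_equals_genome_wide(self, gm30):
        r = rho(gm30)
        op_gw = qrig_inverse(gm30, gm30.ids[:12], rho=r, theta=THETA)
        op_cw = qrig_inverse(gm30, gm30.ids[:12], rho=r, theta=THETA,
                             by_chromosome=True)
        rng = np.random.default_rng(2)
        for _ in range(5):
            z = rng.standard_normal(30)
            np.testing.assert_allclose(op_cw.matvec(z), op_gw.matvec(z),
                                       atol=1e-9)

    def test_qr_core_gram_identity(self, gm30):
        # G_n = R_n' R_n / rho for the core block
        r = rho(gm30)
        core = gm30.ids[:12]
        op = qrig_inverse(gm30, core, rho=r, theta=THETA)
        Xn = gm30.dosages[:12]
        np.testing.assert_allclose(op.A[:12] @ op.A[:12].T, Xn @ Xn.T,
                                   atol=1e-9)

    def test_agreement_with_pcig_at_losslessness(self, gm30):
        r = rho(gm30)
        op_q = qrig_inverse(gm30, gm30.ids, rho=r, theta=THETA)
        basis = core_svd(gm30, gm30.ids, threshold=1.0)
        ts = two_stage_svd(project_scores(gm30, basis))
        op_p = pcig_inverse(ts, rho=r, theta=THETA)
        assert np.abs(op_q.materialize() - op_p.materialize()).max() <= 1e-8


class TestApyInverse:
    def test_core_all_equals_dense(self, gm30):
        G = build_grm(gm30).G
        op = apy_inverse(G, np.zeros((0, 30)), np.zeros(0), theta=THETA)
        dense = np.linalg.inv(G + THETA * np.eye(30))
        assert np.abs(op.materialize() - dense).max() <= 1e-9

    def test_duplicate_noncore_small_conditional_variance(self):
        rng = np.random.default_rng(37)
        gm = random_genotypes(rng, 12, 80)
        gm.dosages[11] = gm.dosages[0]
        gm = center(GenotypeMatrix(gm.dosages, gm.ids, gm.snp_ids,
                                   gm.dosages.mean(0) / 2, gm.chrom_of, "raw"))
        G = build_grm(gm).G
        nc = 8
        op = apy_inverse(G[:nc, :nc], G[nc:, :nc], np.diag(G)[nc:],
                         theta=THETA)
        # clone of core animal 0 is the last non-core animal
        d_clone = 1.0 / op.d_inv[-1]
        assert d_clone <= 3 * THETA

    def test_gblup_correlation_against_dense(self, tiny_sim):
        from svdgp.evaluation import fit_all_methods, metrics
        from svdgp.genotype_io import VarianceComponents, standardize
        gm = standardize(tiny_sim.genotypes, drop_monomorphic=True)
        n = gm.n_individuals
        rng = np.random.default_rng(3)
        y = tiny_sim.phenotypes.y - tiny_sim.phenotypes.y.mean()
        core_idx = np.sort(rng.choice(n, size=n // 3, replace=False))
        mask = np.ones(n, dtype=bool)
        vc = VarianceComponents(1.0, 1.0)
        ebv, _, errors = fit_all_methods(gm, y, mask, core_idx, vc,
                                         methods=("gblup", "apy"))
        assert not errors
        assert metrics(ebv["apy"], ebv["gblup"]) >= 0.95


class TestRowsAndExport:
    def test_rows_stack_to_materialization(self, gm30):
        op = woodbury_inverse_markers(
            center(random_genotypes(np.random.default_rng(5), 20, 8)),
            theta=THETA)
        stacked = np.vstack([inverse_row(op, i) for i in range(20)])
        np.testing.assert_allclose(stacked, op.materialize(), atol=1e-12)

    def test_row_equals_column(self, gm30):
        r = rho(gm30)
        basis = core_svd(gm30, gm30.ids[:15], threshold=0.9)
        op = pcig_inverse(project_scores(gm30, basis), rho=r, theta=THETA)
        M = op.materialize()
        np.testing.assert_allclose(op.row(7), M[:, 7], atol=1e-12)

    def test_row_oracle(self, gm30):
        r = rho(gm30)
        basis = core_svd(gm30, gm30.ids[:15], threshold=0.9)
        op = pcig_inverse(project_scores(gm30, basis), rho=r, theta=THETA)
        dense = dense_inverse_of(op)
        assert np.abs(op.row(7) - dense[7]).max() <= 1e-9

    def test_row_index_range(self, gm30):
        op = qrig_inverse(gm30, gm30.ids[:5], rho=rho(gm30), theta=THETA)
        with pytest.raises(IndexError):
            op.row(30)

    def test_export_identity_operator(self, tmp_path):
        from svdgp.svd_reduction import ScoreMatrix
        sc = ScoreMatrix(C=np.zeros((3, 1)), chrom_labels=["1"],
                         block_sizes=[1])
        op = pcig_inverse(sc, rho=1.0, theta=0.5)  # inverse = 2 I
        path = tmp_path / "trip.txt"
        n = export_inverse(op, path, min_abs=0.0)
        lines = path.read_text().strip().splitlines()
        assert n == len(lines)
        diag = [ln for ln in lines if ln.split()[0] == ln.split()[1]]
        assert len(diag) == 3
        assert all(float(ln.split()[2]) == pytest.approx(2.0) for ln in diag)

    def test_export_roundtrip(self, tmp_path, gm30):
        r = rho(gm30)
        basis = core_svd(gm30, gm30.ids[:10], threshold=0.9)
        op = pcig_inverse(project_scores(gm30, basis), rho=r, theta=THETA)
        path = tmp_path / "trip.txt"
        export_inverse(op, path, min_abs=0.0)
        M = np.zeros((30, 30))
        for ln in path.read_text().splitlines():
            i, j, v = ln.split()
            i, j, v = int(i) - 1, int(j) - 1, float(v)
            M[i, j] = v
            M[j, i] = v
        np.testing.assert_allclose(M, op.materialize(), atol=1e-9)


class TestWeightedPcig:
    def _setup(self):
        rng = np.random.default_rng(41)
        gm = center(random_genotypes(rng, 25, 120))
        p = np.clip(gm.allele_freq, 0.02, 0.98)
        D = vanraden2_weights(p)
        basis = core_svd(gm, gm.ids[:15], threshold=0.95, by_chromosome=True)
        sc = project_scores(gm, basis)
        return gm, D, basis, sc

    def test_identity_weights_reduce_to_pcig(self):
        gm, _, basis, sc = self._setup()
        r = rho(gm)
        D1 = np.ones(gm.n_loci)
        op_w = weighted_pcig_inverse(sc, basis, D1, rho=r, theta=THETA)
        op_p = pcig_inverse(sc, rho=r, theta=THETA)
        assert np.abs(op_w.materialize() - op_p.materialize()).max() <= 1e-9

    def test_against_dense_oracle(self):
        gm, D, basis, sc = self._setup()
        r = rho(gm, D)
        op = weighted_pcig_inverse(sc, basis, D, rho=r, theta=THETA)
        dense = np.linalg.inv(op.approx_grm())
        assert np.abs(op.materialize() - dense).max() <= 1e-9

    def test_weighted_centered_matches_standardized_vanraden1(self):
        rng = np.random.default_rng(43)
        raw = random_genotypes(rng, 25, 120)
        from svdgp.genotype_io import drop_monomorphic
        raw = drop_monomorphic(raw)
        gm_c = center(raw)
        gm_s = standardize(raw)
        D = vanraden2_weights(gm_c.allele_freq)
        G_w = build_grm(gm_c, method="weighted", D=D).G
        G_s = (gm_s.dosages @ gm_s.dosages.T) / gm_s.n_loci
        np.testing.assert_allclose(G_w, G_s, atol=1e-10)

    def test_negative_weights_rejected(self):
        gm, D, basis, sc = self._setup()
        D = D.copy()
        D[0] = -1.0
        with pytest.raises(ValueError, match="positive"):
            weighted_pcig_inverse(sc, basis, D, rho=1.0, theta=THETA)
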