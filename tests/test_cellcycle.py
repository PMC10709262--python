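import numpy as np
import pytest

from conftest import standard_config, standard_design
from scstate._circstats import circular_correlation
from scstate.cellcycle import (
    STAGES,
    StageScores,
    assign_stages,
    default_profiles,
    fit_circular_phase,
    four_label,
    refine_assignments,
    score_stages,
)
from scstate.io_core import GeneSetCollection, LogExpressionMatrix
from scstate.qc import normalize_log
from scstate.synthetic_data import SECTOR, simulate


def _scores(values, cells=None):
    values = np.asarray(values, dtype=float)
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    return StageScores(cells, values, np.zeros(values.shape[0], dtype=bool))


class TestScoreStages:
    def _expr_and_sets(self):
        genes = [f"{s}_gene{i}" for s in STAGES for i in range(2)]
        sets = GeneSetCollection({s: [f"{s}_gene0", f"{s}_gene1"] for s in STAGES})
        return genes, sets

    def test_exclusive_expression_peaks_at_own_stage(self):
        genes, sets = self._expr_and_sets()
        values = np.zeros((10, 1))
        values[[genes.index("G2_gene0"), genes.index("G2_gene1")], 0] = 5.0
        expr = LogExpressionMatrix(genes, ["c1"], values)
        scores = score_stages(expr, sets)
        assert np.argmax(scores.values[0]) == STAGES.index("G2")

    def test_all_equal_raw_scores_degenerate(self):
        genes, sets = self._expr_and_sets()
        expr = LogExpressionMatrix(genes, ["c1"], np.full((10, 1), 2.0))
        scores = score_stages(expr, sets)
        assert scores.degenerate[0]
        np.testing.assert_array_equal(scores.values[0], 0.0)

    def test_missing_stage_set_errors(self):
        genes, _ = self._expr_and_sets()
        sets = GeneSetCollection({s: [f"{s}_gene0"] for s in STAGES[:4]})
        expr = LogExpressionMatrix(genes, ["c1"], np.zeros((10, 1)))
        with pytest.raises(ValueError, match="M.G1"):
            score_stages(expr, sets)

    def test_stage_with_no_matching_genes_errors(self):
        genes, _ = self._expr_and_sets()
        sets = GeneSetCollection({s: [f"{s}_gene0"] for s in STAGES[:4]}
                                 | {"M.G1": ["absent_gene"]})
        expr = LogExpressionMatrix(genes, ["c1"], np.zeros((10, 1)))
        with pytest.raises(ValueError, match="M.G1"):
            score_stages(expr, sets)

    def test_s_sector_cells_have_highest_s_score(self, sim1, cfg_std):
        # generator construction is the oracle
        counts, _, truth, stage_sets = sim1
        expr = normalize_log(counts, counts.cells, cfg_std)
        scores = score_stages(expr, stage_sets)
        s_lo, s_hi = SECTOR, 2 * SECTOR
        in_s = (truth.theta_true >= s_lo) & (truth.theta_true < s_hi)
        means = scores.values[in_s].mean(axis=0)
        assert np.argmax(means) == STAGES.index("S")


class TestAssignStages:
    def test_exact_profile_gives_correlation_one(self):
        profiles = default_profiles()
        scores = _scores(profiles[2:3])
        labels, corr = assign_stages(scores, profiles, cor_thr=0.2)
        assert labels[0] == STAGES[2]
        assert corr[0] == pytest.approx(1.0)

    def test_threshold_above_one_unassigns_all(self):
        scores = _scores(default_profiles())
        labels, _ = assign_stages(scores, default_profiles(), cor_thr=1.01)
        assert (labels == "unassigned").all()

    def test_peaked_vector_assigned_g1s(self):
        # brute-force oracle: all five correlations computed with np.corrcoef
        vec = np.array([2.0, -0.5, -0.5, -0.5, -0.5])
        profiles = default_profiles()
        expected = [np.corrcoef(vec, p)[0, 1] for p in profiles]
        assert int(np.argmax(expected)) == 0
        labels, corr = assign_stages(_scores(vec[None, :]), profiles, cor_thr=0.2)
        assert labels[0] == "G1.S"
        assert corr[0] == pytest.approx(max(expected))

    def test_zero_variance_vector_unassigned(self):
        labels, corr = assign_stages(_scores(np.zeros((1, 5))), default_profiles(), 0.2)
        assert labels[0] == "unassigned"
        assert np.isnan(corr[0])

    def test_raising_cor_thr_monotone(self, run1):
        scores = run1.scores
        counts = [
            (assign_stages(scores, default_profiles(), thr)[0] != "unassigned").sum()
            for thr in (0.0, 0.2, 0.5, 0.8, 0.95)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_permuting_cells_permutes_outputs(self, run1):
        scores = run1.scores
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(scores.cells))
        shuffled = StageScores([scores.cells[i] for i in perm],
                               scores.values[perm], scores.degenerate[perm])
        l1, c1 = assign_stages(scores, default_profiles(), 0.2)
        l2, c2 = assign_stages(shuffled, default_profiles(), 0.2)
        np.testing.assert_array_equal(l1[perm], l2)
        np.testing.assert_allclose(c1[perm], c2)


class TestRefineAssignments:
    def test_zero_iterations_is_plain_assignment(self, run1):
        scores = run1.scores
        l0, c0 = assign_stages(scores, default_profiles(), 0.2)
        l1, c1, _, n = refine_assignments(scores, cor_thr=0.2, refine_iter=0)
        assert n == 0
        np.testing.assert_array_equal(l0, l1)

    def test_blob_partition_recovered(self):
        # two tight blobs of score vectors; slightly perturbed initial profiles
        rng = np.random.default_rng(0)
        a = np.array([1.5, -0.5, -0.5, -0.3, -0.2])
        b = np.array([-0.4, -0.4, 1.6, -0.4, -0.4])
        vecs = np.vstack([a + rng.normal(0, 0.05, (30, 5)),
                          b + rng.normal(0, 0.05, (30, 5))])
        init = default_profiles() + rng.normal(0, 0.1, (5, 5))
        labels, _, _, n_iter = refine_assignments(_scores(vecs), init, 0.2, 200)
        assert n_iter <= 5
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[30]

    def test_fixed_point_is_stable(self, run1):
        scores = run1.scores
        labels, _, profiles, _ = refine_assignments(scores, cor_thr=0.2, refine_iter=200)
        again, _, _, n = refine_assignments(scores, profiles, 0.2, refine_iter=200)
        assert n <= 1
        np.testing.assert_array_equal(labels, again)

    def test_iteration_bound_enforced(self, run1):
        _, _, _, n = refine_assignments(run1.scores, cor_thr=0.2, refine_iter=3)
        assert n <= 3


class TestCircularPhase:
    def test_uniform_circle_recovered(self):
        # score vectors exactly on a circle in a 2-dim plane of score space
        # (orthonormal basis so the embedded circle stays a circle)
        n = 40
        ang = 2 * np.pi * np.arange(n) / n
        basis = np.array([[1.0, -1.0, 0.0, 0.0, 0.0],
                          [0.0, 0.0, 1.0, -1.0, 0.0]]) / np.sqrt(2)
        vecs = np.cos(ang)[:, None] * basis[0] + np.sin(ang)[:, None] * basis[1]
        labels = np.array([STAGES[int(a // SECTOR) % 5] for a in ang], dtype=object)
        theta = fit_circular_phase(_scores(vecs), labels)
        # uniformly spaced: all sorted angular gaps equal 2*pi/n
        gaps = np.diff(np.sort(theta))
        assert np.allclose(gaps, 2 * np.pi / n, atol=1e-8)
        # order-preserving: theta is a rotation of the input angles
        assert circular_correlation(theta, ang) > 0.999

    def test_reflection_invariance_after_anchoring(self, run1):
        scores = run1.scores
        reflected = StageScores(scores.cells, -scores.values, scores.degenerate)
        t1 = fit_circular_phase(scores, run1.stage_labels)
        t2 = fit_circular_phase(reflected, run1.stage_labels)
        # anchoring on stage order makes theta invariant to reflections
        assert circular_correlation(t1, t2) > 0.999

    def test_recovers_true_phase(self, run1, sim1, kept_idx1):
        truth = sim1[2]
        cc = circular_correlation(run1.theta, truth.theta_true[kept_idx1])
        assert cc >= 0.8

    def test_stage_means_in_cycle_order(self, run1):
        from scstate._circstats import circular_mean
        means = [circular_mean(run1.theta[run1.stage_labels == s]) for s in STAGES]
        assert means[0] < 0.5 or means[0] > 2 * np.pi - 0.5  # G1.S anchored near 0
        assert all(b > a for a, b in zip(means[1:], means[2:]))

    def test_all_degenerate_errors(self):
        s = StageScores(["a", "b", "c"], np.zeros((3, 5)), np.ones(3, dtype=bool))
        with pytest.raises(ValueError, match="non-degenerate"):
            fit_circular_phase(s, np.array(["G1.S"] * 3, dtype=object))


class TestStageAccuracy:
    def test_accuracy_at_least_090_on_standard_design(self, run1, sim1, kept_idx1):
        truth = sim1[2]
        stage_true = truth.stage_true()[kept_idx1]
        assigned = run1.stage_labels != "unassigned"
        acc = (run1.stage_labels[assigned] == stage_true[assigned]).mean()
        assert acc >= 0.90


def test_packaged_stage_genesets_cover_all_stages():
    from scstate.cellcycle import packaged_stage_genesets
    coll = packaged_stage_genesets()
    assert set(coll.names()) == set(STAGES)
    assert all(len(coll[s]) >= 5 for s in STAGES)


def test_four_label_mapping():
    five = np.array(["M.G1", "G1.S", "S", "G2", "G2.M", "unassigned"], dtype=object)
    np.testing.assert_array_equal(
        four_label(five),
        np.array(["G1", "G1/S", "S/G2", "S/G2", "G2/M", "unassigned"], dtype=object))
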