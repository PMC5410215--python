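import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tnbc_subtyper import (
    ConsensusMatrix,
    ExpressionMatrix,
    SimConfig,
    cdf_and_area,
    choose_k,
    consensus_matrix,
    delta_areas,
    filter_by_sd,
    final_assignments,
    generate_cohort,
    run_consensus,
)


def _matrix_from_points(points, probe_prefix="F"):
    """points: samples x features array -> ExpressionMatrix (features as probes)."""
    points = np.asarray(points, dtype=float)
    values = pd.DataFrame(
        points.T,
        index=[f"{probe_prefix}{i}" for i in range(points.shape[1])],
        columns=[f"s{j}" for j in range(points.shape[0])],
    )
    return ExpressionMatrix(values)


def _cm(M, ids=None):
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    return ConsensusMatrix(
        sample_ids=ids or [f"s{i}" for i in range(n)],
        M=M, I=np.full_like(M, 10.0), k=2, n_resamples=10,
        subsample_fraction=0.8, seed=0,
    )


class TestConsensusMatrix:
    def test_duplicated_points_give_binary_consensus(self):
        points = np.vstack([np.tile([0.0, 0.0], (10, 1)), np.tile([8.0, 8.0], (10, 1))])
        m = _matrix_from_points(points)
        cm = consensus_matrix(m, k=2, n_resamples=50, subsample_fraction=0.8, seed=0,
                              standardize=False)
        included = cm.I > 0
        within = np.zeros_like(cm.M, dtype=bool)
        within[:10, :10] = True
        within[10:, 10:] = True
        assert np.all(cm.M[within & included] == 1.0)
        assert np.all(cm.M[~within & included] == 0.0)

    def test_full_fraction_is_single_run_indicator(self):
        points = np.vstack([np.tile([0.0], (6, 1)), np.tile([9.0], (6, 1))])
        m = _matrix_from_points(points)
        cm1 = consensus_matrix(m, k=2, n_resamples=1, subsample_fraction=1.0, seed=0,
                               standardize=False)
        cm5 = consensus_matrix(m, k=2, n_resamples=5, subsample_fraction=1.0, seed=1,
                               standardize=False)
        assert set(np.unique(cm1.M)) <= {0.0, 1.0}
        # with no resampling variance the resample count is irrelevant
        np.testing.assert_array_equal(cm1.M, cm5.M)

    def test_entries_are_valid_ratios(self, tnbc_cohort):
        matrix, _ = tnbc_cohort
        sub = matrix.subset_samples(matrix.sample_ids[:40])
        cm = consensus_matrix(sub, k=3, n_resamples=30, seed=2)
        assert (cm.M >= 0).all() and (cm.M <= 1).all()
        assert (cm.M * cm.I <= cm.I).all()
        diag_included = np.diag(cm.I) > 0
        assert np.all(np.diag(cm.M)[diag_included] == 1.0)

    def test_truth_channel_block_structure_at_true_k(self):
        config = SimConfig(n_datasets=1, samples_per_dataset=60, n_probes=200,
                           n_subtypes=3, tnbc_only=True, batch_shift_sd=0.0, seed=5)
        matrix, truth = generate_cohort(config)
        filtered = filter_by_sd(matrix, 0.9).apply(matrix)
        cm = consensus_matrix(filtered, k=3, n_resamples=100, seed=5)
        labels = truth.subtype.to_numpy()
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        assert cm.M[same & off_diag].mean() > 0.9
        assert cm.M[~same].mean() < 0.1

    def test_k_larger_than_n_is_an_error(self, small_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            consensus_matrix(small_matrix, k=10, n_resamples=5)


class TestCdfArea:
    def test_all_zero_entries_give_area_one(self):
        _, area = cdf_and_area(_cm(np.eye(5)))
        assert area == pytest.approx(1.0)

    def test_two_step_cdf_area_equals_zero_fraction(self):
        M = np.ones((4, 4))
        M[0, 1] = M[1, 0] = M[2, 3] = M[3, 2] = 0.0  # 2 of 6 pairs at zero
        _, area = cdf_and_area(_cm(M))
        assert area == pytest.approx(2 / 6)

    def test_uniform_entries_give_area_half(self):
        rng = np.random.default_rng(0)
        n = 142  # ~10k upper-triangle entries
        M = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        M[iu] = rng.random(len(iu[0]))
        M = M + M.T
        np.fill_diagonal(M, 1.0)
        _, area = cdf_and_area(_cm(M))
        assert abs(area - 0.5) < 0.02

    def test_area_equals_one_minus_mean_entry(self):
        rng = np.random.default_rng(1)
        n = 30
        M = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        M[iu] = rng.random(len(iu[0]))
        M = M + M.T
        _, area = cdf_and_area(_cm(M))
        assert area == pytest.approx(1.0 - M[iu].mean(), rel=1e-9)


class TestDeltaAreas:
    def test_arithmetic(self):
        assert delta_areas({2: 0.4, 3: 0.6}) == {2: 0.4, 3: pytest.approx(0.5)}

    def test_constant_areas_give_zero_deltas(self):
        deltas = delta_areas({k: 0.7 for k in range(2, 7)})
        assert all(deltas[k] == 0.0 for k in range(3, 7))

    def test_recomputation_from_stored_areas(self, tnbc_cohort):
        matrix, _ = tnbc_cohort
        sub = matrix.subset_samples(matrix.sample_ids[:50])
        filtered = filter_by_sd(sub, 0.9).apply(sub)
        result = run_consensus(filtered, k_max=5, n_resamples=25, seed=0)
        recomputed = {2: result.areas[2]}
        for k in range(3, 6):
            recomputed[k] = (result.areas[k] - result.areas[k - 1]) / result.areas[k - 1]
        for k, v in result.deltas.items():
            assert v == pytest.approx(recomputed[k], rel=1e-12)

    def test_non_consecutive_k_is_an_error(self):
        with pytest.raises(ValueError, match="consecutive"):
            delta_areas({2: 0.4, 4: 0.6})


class TestChooseK:
    def test_rule_application(self):
        assert choose_k({2: 0.60, 3: 0.30, 4: 0.02, 5: 0.01}, threshold=0.05) == 3

    def test_all_above_threshold_returns_k_max(self, caplog):
        with caplog.at_level("WARNING"):
            assert choose_k({2: 0.6, 3: 0.3, 4: 0.2}, threshold=0.05) == 4
        assert "k_max" in caplog.text

    def test_k_max_below_three_is_an_error(self):
        with pytest.raises(ValueError):
            choose_k({2: 0.5})


class TestFinalAssignments:
    def test_block_diagonal_recovered_exactly(self):
        blocks = [3, 4, 5]
        n = sum(blocks)
        M = np.zeros((n, n))
        start = 0
        truth = []
        for b, size in enumerate(blocks):
            M[start:start + size, start:start + size] = 1.0
            truth += [b] * size
            start += size
        labels = final_assignments(_cm(M), k=3)
        assert adjusted_rand_score(truth, labels) == 1.0
        # renamed by decreasing size: C1 is the largest block
        assert (labels == "C1").sum() == 5

    def test_k_one_is_an_error(self):
        with pytest.raises(ValueError):
            final_assignments(_cm(np.eye(4)), k=1)

    def test_truth_channel_ari(self, tnbc_cohort):
        matrix, truth = tnbc_cohort
        filtered = filter_by_sd(matrix, 0.9).apply(matrix)
        cm = consensus_matrix(filtered, k=5, n_resamples=100, seed=3)
        labels = final_assignments(cm, k=5)
        ari = adjusted_rand_score(truth.subtype, labels.reindex(truth.subtype.index))
        assert ari >= 0.9


class TestPipelineInvariances:
    def test_area_invariant_to_sample_order_with_deterministic_base(self):
        points = np.vstack([
            np.tile([0.0, 1.0], (6, 1)),
            np.tile([6.0, 5.0], (6, 1)),
            np.tile([12.0, 0.0], (6, 1)),
        ])
        m = _matrix_from_points(points)
        perm = np.random.default_rng(0).permutation(m.n_samples)
        m_perm = m.subset_samples([m.sample_ids[i] for i in perm])
        areas = {}
        for name, mat in (("orig", m), ("perm", m_perm)):
            cm = consensus_matrix(mat, k=3, n_resamples=3, subsample_fraction=1.0,
                                  seed=0, standardize=False)
            _, areas[name] = cdf_and_area(cm)
        assert areas["orig"] == pytest.approx(areas["perm"], abs=1e-12)
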