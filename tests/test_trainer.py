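"""Training-loop, update-mechanism and variant-semantics tests."""

import numpy as np
import pytest

import assl
from assl import (
    ExpressionMatrix,
    LabeledPool,
    ModelState,
    PseudoLabelRecord,
    SampleStatus,
    Schedule,
    TrainerConfig,
    Variant,
    apply_update_mechanism,
    detect_flips,
    oracle_label,
    run_variant,
)


def make_pool(n_labeled=6, n_pool=4, seed=0, separation=0.0):
    """A tiny hand-checkable pool; `separation` pushes the two classes apart."""
    rng = np.random.default_rng(seed)
    n = n_labeled + n_pool
    X = rng.standard_normal((n, 3))
    truth = (np.arange(n) % 2).astype(int)
    X[:, 0] += separation * (2 * truth - 1)
    labeled = np.zeros(n, dtype=bool)
    labeled[:n_labeled] = True
    return LabeledPool.from_labels(ExpressionMatrix.from_array(X), truth, labeled, truth=truth)


class TestDetectFlips:
    def setup_method(self):
        # model: prob = sigmoid(x0), so x0 sign controls the implied label
        self.model = ModelState(0.0, np.array([1.0, 0.0]), 0.0)

    def _record(self, idx, label, selector="AL"):
        return PseudoLabelRecord(idx, selector, 1, 0.5, label)

    def test_crossing_the_boundary_flips(self):
        X = ExpressionMatrix.from_array(np.array([[-1.0, 0.0], [2.0, 0.0]]))
        recs = [self._record(0, 1), self._record(1, 1)]
        flips = detect_flips(self.model, recs, X)
        assert [f.sample_index for f in flips] == [0]  # prob ~0.27 but label 1

    def test_same_side_no_flip(self):
        X = ExpressionMatrix.from_array(np.array([[2.3, 0.0], [0.0, 1.0]]))
        recs = [self._record(0, 1)]  # prob ~0.91, label 1
        assert detect_flips(self.model, recs, X) == []

    def test_empty_records(self):
        X = ExpressionMatrix.from_array(np.zeros((2, 2)))
        assert detect_flips(self.model, [], X) == []

    def test_retired_records_ignored(self):
        X = ExpressionMatrix.from_array(np.array([[-1.0, 0.0], [0.0, 0.0]]))
        rec = self._record(0, 1)
        rec.retired = True
        assert detect_flips(self.model, [rec], X) == []


class TestUpdateMechanism:
    def test_ssl_flip_returns_to_pool(self):
        pool = make_pool(n_labeled=6, n_pool=4)
        i = pool.pool_indices[0]
        pool.status[i] = SampleStatus.PSEUDO_SSL
        pool.label[i] = 1.0
        rec = PseudoLabelRecord(int(i), "SSL", 1, 0.97, 1)
        before_pool = len(pool.pool_indices)
        before_train = len(pool.training_indices)
        apply_update_mechanism(pool, [rec])
        assert len(pool.pool_indices) == before_pool + 1
        assert len(pool.training_indices) == before_train - 1
        assert pool.status[i] == SampleStatus.UNLABELED
        assert np.isnan(pool.label[i])
        assert rec.retired

    def test_al_flip_revises_label_in_place(self):
        pool = make_pool()
        i = pool.pool_indices[0]
        pool.status[i] = SampleStatus.PSEUDO_AL
        pool.label[i] = 1.0
        rec = PseudoLabelRecord(int(i), "AL", 1, 0.52, 1)
        sizes = (len(pool.pool_indices), len(pool.training_indices))
        apply_update_mechanism(pool, [rec])
        assert (len(pool.pool_indices), len(pool.training_indices)) == sizes
        assert pool.label[i] == 0.0
        assert rec.current_label == 0
        assert rec.revision_count == 1
        assert not rec.retired

    def test_no_flips_is_a_noop(self):
        pool = make_pool()
        status, label = pool.status.copy(), pool.label.copy()
        apply_update_mechanism(pool, [])
        assert np.array_equal(pool.status, status)
        assert np.array_equal(pool.label, label, equal_nan=True)

    def test_flip_on_originally_labeled_sample_rejected(self):
        pool = make_pool()
        rec = PseudoLabelRecord(0, "SSL", 1, 0.9, 1)  # sample 0 is LABELED
        with pytest.raises(ValueError):
            apply_update_mechanism(pool, [rec])


class TestOracleLabel:
    def test_exhausted_budget_issues_nothing(self):
        pool = make_pool()
        idx = pool.pool_indices
        chosen, labels, budget = oracle_label(pool, idx, np.full(len(idx), 0.5), 0)
        assert chosen.size == 0 and labels.size == 0 and budget == 0

    def test_priority_closest_to_half(self):
        pool = make_pool(n_labeled=6, n_pool=4)
        idx = pool.pool_indices[:3]
        probs = np.array([0.50, 0.52, 0.48])
        chosen, labels, budget = oracle_label(pool, idx, probs, 2)
        assert set(chosen) == {idx[0], idx[2]}
        assert budget == 0
        assert np.array_equal(labels, pool.truth[chosen])

    def test_ample_budget_labels_all_with_truth(self):
        pool = make_pool()
        idx = pool.pool_indices
        chosen, labels, budget = oracle_label(pool, idx, np.linspace(0.4, 0.6, len(idx)), 100)
        assert set(chosen) == set(idx)
        assert np.array_equal(labels, pool.truth[chosen])
        assert budget == 100 - len(idx)

    def test_missing_truth_raises(self):
        pool = make_pool()
        pool.truth = None
        with pytest.raises(ValueError):
            oracle_label(pool, pool.pool_indices, np.full(4, 0.5), 5)


class TestRunVariant:
    def test_logistic_baseline_fits_once_without_selection(self):
        pool = make_pool(n_labeled=10, n_pool=6, separation=1.5)
        model, log, recs = run_variant(pool, TrainerConfig(variant="logistic", penalty=1.0))
        assert len(log) == 1
        assert log.rows[0].n_ssl_selected == 0 and log.rows[0].n_al_selected == 0
        assert recs == []
        assert (pool.status == SampleStatus.UNLABELED).sum() == 6  # pool untouched

    def test_confident_pool_drains_in_one_iteration(self):
        """With all pool samples far on one side, SSL takes the lot at t=1."""
        rng = np.random.default_rng(1)
        n_lab = 20
        X = rng.standard_normal((n_lab + 5, 2))
        truth = (np.arange(n_lab + 5) % 2).astype(int)
        X[:, 0] = np.where(truth == 1, 5.0, -5.0) + 0.1 * X[:, 0]
        truth[n_lab:] = 1
        X[n_lab:, 0] = 5.0  # pool samples deep in class-1 territory
        labeled = np.zeros(n_lab + 5, dtype=bool)
        labeled[:n_lab] = True
        pool = LabeledPool.from_labels(
            ExpressionMatrix.from_array(X), truth, labeled, truth=truth
        )
        model, log, recs = run_variant(
            pool, TrainerConfig(variant="auto-assl-b", penalty=0.05, schedule=Schedule(0.1, 10))
        )
        assert len(log) == 1  # early termination: pool emptied at t=1
        assert log.rows[0].n_ssl_selected == 5
        assert log.rows[0].pool_size == 0
        assert all(r.selector == "SSL" and r.current_label == 1 for r in recs)

    def test_update_mechanism_inactive_without_flips(self):
        """A and B coincide when no pseudo-label ever flips (separable data)."""
        pool_a = make_pool(n_labeled=12, n_pool=8, separation=3.0)
        pool_b = pool_a.copy()
        m_a, _, _ = run_variant(pool_a, TrainerConfig(variant="auto-assl-a", penalty=0.5, seed=1))
        m_b, log_b, _ = run_variant(pool_b, TrainerConfig(variant="auto-assl-b", penalty=0.5, seed=1))
        assert sum(r.n_flips for r in log_b.rows) == 0
        assert m_a.intercept == pytest.approx(m_b.intercept, abs=1e-10)
        assert np.allclose(m_a.coefficients, m_b.coefficients, atol=1e-10)

    @pytest.mark.parametrize("variant", [v.value for v in Variant if v is not Variant.LOGISTIC])
    def test_conservation_and_label_provenance(self, variant, small_dataset):
        """Training set + pool always partition the samples; original labels survive."""
        pool = small_dataset.to_pool()
        n = pool.n
        init_labeled = pool.status == SampleStatus.LABELED
        init_labels = pool.label.copy()
        model, log, recs = run_variant(
            pool, TrainerConfig(variant=variant, penalty=2.0, seed=3)
        )
        for row in log.rows:
            assert row.train_size + row.pool_size == n
        assert np.array_equal(pool.status[init_labeled], np.full(init_labeled.sum(), SampleStatus.LABELED))
        assert np.array_equal(pool.label[init_labeled], init_labels[init_labeled])

    def test_self_labeling_variants_drain_pool_by_final_iteration(self, small_dataset):
        for variant in ("ssl-lo", "auto-assl-a", "auto-assl-b"):
            pool = small_dataset.to_pool()
            _, log, _ = run_variant(pool, TrainerConfig(variant=variant, penalty=2.0, seed=3))
            if variant != "ssl-lo":  # SSL-only never covers the middle band
                assert len(pool.pool_indices) == 0

    def test_oracle_budget_respected(self, small_dataset):
        frac = 0.4
        pool = small_dataset.to_pool()
        n2 = len(pool.pool_indices)
        _, log, _ = run_variant(
            pool,
            TrainerConfig(variant="al-lo", penalty=2.0, seed=3, oracle_budget_fraction=frac),
        )
        n_oracle = (pool.status == SampleStatus.ORACLE_LABELED).sum()
        assert n_oracle <= round(frac * n2)

    def test_degenerate_labeled_set_raises(self):
        pool = make_pool()
        pool.label[pool.status == SampleStatus.LABELED] = 1.0  # one class only
        with pytest.raises(ValueError):
            run_variant(pool, TrainerConfig(variant="logistic", penalty=1.0))

    def test_deterministic_given_seed(self, small_dataset):
        results = []
        for _ in range(2):
            pool = small_dataset.to_pool()
            m, log, _ = run_variant(pool, TrainerConfig(variant="auto-assl-b", seed=9))
            results.append((m.intercept, tuple(m.coefficients), log.penalty))
        assert results[0] == results[1]


class TestTrainerConfig:
    def test_update_mechanism_tied_to_variant(self):
        assert TrainerConfig(variant="auto-assl-b").update_mechanism
        for v in ("logistic", "al-lo", "ssl-lo", "assl-lo", "auto-assl-a"):
            assert not TrainerConfig(variant=v).update_mechanism

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            TrainerConfig(variant="bogus")
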