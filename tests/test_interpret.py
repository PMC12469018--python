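import numpy as np
import pandas as pd
import pytest

from neurolatent.core_io import NetworkMap, default_network_map
from neurolatent.finetune import LatentMatrix
from neurolatent.interpret import (
    MappingMatrix,
    NetworkImportance,
    component_to_latent_mapping,
    cross_cohort_consistency,
    fit_probe,
    network_importance,
    subject_mapping,
)
from neurolatent.model import AttentionRecord, HierarchicalAttentionNet, ModelConfig


def loop_oracle(w_enc, w_main, alpha_win, alpha_global):
    """Literal double-loop accumulation from the attribution pseudocode."""
    k_n, t_n = alpha_win.shape
    m = np.zeros((w_main.shape[0], w_enc.shape[1]))
    for k in range(k_n):
        w_main_scaled = alpha_global[k] * w_main
        for t in range(t_n):
            w_enc_scaled = alpha_win[k, t] * w_enc
            m += w_main_scaled @ w_enc_scaled
    return m


class TestMapping:
    def test_single_term_sum_is_plain_product(self, rng):
        w_enc = rng.standard_normal((4, 3))
        w_main = rng.standard_normal((5, 4))
        m = component_to_latent_mapping(w_enc, w_main, np.array([[1.0]]), np.array([1.0]))
        np.testing.assert_allclose(m.M, w_main @ w_enc, atol=1e-12)

    def test_vectorized_equals_loop_oracle_on_100_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            d_main, d_enc, c = rng.integers(2, 7, size=3)
            k, t = rng.integers(1, 5, size=2)
            w_enc = rng.standard_normal((d_enc, c))
            w_main = rng.standard_normal((d_main, d_enc))
            aw = rng.standard_normal((k, t))          # arbitrary, not normalized
            ag = rng.standard_normal(k)
            m = component_to_latent_mapping(w_enc, w_main, aw, ag).M
            np.testing.assert_allclose(m, loop_oracle(w_enc, w_main, aw, ag),
                                       atol=1e-10)

    def test_probability_attentions_collapse_to_weight_product(self, rng):
        w_enc = rng.standard_normal((6, 5))
        w_main = rng.standard_normal((4, 6))
        aw = rng.dirichlet(np.ones(10), size=3)      # rows sum to 1
        ag = rng.dirichlet(np.ones(3))
        m = component_to_latent_mapping(w_enc, w_main, aw, ag).M
        np.testing.assert_allclose(m, w_main @ w_enc, atol=1e-10)

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="conformable"):
            component_to_latent_mapping(rng.standard_normal((3, 2)),
                                        rng.standard_normal((4, 5)),
                                        np.ones((1, 1)), np.ones(1))
        with pytest.raises(ValueError, match="windows"):
            component_to_latent_mapping(rng.standard_normal((5, 2)),
                                        rng.standard_normal((4, 5)),
                                        np.ones((2, 3)), np.ones(3))


class TestSubjectMapping:
    @pytest.fixture()
    def model(self, tiny_model_cfg):
        return HierarchicalAttentionNet(tiny_model_cfg, seed=3)

    def _record(self, rng, k=2, t=4):
        aw = rng.dirichlet(np.ones(t), size=k)
        ag = rng.dirichlet(np.ones(k))
        return AttentionRecord(aw, ag, np.abs(rng.standard_normal((k, t))),
                               np.abs(rng.standard_normal(k)))

    def test_single_subject_equals_its_own_mapping(self, model, rng):
        rec = self._record(rng)
        single = subject_mapping(model, [rec])
        assert single.M.shape == (model.cfg.D_main, model.cfg.C)

    def test_duplicated_subject_leaves_mean_unchanged(self, model, rng):
        rec = self._record(rng)
        a = subject_mapping(model, [rec], mapping="score")
        b = subject_mapping(model, [rec, rec], mapping="score")
        np.testing.assert_allclose(a.M, b.M, atol=1e-12)

    def test_empty_subject_set_errors(self, model):
        with pytest.raises(ValueError, match="empty"):
            subject_mapping(model, [])

    def test_default_scale_mapping_shape(self):
        model = HierarchicalAttentionNet(ModelConfig(), seed=0)
        rng = np.random.default_rng(0)
        rec = AttentionRecord(rng.dirichlet(np.ones(20), size=7),
                              rng.dirichlet(np.ones(7)),
                              np.zeros((7, 20)), np.zeros(7))
        assert subject_mapping(model, [rec]).M.shape == (200, 53)


class TestProbe:
    def test_planted_patient_feature_gets_largest_positive_coefficient(self, rng):
        """Positive class is the patient group: a feature tracking patient
        status must receive the largest positive coefficient."""
        n = 120
        labels = np.tile([0, 1], n // 2)          # 0 = patient
        x = rng.standard_normal((n, 12))
        x[:, 0] = (labels == 0) + 0.3 * rng.standard_normal(n)
        probe = fit_probe(LatentMatrix(x, labels, {}), seed=0)
        assert np.argmax(np.abs(probe.beta)) == 0
        assert probe.beta[0] > 0
        assert probe.probe_auc > 0.9

    def test_flipping_positive_class_negates_coefficients(self, rng):
        x = rng.standard_normal((60, 6))
        labels = np.tile([0, 1], 30)
        x[:, 2] += labels
        a = fit_probe(LatentMatrix(x, labels, {}), positive_class="patient", seed=1)
        b = fit_probe(LatentMatrix(x, labels, {}), positive_class="control", seed=1)
        np.testing.assert_allclose(a.beta, -b.beta, atol=1e-8)

    def test_null_latents_probe_near_chance(self, rng):
        # cross-validated AUC on label-independent data is noisy (and slightly
        # pessimistic) per draw; the mean over draws must sit near chance
        aucs, max_beta = [], 0.0
        labels = np.tile([0, 1], 100)
        for seed in range(6):
            x = rng.standard_normal((200, 10))
            probe = fit_probe(LatentMatrix(x, labels, {}), seed=seed)
            aucs.append(probe.probe_auc)
            max_beta = max(max_beta, np.abs(probe.beta).max())
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.08)
        assert max_beta < 0.5

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            fit_probe(LatentMatrix(rng.standard_normal((10, 3)), np.ones(10), {}))

    def test_fold_betas_shape(self, rng):
        x = rng.standard_normal((50, 4))
        labels = np.tile([0, 1], 25)
        probe = fit_probe(LatentMatrix(x, labels, {}), seed=0)
        assert probe.fold_betas.shape == (5, 4)
        np.testing.assert_allclose(probe.beta, probe.fold_betas.mean(axis=0))


class TestNetworkImportance:
    def _probe(self, beta, n_folds=3):
        from neurolatent.interpret import ProbeResult
        beta = np.asarray(beta, dtype=float)
        return ProbeResult(beta=beta, intercept=0.0,
                           fold_betas=np.tile(beta, (n_folds, 1)),
                           probe_auc=0.5, positive_class="patient")

    def test_unit_beta_all_ones_mapping_gives_unit_scores(self, network_map):
        probe = self._probe(np.eye(10)[0])
        mapping = MappingMatrix(np.ones((10, 53)))
        imp = network_importance(probe, mapping, network_map)
        np.testing.assert_allclose(imp.per_component, np.ones(53))
        assert all(imp.scores == 1.0)

    def test_zero_mapping_column_contributes_nothing(self, network_map):
        probe = self._probe(np.ones(4))
        m = np.ones((4, 53))
        m[:, 7] = 0.0
        imp = network_importance(probe, MappingMatrix(m), network_map)
        assert imp.per_component[7] == 0.0

    def test_component_count_mismatch_errors(self, network_map):
        probe = self._probe(np.ones(4))
        with pytest.raises(ValueError, match="components"):
            network_importance(probe, MappingMatrix(np.ones((4, 10))), network_map)

    def test_equivariance_under_network_relabeling(self, network_map, rng):
        probe = self._probe(rng.standard_normal(6))
        mapping = MappingMatrix(rng.standard_normal((6, 53)))
        imp = network_importance(probe, mapping, network_map)
        # swap two network labels wholesale
        swapped = {
            c: {"Auditory": "Visual", "Visual": "Auditory"}.get(n, n)
            for c, n in network_map.assignment.items()
        }
        imp_sw = network_importance(probe, mapping, NetworkMap(swapped))
        assert imp_sw.scores["Visual"] == pytest.approx(imp.scores["Auditory"])
        assert imp_sw.scores["Auditory"] == pytest.approx(imp.scores["Visual"])


class TestConsistency:
    def _imp(self, values, names=("A", "B", "C")):
        s = pd.Series(values, index=list(names))
        return NetworkImportance(s, s * 0, np.zeros(3))

    def test_identical_and_negated_vectors(self):
        a = self._imp([1.0, -2.0, 0.5])
        assert cross_cohort_consistency(a, a) == pytest.approx(1.0)
        b = self._imp([-1.0, 2.0, -0.5])
        assert cross_cohort_consistency(a, b) == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        a = self._imp([1.0, 1.0, 1.0])
        b = self._imp([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero-variance"):
            cross_cohort_consistency(a, b)

    def test_mismatched_network_order_errors(self):
        a = self._imp([1.0, 2.0, 3.0], names=("A", "B", "C"))
        b = self._imp([1.0, 2.0, 3.0], names=("C", "B", "A"))
        with pytest.raises(ValueError, match="differ"):
            cross_cohort_consistency(a, b)


def test_feature_mask_restricts_probe(rng):
    x = rng.standard_normal((80, 8))
    labels = np.tile([0, 1], 40)
    x[:, 3] += (labels == 0) * 1.5
    mask = np.zeros(8, dtype=bool)
    mask[[3, 5]] = True
    probe = fit_probe(LatentMatrix(x, labels, {}), feature_mask=mask, seed=0)
    assert probe.beta.shape == (8,)
    assert np.all(probe.beta[~mask] == 0)
    assert probe.beta[3] > 0
    with pytest.raises(ValueError, match="excludes every"):
        fit_probe(LatentMatrix(x, labels, {}), feature_mask=np.zeros(8, bool))
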