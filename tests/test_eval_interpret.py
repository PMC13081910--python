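"""Exact metrics vs brute-force oracles; interpretability invariants."""

import numpy as np
import pytest

from epigat.eval_interpret import (PredictionResult, auroc,
                                   attention_interaction_matrix,
                                   evaluate_complexwise, exact_aupr,
                                   fused_mask_profile,
                                   ground_truth_interaction_matrix,
                                   interface_composition, pr_curve,
                                   predicted_interaction_matrix, AA_INDEX)
from epigat.structure_io import ComplexStructure, Residue


def brute_force_aupr(p, y):
    """Exhaustive threshold enumeration over distinct scores."""
    pts = []
    for t in sorted(set(p), reverse=True):
        sel = p >= t
        tp = int((y[sel] == 1).sum())
        fp = int((y[sel] == 0).sum())
        pts.append((tp / y.sum(), tp / (tp + fp)))
    area, prev_r = 0.0, 0.0
    for r, prec in pts:
        area += prec * (r - prev_r)
        prev_r = r
    return area


def brute_force_auroc(p, y):
    pos, neg = p[y == 1], p[y == 0]
    wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


class TestExactAUPR:
    def test_perfect_ranking(self):
        assert exact_aupr([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_constant_scores_give_base_rate(self):
        y = np.array([1, 0, 0, 0, 1])
        assert exact_aupr(np.full(5, 0.5), y) == pytest.approx(0.4)

    def test_hand_case_matches_exhaustive_enumeration(self):
        p = np.array([0.9, 0.8, 0.8, 0.7, 0.6, 0.5, 0.5, 0.4, 0.3, 0.2, 0.2, 0.1])
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0, 0, 1, 0, 0])
        assert exact_aupr(p, y) == pytest.approx(brute_force_aupr(p, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 500))
        y = (rng.random(n) < 0.2).astype(int)
        y[0], y[1] = 1, 0
        p = np.round(rng.random(n), 2)  # rounding forces ties
        assert exact_aupr(p, y) == pytest.approx(brute_force_aupr(p, y), abs=1e-12)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            exact_aupr([0.1, 0.2], [1, 1])

    def test_valid_mask_is_applied(self):
        p = np.array([0.9, 0.1, 0.5])
        y = np.array([1, 0, 1])
        v = np.array([True, True, False])
        assert exact_aupr(p, y, v) == exact_aupr(p[:2], y[:2])


class TestAUROC:
    def test_perfect_and_constant(self):
        assert auroc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0
        assert auroc(np.full(6, 0.3), [1, 0, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_hand_case_matches_pair_counting(self):
        rng = np.random.default_rng(0)
        p = np.round(rng.random(10), 1)
        y = np.array([1, 0, 1, 0, 0, 1, 0, 0, 1, 0])
        assert auroc(p, y) == pytest.approx(brute_force_auroc(p, y), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        p = rng.random(200)
        y = (rng.random(200) < 0.3).astype(int)
        y[0], y[1] = 1, 0
        assert auroc(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_permuted_scores_concentrate_at_half(self):
        rng = np.random.default_rng(2)
        y = np.zeros(400, int)
        y[:80] = 1
        vals = []
        for _ in range(50):
            vals.append(auroc(rng.permutation(400) / 400.0, y))
        # null AUROC has std ~ sqrt((n+1)/(12*npos*nneg))
        sd = np.sqrt((400 + 1) / (12 * 80 * 320))
        assert abs(np.mean(vals) - 0.5) < 3 * sd / np.sqrt(50)


class TestPropertyBased:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.tuples(st.integers(0, 100), st.booleans()),
                    min_size=4, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_metrics_match_brute_force_on_arbitrary_score_sets(self, raw):
        p = np.array([r[0] / 100.0 for r in raw])
        y = np.array([int(r[1]) for r in raw])
        if y.sum() in (0, len(y)):
            y[0], y[1] = 1, 0
        assert exact_aupr(p, y) == pytest.approx(brute_force_aupr(p, y), abs=1e-12)
        assert auroc(p, y) == pytest.approx(brute_force_auroc(p, y), abs=1e-12)


class TestPRCurve:
    def test_recall_nondecreasing_and_area_consistent(self):
        rng = np.random.default_rng(3)
        p = rng.random(100)
        y = (rng.random(100) < 0.3).astype(int)
        y[0], y[1] = 1, 0
        curve = pr_curve(p, y)
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert 0.0 <= exact_aupr(p, y) <= 1.0


def _pred(rng, L=30, pi=0.25, cid="c1"):
    itf = (rng.random(L) < pi).astype(int)
    itf[0], itf[1] = 1, 0
    side = np.array(["antibody"] * (L // 2) + ["antigen"] * (L - L // 2), dtype=object)
    types = np.array(list("ACDEFGHIKLMNPQRSTVWY" * 3))[:L].astype(object)
    return PredictionResult(cid, rng.random(L), side, np.ones(L, bool), itf,
                            restypes=types)


class TestEvaluateComplexwise:
    def test_perfect_predictions_score_one(self):
        rng = np.random.default_rng(0)
        pr = _pred(rng)
        pr.p = pr.itf.astype(float)
        rep = evaluate_complexwise([pr])
        for key in ("overall", "paratope", "epitope"):
            assert rep[key]["aupr"] == 1.0 and rep[key]["auroc"] == 1.0

    def test_degenerate_side_reports_none_not_exception(self):
        rng = np.random.default_rng(1)
        pr = _pred(rng)
        pr.itf[pr.side == "antigen"] = 0  # no epitopes anywhere
        pr.itf[0] = 1
        rep = evaluate_complexwise([pr])
        assert rep["epitope"]["aupr"] is None
        assert rep["overall"]["aupr"] is not None

    def test_pooled_metric_equals_concatenation_oracle(self):
        rng = np.random.default_rng(2)
        preds = [_pred(rng, cid=f"c{i}") for i in range(3)]
        rep = evaluate_complexwise(preds)
        p = np.concatenate([pr.p for pr in preds])
        y = np.concatenate([pr.itf for pr in preds])
        assert rep["overall"]["aupr"] == pytest.approx(exact_aupr(p, y))


class TestMaskProfile:
    def test_fused_is_mean_over_layers(self):
        masks = {"a": np.array([[0.2, 0.6]]), "b": np.array([[0.8, 0.2]])}
        prof = fused_mask_profile(masks)
        np.testing.assert_allclose(prof.fused, [0.5, 0.4])

    def test_values_strictly_inside_unit_interval(self, tiny_cfg, tiny_batches):
        from epigat.mga_model import MaskedGraphAttentionNet

        model = MaskedGraphAttentionNet(tiny_cfg, seed=0)
        fwd = model.forward(tiny_batches[0])
        prof = fused_mask_profile(fwd.dym_masks)
        assert np.all((prof.fused > 0) & (prof.fused < 1))


def _single_contact_complex():
    def res(cid, ordinal, aa, pos):
        return Residue(cid, ordinal, aa, ["CA"], np.array([pos], dtype=float),
                       np.ones(1, dtype=bool))
    return ComplexStructure(chains=[
        ("heavy", [res("H", 0, "Y", [0, 0, 0]), res("H", 1, "A", [40, 0, 0])]),
        ("antigen", [res("A", 0, "N", [4.0, 0, 0]), res("A", 1, "G", [80, 0, 0])]),
    ])


class TestInteractionMatrices:
    def test_single_contact_yields_single_unit_entry(self):
        mat = ground_truth_interaction_matrix([_single_contact_complex()], 4.5)
        expect = np.zeros((20, 20))
        expect[AA_INDEX["Y"], AA_INDEX["N"]] = 1.0
        np.testing.assert_allclose(mat.matrix, expect)

    def test_uniform_probabilities_reduce_to_type_pair_counts(self):
        rng = np.random.default_rng(4)
        pr = _pred(rng)
        pr.p = np.full(len(pr.p), 0.4)
        mat = predicted_interaction_matrix([pr]).matrix
        counts = np.zeros((20, 20))
        ab = pr.valid & (pr.side == "antibody")
        ag = pr.valid & (pr.side == "antigen")
        for ta in pr.restypes[ab]:
            for tg in pr.restypes[ag]:
                counts[AA_INDEX[ta], AA_INDEX[tg]] += 1
        np.testing.assert_allclose(mat, counts / counts.sum(), atol=1e-12)

    def test_matrices_normalize_to_one(self):
        rng = np.random.default_rng(5)
        pr = _pred(rng)
        attn = rng.random((4, len(pr.p), len(pr.p)))
        for m in (predicted_interaction_matrix([pr]),
                  attention_interaction_matrix([pr], [attn]),
                  ground_truth_interaction_matrix([_single_contact_complex()])):
            assert m.matrix.min() >= 0
            assert m.matrix.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_accumulation_warns_and_stays_zero(self):
        def res(cid, ordinal, aa, pos):
            return Residue(cid, ordinal, aa, ["CA"], np.array([pos], dtype=float),
                           np.ones(1, dtype=bool))
        cx = ComplexStructure(chains=[
            ("heavy", [res("H", 0, "Y", [0, 0, 0])]),
            ("antigen", [res("A", 0, "N", [50, 0, 0])])])
        with pytest.warns(UserWarning):
            mat = ground_truth_interaction_matrix([cx], 4.5)
        assert mat.matrix.sum() == 0.0


class TestComposition:
    def test_single_positive_residue_is_indicator(self):
        rng = np.random.default_rng(6)
        pr = _pred(rng)
        pr.itf[:] = 0
        idx = np.where(pr.restypes == "S")[0][0]
        pr.itf[idx] = 1
        vec = interface_composition([pr], "ground_truth")
        expect = np.zeros(20)
        expect[AA_INDEX["S"]] = 1.0
        np.testing.assert_allclose(vec, expect)

    def test_uniform_predictions_reduce_to_global(self):
        rng = np.random.default_rng(7)
        pr = _pred(rng)
        pr.p = np.full(len(pr.p), 0.3)
        np.testing.assert_allclose(interface_composition([pr], "predicted"),
                                   interface_composition([pr], "global"),
                                   atol=1e-12)

    def test_vectors_sum_to_one(self):
        rng = np.random.default_rng(8)
        pr = _pred(rng)
        for src in ("ground_truth", "predicted", "global"):
            assert interface_composition([pr], src).sum() == pytest.approx(1.0)
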