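"""Binding model: flanks, kernels, multi-task structure, prediction."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from _oracles import wd_kernel_bruteforce
from mirclash.binding import (BindingExample, BindingModel, BindingTrainConfig,
                              CombinedScorer, FlankPair, PositionalContext,
                              combine_scores, combined_kernel, default_beta,
                              extract_flanks, gene_level_score,
                              make_binding_examples, multitask_kernel,
                              positional_context, positional_kernel,
                              predict_binding, train_binding, wd_kernel)
from mirclash.io import InputError, UtrRecord
from mirclash.trainset import SeedMatch


def _utr(seq, ends=None, tid="u"):
    return UtrRecord(tid, seq, ends or (len(seq),))


class TestFlanks:
    def test_interior_match_is_plain_slicing(self):
        seq = "".join("ACGU"[i % 4] for i in range(100))
        utr = _utr(seq)
        match = SeedMatch("u", 40, 46, "f", 0, 45)
        fp = extract_flanks(utr, match)
        assert fp.upstream == seq[10:40]
        assert fp.downstream == seq[46:76]

    def test_boundary_truncation_pads(self):
        utr = _utr("ACGUACGUACGUACGUACGUACGUACGUACGUACGUACGU")
        match = SeedMatch("u", 3, 9, "f", 0, 8)
        fp = extract_flanks(utr, match)
        assert fp.upstream == "." * 27 + utr.sequence[:3]
        assert len(fp.downstream) == 30

    def test_downstream_position_zero_faces_mirna_nt1(self):
        # the base immediately 3' of the seed match is opposite miRNA nt 1
        seq = "C" * 40 + "UACCUC" + "A" + "G" * 40
        fp = extract_flanks(_utr(seq), SeedMatch("u", 40, 46, "f", 0, 45))
        assert fp.downstream[0] == "A"
        assert fp.upstream[-1] == "C"   # nearest-seed upstream base (nt 8 side)


class TestPositionalContext:
    def test_distances_from_anchor(self):
        utr = _utr("A" * 400, ends=(150, 400))
        c = positional_context(utr, 100)
        assert (c.d_stop, c.d_next_end, c.d_prev_end) == (100, 50, None)
        c2 = positional_context(utr, 200)
        assert (c2.d_stop, c2.d_next_end, c2.d_prev_end) == (200, 200, 50)

    def test_identity_gives_one(self):
        c = PositionalContext(10, 20, 5)
        assert positional_kernel(c, c, gamma=1.0) == pytest.approx(1.0)

    def test_gamma_to_zero_limit(self):
        c1 = PositionalContext(0, 3000, None)
        c2 = PositionalContext(9000, 1, 4)
        assert positional_kernel(c1, c2, gamma=1e-12) == pytest.approx(1.0)

    def test_unit_distance_value(self):
        # transformed vectors differ by exactly 1 in the first component
        c1 = PositionalContext(0, 0, 0)
        c2 = PositionalContext(9, 0, 0)    # log10(1 + 9) = 1
        assert positional_kernel(c1, c2, gamma=0.5) \
            == pytest.approx(np.exp(-0.5))

    def test_gamma_must_be_positive(self):
        with pytest.raises(InputError):
            positional_kernel(PositionalContext(0, 0, 0),
                              PositionalContext(0, 0, 0), gamma=0.0)


class TestWDKernel:
    def test_self_match_closed_form(self):
        seq = "ACGU" * 7 + "AC"   # length 30, no pads
        beta = default_beta(6)
        expected = sum(beta[k - 1] * (31 - k) for k in range(1, 7))
        assert wd_kernel(seq, seq) == pytest.approx(expected)

    def test_fully_mismatched_is_zero(self):
        assert wd_kernel("A" * 30, "C" * 30) == 0.0

    def test_matches_bruteforce_feature_expansion(self):
        rng = np.random.default_rng(11)
        beta = default_beta(3)
        for _ in range(25):
            a = "".join(rng.choice(list("ACGU"), 12))
            z = "".join(rng.choice(list("ACGU"), 12))
            assert wd_kernel(a, z, degree=3, beta=beta) \
                == pytest.approx(wd_kernel_bruteforce(a, z, 3, beta))

    def test_pads_never_match(self):
        assert wd_kernel("." * 30, "." * 30) == 0.0
        a = "." * 29 + "A"
        assert wd_kernel(a, a) == pytest.approx(default_beta(6)[0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            wd_kernel("ACGU", "ACG")


def _random_examples(n, seed=0, tasks=("t0",)):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        up = "".join(rng.choice(list("ACGU"), 30))
        down = "".join(rng.choice(list("ACGU"), 30))
        ctx = PositionalContext(int(rng.integers(0, 2000)),
                                int(rng.integers(0, 500)),
                                None if rng.random() < 0.3
                                else int(rng.integers(0, 500)))
        out.append(BindingExample(FlankPair(up, down), ctx,
                                 tasks[i % len(tasks)],
                                 1 if i % 2 == 0 else -1, f"e{i}"))
    return out


class TestCombinedKernel:
    def test_raw_diagonal_is_sum_of_self_matches(self):
        examples = _random_examples(10)
        km = combined_kernel(examples, normalize=False)
        for i, e in enumerate(examples):
            expected = wd_kernel(e.flanks.upstream, e.flanks.upstream) \
                + wd_kernel(e.flanks.downstream, e.flanks.downstream) + 1.0
            assert km.matrix[i, i] == pytest.approx(expected)

    def test_component_tags_recoverable(self):
        km = combined_kernel(_random_examples(6))
        assert set(km.tags) == {"wd_up", "wd_down", "positional"}
        assert np.allclose(sum(km.components.values()), km.matrix)

    def test_symmetric_psd(self):
        km = combined_kernel(_random_examples(60, seed=3))
        assert np.allclose(km.matrix, km.matrix.T)
        assert np.linalg.eigvalsh(km.matrix).min() >= -1e-8


class TestMultitaskKernel:
    def test_same_and_cross_task_scaling(self):
        examples = _random_examples(8, tasks=("a", "b"))
        base = combined_kernel(examples)
        tasks = [e.task for e in examples]
        mt = multitask_kernel(base, tasks, mu=1.0)
        for i in range(8):
            for j in range(8):
                factor = 2.0 if tasks[i] == tasks[j] else 1.0
                assert mt.matrix[i, j] == pytest.approx(factor * base.matrix[i, j])

    def test_mu_zero_is_block_diagonal(self):
        examples = _random_examples(8, tasks=("a", "b"))
        tasks = np.array([e.task for e in examples])
        mt = multitask_kernel(combined_kernel(examples), tasks, mu=0.0)
        cross = tasks[:, None] != tasks[None, :]
        assert np.all(mt.matrix[cross] == 0.0)

    def test_psd_preserved(self):
        examples = _random_examples(40, seed=9, tasks=("a", "b", "c"))
        mt = multitask_kernel(combined_kernel(examples),
                              [e.task for e in examples], mu=0.7)
        assert np.linalg.eigvalsh(mt.matrix).min() >= -1e-8

    def test_negative_mu_rejected(self):
        with pytest.raises(InputError):
            multitask_kernel(np.eye(2), ["a", "b"], mu=-0.1)


class TestTrainPredict:
    def test_task_minus_common_identity(self, binding_fixture):
        # f_t(x) - f_common(x) = sum over same-task support of a_i y_i K(x_i, x)
        model = binding_fixture["model"]
        assert model.mu is not None
        t = model.tasks[0]
        for ex in binding_fixture["test"][:10]:
            f_t = predict_binding(model, ex, mode=f"task:{t}")
            f_c = predict_binding(model, ex, mode="common")
            comps = model.kernel_to([ex])
            K = sum(comps.values())[:, 0]
            sup_tasks = np.array([model.examples[i].task for i in model.support])
            expected = float((model.dual_coef[sup_tasks == t]
                              * K[sup_tasks == t]).sum())
            assert f_t - f_c == pytest.approx(expected, abs=1e-9)

    def test_large_mu_makes_task_and_common_rankings_agree(self, binding_fixture):
        train = binding_fixture["train"]
        test = binding_fixture["test"]
        model = train_binding(train, BindingTrainConfig(mu=100.0, rng_seed=0))
        t = model.tasks[0]
        rho = spearmanr(predict_binding(model, test, mode="common"),
                        predict_binding(model, test, mode=f"task:{t}")).statistic
        assert rho > 0.99

    def test_single_task_fallback_warns(self, caplog):
        examples = _random_examples(20, tasks=("only",))
        with caplog.at_level("WARNING"):
            model = train_binding(examples,
                                  BindingTrainConfig(multitask=True))
        assert model.mu is None
        assert "single task" in caplog.text

    def test_prediction_deterministic(self, binding_fixture):
        model = binding_fixture["model"]
        ex = binding_fixture["test"][0]
        assert predict_binding(model, ex) == predict_binding(model, ex)

    def test_unknown_task_rejected(self, binding_fixture):
        with pytest.raises(InputError, match="unknown task"):
            predict_binding(binding_fixture["model"],
                            binding_fixture["test"][0], mode="task:nope")

    def test_small_recovery_smoke(self, binding_fixture):
        from mirclash.evaluate import auroc
        model = binding_fixture["model"]
        test = binding_fixture["test"]
        s = predict_binding(model, test, mode="common")
        labels = np.array([e.label for e in test])
        assert auroc(s[labels > 0], s[labels < 0]) > 0.8

    def test_model_json_round_trip_bitwise_predictions(self, binding_fixture,
                                                       tmp_path):
        model = binding_fixture["model"]
        model.to_json(tmp_path / "b.json")
        back = BindingModel.from_json(tmp_path / "b.json")
        ex = binding_fixture["test"][:5]
        assert np.array_equal(predict_binding(model, ex),
                              predict_binding(back, ex))


class TestCombination:
    def test_equal_z_scores_sum_to_two(self):
        scorer = CombinedScorer().fit([0.0, 2.0], [10.0, 30.0])
        # one std above each training mean -> z = 1 + 1
        assert combine_scores(2.0, 30.0, scorer) == pytest.approx(2.0)

    def test_unfitted_scorer_rejected(self):
        with pytest.raises(InputError):
            CombinedScorer().combine([1.0], [1.0])

    def test_combination_beats_both_components(self):
        rng = np.random.default_rng(2)
        from mirclash.evaluate import auroc
        n = 400
        d_pos, d_neg = rng.normal(1, 1, n), rng.normal(0, 1, n)
        b_pos, b_neg = rng.normal(1, 1, n), rng.normal(0, 1, n)
        scorer = CombinedScorer().fit(np.r_[d_pos, d_neg], np.r_[b_pos, b_neg])
        c_pos = scorer.combine(d_pos, b_pos)
        c_neg = scorer.combine(d_neg, b_neg)
        assert auroc(c_pos, c_neg) >= max(auroc(d_pos, d_neg),
                                          auroc(b_pos, b_neg))

    def test_scheme_recorded(self):
        assert CombinedScorer(scheme="min_rank").scheme == "min_rank"


class TestGeneLevel:
    def test_max_over_sites(self):
        assert gene_level_score({"g": [2.0, 3.5, -1.0]}) == {"g": 3.5}

    def test_single_site_is_itself(self):
        assert gene_level_score({"g": [0.7]}) == {"g": 0.7}

    def test_empty_gene_excluded(self):
        assert gene_level_score({"g": []}) == {}
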