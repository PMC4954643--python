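"""Duplex alignment: DP vs enumeration, feature identity, training loop."""

import json

import numpy as np
import pytest

from _oracles import enumerate_duplex_best
from mirclash.duplex import (DIM, DuplexExample, DuplexModel, DuplexTrainConfig,
                             DuplexWeights, EMPTY_ALIGNMENT, align_duplex,
                             alignment_from_pairs, builtin_init_weights,
                             featurize, format_alignment, init_alignment,
                             parse_duplex_structure, rank_mirnas, score_pair,
                             train_duplex, _fit_linear_hinge)
from mirclash.io import InputError, MiRNA


def _random_instance(rng, max_m=8, max_l=10, scale=1.5):
    M = int(rng.integers(2, max_m + 1))
    L = int(rng.integers(2, max_l + 1))
    mirna = "".join(rng.choice(list("ACGU"), M))
    site = "".join(rng.choice(list("ACGU"), L))
    w = DuplexWeights(rng.normal(0, scale, DIM))
    return w, mirna, site


class TestAlignDuplex:
    def test_zero_weights_give_empty_alignment(self):
        aln = align_duplex(DuplexWeights(), "UGAGGUAG", "CUACCUCA")
        assert aln is EMPTY_ALIGNMENT and aln.score == 0.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            w, mirna, site = _random_instance(rng)
            assert align_duplex(w, mirna, site).score \
                == enumerate_duplex_best(w, mirna, site)

    def test_score_equals_weights_dot_features(self):
        rng = np.random.default_rng(43)
        for _ in range(200):
            w, mirna, site = _random_instance(rng, max_m=12, max_l=16)
            aln = align_duplex(w, mirna, site)
            assert abs(float(w.vector @ featurize(aln)) - aln.score) < 1e-9

    def test_position_one_pairs_only_opposite_a(self):
        rng = np.random.default_rng(44)
        for _ in range(300):
            w, mirna, site = _random_instance(rng, scale=3.0)
            for ev in align_duplex(w, mirna, site).events:
                if ev[0] == "PAIR" and ev[1] == 1:
                    assert site[ev[2]] == "A"
                    assert ev[3] == "m1A"

    def test_monotone_in_pair_scores(self):
        rng = np.random.default_rng(45)
        for _ in range(60):
            w, mirna, site = _random_instance(rng)
            before = align_duplex(w, mirna, site).score
            w2 = w.copy()
            idx = int(rng.integers(0, 6 * 27))
            w2.vector[idx] += abs(float(rng.normal(0, 2)))
            assert align_duplex(w2, mirna, site).score >= before - 1e-12

    def test_n_bases_are_unpairable(self):
        w = builtin_init_weights()
        # site is the perfect complement of positions 2..8 with N inserted
        aln = align_duplex(w, "UGAGGUAG", "NNNNNNNN")
        assert aln.is_empty()

    def test_non_rna_mirna_rejected(self):
        with pytest.raises(InputError):
            align_duplex(DuplexWeights(), "ACGTX", "ACGU")

    def test_mirna_longer_than_p_max_rejected(self):
        with pytest.raises(InputError, match="27"):
            align_duplex(DuplexWeights(), "A" * 28, "ACGU")

    def test_deterministic(self):
        rng = np.random.default_rng(46)
        w, mirna, site = _random_instance(rng)
        assert align_duplex(w, mirna, site) == align_duplex(w, mirna, site)


class TestFeaturize:
    def test_consecutive_pairs_no_loops(self):
        w = builtin_init_weights()
        # miRNA 2..7 = GAGGUA pairs UACCUC (antiparallel)
        aln = align_duplex(w, "UGAGGUAG", "GGUACCUCGG")
        phi = featurize(aln)
        pair_block = phi[:6 * 27].reshape(27, 6)
        assert pair_block.sum() >= 6
        n_loops = phi[6 * 27 + 1:6 * 27 + 1 + 27].sum()
        assert n_loops == 0

    def test_loop_decomposition_bookkeeping(self):
        w = builtin_init_weights()
        # G:C pairs at miRNA 2 and 5 with a 2(miRNA) x 1(site) internal loop
        aln = alignment_from_pairs([(2, 5), (5, 3)], "UGAGGUAG", "AAACGCAAA", w)
        kinds = [e[0] for e in aln.events]
        assert kinds == ["PAIR", "LOOP_OPEN", "SYM_EXT", "ASYM_EXT_MIRNA", "PAIR"]
        assert abs(float(w.vector @ featurize(aln)) - aln.score) < 1e-12

    def test_empty_alignment_is_zero_vector(self):
        assert not featurize(EMPTY_ALIGNMENT).any()

    def test_malformed_event_order_rejected(self):
        from mirclash.duplex import DuplexAlignment
        bad = DuplexAlignment(events=(("SYM_EXT", 3),), score=0.0)
        with pytest.raises(InputError):
            featurize(bad)


class TestInitializer:
    def test_perfect_complement_stacks_without_loops(self):
        # site = reverse complement of the 8-mer with A opposite position 1
        aln = init_alignment("UGAGGUAG", "CUACCUCA")
        pairs = aln.pairs
        assert len(pairs) == 8
        assert [p for p, q in pairs] == list(range(1, 9))
        assert not any(e[0] == "LOOP_OPEN" for e in aln.events)

    def test_builtin_matches_enumeration(self):
        rng = np.random.default_rng(47)
        w = builtin_init_weights()
        for _ in range(40):
            M, L = int(rng.integers(4, 9)), int(rng.integers(4, 11))
            mirna = "".join(rng.choice(list("ACGU"), M))
            site = "".join(rng.choice(list("ACGU"), L))
            assert init_alignment(mirna, site).score \
                == enumerate_duplex_best(w, mirna, site)

    def test_external_bracket_with_mirna_bulge(self):
        # pairs at miRNA 2, 4, 5 (position 3 bulged) onto site 4, 3, 2
        aln = parse_duplex_structure(".(.((&..)))", "UGAGGUAG", "AACCCAAAAA",
                                     builtin_init_weights())
        assert aln.pairs == [(2, 4), (4, 3), (5, 2)]
        kinds = [e[0] for e in aln.events]
        assert kinds.count("LOOP_OPEN") == 1
        assert kinds.count("ASYM_EXT_MIRNA") == 1

    def test_external_conversion_bookkeeping(self):
        w = builtin_init_weights()
        # G:C at (2,8), A:U at (3,6): one site base bulged between them
        aln = alignment_from_pairs([(2, 8), (3, 6)], "UGAGGUAG", "AAAAAAUACA", w)
        kinds = [e[0] for e in aln.events]
        assert kinds.count("LOOP_OPEN") == 1
        assert kinds.count("ASYM_EXT_SITE") == 1


class TestTraining:
    @staticmethod
    def _examples(n=30, seed=0):
        rng = np.random.default_rng(seed)
        mirna = "UGAGGUAGUAGGUUGUAUAGUU"
        out = []
        for i in range(n):
            if i % 2 == 0:
                site = "GGACAACCUACUACCUCA"  # seed + 3' complement
                label = 1
            else:
                site = "".join(rng.choice(list("ACGU"), 18))
                label = -1
            out.append(DuplexExample(f"m{i}", "famA", mirna, site, label,
                                     "clash"))
        return out

    def test_single_iteration_equals_single_svm_fit(self):
        examples = self._examples()
        cfg = DuplexTrainConfig(iterations=1, inner_max=1, rng_seed=0)
        model = train_duplex(examples, cfg)
        X = np.vstack([featurize(init_alignment(e.mirna_seq, e.site_seq))
                       for e in examples])
        y = np.array([e.label for e in examples], dtype=float)
        w, b = _fit_linear_hinge(X, y, float(cfg.C))
        assert np.allclose(model.weights.vector, w)
        assert model.bias == pytest.approx(b)

    def test_label_flip_flips_weights(self):
        examples = self._examples()
        flipped = [DuplexExample(e.mirna_name, e.family, e.mirna_seq,
                                 e.site_seq, -e.label, e.source)
                   for e in examples]
        cfg = DuplexTrainConfig(iterations=1, inner_max=1, rng_seed=0,
                                clash_neg_ratio=2.0)
        w1 = train_duplex(examples, cfg).weights.vector
        w2 = train_duplex(flipped, cfg).weights.vector
        # agreement is limited by the SVM solver's dual tolerance (1e-3)
        assert np.allclose(w1, -w2, atol=5e-4)

    def test_default_iterations_is_twelve(self):
        assert DuplexTrainConfig().iterations == 12

    def test_deterministic_model_serialization(self, tmp_path):
        examples = self._examples()
        cfg = DuplexTrainConfig(iterations=2, rng_seed=5)
        train_duplex(examples, cfg).to_json(tmp_path / "a.json")
        train_duplex(examples, cfg).to_json(tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() \
            == (tmp_path / "b.json").read_bytes()

    def test_single_class_rejected(self):
        examples = [e for e in self._examples() if e.label > 0]
        with pytest.raises(InputError):
            train_duplex(examples, DuplexTrainConfig(iterations=1))

    def test_trace_length_equals_iterations(self):
        model = train_duplex(self._examples(), DuplexTrainConfig(iterations=3))
        assert model.iterations_run == 3


@pytest.fixture(scope="module")
def trained_model():
    return train_duplex(TestTraining._examples(),
                        DuplexTrainConfig(iterations=2))


class TestScoring:
    @pytest.fixture()
    def model(self, trained_model):
        return trained_model

    def test_score_is_alignment_plus_bias(self, model):
        mirna, site = "UGAGGUAGUAGGUUGUAUAGUU", "GGACAACCUACUACCUCA"
        expected = align_duplex(model.weights, mirna, site).score + model.bias
        assert score_pair(model, mirna, site) == pytest.approx(expected)

    def test_ranking_stable_and_order_invariant(self, model):
        mirnas = [MiRNA("b", "f1", "UGAGGUAGUAGGUUGUAUAGUU"),
                  MiRNA("a", "f2", "UGAGGUAGUAGGUUGUAUAGUU"),
                  MiRNA("c", "f3", "ACGUACGUACGUACGUACGUAC")]
        site = "GGACAACCUACUACCUCA"
        r1 = rank_mirnas(model, mirnas, site)
        r2 = rank_mirnas(model, list(reversed(mirnas)), site)
        assert r1 == r2
        assert [n for n, _ in r1[:2]] == ["a", "b"]   # tie broken by name

    def test_model_json_round_trip_exact(self, model, tmp_path):
        model.to_json(tmp_path / "m.json")
        back = DuplexModel.from_json(tmp_path / "m.json")
        assert np.array_equal(back.weights.vector, model.weights.vector)
        assert back.bias == model.bias and back.trace == model.trace

    def test_pretty_printer_renders_pairs(self, model):
        aln = align_duplex(model.weights, "UGAGGUAGUAGGUUGUAUAGUU",
                           "GGACAACCUACUACCUCA")
        text = format_alignment("UGAGGUAGUAGGUUGUAUAGUU",
                                "GGACAACCUACUACCUCA", aln)
        assert "miRNA" in text and "|" in text
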