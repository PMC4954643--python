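"""POIMs, score decomposition, enrichment testing, empirical FDR."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from mirclash.binding import (BindingExample, BindingTrainConfig, FlankPair,
                              PositionalContext, predict_binding, train_binding)
from mirclash.interpret import (EnrichmentResult, Poim, decode_kmer,
                                decompose_flank, decompose_score,
                                effective_linear_weights, empirical_fdr,
                                encode_kmer, flank_score_from_weights,
                                kmer_enrichment, poim_from_weights,
                                positional_part, site_position_profile,
                                top_kmers)
from mirclash.io import InputError, ProbeTable
from mirclash.synthetic import SimConfig, simulate_probe_table


def _zero_weights(degree=6, width=30):
    return {fl: [np.zeros((width - m + 1, 4 ** m))
                 for m in range(1, degree + 1)] for fl in ("up", "down")}


class TestEffectiveWeights:
    def test_reconstructs_discriminant(self, binding_fixture):
        model = binding_fixture["model"]
        W = effective_linear_weights(model, "common")
        for ex in binding_fixture["test"][:40]:
            f = predict_binding(model, ex, mode="common")
            rec = (flank_score_from_weights(W, "up", ex.flanks.upstream)
                   + flank_score_from_weights(W, "down", ex.flanks.downstream)
                   + positional_part(model, ex, "common") + model.bias)
            assert abs(f - rec) < 1e-6

    def test_weights_scale_linearly_in_dual_coefficients(self, binding_fixture):
        import copy
        model = binding_fixture["model"]
        W1 = effective_linear_weights(model, "common")
        doubled = copy.copy(model)
        doubled.dual_coef = model.dual_coef * 2.0
        W2 = effective_linear_weights(doubled, "common")
        for m in range(6):
            assert np.allclose(W2["down"][m], 2.0 * W1["down"][m])

    def test_zero_dual_coefficients_give_zero_maps(self, binding_fixture):
        import copy
        model = copy.copy(binding_fixture["model"])
        model.dual_coef = np.zeros_like(model.dual_coef)
        W = effective_linear_weights(model, "common")
        assert not any(Wm.any() for fl in W.values() for Wm in fl)


class TestPoim:
    def test_single_feature_model_peaks_at_that_feature(self):
        W = _zero_weights()
        kmer, pos = "UGCAUG", 7
        W["down"][5][pos, encode_kmer(kmer)] = 1.0
        poim = poim_from_weights(W, 6, "down")
        z, j = np.unravel_index(np.argmax(poim.Q), poim.Q.shape)
        assert decode_kmer(int(z), 6) == kmer and j == pos

    def test_all_zero_model_gives_zero_poim(self):
        poim = poim_from_weights(_zero_weights(), 4, "up")
        assert not poim.Q.any()

    def test_background_weighted_column_means_vanish(self, binding_fixture):
        W = effective_linear_weights(binding_fixture["model"], "common")
        for k in (1, 3, 5):
            poim = poim_from_weights(W, k, "down")
            assert np.abs(poim.Q.mean(axis=0)).max() < 1e-9

    def test_matches_monte_carlo(self, binding_fixture):
        W = effective_linear_weights(binding_fixture["model"], "common")
        k = 2
        poim = poim_from_weights(W, k, "down")
        rng = np.random.default_rng(0)
        n = 60000
        seqs = rng.integers(0, 4, size=(n, 30))
        g = np.zeros(n)
        for m, Wm in enumerate(W["down"], start=1):
            npos = Wm.shape[0]
            codes = np.zeros((n, npos), dtype=np.int64)
            for t in range(m):
                codes = codes * 4 + seqs[:, t:t + npos]
            for j in range(npos):
                g += Wm[j, codes[:, j]]
        j0 = 5
        codes2 = seqs[:, j0] * 4 + seqs[:, j0 + 1]
        for z in range(16):
            sel = codes2 == z
            mc = g[sel].mean() - g.mean()
            se = np.sqrt(g[sel].var() / sel.sum() + g.var() / n)
            assert abs(mc - poim.Q[z, j0]) < 4 * se + 1e-9

    def test_sub_kmer_features_spread_over_covering_positions(self):
        # a single 1-mer weight contributes to every k-window covering it
        W = _zero_weights()
        W["up"][0][10, encode_kmer("G")] = 1.0
        poim = poim_from_weights(W, 3, "up")
        for j in (8, 9, 10):
            col = poim.Q[:, j]
            assert col.max() > 0
        assert not poim.Q[:, 4].any()


class TestTopKmers:
    def test_default_n_top_is_fifteen(self):
        W = _zero_weights()
        rng = np.random.default_rng(1)
        W["down"][5][3] = rng.normal(size=4 ** 6)
        poims = [poim_from_weights(W, k, fl)
                 for k in (5, 6) for fl in ("up", "down")]
        top = top_kmers(poims)
        assert len(top.kmers) == 15

    def test_single_feature_ranks_first(self):
        W = _zero_weights()
        W["down"][5][3, encode_kmer("ACGUAC")] = 2.0
        poims = [poim_from_weights(W, k, fl)
                 for k in (5, 6) for fl in ("up", "down")]
        top = top_kmers(poims)
        assert (top.flank, top.k, top.position) == ("down", 6, 3)
        assert top.kmers[0] == "ACGUAC"

    def test_ties_broken_lexicographically(self):
        W = _zero_weights()
        W["up"][4][0, encode_kmer("GGGGG")] = 1.0
        W["up"][4][0, encode_kmer("AAAAA")] = 1.0
        poim = poim_from_weights(W, 5, "up")
        top = top_kmers([poim], k_choices=(5,), n_top=2)
        assert top.kmers == ("AAAAA", "GGGGG")


class TestDecomposition:
    def test_sum_identity_for_every_test_example(self, binding_fixture):
        model = binding_fixture["model"]
        for ex in binding_fixture["test"][:40]:
            d = decompose_score(model, ex, "common")
            assert abs(d.total - predict_binding(model, ex, "common")) < 1e-9

    def test_all_pad_sequence_contributes_nothing(self, binding_fixture):
        W = effective_linear_weights(binding_fixture["model"], "common")
        assert not decompose_flank(W, "up", "." * 30).any()

    def test_planted_motif_shows_positive_block(self):
        from mirclash.experiments import binding_recovery
        res = binding_recovery(seed=11)
        assert res.motif_recovered


class TestEnrichment:
    def _table(self, with_kmer_top=True):
        # 12 probes; the 3-mer "GGG" sits only in the top-intensity probes
        probes, intens = [], []
        for i in range(12):
            has = i < 4 if with_kmer_top else i % 3 == 0
            probes.append(("AAGGGAA" if has else "AACACAA") + "ACGU")
            intens.append(10.0 - i + (0.01 * i))
        return ProbeTable("exp", tuple(probes), tuple(intens))

    def test_enriched_kmer_significant_and_matches_enumeration(self):
        table = self._table()
        res = kmer_enrichment(table, ["GGG"], n_top_probes=12)
        assert res.p_value < 0.01
        # exact oracle: enumerate all ways to assign 4 of 12 intensities to
        # the "with" group and count rank sums at least as extreme
        intens = np.array(table.intensities)
        obs = sum(sorted(intens, reverse=True)[:4])
        count = total = 0
        for combo in itertools.combinations(range(12), 4):
            total += 1
            if intens[list(combo)].sum() >= obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_absent_kmers_flagged_p_one(self):
        table = self._table()
        res = kmer_enrichment(table, ["UUUUUU"], n_top_probes=12)
        assert res.flagged and res.p_value == 1.0

    def test_too_few_probes_rejected(self):
        with pytest.raises(InputError, match="probes"):
            kmer_enrichment(self._table(), ["GGG"], n_top_probes=100)

    def test_planted_probe_effect_detected(self):
        cfg = SimConfig(rng_seed=0)
        table = simulate_probe_table(cfg, motif="UGCAUG", n_probes=1100,
                                     effect=2.0, plant_prob=0.25)
        assert kmer_enrichment(table, ["UGCAUG"], 1000).p_value < 1e-3


class TestEmpiricalFdr:
    @staticmethod
    def _small_examples(seed=0, n=40):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            up = "".join(rng.choice(list("ACGU"), 30))
            down = "".join(rng.choice(list("ACGU"), 30))
            ctx = PositionalContext(int(rng.integers(0, 500)),
                                    int(rng.integers(0, 300)), None)
            out.append(BindingExample(FlankPair(up, down), ctx, "t0",
                                      1 if i % 2 == 0 else -1, f"e{i}"))
        return out

    def test_observed_p_below_all_nulls_bounds_fdr(self):
        examples = self._small_examples()
        cfg = SimConfig(rng_seed=0)
        probe = simulate_probe_table(cfg, motif="", n_probes=1050, effect=0.0)
        observed = EnrichmentResult("exp", 5.0, 1e-12, ("ACGUAC",), 6, 2,
                                    "down")
        res = empirical_fdr(observed, examples, probe,
                            BindingTrainConfig(rng_seed=0), n_perm=5,
                            rng_seed=0)
        assert res.fdr == pytest.approx(1 / 6)

    def test_permuted_observed_model_fdr_is_exchangeable_rank(self):
        """A label-permuted 'observed' model is exchangeable with the nulls,
        so its empirical FDR behaves like a uniform rank (its mean over
        repeats sits near 1/2, not near 0 or 1)."""
        cfg = SimConfig(rng_seed=3)
        probe = simulate_probe_table(cfg, motif="UGCAUG", n_probes=1050,
                                     effect=1.0)
        fdrs = []
        for rep in range(6):
            examples = self._small_examples(seed=rep)
            rng = np.random.default_rng(rep)
            labels = rng.permutation([e.label for e in examples])
            permuted = [replace(e, label=int(l))
                        for e, l in zip(examples, labels)]
            tcfg = BindingTrainConfig(rng_seed=rep)
            model = train_binding(permuted, tcfg)
            W = effective_linear_weights(model, "common")
            poims = [poim_from_weights(W, k, fl)
                     for k in (5, 6) for fl in ("up", "down")]
            top = top_kmers(poims)
            obs = kmer_enrichment(probe, top.kmers, 1000, k=top.k,
                                  position=top.position, flank=top.flank)
            fdrs.append(empirical_fdr(obs, permuted, probe, tcfg, n_perm=19,
                                      rng_seed=rep + 100).fdr)
        assert 0.1 < np.mean(fdrs) < 0.9


class TestPositionProfile:
    def test_identical_distributions_have_zero_ks(self, small_sim):
        pos = [s for s in small_sim.truth_sites if s.label == "positive"][:20]
        mirrored = [replace(s, label="negative") for s in pos]
        prof = site_position_profile(pos + mirrored, small_sim.utrs)
        assert prof.ks["d_stop"][0] == 0.0 and prof.ks["d_stop"][1] == 1.0

    def test_histogram_counts_sum_to_n(self, small_sim):
        sites = [s for s in small_sim.truth_sites if s.source == "clip"]
        prof = site_position_profile(sites, small_sim.utrs)
        for cls in ("positive", "negative"):
            n = sum(1 for s in sites if s.label == cls)
            assert prof.histograms[cls]["d_stop"].sum() == n

    def test_planted_bias_toward_isoform_ends_detected(self):
        from mirclash.experiments import binding_sim_config
        from mirclash.synthetic import simulate_dataset
        cfg = binding_sim_config(2, positional_odds=8.0, motif_prob=0.0,
                                 n_clip_candidates=300)
        data = simulate_dataset(cfg)
        sites = [s for s in data.truth_sites if s.source == "clip"]
        prof = site_position_profile(sites, data.utrs)
        assert prof.ks["d_next_end"][1] < 0.01
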