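"""Where do AGO-bound sites sit within 3'UTR isoforms?

Simulates bound sites biased into windows upstream of isoform 3' ends,
then compares the positional distributions of bound vs unbound seed
matches (distance to the UTR start and to the next/previous isoform end)
with two-sample KS tests.
"""

from mirclash.experiments import binding_sim_config
from mirclash.interpret import site_position_profile
from mirclash.synthetic import simulate_dataset

cfg = binding_sim_config(seed=2, positional_odds=6.0, n_clip_candidates=300)
data = simulate_dataset(cfg)
sites = [s for s in data.truth_sites if s.source == "clip"]

prof = site_position_profile(sites, data.utrs)
for axis, label in (("d_stop", "distance to UTR start"),
                    ("d_next_end", "distance to next isoform 3' end"),
                    ("d_prev_end", "distance to previous isoform 3' end")):
    stat, p = prof.ks[axis]
    med_p = float(sorted(prof.distances["positive"][axis])
                  [len(prof.distances["positive"][axis]) // 2])
    med_n = float(sorted(prof.distances["negative"][axis])
                  [len(prof.distances["negative"][axis]) // 2])
    print(f"{label:38s} KS={stat:.3f} p={p:.2g} "
          f"(median bound {med_p:.0f} nt vs unbound {med_n:.0f} nt)")
print("\nA small KS p on the next-end axis means bound sites crowd the "
      "windows just upstream of polyadenylation sites, the positional "
      "signal the binding model's RBF kernel encodes.")
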