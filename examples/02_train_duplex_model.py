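"""Train the duplex structural SVM on synthetic CLASH/CLIP data.

Generates a fixture with a planted scoring vector w*, assembles the
training set through the published filtering rules (chimeric-read filters,
mispaired decoys at 15x, CLIP negatives at 1x), trains with one miRNA
family held out, and reports the held-out ranking quality.
"""

from mirclash.experiments import duplex_recovery

res = duplex_recovery(seed=1)

print(f"training examples      : {res.n_train}")
print(f"held-out positives     : {res.n_test_pos}")
print(f"held-out negatives     : {res.n_test_neg}")
print(f"held-out family auROC  : {res.auroc:.3f}")
print(f"weight-change trace    : {[round(x, 2) for x in res.trace]}")
print(f"final step / ||w||     : {res.convergence_ratio:.4f}")
print("\nauROC near 1 means the learned alignment scores rank true "
      "(miRNA, site) interactions of an unseen seed family above decoys; "
      "the trace reaching ~0 shows the alternating optimization hit a "
      "fixed point.")
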