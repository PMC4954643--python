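"""Align a miRNA against a target site and inspect the duplex.

Builds the thermodynamic-flavoured default scoring vector, aligns let-7a
against a site carrying a seed match plus 3'-supplementary pairing, and
prints the optimal duplex with its additive score.
"""

from mirclash.duplex import (align_duplex, builtin_init_weights, featurize,
                             format_alignment)

mirna = "UGAGGUAGUAGGUUGUAUAGUU"            # let-7a, 5'->3'
site = "GGCAACCUACCACUACCUCAGG"             # UTR fragment, 5'->3'

weights = builtin_init_weights()
aln = align_duplex(weights, mirna, site)

print(format_alignment(mirna, site, aln))
print(f"\nalignment score : {aln.score:.2f}")
print(f"paired positions: {[p for p, _ in aln.pairs]}")
phi = featurize(aln)
print(f"w . phi check   : {float(weights.vector @ phi):.2f} (equals the score)")
print("\nThe score is the sum of per-event weights (pair type x miRNA "
      "position, loop events, paired indicators); the same vector acts as "
      "the alignment parameters and the SVM model.")
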