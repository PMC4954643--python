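"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and vectorized
code paths: alignments are enumerated event sequence by event sequence,
kernels are expanded into explicit feature maps, and ranking metrics are
accumulated threshold by threshold.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMPLEMENT = {("A", "U"): "AU", ("U", "A"): "UA", ("G", "C"): "GC",
               ("C", "G"): "CG", ("G", "U"): "GU", ("U", "G"): "UG"}


def enumerate_duplex_best(weights, mirna: str, site: str) -> float:
    """Max score over every legal duplex event sequence, by full enumeration.

    Uses the same float accumulation order (left to right along the event
    sequence) as the dynamic program, so optimal scores agree exactly.
    Returns 0.0 when no alignment scores above zero (the empty alignment).
    """
    mseq = mirna.upper().replace("T", "U")
    rs = site.upper().replace("T", "U")[::-1]
    M, L = len(mseq), len(rs)
    w_open = weights.loop_open
    w_sym = weights.loop_sym
    w_asym = weights.loop_asym

    def pairscore(i: int, j: int):
        sb = rs[j - 1]
        if i == 1:
            if sb == "A":
                return weights.m1a + weights.paired[0]
            return None
        b = _COMPLEMENT.get((mseq[i - 1], sb))
        if b is None:
            return None
        return weights.pair[i - 1, {"AU": 0, "UA": 1, "GC": 2, "CG": 3,
                                    "GU": 4, "UG": 5}[b]] + weights.paired[i - 1]

    best = 0.0

    def extend(i: int, j: int, acc: float):
        nonlocal best
        if acc > best:
            best = acc
        for i2 in range(i + 1, M + 1):
            for j2 in range(j + 1, L + 1):
                ps = pairscore(i2, j2)
                if ps is None:
                    continue
                a, b = i2 - i - 1, j2 - j - 1
                if a == 0 and b == 0:
                    extend(i2, j2, ps + acc)
                    continue

                # enumerate every loop decomposition, threading the running
                # sum so float accumulation matches the DP exactly
                def rec(cm, cs, run, first):
                    if cm == a and cs == b:
                        extend(i2, j2, ps + run)
                        return
                    if cm < a and cs < b:
                        idx = i + cm + 1
                        add = (w_open[idx - 1] + w_sym[idx - 1]) if first \
                            else w_sym[idx - 1]
                        rec(cm + 1, cs + 1, run + add, False)
                    if cm < a:
                        idx = i + cm + 1
                        add = (w_open[idx - 1] + w_asym[idx - 1]) if first \
                            else w_asym[idx - 1]
                        rec(cm + 1, cs, run + add, False)
                    if cs < b:
                        idx = i + cm
                        add = (w_open[idx - 1] + w_asym[idx - 1]) if first \
                            else w_asym[idx - 1]
                        rec(cm, cs + 1, run + add, False)

                rec(0, 0, acc, True)

    for i in range(1, M + 1):
        for j in range(1, L + 1):
            ps = pairscore(i, j)
            if ps is not None:
                extend(i, j, ps + 0.0)
    return best


def wd_kernel_feature_map(seq: str, degree: int, beta) -> dict:
    """Explicit positional k-mer feature map of the weighted degree kernel."""
    feats: dict = {}
    for k in range(1, degree + 1):
        w = np.sqrt(beta[k - 1])
        for j in range(len(seq) - k + 1):
            kmer = seq[j:j + k]
            if any(c not in "ACGU" for c in kmer):
                continue
            feats[(k, j, kmer)] = feats.get((k, j, kmer), 0.0) + w
    return feats


def wd_kernel_bruteforce(a: str, z: str, degree: int, beta) -> float:
    fa = wd_kernel_feature_map(a, degree, beta)
    fz = wd_kernel_feature_map(z, degree, beta)
    return sum(v * fz[key] for key, v in fa.items() if key in fz)


def auroc_bruteforce(pos, neg) -> float:
    """Pairwise win-count auROC with ties worth one half."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pr_points(pos, neg):
    """(recall, precision) at every distinct threshold, descending scores."""
    scores = sorted(set(list(pos) + list(neg)), reverse=True)
    pts = []
    for t in scores:
        tp = sum(1 for s in pos if s >= t)
        fp = sum(1 for s in neg if s >= t)
        pts.append((tp / len(pos), tp / (tp + fp)))
    return pts


def aupr_bruteforce(pos, neg, max_recall: float = 1.0) -> float:
    """Step-function area under the PR curve up to ``max_recall``."""
    area = 0.0
    prev_r = 0.0
    for r, p in pr_points(pos, neg):
        if r <= prev_r:
            continue
        hi = min(r, max_recall)
        if hi > prev_r:
            area += (hi - prev_r) * p
            prev_r = hi
        if prev_r >= max_recall:
            break
    return area / max_recall
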