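"""Ranking metrics and the held-out-family evaluation harness.

auROC uses the Mann-Whitney tie convention (ties count one half). auPR
integrates precision over recall with the step convention (no linear
interpolation of precision between achieved points); auPR50 integrates up
to 50% recall and is normalized by 0.5 so both areas live on [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .duplex import DuplexTrainConfig, score_pair, train_duplex
from .io import InputError
from .trainset import LabeledSite, holdout_by_family, make_duplex_examples

logger = logging.getLogger(__name__)


def _check(pos, neg):
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise InputError("both score lists must be non-empty")
    return pos, neg


def auroc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Area under the ROC curve (Mann-Whitney with ties worth 1/2)."""
    pos, neg = _check(scores_pos, scores_neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:len(pos)].sum()
    n_p, n_n = len(pos), len(neg)
    return float((r_pos - n_p * (n_p + 1) / 2) / (n_p * n_n))


def _pr_steps(pos: np.ndarray, neg: np.ndarray):
    """(recall, precision) at each distinct descending threshold."""
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    tp = np.cumsum(labels)
    fp = np.cumsum(1 - labels)
    # keep only the last index of each tied score block
    distinct = np.r_[scores[1:] != scores[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    recall = tp / len(pos)
    precision = tp / (tp + fp)
    return recall, precision


def aupr(scores_pos: Sequence[float], scores_neg: Sequence[float],
         max_recall: float = 1.0) -> float:
    """Step-function area under the precision-recall curve up to
    ``max_recall``, normalized by ``max_recall``."""
    pos, neg = _check(scores_pos, scores_neg)
    recall, precision = _pr_steps(pos, neg)
    area = 0.0
    prev_r = 0.0
    for r, p in zip(recall, precision):
        if r <= prev_r:
            continue
        hi = min(r, max_recall)
        if hi > prev_r:
            area += (hi - prev_r) * p
            prev_r = hi
        if prev_r >= max_recall:
            break
    return float(area / max_recall)


def aupr50(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """auPR integrated over recall in [0, 0.5], normalized to [0, 1]."""
    return aupr(scores_pos, scores_neg, max_recall=0.5)


@dataclass
class RankingEval:
    """Held-out ranking metrics for one miRNA seed family."""

    family: str
    n_pos: int
    n_neg: int
    auroc: float
    aupr: float
    aupr50: float
    score_source: str = "duplex"

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise InputError("n_pos and n_neg must be >= 1")
        for m in (self.auroc, self.aupr, self.aupr50):
            if not 0.0 <= m <= 1.0:
                raise InputError("metrics must be in [0, 1]")


def signed_rank_p(metric_a: Sequence[float], metric_b: Sequence[float]) -> float:
    """Wilcoxon signed-rank p for paired per-family metrics (1.0 when all
    pairs are tied)."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if np.allclose(a, b):
        return 1.0
    return float(stats.wilcoxon(a, b).pvalue)


def evaluate_heldout(mirnas, utrs, examples: Sequence[LabeledSite],
                     families: Sequence[str] | None = None,
                     duplex_config: DuplexTrainConfig | None = None,
                     decoy_families: Sequence[str] = (),
                     score_source: str = "duplex") -> list[RankingEval]:
    """Held-out-family evaluation of the duplex model.

    For each family, all its examples (and any example sharing its sites)
    are held out, the duplex model is trained on the rest, and the
    held-out positives are ranked against the held-out negative pool.
    ``decoy_families`` name families excluded from every training run and
    usable only as negatives. Families with no test positives are skipped
    with a log entry.
    """
    all_fams = sorted({e.family for e in examples})
    if len(all_fams) < 2:
        raise InputError("need >= 2 families")
    targets = list(families) if families is not None \
        else [f for f in all_fams if f not in set(decoy_families)]
    out: list[RankingEval] = []
    for fam in targets:
        train, test = holdout_by_family(examples, fam)
        train = [e for e in train if e.family not in set(decoy_families)]
        model = train_duplex(make_duplex_examples(train, mirnas, utrs),
                             duplex_config)
        test_ex = make_duplex_examples(test, mirnas, utrs)
        pos = [score_pair(model, e.mirna_seq, e.site_seq)
               for e in test_ex if e.label > 0]
        neg = [score_pair(model, e.mirna_seq, e.site_seq)
               for e in test_ex if e.label < 0]
        if not pos or not neg:
            logger.info("family %s skipped: %d test positives, %d negatives",
                        fam, len(pos), len(neg))
            continue
        out.append(RankingEval(family=fam, n_pos=len(pos), n_neg=len(neg),
                               auroc=auroc(pos, neg), aupr=aupr(pos, neg),
                               aupr50=aupr50(pos, neg),
                               score_source=score_source))
    return out
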