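"""miRNA-mRNA duplex alignment model.

The duplex between a miRNA and a target-site sequence is represented as an
ordered list of *events* on the miRNA axis (positions 1..P, 5'->3'; the site
is traversed antiparallel, 3'->5'):

* ``PAIR(p, q, b)`` — miRNA position ``p`` pairs site position ``q`` with
  pair type ``b`` in {AU, UA, GC, CG, GU, UG}; a pair at ``p = 1`` is only
  permitted opposite an ``A`` in the site (the m1A rule) and is scored by a
  single dedicated weight rather than a pair-type weight.
* ``LOOP_OPEN(p)`` — an internal loop opens.
* ``SYM_EXT(p)`` — the loop extends symmetrically, consuming one unpaired
  base from each strand.
* ``ASYM_EXT_MIRNA(p)`` / ``ASYM_EXT_SITE(p)`` — asymmetric extension
  consuming a single unpaired base from one strand.

Loop events are indexed by the miRNA position current when the event
occurs; a site-side extension carries the last consumed miRNA position.
Mismatched (non-complementary) opposed bases are not pairs: they are
realized inside loops (a symmetric extension consumes one base from each
strand). The alignment score is the additive sum of event weights, so with
feature vector phi counting events per position, score = w . phi exactly;
the same weight vector serves as both the SVM model and the local-alignment
scoring system.

The optimal alignment under a weight vector is found by dynamic
programming over two matrices (ended-in-pair / inside-loop); training
alternates realignment under the current weights with refitting a linear
hinge-loss SVM on the event-count features.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.svm import SVC

from .io import InputError, MiRNA, normalize_rna

P_MAX = 27
PAIR_TYPES = ("AU", "UA", "GC", "CG", "GU", "UG")
_PAIR_INDEX = {b: i for i, b in enumerate(PAIR_TYPES)}
# complementary (miRNA base, site base) -> pair type
_COMPLEMENT = {("A", "U"): "AU", ("U", "A"): "UA", ("G", "C"): "GC",
               ("C", "G"): "CG", ("G", "U"): "GU", ("U", "G"): "UG"}

NEG_INF = -1e30

# weight vector layout (length 6*P_MAX + 1 + 4*P_MAX)
_N_PAIR = 6 * P_MAX
_OFF_M1A = _N_PAIR
_OFF_OPEN = _OFF_M1A + 1
_OFF_SYM = _OFF_OPEN + P_MAX
_OFF_ASYM = _OFF_SYM + P_MAX
_OFF_PAIRED = _OFF_ASYM + P_MAX
DIM = _OFF_PAIRED + P_MAX


class DuplexWeights:
    """The alignment scoring vector w, with named views into its blocks.

    Blocks: ``pair[p-1, b]`` per-position pair-type scores (position 1 is
    never read — position-1 pairing is scored by ``m1a``), ``m1a``,
    ``loop_open``/``loop_sym``/``loop_asym`` per position, and
    ``paired`` per-position paired-indicator weights.
    """

    __slots__ = ("vector",)

    def __init__(self, vector: np.ndarray | None = None):
        if vector is None:
            vector = np.zeros(DIM)
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (DIM,):
            raise ValueError(f"weight vector must have shape ({DIM},)")
        if not np.all(np.isfinite(vector)):
            raise ValueError("weights must be finite")
        self.vector = vector

    @property
    def pair(self) -> np.ndarray:
        return self.vector[:_N_PAIR].reshape(P_MAX, 6)

    @property
    def m1a(self) -> float:
        return float(self.vector[_OFF_M1A])

    @m1a.setter
    def m1a(self, value: float) -> None:
        self.vector[_OFF_M1A] = value

    @property
    def loop_open(self) -> np.ndarray:
        return self.vector[_OFF_OPEN:_OFF_OPEN + P_MAX]

    @property
    def loop_sym(self) -> np.ndarray:
        return self.vector[_OFF_SYM:_OFF_SYM + P_MAX]

    @property
    def loop_asym(self) -> np.ndarray:
        return self.vector[_OFF_ASYM:_OFF_ASYM + P_MAX]

    @property
    def paired(self) -> np.ndarray:
        return self.vector[_OFF_PAIRED:_OFF_PAIRED + P_MAX]

    def copy(self) -> "DuplexWeights":
        return DuplexWeights(self.vector.copy())

    def to_dict(self) -> dict:
        return {
            "pair": {b: self.pair[:, i].tolist() for b, i in _PAIR_INDEX.items()},
            "m1a": self.m1a,
            "loop_open": self.loop_open.tolist(),
            "loop_sym": self.loop_sym.tolist(),
            "loop_asym": self.loop_asym.tolist(),
            "paired": self.paired.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DuplexWeights":
        w = cls()
        for b, i in _PAIR_INDEX.items():
            w.pair[:, i] = d["pair"][b]
        w.m1a = d["m1a"]
        w.loop_open[:] = d["loop_open"]
        w.loop_sym[:] = d["loop_sym"]
        w.loop_asym[:] = d["loop_asym"]
        w.paired[:] = d["paired"]
        return w


def builtin_init_weights() -> DuplexWeights:
    """Fixed thermodynamic-flavoured default weights for initial alignments.

    GC/CG pairs score 3, AU/UA 2, GU/UG wobbles 1 at every position; loop
    opening costs 3, symmetric extension 1, asymmetric extension 2;
    paired indicators are 0 and the position-1 A recognition scores 2.
    """
    w = DuplexWeights()
    for b, s in (("GC", 3.0), ("CG", 3.0), ("AU", 2.0), ("UA", 2.0),
                 ("GU", 1.0), ("UG", 1.0)):
        w.pair[:, _PAIR_INDEX[b]] = s
    w.m1a = 2.0
    w.loop_open[:] = -3.0
    w.loop_sym[:] = -1.0
    w.loop_asym[:] = -2.0
    return w


# ---------------------------------------------------------------------------
# alignments and features
# ---------------------------------------------------------------------------

# events are tuples: ("PAIR", p, q, b) with b a pair type or "m1A";
# ("LOOP_OPEN"|"SYM_EXT"|"ASYM_EXT_MIRNA"|"ASYM_EXT_SITE", p)

@dataclass(frozen=True)
class DuplexAlignment:
    """An event-level duplex structure with its additive score."""

    events: tuple
    score: float

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(e[1], e[2]) for e in self.events if e[0] == "PAIR"]

    def is_empty(self) -> bool:
        return not self.events


EMPTY_ALIGNMENT = DuplexAlignment(events=(), score=0.0)


def featurize(alignment: DuplexAlignment) -> np.ndarray:
    """Event counts phi such that w . phi equals the alignment score.

    Validates the event grammar: PAIR positions strictly increasing, loops
    bracketed by pairs and begun by exactly one LOOP_OPEN.
    """
    phi = np.zeros(DIM)
    last_p = 0
    in_loop = False
    seen_pair = False
    for ev in alignment.events:
        kind = ev[0]
        p = ev[1]
        if not 1 <= p <= P_MAX:
            raise InputError(f"event position {p} outside 1..{P_MAX}")
        if kind == "PAIR":
            if p <= last_p:
                raise InputError("PAIR positions must be strictly increasing")
            last_p = p
            b = ev[3]
            if p == 1:
                if b != "m1A":
                    raise InputError("position-1 pair must be the m1A event")
                phi[_OFF_M1A] += 1.0
            else:
                phi[(p - 1) * 6 + _PAIR_INDEX[b]] += 1.0
            phi[_OFF_PAIRED + p - 1] = 1.0
            in_loop = False
            seen_pair = True
        elif kind == "LOOP_OPEN":
            if in_loop or not seen_pair:
                raise InputError("LOOP_OPEN must follow a PAIR and open one loop")
            in_loop = True
            phi[_OFF_OPEN + p - 1] += 1.0
        elif kind in ("SYM_EXT", "ASYM_EXT_MIRNA", "ASYM_EXT_SITE"):
            if not in_loop:
                raise InputError(f"{kind} outside a loop")
            off = _OFF_SYM if kind == "SYM_EXT" else _OFF_ASYM
            phi[off + p - 1] += 1.0
        else:
            raise InputError(f"unknown event kind {kind!r}")
    if in_loop:
        raise InputError("alignment ends inside a loop")
    return phi


def _check_mirna_seq(mirna: str) -> str:
    seq = normalize_rna(mirna, allow_n=False, context="miRNA")
    if len(seq) > P_MAX:
        raise InputError(f"miRNA longer than {P_MAX} nt")
    return seq


def align_duplex(weights: DuplexWeights, mirna: str, site: str,
                 mode: str = "local") -> DuplexAlignment:
    """Maximum-score duplex alignment of a miRNA against a site sequence.

    The alignment is local on both strands (``mode="local"``); with
    ``mode="global_mirna"`` it must start at miRNA position 1 and end at
    the last miRNA position. ``N`` bases in the site are unpairable but
    may sit inside loops. Returns the empty alignment (score 0) when no
    legal alignment scores above 0.
    """
    mseq = _check_mirna_seq(mirna)
    sseq = normalize_rna(site, allow_n=True, context="site")
    M, L = len(mseq), len(sseq)
    rs = sseq[::-1]  # rs[j-1] is site index L-j (antiparallel traversal)

    pair = weights.pair
    w_open = weights.loop_open
    w_sym = weights.loop_sym
    w_asym = weights.loop_asym
    w_paired = weights.paired
    m1a = weights.m1a

    # pair scores per (i, j); NEG_INF where pairing is not allowed
    ps = np.full((M + 1, L + 1), NEG_INF)
    for i in range(1, M + 1):
        mb = mseq[i - 1]
        for j in range(1, L + 1):
            sb = rs[j - 1]
            if i == 1:
                if sb == "A":
                    ps[i, j] = m1a + w_paired[0]
            else:
                b = _COMPLEMENT.get((mb, sb))
                if b is not None:
                    ps[i, j] = pair[i - 1, _PAIR_INDEX[b]] + w_paired[i - 1]

    P = np.full((M + 1, L + 1), NEG_INF)
    Lm = np.full((M + 1, L + 1), NEG_INF)
    for i in range(1, M + 1):
        start_ok = (mode == "local") or i == 1
        prev_best = np.maximum(P[i - 1, :-1], Lm[i - 1, :-1])
        if start_ok:
            prev_best = np.maximum(prev_best, 0.0)
        P[i, 1:] = np.where(ps[i, 1:] > NEG_INF / 2, ps[i, 1:] + prev_best, NEG_INF)

        o, s, a = w_open[i - 1], w_sym[i - 1], w_asym[i - 1]
        cand = np.maximum.reduce([
            P[i - 1, :-1] + (o + s),   # open with a symmetric extension
            P[i - 1, 1:] + (o + a),    # open with a miRNA-side extension
            Lm[i - 1, :-1] + s,        # continue symmetrically
            Lm[i - 1, 1:] + a,         # continue on the miRNA side
        ])
        row = Lm[i]
        Prow = P[i]
        prev = NEG_INF
        for j in range(1, L + 1):
            v = cand[j - 1]
            h1 = Prow[j - 1] + (o + a)  # open on the site side after a pair
            h2 = prev + a               # continue on the site side
            if h1 > v:
                v = h1
            if h2 > v:
                v = h2
            row[j] = v
            prev = v

    if mode == "local":
        best = float(P[1:, 1:].max()) if M and L else NEG_INF
        if best <= 0.0:
            return EMPTY_ALIGNMENT
        loc = np.argwhere(P == best)
        bi, bj = (int(loc[0][0]), int(loc[0][1]))
    else:
        best = float(P[M, 1:].max()) if M and L else NEG_INF
        if best <= 0.0:
            return EMPTY_ALIGNMENT
        bi = M
        bj = int(np.argmax(P[M, 1:]) + 1)

    events = _traceback(P, Lm, ps, weights, mseq, rs, bi, bj, mode)
    events.reverse()
    # rewrite site coordinates from reversed to original indexing
    out = []
    for ev in events:
        if ev[0] == "PAIR":
            out.append(("PAIR", ev[1], L - ev[2], ev[3]))
        else:
            out.append(ev)
    return DuplexAlignment(events=tuple(out), score=best)


def _traceback(P, Lm, ps, weights, mseq, rs, bi, bj, mode):
    """Reconstruct the optimal event list by re-deriving each DP decision.

    Candidate values are recomputed with the same float expressions used in
    the forward pass, so the stored optimum is matched exactly; ties are
    broken by a fixed preference order (stacking, then loop closure; inside
    loops symmetric before asymmetric, opening before continuation).
    """
    events = []
    i, j, state = bi, bj, "P"
    while True:
        if state == "P":
            if i == 1:
                b = "m1A"
            else:
                b = _COMPLEMENT[(mseq[i - 1], rs[j - 1])]
            events.append(("PAIR", i, j, b))
            start_ok = (mode == "local") or i == 1
            cands = [("P", i - 1, j - 1, P[i - 1, j - 1], None),
                     ("L", i - 1, j - 1, Lm[i - 1, j - 1], None)]
            best = max(c[3] for c in cands)
            # prefer the local start when it attains the optimum
            if start_ok and 0.0 >= best:
                return events
            for st, ni, nj, v, _ in cands:
                if v == best:
                    i, j, state = ni, nj, st
                    break
        else:
            o = weights.loop_open[i - 1]
            s = weights.loop_sym[i - 1]
            a = weights.loop_asym[i - 1]
            cands = [
                ("P", i - 1, j - 1, P[i - 1, j - 1] + (o + s), ("SYM_EXT", True)),
                ("P", i - 1, j, P[i - 1, j] + (o + a), ("ASYM_EXT_MIRNA", True)),
                ("P", i, j - 1, P[i, j - 1] + (o + a), ("ASYM_EXT_SITE", True)),
                ("L", i - 1, j - 1, Lm[i - 1, j - 1] + s, ("SYM_EXT", False)),
                ("L", i - 1, j, Lm[i - 1, j] + a, ("ASYM_EXT_MIRNA", False)),
                ("L", i, j - 1, Lm[i, j - 1] + a, ("ASYM_EXT_SITE", False)),
            ]
            best = max(c[3] for c in cands)
            for st, ni, nj, v, (kind, opens) in cands:
                if v == best:
                    events.append((kind, i))
                    if opens:
                        events.append(("LOOP_OPEN", i))
                    i, j, state = ni, nj, st
                    break


def alignment_from_pairs(pairs: Sequence[tuple[int, int]], mirna: str, site: str,
                         weights: DuplexWeights) -> DuplexAlignment:
    """Build an alignment from a list of (miRNA pos, site pos) base pairs.

    Gaps between consecutive pairs become loops with a canonical
    decomposition: symmetric extensions first (consuming one base from each
    strand), then asymmetric extensions on the longer side. Pairs must be
    antiparallel-consistent (p increasing, site q decreasing). Score is
    computed as w . phi.
    """
    mseq = _check_mirna_seq(mirna)
    sseq = normalize_rna(site, allow_n=True, context="site")
    events = []
    prev = None
    for p, q in sorted(pairs):
        mb, sb = mseq[p - 1], sseq[q]
        if p == 1:
            if sb != "A":
                raise InputError("position-1 pair requires A in the site")
            b = "m1A"
        else:
            b = _COMPLEMENT.get((mb, sb))
            if b is None:
                raise InputError(f"bases {mb}/{sb} at p={p} cannot pair")
        if prev is not None:
            pp, pq = prev
            if p <= pp or q >= pq:
                raise InputError("pairs must advance antiparallel")
            n_m = p - pp - 1
            n_s = pq - q - 1
            if n_m or n_s:
                n_sym = min(n_m, n_s)
                events.append(("LOOP_OPEN", pp + 1 if n_m else pp))
                mpos = pp
                for _ in range(n_sym):
                    mpos += 1
                    events.append(("SYM_EXT", mpos))
                for _ in range(n_m - n_sym):
                    mpos += 1
                    events.append(("ASYM_EXT_MIRNA", mpos))
                for _ in range(n_s - n_sym):
                    events.append(("ASYM_EXT_SITE", mpos))
        events.append(("PAIR", p, q, b))
        prev = (p, q)
    aln = DuplexAlignment(events=tuple(events), score=0.0)
    score = float(weights.vector @ featurize(aln))
    return DuplexAlignment(events=aln.events, score=score)


def parse_duplex_structure(structure: str, mirna: str, site: str,
                           weights: DuplexWeights,
                           mirna_start: int = 1,
                           site_start: int = 0) -> DuplexAlignment:
    """Convert a dot-bracket duplex (``(((...&...)))``) to the event grammar.

    The part before ``&`` describes the miRNA 5'->3', the part after the
    site 5'->3'; brackets pair first-to-last across the ``&``. A pair of
    miRNA position 1 opposite a non-A base is dropped (the m1A rule).
    ``mirna_start`` (1-based) and ``site_start`` (0-based) anchor the
    structure on the full sequences.
    """
    if "&" not in structure:
        raise InputError("duplex structure must contain '&'")
    left, right = structure.split("&", 1)
    opens = [mirna_start + k for k, c in enumerate(left) if c == "("]
    closes = [site_start + k for k, c in enumerate(right) if c == ")"]
    if len(opens) != len(closes):
        raise InputError("unbalanced duplex structure")
    pairs = list(zip(opens, reversed(closes)))
    sseq = normalize_rna(site, allow_n=True, context="site")
    pairs = [(p, q) for p, q in pairs if not (p == 1 and sseq[q] != "A")]
    if not pairs:
        return EMPTY_ALIGNMENT
    return alignment_from_pairs(pairs, mirna, site, weights)


def init_alignment(mirna: str, site: str, initializer: str = "builtin",
                   structure: str | None = None,
                   weights: DuplexWeights | None = None) -> DuplexAlignment:
    """Initial duplex structure for a (miRNA, site) pair.

    ``builtin`` aligns under fixed thermodynamic-flavoured default weights;
    ``external`` converts a dot-bracket structure from an RNA duplex
    folding tool (scored under ``weights``, default the builtin defaults).
    """
    if initializer == "builtin":
        return align_duplex(builtin_init_weights(), mirna, site)
    if initializer == "external":
        if structure is None:
            raise InputError("external initializer requires a structure string")
        return parse_duplex_structure(structure, mirna, site,
                                      weights or builtin_init_weights())
    raise InputError(f"unknown initializer {initializer!r}")


def format_alignment(mirna: str, site: str, alignment: DuplexAlignment) -> str:
    """Three-line text rendering of a duplex (miRNA on top, site below)."""
    if alignment.is_empty():
        return "(no duplex)"
    mseq = normalize_rna(mirna)
    sseq = normalize_rna(site, allow_n=True)
    top, mid, bot = [], [], []
    prev = None
    for p, q in alignment.pairs:
        if prev is not None:
            pp, pq = prev
            gm = mseq[pp:p - 1]
            gs = sseq[q + 1:pq][::-1]
            width = max(len(gm), len(gs))
            top.append(gm.ljust(width, "-"))
            mid.append(" " * width)
            bot.append(gs.ljust(width, "-"))
        top.append(mseq[p - 1])
        mid.append("|")
        bot.append(sseq[q])
        prev = (p, q)
    return ("5' " + "".join(top) + " 3' (miRNA)\n"
            "   " + "".join(mid) + "\n"
            "3' " + "".join(bot) + " 5' (site)")


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplexExample:
    """One (miRNA, site-sequence) training example for the duplex model."""

    mirna_name: str
    family: str
    mirna_seq: str
    site_seq: str
    label: int           # +1 / -1
    source: str          # "clash" | "clip"
    task: str = "default"


@dataclass
class DuplexTrainConfig:
    C: float | str = 0.01         # "cv" selects C on a {0.001,0.01,0.1,1} grid
    iterations: int = 12
    inner_max: int = 4            # cutting-plane passes per iteration
    clash_neg_ratio: float = 15.0
    clip_neg_ratio: float = 1.0
    rng_seed: int = 0
    initializer: str = "builtin"
    mode: str = "local"


@dataclass
class DuplexModel:
    """Trained duplex model: scoring weights plus training metadata."""

    weights: DuplexWeights
    bias: float
    config: dict
    trace: list[float] = field(default_factory=list)

    @property
    def iterations_run(self) -> int:
        return len(self.trace)

    def to_json(self, path: str | Path) -> None:
        doc = {"format": "mirclash-duplex-model", "version": 1,
               "weights": self.weights.to_dict(), "bias": self.bias,
               "config": self.config, "trace": self.trace}
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DuplexModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "mirclash-duplex-model":
            raise InputError(f"{path}: not a duplex model file")
        return cls(weights=DuplexWeights.from_dict(doc["weights"]),
                   bias=doc["bias"], config=doc["config"], trace=doc["trace"])


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    return np.random.default_rng((seed * 1_000_003 + iteration) % (2**31))


def _sample(pool: list, k: int, rng: np.random.Generator) -> list:
    if k >= len(pool):
        return list(pool)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def _fit_linear_hinge(X: np.ndarray, y: np.ndarray,
                      C: float) -> tuple[np.ndarray, float]:
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    return (clf.dual_coef_ @ clf.support_vectors_).ravel().copy(), \
        float(clf.intercept_[0])


def _phi_key(phi: np.ndarray) -> tuple:
    nz = phi.nonzero()[0]
    return (tuple(nz.tolist()), tuple(phi[nz].tolist()))


def train_duplex(examples: Sequence[DuplexExample],
                 config: DuplexTrainConfig | None = None) -> DuplexModel:
    """Latent structural-SVM training of the duplex scoring vector.

    Training alternates inference and weight updates for ``iterations``
    rounds. In each round the positives' duplex structures are recomputed
    as their best alignment under the current weights (round 1 uses the
    configured initializer) and negatives are resampled per source at the
    configured ratios. Because a negative example must score low under
    *every* alignment, each round then runs up to ``inner_max``
    cutting-plane passes: fit a linear hinge-loss SVM, realign the
    negatives under the new weights, and add any newly violated alignment
    feature vectors to a per-example working set, stopping early when no
    new alignment appears. The procedure reaches an exact fixed point
    (zero weight change) once the positives' alignments and the working
    sets stop changing. Deterministic under a fixed ``rng_seed``.

    ``inner_max=1`` disables the working set, recovering the plain
    realign-refit alternation (with ``iterations=1`` this is a single SVM
    fit on the initializer alignments).
    """
    cfg = config or DuplexTrainConfig()
    pos = [e for e in examples if e.label > 0]
    neg = {"clash": [e for e in examples if e.label < 0 and e.source == "clash"],
           "clip": [e for e in examples if e.label < 0 and e.source == "clip"]}
    if not pos or not (neg["clash"] or neg["clip"]):
        raise InputError("training requires both positive and negative examples")
    n_pos = {"clash": sum(1 for e in pos if e.source == "clash"),
             "clip": sum(1 for e in pos if e.source == "clip")}

    # per-negative working sets of alignment feature vectors, keyed by
    # example identity so they persist across resampling rounds
    banks: dict[int, dict[tuple, np.ndarray]] = {}

    def neg_phi(e: DuplexExample, w: DuplexWeights | None) -> np.ndarray:
        if w is None:
            aln = init_alignment(e.mirna_seq, e.site_seq, cfg.initializer)
        else:
            aln = align_duplex(w, e.mirna_seq, e.site_seq, mode=cfg.mode)
        return featurize(aln)

    C = cfg.C
    weights = DuplexWeights()
    bias = 0.0
    trace: list[float] = []
    for t in range(1, cfg.iterations + 1):
        rng = _iteration_rng(cfg.rng_seed, t)
        sampled_neg: list[DuplexExample] = []
        for src, ratio in (("clash", cfg.clash_neg_ratio),
                           ("clip", cfg.clip_neg_ratio)):
            want = int(round(ratio * n_pos[src]))
            if n_pos[src] == 0 and neg[src]:
                want = len(neg[src])
            sampled_neg.extend(_sample(neg[src], want, rng))
        if not sampled_neg:
            raise InputError("no negatives sampled; check ratios")
        w_cur = None if t == 1 else weights
        phi_pos = [featurize(init_alignment(e.mirna_seq, e.site_seq,
                                            cfg.initializer)) if t == 1
                   else featurize(align_duplex(weights, e.mirna_seq,
                                               e.site_seq, mode=cfg.mode))
                   for e in pos]
        for e in sampled_neg:
            bank = banks.setdefault(id(e), {})
            if cfg.inner_max == 1:
                phi = neg_phi(e, w_cur)
                bank.clear()
                bank[_phi_key(phi)] = phi
            elif not bank:
                phi = neg_phi(e, w_cur)
                bank[_phi_key(phi)] = phi
        w_inner = weights
        for _ in range(max(1, cfg.inner_max)):
            X = np.vstack(phi_pos + [p for e in sampled_neg
                                     for p in banks[id(e)].values()])
            y = np.concatenate([np.ones(len(phi_pos)),
                                -np.ones(X.shape[0] - len(phi_pos))])
            if C == "cv":
                C = _select_c(X, y)
            w_new, bias = _fit_linear_hinge(X, y, float(C))
            w_inner = DuplexWeights(w_new)
            if cfg.inner_max == 1:
                break
            added = 0
            for e in sampled_neg:
                phi = neg_phi(e, w_inner)
                key = _phi_key(phi)
                if key not in banks[id(e)]:
                    banks[id(e)][key] = phi
                    added += 1
            if added == 0:
                break
        trace.append(float(np.linalg.norm(w_inner.vector - weights.vector)))
        weights = w_inner
    return DuplexModel(weights=weights, bias=bias,
                       config={"C": C, "iterations": cfg.iterations,
                               "inner_max": cfg.inner_max,
                               "clash_neg_ratio": cfg.clash_neg_ratio,
                               "clip_neg_ratio": cfg.clip_neg_ratio,
                               "rng_seed": cfg.rng_seed,
                               "initializer": cfg.initializer,
                               "mode": cfg.mode},
                       trace=trace)


def _select_c(X: np.ndarray, y: np.ndarray, seed: int = 0,
              grid=(0.001, 0.01, 0.1, 1.0)) -> float:
    from sklearn.model_selection import StratifiedKFold
    from sklearn.metrics import roc_auc_score
    best_c, best_auc = grid[0], -1.0
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed % (2**31))
    for c in grid:
        aucs = []
        for tr, te in skf.split(X, y):
            w, b = _fit_linear_hinge(X[tr], y[tr], c)
            aucs.append(roc_auc_score(y[te], X[te] @ w + b))
        mean = float(np.mean(aucs))
        if mean > best_auc:
            best_auc, best_c = mean, c
    return best_c


def score_pair(model: DuplexModel, mirna: str, site: str) -> float:
    """Discriminant score: optimal alignment score plus the model bias."""
    mode = model.config.get("mode", "local")
    return align_duplex(model.weights, mirna, site, mode=mode).score + model.bias


def rank_mirnas(model: DuplexModel, mirnas: Sequence[MiRNA],
                site: str) -> list[tuple[str, float]]:
    """Rank catalog miRNAs against one site, descending score, stable by name."""
    scored = [(m.name, score_pair(model, m.sequence, site)) for m in mirnas]
    return sorted(scored, key=lambda t: (-t[1], t[0]))
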