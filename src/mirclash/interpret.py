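"""Interpretation of the AGO binding model.

Positional oligomer importance matrices (POIMs) score every k-mer z at
every flank position j by the expected change in the model's effective
linear flank score when z is clamped at j under a uniform i.i.d.
background: Q(z, j) = E[f(x) | x_j..j+k-1 = z] - E[f(x)]. Because the
weighted degree kernel has a finite explicit feature map, the dual SVM can
be converted to explicit positional k-mer weights and the expectations
computed exactly (sub- and super-k-mers contribute through overlap
marginalization). The top differential-POIM position yields candidate
motifs, which are tested for enrichment among high-intensity RNAcompete
probes with a one-sided rank-sum test and a label-permutation empirical
FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
from scipy import stats

from .binding import (BindingExample, BindingModel, BindingTrainConfig,
                      FLANK_WIDTH, encode_flank, train_binding, _featurize_set,
                      _rbf_matrix)
from .io import InputError, ProbeTable, UtrRecord
from .trainset import LabeledSite

_BASES = "ACGU"


def _support_scales(model: BindingModel, mode: str) -> np.ndarray:
    """Per-support-vector multiplier realizing the common/task discriminant."""
    if model.mu is None:
        return np.ones(len(model.support))
    if mode == "common":
        return np.full(len(model.support), model.mu)
    if mode.startswith("task:"):
        t = mode.split(":", 1)[1]
        if t not in model.tasks:
            raise InputError(f"unknown task {t!r}")
        sup_tasks = np.array([model.examples[i].task for i in model.support])
        return model.mu + (sup_tasks == t).astype(float)
    raise InputError(f"unknown mode {mode!r}")


def effective_linear_weights(model: BindingModel, mode: str = "common"
                             ) -> dict[str, list[np.ndarray]]:
    """Explicit positional k-mer weights per flank.

    Returns ``{"up": [W_1..W_d], "down": [...]}`` where ``W_m`` has shape
    (n_positions, 4**m) and entry (l, code) carries
    beta_m * sum_i alpha_i y_i s_i 1[x_i has that m-mer at l] / c_flank,
    with s_i the common/task scaling and c_flank the kernel trace
    normalizer. The dot product with an example's k-mer indicators
    reproduces the flank part of the discriminant.
    """
    coef = model.dual_coef * _support_scales(model, mode)
    sup = [model.examples[i] for i in model.support]
    out: dict[str, list[np.ndarray]] = {}
    for flank, attr, tag in (("up", "upstream", "wd_up"),
                             ("down", "downstream", "wd_down")):
        maps: list[np.ndarray] = []
        if tag not in model.norms:
            out[flank] = [np.zeros((FLANK_WIDTH - m + 1, 4 ** m))
                          for m in range(1, model.degree + 1)]
            continue
        E = np.stack([encode_flank(getattr(e.flanks, attr)) for e in sup])
        norm = model.norms[tag]
        L = E.shape[1]
        for m in range(1, model.degree + 1):
            npos = L - m + 1
            W = np.zeros((npos, 4 ** m))
            codes = np.zeros((len(sup), npos), dtype=np.int64)
            valid = np.ones((len(sup), npos), dtype=bool)
            for t in range(m):
                col = E[:, t:t + npos]
                codes = codes * 4 + np.maximum(col, 0)
                valid &= col >= 0
            scale = model.beta[m - 1] / norm
            for j in range(npos):
                v = valid[:, j]
                if v.any():
                    np.add.at(W[j], codes[v, j], coef[v] * scale)
            maps.append(W)
        out[flank] = maps
    return out


def flank_score_from_weights(weights: dict[str, list[np.ndarray]],
                             flank: str, sequence: str) -> float:
    """Score one flank sequence against an explicit weight map."""
    E = encode_flank(sequence)
    total = 0.0
    for m, W in enumerate(weights[flank], start=1):
        for j in range(len(E) - m + 1):
            window = E[j:j + m]
            if (window < 0).any():
                continue
            code = 0
            for b in window:
                code = code * 4 + int(b)
            total += W[j, code]
    return total


# ---------------------------------------------------------------------------
# POIM
# ---------------------------------------------------------------------------

@dataclass
class Poim:
    """Positional oligomer importance matrix for one flank and one k.

    ``Q[z, j]``: z encoded base-4 big-endian over A,C,G,U; j the 0-based
    start position in the flank. ``differential[j] = max_z Q - min_z Q``.
    """

    flank: str
    k: int
    Q: np.ndarray

    @property
    def differential(self) -> np.ndarray:
        return self.Q.max(axis=0) - self.Q.min(axis=0)


def encode_kmer(kmer: str) -> int:
    code = 0
    for c in kmer:
        code = code * 4 + _BASES.index(c)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def poim_from_weights(weights: dict[str, list[np.ndarray]], k: int,
                      flank: str, width: int = FLANK_WIDTH) -> Poim:
    """Exact POIM under a uniform i.i.d. background.

    Every effective m-mer weight (m = 1..degree) overlapping the clamped
    window contributes its overlap-marginalized mean minus its
    unconditional mean; non-overlapping features cancel.
    """
    if not 1 <= k <= len(weights[flank]):
        raise InputError("k outside 1..degree")
    npos = width - k + 1
    Q = np.zeros((4 ** k, npos))
    for m, W in enumerate(weights[flank], start=1):
        n_l = W.shape[0]
        means = W.mean(axis=1)
        cube = W.reshape((n_l,) + (4,) * m)
        for l in range(n_l):
            if not W[l].any():
                continue
            for j in range(max(0, l - k + 1), min(npos, l + m)):
                a = max(l, j)
                b = min(l + m, j + k)
                keep = tuple(range(a - l, b - l))
                drop = tuple(ax for ax in range(m) if ax not in keep)
                marg = cube[l].mean(axis=drop) if drop else cube[l]
                za, zb = a - j, b - j
                shape = (1,) * za + (4,) * (zb - za) + (1,) * (k - zb)
                contrib = marg.reshape(shape) - means[l]
                Q[:, j] += np.broadcast_to(contrib, (4,) * k).ravel()
    return Poim(flank=flank, k=k, Q=Q)


def compute_poim(model: BindingModel, k: int, flank: str,
                 mode: str = "common") -> Poim:
    """POIM of the trained binding model for one flank and k."""
    return poim_from_weights(effective_linear_weights(model, mode), k, flank)


@dataclass
class TopKmers:
    flank: str
    k: int
    position: int
    kmers: tuple[str, ...]


def top_kmers(poims: Sequence[Poim], k_choices: Sequence[int] = (5, 6),
              n_top: int = 15) -> TopKmers:
    """The k-mers with highest POIM weight at the position of highest
    differential POIM weight over the requested k values."""
    cands = [p for p in poims if p.k in set(k_choices)]
    if not cands:
        raise InputError("no POIMs for the requested k values")
    best = None
    for p in sorted(cands, key=lambda p: (p.flank, p.k)):
        D = p.differential
        for j in range(len(D)):
            if best is None or D[j] > best[0]:
                best = (D[j], p, j)
    _, poim, j = best
    col = poim.Q[:, j]
    order = sorted(range(len(col)),
                   key=lambda z: (-col[z], decode_kmer(z, poim.k)))
    kmers = tuple(decode_kmer(z, poim.k) for z in order[:n_top])
    return TopKmers(flank=poim.flank, k=poim.k, position=j, kmers=kmers)


# ---------------------------------------------------------------------------
# score decomposition
# ---------------------------------------------------------------------------

@dataclass
class DecomposedScore:
    """Per-position flank contributions plus the positional part and bias;
    their sum reproduces the discriminant."""

    up: np.ndarray
    down: np.ndarray
    positional: float
    bias: float

    @property
    def total(self) -> float:
        return float(self.up.sum() + self.down.sum() + self.positional
                     + self.bias)


def decompose_flank(weights: dict[str, list[np.ndarray]], flank: str,
                    sequence: str, cover: bool = False) -> np.ndarray:
    """Per-position contributions: k-mers *starting* at j are summed onto
    j (``cover=True`` spreads each k-mer over the positions it covers)."""
    E = encode_flank(sequence)
    out = np.zeros(len(E))
    for m, W in enumerate(weights[flank], start=1):
        for j in range(len(E) - m + 1):
            window = E[j:j + m]
            if (window < 0).any():
                continue
            code = 0
            for b in window:
                code = code * 4 + int(b)
            w = W[j, code]
            if cover:
                out[j:j + m] += w / m
            else:
                out[j] += w
    return out


def positional_part(model: BindingModel, example: BindingExample,
                    mode: str = "common") -> float:
    """The positional-RBF share of the discriminant for one example."""
    if "positional" not in model.norms:
        return 0.0
    coef = model.dual_coef * _support_scales(model, mode)
    _, _, T = model._features()
    from .binding import transform_context
    t = transform_context(example.context)[None, :]
    kp = _rbf_matrix(T, t, model.gamma)[:, 0] / model.norms["positional"]
    return float((coef * kp).sum())


def decompose_score(model: BindingModel, example: BindingExample,
                    mode: str = "common", cover: bool = False
                    ) -> DecomposedScore:
    weights = effective_linear_weights(model, mode)
    return DecomposedScore(
        up=decompose_flank(weights, "up", example.flanks.upstream, cover),
        down=decompose_flank(weights, "down", example.flanks.downstream, cover),
        positional=positional_part(model, example, mode),
        bias=model.bias)


# ---------------------------------------------------------------------------
# RNAcompete enrichment and empirical FDR
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    experiment_id: str
    statistic: float
    p_value: float
    kmers: tuple[str, ...]
    k: int
    position: int
    flank: str = ""
    fdr: float | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise InputError("p must be in (0, 1]")
        if self.fdr is not None and not 0.0 <= self.fdr <= 1.0:
            raise InputError("FDR must be in [0, 1]")


def kmer_enrichment(probe_table: ProbeTable, kmers: Sequence[str],
                    n_top_probes: int = 1000,
                    restrict_to_top: bool = True,
                    k: int = 0, position: int = -1,
                    flank: str = "") -> EnrichmentResult:
    """One-sided rank-sum test of k-mer enrichment in high-intensity probes.

    The ``n_top_probes`` highest-intensity probes are selected and their
    intensities compared between probes containing at least one of the
    k-mers and probes containing none (exact null below 50 per group,
    normal approximation with continuity correction otherwise).
    ``restrict_to_top=False`` instead splits the full probe set.
    Degenerate groupings are flagged with p = 1.
    """
    n = len(probe_table.probes)
    if n < n_top_probes:
        raise InputError(
            f"{probe_table.experiment_id}: {n} probes < n_top_probes={n_top_probes}")
    intens = np.asarray(probe_table.intensities, dtype=float)
    order = np.argsort(-intens, kind="stable")
    sel = order[:n_top_probes] if restrict_to_top else order
    kmer_set = [str(km).upper().replace("T", "U") for km in kmers]
    has = np.array([any(km in probe_table.probes[i] for km in kmer_set)
                    for i in sel])
    g_with = intens[sel[has]]
    g_without = intens[sel[~has]]
    kk = k or (len(kmer_set[0]) if kmer_set else 0)
    if len(g_with) == 0 or len(g_without) == 0:
        return EnrichmentResult(probe_table.experiment_id, float("nan"), 1.0,
                                tuple(kmer_set), kk, position, flank,
                                flagged=True)
    method = "exact" if max(len(g_with), len(g_without)) < 50 else "asymptotic"
    try:
        res = stats.mannwhitneyu(g_with, g_without, alternative="greater",
                                 method=method)
    except ValueError:  # exact method cannot handle ties
        res = stats.mannwhitneyu(g_with, g_without, alternative="greater",
                                 method="asymptotic")
    p = float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))
    return EnrichmentResult(probe_table.experiment_id, float(res.statistic), p,
                            tuple(kmer_set), kk, position, flank)


def empirical_fdr(observed: EnrichmentResult,
                  examples: Sequence[BindingExample],
                  probe_table: ProbeTable,
                  train_config: BindingTrainConfig | None = None,
                  n_perm: int = 100,
                  rng_seed: int = 0,
                  n_top_probes: int = 1000,
                  mode: str = "common") -> EnrichmentResult:
    """Label-permutation empirical FDR for an enrichment result.

    For each permutation the binding SVM is retrained on permuted class
    labels, the top POIM k-mers are extracted at the same (flank, k,
    position) as the observed model, and their enrichment p-value is
    computed; the FDR is the empirical quantile
    (1 + #{null p <= observed p}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    cfg = train_config or BindingTrainConfig()
    rng = np.random.default_rng(rng_seed % (2**31))
    labels = np.array([e.label for e in examples])
    null_p = []
    n_top = len(observed.kmers)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        permuted = [dc_replace(e, label=int(l)) for e, l in zip(examples, perm)]
        model = train_binding(permuted, cfg)
        weights = effective_linear_weights(model, mode)
        poim = poim_from_weights(weights, observed.k, observed.flank or "down")
        col = poim.Q[:, observed.position]
        order = sorted(range(len(col)),
                       key=lambda z: (-col[z], decode_kmer(z, observed.k)))
        kmers = [decode_kmer(z, observed.k) for z in order[:n_top]]
        res = kmer_enrichment(probe_table, kmers, n_top_probes,
                              k=observed.k, position=observed.position,
                              flank=observed.flank)
        null_p.append(res.p_value)
    fdr = (1 + sum(1 for p in null_p if p <= observed.p_value)) / (n_perm + 1)
    return dc_replace(observed, fdr=float(fdr))


# ---------------------------------------------------------------------------
# positional distribution of sites within 3'UTRs
# ---------------------------------------------------------------------------

@dataclass
class PositionProfile:
    """Anchor-distance distributions per class with two-sample KS tests."""

    distances: dict[str, dict[str, np.ndarray]]   # class -> axis -> values
    histograms: dict[str, dict[str, np.ndarray]]  # class -> axis -> counts
    bin_edges: dict[str, np.ndarray]
    ks: dict[str, tuple[float, float]]            # axis -> (stat, p)


def site_position_profile(examples: Sequence[LabeledSite],
                          utrs: Sequence[UtrRecord],
                          n_bins: int = 30) -> PositionProfile:
    """Distances from site anchors to the UTR start and to the next and
    previous isoform 3' ends, per class, with KS statistics between the
    positive and negative distributions on each axis."""
    from .binding import positional_context
    utr_by_id = {u.transcript_id: u for u in utrs}
    dist: dict[str, dict[str, list[float]]] = {
        cls: {"d_stop": [], "d_next_end": [], "d_prev_end": []}
        for cls in ("positive", "negative")}
    for s in examples:
        utr = utr_by_id[s.transcript_id]
        c = positional_context(utr, s.anchor_position)
        d = dist[s.label]
        d["d_stop"].append(c.d_stop)
        d["d_next_end"].append(c.d_next_end)
        if c.d_prev_end is not None:
            d["d_prev_end"].append(c.d_prev_end)
    distances = {cls: {ax: np.asarray(v, dtype=float) for ax, v in axes.items()}
                 for cls, axes in dist.items()}
    histograms: dict[str, dict[str, np.ndarray]] = {c: {} for c in distances}
    edges: dict[str, np.ndarray] = {}
    ks: dict[str, tuple[float, float]] = {}
    for ax in ("d_stop", "d_next_end", "d_prev_end"):
        pooled = np.concatenate([distances[c][ax] for c in distances]) \
            if any(len(distances[c][ax]) for c in distances) else np.array([0.0])
        edges[ax] = np.histogram_bin_edges(pooled, bins=n_bins)
        for cls in distances:
            histograms[cls][ax] = np.histogram(distances[cls][ax],
                                               bins=edges[ax])[0]
        a, b = distances["positive"][ax], distances["negative"][ax]
        if len(a) and len(b):
            if np.array_equal(np.sort(a), np.sort(b)):
                ks[ax] = (0.0, 1.0)
            else:
                res = stats.ks_2samp(a, b)
                ks[ax] = (float(res.statistic), float(res.pvalue))
        else:
            ks[ax] = (float("nan"), float("nan"))
    return PositionProfile(distances=distances, histograms=histograms,
                           bin_edges=edges, ks=ks)
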