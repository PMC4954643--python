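"""Synthetic fixture generator with planted, known structure.

Emulates the data classes the models train on — a miRNA catalog grouped
into seed families, a 3'UTR atlas with 1-3 isoform ends per transcript,
chimeric-read interactions, AGO peaks, and RNAcompete-style probe tables —
without any download. Interaction labels are defined through the same
duplex grammar the duplex model learns: candidate sites of graded
complementarity (seed plus 3'-supplementary pairing, seed-only, or random)
are embedded into background UTRs and labeled positive when their optimal
alignment under a planted weight vector w* scores above a quantile
threshold, which makes parameter recovery a well-posed experiment. AGO
binding signal is planted as a flank motif at a fixed offset and a
positional bias toward windows upstream of isoform 3' ends; evidence
(chimeras, peaks) is derived from the labels with configurable noise.

What this does not emulate: read-level CLIP coverage, crosslink-induced
mutations, ligation biases, or expression-dependent site occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .duplex import DuplexWeights, align_duplex, builtin_init_weights, _PAIR_INDEX
from .io import (AgoPeak, ChimericInteraction, MiRNA, UtrRecord,
                 write_interactions, write_mirna_catalog, write_peaks,
                 write_probe_table, write_utr_atlas, ProbeTable)
from .trainset import LabeledSite, seed_site, write_labeled_sites

_BASES = "ACGU"
_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _rc(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def planted_duplex_weights() -> DuplexWeights:
    """The default planted scoring vector w*.

    Strong seed-region pairing (miRNA positions 2-8), moderate
    3'-supplementary pairing (positions 12-18), weak elsewhere; m1A bonus;
    loop penalties; small paired-indicator bonuses concentrated in the
    seed. Chosen to mirror the known position dependence of miRNA
    targeting efficacy.
    """
    w = DuplexWeights()
    strong = slice(1, 8)    # positions 2-8 (0-based rows 1..7)
    supp = slice(11, 18)    # positions 12-18
    for b, s_strong, s_supp, s_rest in (("GC", 4.0, 2.0, 0.5), ("CG", 4.0, 2.0, 0.5),
                                        ("AU", 3.5, 1.7, 0.4), ("UA", 3.5, 1.7, 0.4),
                                        ("GU", 1.0, 0.5, 0.1), ("UG", 1.0, 0.5, 0.1)):
        col = _PAIR_INDEX[b]
        w.pair[:, col] = s_rest
        w.pair[strong, col] = s_strong
        w.pair[supp, col] = s_supp
    w.m1a = 2.5
    w.loop_open[:] = -4.0
    w.loop_sym[:] = -1.5
    w.loop_asym[:] = -2.5
    w.paired[:] = 0.05
    w.paired[strong] = 0.2
    return w


@dataclass
class SimConfig:
    """Generator parameters; fixed seeds give byte-identical outputs."""

    rng_seed: int = 0
    # catalog
    n_families: int = 8
    mirnas_per_family: int = 2
    mirna_length: int = 22
    n_utrs: int = 300
    utr_length_mean: float = 400.0
    utr_length_sd: float = 120.0
    utr_length_min: int = 150
    base_composition: tuple[float, ...] = (0.3, 0.2, 0.2, 0.3)  # A C G U
    # duplex planting
    w_star: DuplexWeights = field(default_factory=planted_duplex_weights)
    n_clash_candidates: int = 200
    n_clip_candidates: int = 600
    p_bound: float = 0.45
    clip_extension_prob: float = 1.0
    fraction_noncanonical: float = 0.4
    score_quantile: float = 0.55
    site_window: int = 26
    # binding planting
    flank_motif: str = "UGCAUG"
    motif_flank: str = "down"
    motif_offset: int = 2
    motif_prob: float = 0.85
    positional_window: int = 150
    positional_odds: float = 4.0
    n_tasks: int = 1
    task_motifs: tuple[str, ...] = ()
    # noise
    label_flip: float = 0.02
    peak_fp_rate: float = 0.05
    peak_fn_rate: float = 0.02

    def __post_init__(self) -> None:
        for p in (self.p_bound, self.clip_extension_prob,
                  self.fraction_noncanonical, self.score_quantile,
                  self.motif_prob, self.label_flip, self.peak_fp_rate,
                  self.peak_fn_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class SimulatedData:
    """A complete synthetic data set plus its ground-truth label table."""

    mirnas: list[MiRNA]
    utrs: list[UtrRecord]
    interactions: list[ChimericInteraction]
    peaks: list[AgoPeak]
    truth_sites: list[LabeledSite]
    config: SimConfig


def _random_seq(rng, length: int, comp) -> str:
    return "".join(rng.choice(list(_BASES), size=length, p=comp))


def simulate_catalog(cfg: SimConfig) -> tuple[list[MiRNA], list[UtrRecord]]:
    """Draw the miRNA catalog (families share exact 2-7 seeds) and
    background UTRs with 1-3 isoform 3' ends each."""
    rng = np.random.default_rng(cfg.rng_seed % (2**31))
    comp = np.asarray(cfg.base_composition) / sum(cfg.base_composition)
    seeds: list[str] = []
    while len(seeds) < cfg.n_families:
        s = _random_seq(rng, 6, None)
        if s not in seeds:
            seeds.append(s)
    mirnas = []
    for f, seed in enumerate(seeds):
        for j in range(cfg.mirnas_per_family):
            rest = _random_seq(rng, cfg.mirna_length - 7, None)
            seq = rest[0] + seed + rest[1:]
            mirnas.append(MiRNA(f"fam{f}-mir{j}", f"fam{f}", seq))
    utrs = []
    for k in range(cfg.n_utrs):
        length = int(max(cfg.utr_length_min,
                         rng.normal(cfg.utr_length_mean, cfg.utr_length_sd)))
        seq = _random_seq(rng, length, comp)
        n_iso = int(rng.integers(1, 4))
        internal = sorted(set(
            int(v) for v in rng.integers(60, max(61, length - 30), size=n_iso - 1)
            if 0 < v < length))
        ends = tuple(internal) + (length,)
        utrs.append(UtrRecord(f"utr{k}", seq, ends))
    return mirnas, utrs


@dataclass
class _Candidate:
    mirna: MiRNA
    tid: str
    start: int          # embedded window start
    end: int            # embedded window end
    match_start: int    # seed-complement interval within the window
    match_end: int
    source: str         # "clash" | "clip"
    intended: bool      # intended-positive (extended complementarity)
    task: str
    score: float = 0.0
    truth: bool = False
    observed: bool = False


def _build_site_fragment(rng, cfg: SimConfig, mir: MiRNA, kind: str
                         ) -> tuple[str, int, int]:
    """Site fragment 5'->3' and the seed-match interval within it.

    ``extended``: rc(miRNA 12-18) + spacer + rc(miRNA 2-8) + A (the A sits
    opposite miRNA position 1); ``seed``: rc(miRNA 2-7) + A; ``weak``:
    random background. The seed-complement interval is returned so flanks
    and anchors can be derived.
    """
    m = mir.sequence
    if kind == "weak":
        frag = _random_seq(rng, cfg.site_window, None)
        return frag, cfg.site_window // 2, cfg.site_window // 2 + 6
    seed_part = _rc(m[1:8])        # pairs miRNA 8..2
    if kind == "extended":
        supp = _rc(m[11:18])
        spacer = _random_seq(rng, int(rng.integers(1, 3)), None)
        frag = supp + spacer + seed_part + "A"
        ms = len(supp) + len(spacer) + 1   # rc(2-7) starts after the m8 base
        return frag, ms, ms + 6
    frag = seed_part + "A"
    return frag, 1, 7


def _mutate_seed(rng, frag: str, match_start: int, match_end: int) -> str:
    pos = int(rng.integers(match_start, match_end))
    old = frag[pos]
    new = rng.choice([b for b in _BASES if b != old])
    return frag[:pos] + new + frag[pos + 1:]


def _place(rng, occupied: dict, utr: UtrRecord, frag_len: int,
           near_end: bool, window: int) -> int | None:
    """Pick a non-overlapping start, optionally within ``window`` nt
    upstream of a random isoform end."""
    length = len(utr.sequence)
    if frag_len + 10 >= length:
        return None
    for _ in range(30):
        if near_end:
            e = int(rng.choice(utr.three_prime_ends))
            lo = max(0, e - window)
            hi = max(lo + 1, e - frag_len)
            start = int(rng.integers(lo, hi))
        else:
            start = int(rng.integers(0, length - frag_len))
        iv = (start - 34, start + frag_len + 34)
        if all(iv[1] <= a or iv[0] >= b for a, b in occupied[utr.transcript_id]):
            occupied[utr.transcript_id].append((start, start + frag_len))
            return start
    return None


def simulate_interactions(cfg: SimConfig, mirnas: Sequence[MiRNA],
                          utrs: Sequence[UtrRecord]
                          ) -> tuple[list[ChimericInteraction], list[AgoPeak],
                                     list[LabeledSite], list[UtrRecord]]:
    """Embed candidate sites, label them under w*, and derive evidence.

    Returns (chimeric interactions, AGO peaks, ground-truth label table,
    UTR records carrying the embedded sites). Chimeras cover observed
    CLASH positives; peaks cover observed bound sites minus the
    false-negative rate plus background false positives.
    """
    rng = np.random.default_rng((cfg.rng_seed + 101) % (2**31))
    seqs = {u.transcript_id: list(u.sequence) for u in utrs}
    occupied = {u.transcript_id: [] for u in utrs}
    utr_by_id = {u.transcript_id: u for u in utrs}
    reps = {}
    for m in mirnas:
        reps.setdefault(m.family, m)
    rep_list = sorted(reps.values(), key=lambda m: m.name)
    tasks = [f"t{k % max(1, cfg.n_tasks)}" for k in range(len(utrs))]
    task_of = {u.transcript_id: tasks[k] for k, u in enumerate(utrs)}

    cands: list[_Candidate] = []

    def embed(mir: MiRNA, kind: str, source: str, near_end: bool,
              plant_motif: bool) -> _Candidate | None:
        frag, ms, me = _build_site_fragment(rng, cfg, mir, kind)
        if kind != "weak" and source == "clash" \
                and rng.random() < cfg.fraction_noncanonical:
            frag = _mutate_seed(rng, frag, ms, me)
        utr = utr_by_id[f"utr{int(rng.integers(cfg.n_utrs))}"]
        start = _place(rng, occupied, utr, len(frag),
                       near_end, cfg.positional_window)
        if start is None:
            return None
        tid = utr.transcript_id
        seqs[tid][start:start + len(frag)] = list(frag)
        if plant_motif and cfg.flank_motif:
            mstart = start + me + cfg.motif_offset
            motif = cfg.flank_motif
            if cfg.task_motifs:
                ti = int(task_of[tid][1:]) % len(cfg.task_motifs)
                extra = cfg.task_motifs[ti]
                motif = motif + extra
            if mstart + len(motif) <= len(utr.sequence):
                seqs[tid][mstart:mstart + len(motif)] = list(motif)
        return _Candidate(mir, tid, start, start + len(frag),
                          start + ms, start + me, source,
                          kind == "extended", task_of[tid])

    # CLASH candidates: graded complementarity
    kinds = ["extended"] * 9 + ["seed"] * 9 + ["weak"] * 2
    for n in range(cfg.n_clash_candidates):
        mir = mirnas[int(rng.integers(len(mirnas)))]
        kind = kinds[int(rng.integers(len(kinds)))]
        c = embed(mir, kind, "clash", near_end=False, plant_motif=False)
        if c is not None:
            cands.append(c)

    # CLIP candidates: bound sites optionally extended, motif-planted and
    # positionally biased; unbound sites are plain seed matches
    p_near = cfg.positional_odds / (1.0 + cfg.positional_odds)
    for n in range(cfg.n_clip_candidates):
        mir = rep_list[int(rng.integers(len(rep_list)))]
        bound = rng.random() < cfg.p_bound
        kind = "extended" if (bound and rng.random() < cfg.clip_extension_prob) \
            else "seed"
        near = bound and (rng.random() < p_near)
        motif = bound and (rng.random() < cfg.motif_prob)
        c = embed(mir, kind, "clip", near_end=near, plant_motif=motif)
        if c is not None:
            c.truth = bound
            cands.append(c)

    new_utrs = [UtrRecord(u.transcript_id, "".join(seqs[u.transcript_id]),
                          u.three_prime_ends) for u in utrs]
    utr_by_id = {u.transcript_id: u for u in new_utrs}

    # score under w*, threshold CLASH candidates at the configured quantile
    clash = [c for c in cands if c.source == "clash"]
    for c in cands:
        seq = utr_by_id[c.tid].sequence
        lo = max(0, c.start - 4)
        hi = min(len(seq), c.end + 4)
        c.score = align_duplex(cfg.w_star, c.mirna.sequence, seq[lo:hi]).score
    if clash:
        tau = float(np.quantile([c.score for c in clash], cfg.score_quantile))
        for c in clash:
            c.truth = c.score >= tau

    # evidence with noise
    interactions, peaks, truth = [], [], []
    peak_n = 0
    for c in cands:
        c.observed = c.truth ^ (rng.random() < cfg.label_flip)
        anchor = c.match_end - 1
        # CLASH sites are the chimera-mapped fragment; CLIP sites are the
        # seed-match interval itself
        s0, s1 = (c.start, c.end) if c.source == "clash" \
            else (c.match_start, c.match_end)
        truth.append(LabeledSite(c.mirna.name, c.mirna.family, c.tid,
                                 s0, s1,
                                 "positive" if c.truth else "negative",
                                 c.source, c.task, anchor))
        if c.source == "clash" and c.observed:
            interactions.append(ChimericInteraction(
                c.mirna.name, c.tid, c.start, c.end,
                1 + int(rng.poisson(2.0)), 1 + int(rng.poisson(3.0))))
        emit_peak = (c.observed and not rng.random() < cfg.peak_fn_rate) \
            if (c.source == "clip" or c.truth) else False
        if not emit_peak and c.source == "clip" and not c.observed:
            emit_peak = rng.random() < cfg.peak_fp_rate
        if emit_peak:
            utr = utr_by_id[c.tid]
            ps = max(0, c.match_start - 5)
            pe = min(len(utr.sequence), c.match_end + 5)
            peaks.append(AgoPeak(c.tid, ps, pe, 5 + int(rng.poisson(10.0)),
                                 f"peak{peak_n}"))
            peak_n += 1
    return interactions, peaks, truth, new_utrs


def simulate_probe_table(cfg: SimConfig, motif: str, n_probes: int = 1200,
                         probe_len: int = 36, effect: float = 2.0,
                         plant_prob: float = 0.2,
                         experiment_id: str = "RBP1",
                         rng_seed: int | None = None) -> ProbeTable:
    """RNAcompete-style probe table: probes carrying the motif get their
    intensity shifted by ``effect`` over a standard-normal background."""
    rng = np.random.default_rng(((rng_seed if rng_seed is not None
                                  else cfg.rng_seed) + 7) % (2**31))
    probes, intensities = [], []
    for _ in range(n_probes):
        seq = _random_seq(rng, probe_len, None)
        if motif and rng.random() < plant_prob:
            pos = int(rng.integers(0, probe_len - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        x = float(rng.normal())
        if motif and motif in seq:
            x += effect
        probes.append(seq)
        intensities.append(x)
    return ProbeTable(experiment_id, tuple(probes), tuple(intensities))


def simulate_dataset(cfg: SimConfig | None = None) -> SimulatedData:
    """Catalog + interactions + peaks + ground truth in one call."""
    cfg = cfg or SimConfig()
    mirnas, utrs = simulate_catalog(cfg)
    interactions, peaks, truth, utrs = simulate_interactions(cfg, mirnas, utrs)
    return SimulatedData(mirnas=mirnas, utrs=utrs, interactions=interactions,
                         peaks=peaks, truth_sites=truth, config=cfg)


def write_dataset(data: SimulatedData, out_dir: str | Path) -> dict[str, Path]:
    """Emit the data set in every reader's external format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_fasta": out / "mirnas.fa",
        "family_table": out / "families.tsv",
        "utr_fasta": out / "utrs.fa",
        "atlas": out / "atlas.tsv",
        "interactions": out / "interactions.tsv",
        "peaks": out / "peaks.bed",
        "ground_truth": out / "ground_truth.tsv",
    }
    write_mirna_catalog(data.mirnas, paths["mirna_fasta"], paths["family_table"])
    write_utr_atlas(data.utrs, paths["utr_fasta"], paths["atlas"])
    write_interactions(data.interactions, paths["interactions"])
    write_peaks(data.peaks, paths["peaks"])
    write_labeled_sites(data.truth_sites, paths["ground_truth"])
    return paths
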