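"""Training-set construction from CLASH interactions and AGO CLIP peaks.

Positive duplex examples are chimeric-read interactions passing three
filters: the site lies in the 3'UTR, it contains a match within edit
distance 1 of the miRNA's 6-mer seed complement, and the interaction has
non-chimeric read support. AGO-bound/unbound seed matches from CLIP peaks
provide additional positives/negatives, and decoy negatives pair bound
sites with miRNAs from non-interacting seed families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .duplex import DuplexExample
from .io import AgoPeak, ChimericInteraction, InputError, MiRNA, UtrRecord

logger = logging.getLogger(__name__)

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def seed_site(mirna_seq: str) -> str:
    """The 6-mer a site must carry to match the seed: reverse complement of
    miRNA nucleotides 2-7 (1-based)."""
    if len(mirna_seq) < 8:
        raise InputError("miRNA shorter than 8 nt")
    return "".join(_RC[c] for c in reversed(mirna_seq[1:7]))


@dataclass(frozen=True)
class SeedMatch:
    """A seed-complementary match on a UTR.

    ``anchor`` is the UTR position opposite miRNA nucleotide 2 (the
    3'-most matched base for an exact match; recomputed from the edit
    alignment for indel-containing matches, ties broken 3'-most).
    """

    transcript_id: str
    match_start: int
    match_end: int
    family: str
    edit_distance: int
    anchor: int

    def __post_init__(self) -> None:
        if self.match_end - self.match_start not in (5, 6, 7):
            raise InputError("seed match window must span 5-7 nt")
        if self.edit_distance not in (0, 1):
            raise InputError("edit_distance must be 0 or 1")


@dataclass(frozen=True)
class LabeledSite:
    """A labeled (miRNA-or-family, UTR site) example."""

    mirna: str
    family: str
    transcript_id: str
    site_start: int
    site_end: int
    label: str            # "positive" | "negative"
    source: str           # "clash" | "clip"
    task: str = "default"
    anchor: int = -1      # -1: derive as site_end - 1

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise InputError(f"bad label {self.label!r}")
        if self.source not in ("clash", "clip"):
            raise InputError(f"bad source {self.source!r}")
        if not self.task:
            raise InputError("task must be non-empty")
        if self.site_start < 0 or self.site_end <= self.site_start:
            raise InputError("invalid site interval")

    @property
    def site_key(self) -> tuple[str, int, int]:
        return (self.transcript_id, self.site_start, self.site_end)

    @property
    def anchor_position(self) -> int:
        return self.anchor if self.anchor >= 0 else self.site_end - 1


def _edit_distance(a: str, b: str) -> int:
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[n]


def _edit_dp(a: str, b: str) -> list[list[int]]:
    m, n = len(a), len(b)
    D = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        D[i][0] = i
    for j in range(n + 1):
        D[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            D[i][j] = min(D[i - 1][j] + 1, D[i][j - 1] + 1,
                          D[i - 1][j - 1] + (a[i - 1] != b[j - 1]))
    return D

def _anchor_offset(window: str, seed: str, ed: int) -> int:
    """Largest 0-based window index aligned to the last seed base in an
    optimal edit alignment (falls back to the last window base when the
    last seed base is deleted)."""
    if len(window) == len(seed) or ed == 0:
        return len(window) - 1
    D = _edit_dp(window, seed)
    n = len(seed)
    best = None
    for i in range(len(window), 0, -1):
        total = D[i - 1][n - 1] + (window[i - 1] != seed[n - 1]) \
            + (len(window) - i)
        if total == ed:
            best = i - 1
            break
    return best if best is not None else len(window) - 1


def scan_seed_matches(utr: UtrRecord, mirna: MiRNA,
                      max_edit: int = 0) -> list[SeedMatch]:
    """All UTR windows within ``max_edit`` (0 or 1) of the seed complement.

    Substitutions and indels are allowed at edit distance 1 (windows of 5
    or 7 nt); overlapping hits at the same start are reported once at
    minimal edit distance (window length preference 6, 7, 5 on ties).
    """
    if max_edit not in (0, 1):
        raise InputError("max_edit must be 0 or 1")
    target = seed_site(mirna.sequence)
    seq = utr.sequence
    out = []
    if max_edit == 0:
        start = seq.find(target)
        while start != -1:
            out.append(SeedMatch(utr.transcript_id, start, start + 6,
                                 mirna.family, 0, start + 5))
            start = seq.find(target, start + 1)
        return out
    out.extend(_scan_region(seq, utr.transcript_id, mirna.family, target,
                            max_edit, 0, len(seq)))
    return out


def _scan_region(seq: str, tid: str, family: str, target: str,
                 max_edit: int, lo: int, hi: int) -> list[SeedMatch]:
    out = []
    for start in range(lo, hi):
        best = None  # (ed, length_pref, length)
        for length in (6, 7, 5):
            if start + length > hi:
                continue
            window = seq[start:start + length]
            ed = 0 if window == target else _edit_distance(window, target)
            if ed > max_edit:
                continue
            pref = {6: 0, 7: 1, 5: 2}[length]
            if best is None or (ed, pref) < (best[0], best[1]):
                best = (ed, pref, length)
        if best is not None:
            ed, _, length = best
            window = seq[start:start + length]
            anchor = start + _anchor_offset(window, target, ed)
            out.append(SeedMatch(tid, start, start + length, family, ed, anchor))
    return out


# ---------------------------------------------------------------------------
# CLASH positives
# ---------------------------------------------------------------------------

def _site_has_seed_match(utr: UtrRecord, mirna: MiRNA, start: int, end: int,
                         max_edit: int = 1) -> bool:
    target = seed_site(mirna.sequence)
    sub = utr.sequence[start:end]
    for s in range(len(sub)):
        for length in (5, 6, 7):
            if s + length > len(sub):
                continue
            if _edit_distance(sub[s:s + length], target) <= max_edit:
                return True
    return False


def clash_filter_counts(interactions: Sequence[ChimericInteraction],
                        utrs: Sequence[UtrRecord],
                        mirnas: Sequence[MiRNA],
                        max_edit: int = 1) -> dict[str, int]:
    """Survival counts after each sequential CLASH filter."""
    utr_by_id = {u.transcript_id: u for u in utrs}
    mir_by_name = {m.name: m for m in mirnas}
    counts = {"input": len(interactions), "known": 0, "in_utr": 0,
              "seed_match": 0, "supported": 0}
    for it in interactions:
        utr = utr_by_id.get(it.transcript_id)
        mir = mir_by_name.get(it.mirna_name)
        if utr is None or mir is None:
            continue
        counts["known"] += 1
        if it.site_end > len(utr.sequence):
            continue
        counts["in_utr"] += 1
        if not _site_has_seed_match(utr, mir, it.site_start, it.site_end, max_edit):
            continue
        counts["seed_match"] += 1
        if it.nonchimeric_support < 1:
            continue
        counts["supported"] += 1
    return counts


def build_clash_positives(interactions: Sequence[ChimericInteraction],
                          utrs: Sequence[UtrRecord],
                          mirnas: Sequence[MiRNA],
                          max_edit: int = 1,
                          task: str = "default") -> list[LabeledSite]:
    """Positive (miRNA, site) examples from chimeric-read interactions.

    Keeps interactions whose site (a) lies within the UTR, (b) contains a
    seed-complement match within ``max_edit``, and (c) has non-chimeric
    read support. Interactions naming unknown transcripts or miRNAs are
    skipped with a logged count.
    """
    utr_by_id = {u.transcript_id: u for u in utrs}
    mir_by_name = {m.name: m for m in mirnas}
    out, skipped = [], 0
    for it in interactions:
        utr = utr_by_id.get(it.transcript_id)
        mir = mir_by_name.get(it.mirna_name)
        if utr is None or mir is None:
            skipped += 1
            continue
        if it.site_end > len(utr.sequence):
            continue
        if not _site_has_seed_match(utr, mir, it.site_start, it.site_end, max_edit):
            continue
        if it.nonchimeric_support < 1:
            continue
        in_site = _scan_region(utr.sequence, it.transcript_id, mir.family,
                               seed_site(mir.sequence), max_edit,
                               it.site_start, it.site_end)
        anchor = min(in_site, key=lambda m: m.edit_distance).anchor \
            if in_site else it.site_end - 1
        out.append(LabeledSite(mir.name, mir.family, it.transcript_id,
                               it.site_start, it.site_end, "positive", "clash",
                               task, anchor))
    if skipped:
        logger.warning("skipped %d interactions with unknown transcript/miRNA",
                       skipped)
    return out


# ---------------------------------------------------------------------------
# CLIP positives / negatives
# ---------------------------------------------------------------------------

def _family_representatives(mirnas: Sequence[MiRNA]) -> dict[str, MiRNA]:
    reps: dict[str, MiRNA] = {}
    for m in mirnas:
        reps.setdefault(m.family, m)
    return reps


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def build_clip_examples(utrs: Sequence[UtrRecord],
                        peaks: Sequence[AgoPeak],
                        mirnas: Sequence[MiRNA],
                        require_unique_family: bool = False,
                        min_read_count: int = 1,
                        coverage: Sequence[AgoPeak] | None = None,
                        task: str = "default") -> list[LabeledSite]:
    """Label exact 6-mer seed matches by AGO peak overlap.

    A seed match overlapping a peak (``read_count >= min_read_count``) is
    positive; a match overlapping no read evidence is negative; matches
    with read evidence but no qualifying peak are discarded. ``coverage``
    optionally distinguishes "no reads" from "reads but no peak"; absent,
    peaks stand in for the read evidence. With ``require_unique_family``,
    positives are kept only when the overlapping peak contains seed
    matches of exactly one cataloged family. Output is independent of peak
    input order.
    """
    reps = _family_representatives(mirnas)
    peaks_by_tid: dict[str, list[AgoPeak]] = {}
    for p in sorted(peaks, key=lambda p: (p.transcript_id, p.start, p.end)):
        peaks_by_tid.setdefault(p.transcript_id, []).append(p)
    cov_by_tid: dict[str, list[AgoPeak]] = {}
    for p in (coverage if coverage is not None else peaks):
        cov_by_tid.setdefault(p.transcript_id, []).append(p)

    out: list[LabeledSite] = []
    for utr in utrs:
        tid = utr.transcript_id
        matches = []
        for family in sorted(reps):
            for m in scan_seed_matches(utr, reps[family], max_edit=0):
                matches.append(m)
        qual = [p for p in peaks_by_tid.get(tid, ())
                if p.read_count >= min_read_count]
        if require_unique_family:
            fams_in_peak = {
                id(p): {m.family for m in matches
                        if _overlaps(m.match_start, m.match_end, p.start, p.end)}
                for p in qual}
        for m in matches:
            hit = [p for p in qual
                   if _overlaps(m.match_start, m.match_end, p.start, p.end)]
            if hit:
                if require_unique_family and not all(
                        len(fams_in_peak[id(p)]) == 1 for p in hit):
                    continue
                label = "positive"
            else:
                any_cov = any(
                    _overlaps(m.match_start, m.match_end, c.start, c.end)
                    for c in cov_by_tid.get(tid, ()))
                if any_cov:
                    continue  # read evidence but no called peak: neither class
                label = "negative"
            out.append(LabeledSite(reps[m.family].name, m.family, tid,
                                   m.match_start, m.match_end, label, "clip",
                                   task, m.anchor))
    return out


def build_mispaired_negatives(positives: Sequence[LabeledSite],
                              mirnas: Sequence[MiRNA],
                              rng_seed: int = 0,
                              decoys_per_site: int = 1) -> list[LabeledSite]:
    """Decoy negatives pairing positive sites with miRNAs from seed
    families not interacting with that site."""
    families = sorted({m.family for m in mirnas})
    if len(families) < 2:
        raise InputError("decoy negatives need a catalog with >= 2 families")
    by_family: dict[str, list[MiRNA]] = {}
    for m in mirnas:
        by_family.setdefault(m.family, []).append(m)
    site_families: dict[tuple, set[str]] = {}
    for s in positives:
        site_families.setdefault(s.site_key, set()).add(s.family)
    rng = np.random.default_rng(rng_seed % (2**31))
    out = []
    for s in positives:
        eligible = [f for f in families if f not in site_families[s.site_key]]
        if not eligible:
            continue
        for _ in range(decoys_per_site):
            fam = eligible[int(rng.integers(len(eligible)))]
            cand = by_family[fam]
            decoy = cand[int(rng.integers(len(cand)))]
            out.append(replace(s, mirna=decoy.name, family=decoy.family,
                               label="negative"))
    return out


def sample_negatives(positives: Sequence[LabeledSite],
                     negatives: Sequence[LabeledSite],
                     clash_ratio: float = 15.0,
                     clip_ratio: float = 1.0,
                     rng_seed: int = 0) -> list[LabeledSite]:
    """Per-source negative sampling without replacement.

    CLASH negatives are sampled at ``clash_ratio`` times the CLASH
    positive count and CLIP negatives at ``clip_ratio`` times the CLIP
    positive count; short pools are taken whole with a logged warning.
    """
    rng = np.random.default_rng(rng_seed % (2**31))
    out: list[LabeledSite] = []
    for source, ratio in (("clash", clash_ratio), ("clip", clip_ratio)):
        n_pos = sum(1 for s in positives if s.source == source)
        pool = [s for s in negatives if s.source == source]
        want = int(round(ratio * n_pos))
        if want >= len(pool):
            if want > len(pool):
                logger.warning("%s negative pool (%d) smaller than requested %d",
                               source, len(pool), want)
            out.extend(pool)
        else:
            idx = rng.choice(len(pool), size=want, replace=False)
            out.extend(pool[i] for i in sorted(idx))
    return out


def holdout_by_family(examples: Sequence[LabeledSite], held_family: str,
                      known_families: Iterable[str] | None = None,
                      include_shared_sites: bool = True
                      ) -> tuple[list[LabeledSite], list[LabeledSite]]:
    """Partition examples so the held family (and, optionally, every
    example touching its sites) is entirely in the test split."""
    families = set(known_families) if known_families is not None \
        else {e.family for e in examples}
    if held_family not in families:
        raise InputError(f"unknown family {held_family!r}")
    held = [e for e in examples if e.family == held_family]
    if not held:
        logger.warning("held family %r has no examples", held_family)
    # sites *bound* by the held family drag every example touching them
    # into the test split; decoy negatives merely using a held-family
    # miRNA elsewhere do not
    held_sites = {e.site_key for e in held if e.label == "positive"}
    test, train = [], []
    for e in examples:
        if e.family == held_family or (include_shared_sites
                                       and e.site_key in held_sites):
            test.append(e)
        else:
            train.append(e)
    return train, test


# ---------------------------------------------------------------------------
# LabeledSite TSV round-trip and duplex-example extraction
# ---------------------------------------------------------------------------

def write_labeled_sites(sites: Sequence[LabeledSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# mirna\tfamily\ttranscript_id\tsite_start\tsite_end\t"
                 "label\tsource\ttask\tanchor\n")
        for s in sites:
            fh.write(f"{s.mirna}\t{s.family}\t{s.transcript_id}\t{s.site_start}"
                     f"\t{s.site_end}\t{s.label}\t{s.source}\t{s.task}"
                     f"\t{s.anchor}\n")


def read_labeled_sites(path: str | Path) -> list[LabeledSite]:
    from .io import _read_tsv_rows, _to_int
    out = []
    for lineno, f in _read_tsv_rows(path, 8, "labeled site"):
        anchor = _to_int(f[8], path, lineno, "anchor") if len(f) > 8 else -1
        out.append(LabeledSite(f[0], f[1], f[2],
                               _to_int(f[3], path, lineno, "site_start"),
                               _to_int(f[4], path, lineno, "site_end"),
                               f[5], f[6], f[7], anchor))
    return out


def make_duplex_examples(sites: Sequence[LabeledSite],
                         mirnas: Sequence[MiRNA],
                         utrs: Sequence[UtrRecord],
                         clip_ext5: int = 18,
                         clip_ext3: int = 3) -> list[DuplexExample]:
    """Extract site sequences for duplex training.

    CLASH sites use the chimera-mapped fragment interval as stored; CLIP
    seed matches are extended ``clip_ext5`` nt on the 5' side (where miRNA
    3'-end pairing falls) and ``clip_ext3`` nt on the 3' side, clipped to
    UTR bounds.
    """
    mir_by_name = {m.name: m for m in mirnas}
    utr_by_id = {u.transcript_id: u for u in utrs}
    out = []
    for s in sites:
        mir = mir_by_name.get(s.mirna)
        utr = utr_by_id.get(s.transcript_id)
        if mir is None or utr is None:
            raise InputError(f"unknown miRNA/transcript for site {s}")
        if s.source == "clip":
            start = max(0, s.site_start - clip_ext5)
            end = min(len(utr.sequence), s.site_end + clip_ext3)
        else:
            start, end = s.site_start, s.site_end
        out.append(DuplexExample(mir.name, mir.family, mir.sequence,
                                 utr.sequence[start:end],
                                 +1 if s.label == "positive" else -1,
                                 s.source, s.task))
    return out
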