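"""Typed readers and writers for the external tables and sequence files.

Coordinate conventions used throughout the package:

* all positions are 0-based, half-open intervals;
* all positions live in 3'UTR space, where position 0 is the first base
  3' of the stop codon;
* sequences are stored in the RNA alphabet (``T`` is normalized to ``U``
  on read); ``N`` is allowed in UTR sequences and never participates in
  any k-mer or base-pair feature.

Genome-to-UTR projection is out of scope: positional inputs (peaks,
chimeric sites, isoform 3' ends) are required in UTR coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")
UTR_ALPHABET = frozenset("ACGUN")


class InputError(ValueError):
    """Raised when an external input file violates its declared schema."""


def normalize_rna(seq: str, *, allow_n: bool = False, context: str = "") -> str:
    """Uppercase a nucleotide string and convert DNA ``T`` to RNA ``U``."""
    s = str(seq).strip().upper().replace("T", "U")
    alphabet = UTR_ALPHABET if allow_n else RNA_ALPHABET
    bad = set(s) - alphabet
    if not s:
        raise InputError(f"empty sequence{': ' + context if context else ''}")
    if bad:
        raise InputError(
            f"illegal characters {sorted(bad)} in sequence"
            f"{': ' + context if context else ''}"
        )
    return s


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA with its seed-family assignment."""

    name: str
    family: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence",
                           normalize_rna(self.sequence, context=self.name))
        if not self.name:
            raise InputError("miRNA name must be non-empty")
        if not self.family:
            raise InputError(f"miRNA {self.name}: family must be non-empty")
        if not 18 <= len(self.sequence) <= 27:
            raise InputError(
                f"miRNA {self.name}: length {len(self.sequence)} outside 18-27"
            )

    @property
    def seed(self) -> str:
        """Nucleotides 2-7 (1-based), the 6-mer seed region."""
        return self.sequence[1:7]


@dataclass(frozen=True)
class UtrRecord:
    """A 3'UTR sequence with the 3'-end positions of its isoforms.

    ``three_prime_ends`` holds, for each polyadenylation isoform, the UTR
    coordinate one past the last transcribed base (so an end equal to
    ``len(sequence)`` is the longest isoform).
    """

    transcript_id: str
    sequence: str
    three_prime_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence",
            normalize_rna(self.sequence, allow_n=True, context=self.transcript_id))
        ends = tuple(int(e) for e in self.three_prime_ends)
        object.__setattr__(self, "three_prime_ends", ends)
        if not ends:
            raise InputError(f"{self.transcript_id}: no 3' ends")
        if any(b <= a for a, b in zip(ends, ends[1:])):
            raise InputError(f"{self.transcript_id}: 3' ends not strictly increasing")
        if ends[0] <= 0 or ends[-1] > len(self.sequence):
            raise InputError(
                f"{self.transcript_id}: 3' end outside (0, {len(self.sequence)}]"
            )


@dataclass(frozen=True)
class AgoPeak:
    """A called Argonaute binding interval on a 3'UTR."""

    transcript_id: str
    start: int
    end: int
    read_count: int = 1
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise InputError(
                f"peak {self.transcript_id}:{self.start}-{self.end}: invalid interval"
            )
        if self.read_count < 0:
            raise InputError(f"peak {self.transcript_id}: negative read_count")


@dataclass(frozen=True)
class ChimericInteraction:
    """A miRNA-site interaction evidenced by a chimeric (hybrid) read."""

    mirna_name: str
    transcript_id: str
    site_start: int
    site_end: int
    chimeric_count: int
    nonchimeric_support: int

    def __post_init__(self) -> None:
        if self.site_start < 0 or self.site_end <= self.site_start:
            raise InputError(
                f"interaction {self.mirna_name}/{self.transcript_id}: invalid interval"
            )
        if self.chimeric_count < 1:
            raise InputError(
                f"interaction {self.mirna_name}/{self.transcript_id}: "
                "chimeric_count must be >= 1"
            )
        if self.nonchimeric_support < 0:
            raise InputError(
                f"interaction {self.mirna_name}/{self.transcript_id}: "
                "negative nonchimeric_support"
            )


@dataclass(frozen=True)
class ProbeTable:
    """One RNAcompete-style experiment: probe sequences with intensities."""

    experiment_id: str
    probes: tuple[str, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.probes) != len(self.intensities):
            raise InputError(f"{self.experiment_id}: probes/intensities length mismatch")
        for i, (p, x) in enumerate(zip(self.probes, self.intensities)):
            if not p:
                raise InputError(f"{self.experiment_id} row {i}: empty probe")
            if not math.isfinite(x):
                raise InputError(
                    f"{self.experiment_id} row {i}: non-finite intensity"
                )


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _read_tsv_rows(path: str | Path, n_cols: int, what: str):
    """Yield (line_number, fields) from a tab-separated file, skipping '#' lines."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < n_cols:
                raise InputError(
                    f"{path} line {lineno}: expected {n_cols} {what} columns, "
                    f"got {len(fields)}"
                )
            yield lineno, fields


def _to_int(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise InputError(f"{path} line {lineno}: bad {what} {value!r}") from None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_mirna_catalog(fasta_path: str | Path,
                       family_table_path: str | Path) -> list[MiRNA]:
    """Read a miRNA FASTA plus a tab-separated name -> family table.

    Every FASTA record must have a family row; missing mappings and
    duplicate names are errors that name the offending records.
    """
    families: dict[str, str] = {}
    for _, fields in _read_tsv_rows(family_table_path, 2, "family table"):
        families[fields[0]] = fields[1]
    catalog: list[MiRNA] = []
    seen: set[str] = set()
    missing: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate miRNA name {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        if rec.id not in families:
            missing.append(rec.id)
            continue
        catalog.append(MiRNA(rec.id, families[rec.id], str(rec.seq)))
    if missing:
        raise InputError(
            "miRNAs missing from family table: " + ", ".join(sorted(missing))
        )
    return catalog


def read_utr_atlas(fasta_path: str | Path,
                   ends_table_path: str | Path | None = None) -> list[UtrRecord]:
    """Read 3'UTR sequences plus an isoform 3'-end atlas table.

    The atlas is a tab-separated (transcript_id, end_position) table in UTR
    coordinates. Ends are sorted and deduplicated per transcript; a
    transcript with no atlas rows gets the single end ``len(sequence)``.
    """
    ends: dict[str, set[int]] = {}
    if ends_table_path is not None:
        for lineno, fields in _read_tsv_rows(ends_table_path, 2, "atlas"):
            tid = fields[0]
            end = _to_int(fields[1], ends_table_path, lineno, "end_position")
            ends.setdefault(tid, set()).add(end)
    records: list[UtrRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq)
        tid = rec.id
        if tid in ends:
            sorted_ends = tuple(sorted(ends[tid]))
            if sorted_ends[-1] > len(seq):
                raise InputError(
                    f"{tid}: atlas 3' end {sorted_ends[-1]} beyond UTR length {len(seq)}"
                )
        else:
            sorted_ends = (len(seq),)
        records.append(UtrRecord(tid, seq, sorted_ends))
    return records


def read_interactions(tsv_path: str | Path) -> list[ChimericInteraction]:
    """Read the chimeric-interaction table.

    Columns: mirna_name, transcript_id, site_start, site_end,
    chimeric_count, nonchimeric_support.
    """
    out = []
    for lineno, f in _read_tsv_rows(tsv_path, 6, "interaction"):
        try:
            out.append(ChimericInteraction(
                f[0], f[1],
                _to_int(f[2], tsv_path, lineno, "site_start"),
                _to_int(f[3], tsv_path, lineno, "site_end"),
                _to_int(f[4], tsv_path, lineno, "chimeric_count"),
                _to_int(f[5], tsv_path, lineno, "nonchimeric_support"),
            ))
        except InputError as exc:
            raise InputError(f"{tsv_path} line {lineno}: {exc}") from None
    return out


def read_peaks(bed_path: str | Path) -> list[AgoPeak]:
    """Read AGO peaks in a BED4+score dialect.

    Columns: transcript_id, start, end, name, read_count (UTR coordinates).
    """
    out = []
    for lineno, f in _read_tsv_rows(bed_path, 5, "peak"):
        try:
            out.append(AgoPeak(
                f[0],
                _to_int(f[1], bed_path, lineno, "start"),
                _to_int(f[2], bed_path, lineno, "end"),
                _to_int(f[4], bed_path, lineno, "read_count"),
                f[3],
            ))
        except InputError as exc:
            raise InputError(f"{bed_path} line {lineno}: {exc}") from None
    return out


def read_probe_table(tsv_path: str | Path,
                     experiment_id: str | None = None) -> ProbeTable:
    """Read one probe-intensity table (probe_sequence, intensity)."""
    if experiment_id is None:
        experiment_id = Path(tsv_path).stem
    probes, intensities = [], []
    for lineno, f in _read_tsv_rows(tsv_path, 2, "probe"):
        try:
            x = float(f[1])
        except ValueError:
            raise InputError(f"{tsv_path} line {lineno}: bad intensity {f[1]!r}") from None
        if not math.isfinite(x):
            raise InputError(
                f"{tsv_path} line {lineno}: non-finite intensity for probe {f[0]!r}"
            )
        probes.append(normalize_rna(f[0], context=f"{tsv_path} line {lineno}"))
        intensities.append(x)
    return ProbeTable(experiment_id, tuple(probes), tuple(intensities))


def read_probe_tables(dir_path: str | Path) -> list[ProbeTable]:
    """Read every ``*.tsv`` probe table in a directory (one per experiment)."""
    paths = sorted(Path(dir_path).glob("*.tsv"))
    return [read_probe_table(p) for p in paths]


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_mirna_catalog(mirnas: Sequence[MiRNA], fasta_path: str | Path,
                        family_table_path: str | Path) -> None:
    write_fasta(((m.name, m.sequence) for m in mirnas), fasta_path)
    with open(family_table_path, "w") as fh:
        fh.write("# name\tfamily\n")
        for m in mirnas:
            fh.write(f"{m.name}\t{m.family}\n")


def write_utr_atlas(utrs: Sequence[UtrRecord], fasta_path: str | Path,
                    ends_table_path: str | Path) -> None:
    write_fasta(((u.transcript_id, u.sequence) for u in utrs), fasta_path)
    with open(ends_table_path, "w") as fh:
        fh.write("# transcript_id\tend_position\n")
        for u in utrs:
            for e in u.three_prime_ends:
                fh.write(f"{u.transcript_id}\t{e}\n")


def write_interactions(interactions: Sequence[ChimericInteraction],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# mirna_name\ttranscript_id\tsite_start\tsite_end\t"
                 "chimeric_count\tnonchimeric_support\n")
        for it in interactions:
            fh.write(f"{it.mirna_name}\t{it.transcript_id}\t{it.site_start}\t"
                     f"{it.site_end}\t{it.chimeric_count}\t{it.nonchimeric_support}\n")


def write_peaks(peaks: Sequence[AgoPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# transcript_id\tstart\tend\tname\tread_count\n")
        for p in peaks:
            fh.write(f"{p.transcript_id}\t{p.start}\t{p.end}\t{p.name}\t{p.read_count}\n")


def write_probe_table(table: ProbeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# probe_sequence\tintensity\n")
        for p, x in zip(table.probes, table.intensities):
            fh.write(f"{p}\t{x!r}\n")
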