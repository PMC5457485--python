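"""Readers and writers for the plain-text genomic formats the pipeline consumes.

Every coordinate in this package is 0-based half-open (BED convention).
1-based numbers appear only in user-facing error messages where they refer
to file line numbers, never to genomic positions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

STRANDS = ("+", "-", ".")
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_SEQ_ALPHABET = frozenset("ACGTN")


class BedParseError(ValueError):
    """Raised for malformed BED lines; message carries the 1-based line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span, the atom of all peak and hit sets."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome token {self.chrom!r}")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end {self.end} must exceed start {self.start}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class SequenceRecord:
    """A named DNA sequence with the genomic offset of its first base.

    ``offset`` lets hit coordinates found on an excised sequence (e.g. a
    peak's sequence) map back onto genome coordinates; whole-chromosome
    records use offset 0.
    """

    id: str
    sequence: str
    offset: int = 0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters outside ACGTN: {sorted(bad)}"
            )
        if len(self.sequence) == 0:
            raise ValueError(f"record {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position probability matrix with background, scored as log2 odds.

    Rows are fixed in A, C, G, T order.  Probabilities include the
    pseudocount applied when the matrix was built from counts, so every
    entry is strictly positive and log-odds are finite.
    """

    motif_id: str
    probabilities: np.ndarray  # 4 x L
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.8

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.shape[0] != 4:
            raise ValueError("probability matrix must have 4 rows (A,C,G,T)")
        colsums = self.probabilities.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: columns do not sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.motif_id}: background does not sum to 1")

    @property
    def length(self) -> int:
        return self.probabilities.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x L matrix of log2(p / background); -inf where p is 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probabilities / self.background[:, None])

    def score_range(self) -> tuple[float, float]:
        """(min, max) attainable log-odds score over all length-L words."""
        lo = self.log_odds()
        return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = 0.8,
    ) -> "PWM":
        """Convert a 4 x L count matrix to probabilities.

        The pseudocount is split across bases proportionally to the
        background before per-column normalisation.
        """
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError("count matrix must have 4 rows (A,C,G,T)")
        if (counts < 0).any():
            raise ValueError(f"{motif_id}: negative counts")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        padded = counts + pseudocount * bg[:, None]
        colsums = padded.sum(axis=0)
        if (colsums == 0).any():
            raise ValueError(f"{motif_id}: empty column with zero pseudocount")
        return cls(motif_id, padded / colsums, bg, pseudocount)


class CutProfile:
    """Per-chromosome, per-strand base-resolution counts of DNase I cut 5' ends.

    Internally each (chrom, strand) holds a pair of parallel arrays
    (sorted positions, counts) so window queries are two binary searches.
    """

    def __init__(self) -> None:
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self.total_cuts: int = 0

    @classmethod
    def from_positions(
        cls, cuts: dict[tuple[str, str], Iterable[int]]
    ) -> "CutProfile":
        """Build from raw (possibly repeated) cut positions per (chrom, strand)."""
        prof = cls()
        for key, positions in cuts.items():
            pos = np.asarray(list(positions), dtype=np.int64)
            if pos.size == 0:
                continue
            uniq, counts = np.unique(pos, return_counts=True)
            prof._data[key] = (uniq, counts)
            prof.total_cuts += int(counts.sum())
        return prof

    @classmethod
    def from_dense(cls, dense: dict[tuple[str, str], np.ndarray]) -> "CutProfile":
        """Build from per-(chrom, strand) dense per-base count arrays."""
        prof = cls()
        for key, counts in dense.items():
            counts = np.asarray(counts)
            pos = np.flatnonzero(counts)
            if pos.size == 0:
                continue
            cnt = counts[pos].astype(np.int64)
            prof._data[key] = (pos.astype(np.int64), cnt)
            prof.total_cuts += int(cnt.sum())
        return prof

    @classmethod
    def merge(cls, profiles: Sequence["CutProfile"]) -> "CutProfile":
        """Pool cut counts across profiles (e.g. replicates of one condition)."""
        merged = cls()
        keys = {k for p in profiles for k in p._data}
        for key in sorted(keys):
            parts_pos = [p._data[key][0] for p in profiles if key in p._data]
            parts_cnt = [p._data[key][1] for p in profiles if key in p._data]
            pos = np.concatenate(parts_pos)
            cnt = np.concatenate(parts_cnt)
            order = np.argsort(pos, kind="stable")
            pos, cnt = pos[order], cnt[order]
            uniq, idx = np.unique(pos, return_index=True)
            summed = np.add.reduceat(cnt, idx)
            merged._data[key] = (uniq, summed)
            merged.total_cuts += int(summed.sum())
        return merged

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._data)

    def chroms(self) -> list[str]:
        return sorted({c for c, _ in self._data})

    def counts_in(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> int:
        """Total cuts with position in [start, end); both strands if None."""
        strands = ("+", "-") if strand is None else (strand,)
        total = 0
        for s in strands:
            entry = self._data.get((chrom, s))
            if entry is None:
                continue
            pos, cnt = entry
            lo, hi = np.searchsorted(pos, (start, end))
            total += int(cnt[lo:hi].sum())
        return total

    def window_array(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> np.ndarray:
        """Dense per-base counts over [start, end); both strands summed if None.

        Positions before base 0 of the chromosome contribute nothing.
        """
        width = end - start
        out = np.zeros(width, dtype=np.int64)
        strands = ("+", "-") if strand is None else (strand,)
        for s in strands:
            entry = self._data.get((chrom, s))
            if entry is None:
                continue
            pos, cnt = entry
            lo, hi = np.searchsorted(pos, (start, end))
            if hi > lo:
                out[pos[lo:hi] - start] += cnt[lo:hi]
        return out

    def to_bed_records(self) -> list[GenomicInterval]:
        """One single-base record per cut event (counts expanded)."""
        records = []
        for (chrom, strand), (pos, cnt) in sorted(self._data.items()):
            for p, c in zip(pos.tolist(), cnt.tolist()):
                records.extend(
                    GenomicInterval(chrom, p, p + 1, strand=strand)
                    for _ in range(c)
                )
        records.sort(key=lambda iv: (iv.chrom, iv.start, iv.strand))
        return records


# ---------------------------------------------------------------------------
# BED


def read_bed(path, expect_strand: bool = False) -> list[GenomicInterval]:
    """Parse a BED3/BED6 file into intervals, in file order.

    track/browser/comment lines are skipped.  Malformed lines raise
    :class:`BedParseError` naming the 1-based line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates"
                ) from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedParseError(f"line {lineno}: non-numeric score") from None
            strand = fields[5] if len(fields) > 5 else "."
            if expect_strand and (len(fields) < 6 or strand == "."):
                raise BedParseError(f"line {lineno}: strand column required")
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand)
                )
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    """Write BED with as many optional columns as are populated consistently."""
    has_name = [iv.name is not None for iv in intervals]
    has_score = [iv.score is not None for iv in intervals]
    has_strand = [iv.strand != "." for iv in intervals]
    for flags, label in ((has_name, "name"), (has_score, "score"), (has_strand, "strand")):
        if any(flags) and not all(flags):
            raise ValueError(f"mixed populated/unpopulated {label} across records")
    n_cols = 3
    if any(has_strand):
        n_cols = 6
    elif any(has_score):
        n_cols = 5
    elif any(has_name):
        n_cols = 4
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if n_cols >= 4:
                fields.append(iv.name if iv.name is not None else ".")
            if n_cols >= 5:
                fields.append(_format_score(iv.score) if iv.score is not None else ".")
            if n_cols >= 6:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def _format_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA; ids are the first whitespace token after '>'."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# JASPAR-style PFM


def read_pwm(
    path,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.8,
) -> list[PWM]:
    """Read JASPAR-style count blocks and convert to probability matrices."""
    with open(path) as fh:
        text = fh.read()
    parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
    pwms = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in _BASES], dtype=float)
        lengths = {len(m.counts[b]) for b in _BASES}
        if len(lengths) != 1:
            raise ValueError(f"{m.matrix_id}: rows of unequal length")
        motif_id = m.matrix_id or m.name
        pwms.append(PWM.from_counts(motif_id, counts, background, pseudocount))
    return pwms


def write_pwm_counts(counts_by_id: dict[str, np.ndarray], path) -> None:
    """Write integer count matrices as JASPAR PFM text."""
    with open(path, "w") as fh:
        for motif_id, counts in counts_by_id.items():
            fh.write(f">{motif_id} {motif_id}\n")
            for base, row in zip(_BASES, np.asarray(counts)):
                vals = " ".join(str(int(v)) for v in row)
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Genome sizes, cut-site BED, TSS tables


def read_genome_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path} line {lineno}: expected chrom<TAB>length")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_genome_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def load_cut_profile(path_bed, genome_sizes: dict[str, int]) -> CutProfile:
    """Accumulate strand-specific single-base cut records into a profile.

    Each BED record must be exactly 1 bp wide with a strand; the position is
    the cut's 5' end as placed by the upstream preprocessor.
    """
    raw: dict[tuple[str, str], list[int]] = {}
    for i, iv in enumerate(read_bed(path_bed, expect_strand=True), start=1):
        if iv.width != 1:
            raise ValueError(f"record {i}: cut interval wider than 1 bp")
        if iv.chrom not in genome_sizes:
            raise ValueError(f"record {i}: unknown chromosome {iv.chrom!r}")
        if iv.start >= genome_sizes[iv.chrom]:
            raise ValueError(
                f"record {i}: position {iv.start} beyond {iv.chrom} length"
            )
        raw.setdefault((iv.chrom, iv.strand), []).append(iv.start)
    return CutProfile.from_positions(raw)


def read_tss_table(path) -> list[GenomicInterval]:
    """TSS table as BED6: name = gene symbol, start = TSS (1-bp records ok)."""
    rows = read_bed(path, expect_strand=False)
    for iv in rows:
        if iv.name is None:
            raise ValueError("TSS table records need a gene name (column 4)")
    return rows
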