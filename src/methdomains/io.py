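"""Readers, writers and containers for per-CpG methylation data.

The central container is :class:`MethylationTrack`, an ordered per-chromosome
collection of :class:`CpGCall` records as produced by WGBS methylation
extractors (MethylDackel-style 6-column bedGraph: chrom, start, end, rate%,
n_methylated, n_unmethylated).  A CpG dyad is addressed by the 0-based
position of the C of the CG dinucleotide on the plus strand; coordinates are
0-based half-open everywhere.

Counts are authoritative: when a row carries read counts, the (possibly
rounded) rate column is recomputed from them and only checked for gross
inconsistency (> 0.5 percentage points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "CpGCall",
    "MethylationTrack",
    "GenomeSequence",
    "Region",
    "RegionSet",
    "MergeResult",
    "ParseError",
    "ValidationError",
    "read_methylation_table",
    "write_methylation_table",
    "merge_dyad_strands",
    "filter_coverage",
    "enumerate_cpg_sites",
    "read_fasta",
    "read_regions",
    "write_regions",
    "write_domains",
    "clone_matrix_rate",
]

RATE_TOLERANCE = 0.5  # percentage points allowed between file rate and counts


class ParseError(ValueError):
    """A malformed input row; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a contract."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpGCall:
    """Methylation evidence for one CpG dyad.

    ``pos`` is the 0-based plus-strand position of the C of the CG
    dinucleotide.  ``rate`` is a percentage in [0, 100]; when coverage is
    positive it always equals ``100 * n_meth / coverage``.
    """

    chrom: str
    pos: int
    n_meth: int
    n_unmeth: int
    rate: float

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValidationError(f"negative counts at {self.chrom}:{self.pos}")
        if not 0.0 <= self.rate <= 100.0:
            raise ValidationError(
                f"rate {self.rate} outside [0, 100] at {self.chrom}:{self.pos}"
            )
        if self.coverage > 0:
            expected = 100.0 * self.n_meth / self.coverage
            if abs(expected - self.rate) > RATE_TOLERANCE:
                raise ValidationError(
                    f"rate {self.rate} inconsistent with counts "
                    f"{self.n_meth}/{self.n_unmeth} at {self.chrom}:{self.pos}"
                )

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @classmethod
    def from_counts(cls, chrom: str, pos: int, n_meth: int, n_unmeth: int) -> "CpGCall":
        cov = n_meth + n_unmeth
        rate = 100.0 * n_meth / cov if cov > 0 else 0.0
        return cls(chrom, pos, n_meth, n_unmeth, rate)


class MethylationTrack:
    """Per-chromosome ordered, duplicate-free collection of CpG calls."""

    def __init__(self, calls: Iterable[CpGCall]):
        by_chrom: dict[str, list[CpGCall]] = {}
        for call in calls:
            by_chrom.setdefault(call.chrom, []).append(call)
        for chrom, chrom_calls in by_chrom.items():
            chrom_calls.sort(key=lambda c: c.pos)
            for a, b in zip(chrom_calls, chrom_calls[1:]):
                if a.pos == b.pos:
                    raise ValidationError(
                        f"duplicate CpG position {chrom}:{a.pos}"
                    )
        self._by_chrom = by_chrom

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def calls(self, chrom: str) -> list[CpGCall]:
        return list(self._by_chrom.get(chrom, []))

    def get(self, chrom: str, pos: int) -> CpGCall | None:
        chrom_calls = self._by_chrom.get(chrom)
        if not chrom_calls:
            return None
        lo, hi = 0, len(chrom_calls)
        while lo < hi:
            mid = (lo + hi) // 2
            if chrom_calls[mid].pos < pos:
                lo = mid + 1
            else:
                hi = mid
        if lo < len(chrom_calls) and chrom_calls[lo].pos == pos:
            return chrom_calls[lo]
        return None

    def __iter__(self) -> Iterator[CpGCall]:
        for chrom in self.chroms:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationTrack):
            return NotImplemented
        return list(self) == list(other)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (c.chrom, c.pos, c.pos + 1, c.rate, c.n_meth, c.n_unmeth)
            for c in self
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "rate", "n_meth", "n_unmeth"]
        )


class GenomeSequence(Mapping[str, str]):
    """chrom -> uppercase nucleotide string over {A, C, G, T, N}."""

    _ALPHABET = set("ACGTN")

    def __init__(self, seqs: Mapping[str, str]):
        cleaned = {}
        for chrom, seq in seqs.items():
            seq = seq.upper()
            if set(seq) - self._ALPHABET:
                # non-standard IUPAC codes collapse to N
                seq = "".join(b if b in self._ALPHABET else "N" for b in seq)
            cleaned[chrom] = seq
        self._seqs = cleaned

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValidationError(
                f"window {chrom}:{start}-{end} outside chromosome bounds "
                f"(length {len(seq)})"
            )
        return seq[start:end]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"region {self.chrom}:{self.start}-{self.end} has start >= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionSet:
    """Sorted intervals (0-based half-open), e.g. DHS peaks or called domains."""

    def __init__(self, regions: Iterable[Region]):
        self._regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def _chrom_index(self, chrom: str) -> tuple[np.ndarray, np.ndarray] | None:
        """(sorted starts, running max of ends) per chromosome, built lazily."""
        if self._index is None:
            self._index = {}
            by_chrom: dict[str, list[Region]] = {}
            for r in self._regions:
                by_chrom.setdefault(r.chrom, []).append(r)
            for c, regs in by_chrom.items():
                starts = np.array([r.start for r in regs], dtype=np.int64)
                ends = np.maximum.accumulate(
                    np.array([r.end for r in regs], dtype=np.int64)
                )
                self._index[c] = (starts, ends)
        return self._index.get(chrom)

    def __iter__(self) -> Iterator[Region]:
        return iter(self._regions)

    def __len__(self) -> int:
        return len(self._regions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self._regions == other._regions

    def regions(self, chrom: str | None = None) -> list[Region]:
        if chrom is None:
            return list(self._regions)
        return [r for r in self._regions if r.chrom == chrom]

    def contains(self, chrom: str, pos: int) -> bool:
        idx = self._chrom_index(chrom)
        if idx is None:
            return False
        starts, max_ends = idx
        i = int(np.searchsorted(starts, pos, side="right"))
        return i > 0 and int(max_ends[i - 1]) > pos

    def overlapping(self, chrom: str, start: int, end: int) -> list[Region]:
        return [
            r for r in self.regions(chrom) if r.start < end and start < r.end
        ]


# ---------------------------------------------------------------------------
# methylation table IO
# ---------------------------------------------------------------------------

def read_methylation_table(path: str | Path, dialect: str = "bedgraph6") -> MethylationTrack:
    """Read a 6-column methylation bedGraph into a validated track.

    Columns: chrom, start, end, rate%, n_methylated, n_unmethylated.
    ``track``/``#`` header lines are skipped.  The rate column is recomputed
    from the counts when coverage is positive (counts are authoritative).
    """
    if dialect != "bedgraph6":
        raise ValueError(f"unknown dialect {dialect!r}")
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                rate = float(fields[3])
                n_meth, n_unmeth = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if not 0.0 <= rate <= 100.0:
                raise ValidationError(
                    f"{path}:{lineno}: rate {rate} outside [0, 100]"
                )
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end <= start")
            cov = n_meth + n_unmeth
            if cov > 0:
                recomputed = 100.0 * n_meth / cov
                if abs(recomputed - rate) > RATE_TOLERANCE:
                    raise ValidationError(
                        f"{path}:{lineno}: rate {rate} inconsistent with "
                        f"counts {n_meth}/{n_unmeth}"
                    )
                rate = recomputed
            calls.append(CpGCall(chrom, start, n_meth, n_unmeth, rate))
    return MethylationTrack(calls)


def write_methylation_table(track: MethylationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in track:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.pos + 1}\t{c.rate:g}\t{c.n_meth}\t{c.n_unmeth}\n"
            )


@dataclass
class MergeResult:
    track: MethylationTrack
    warnings: list[str] = field(default_factory=list)


def merge_dyad_strands(track: MethylationTrack, genome: GenomeSequence) -> MergeResult:
    """Sum plus- and minus-strand calls of each CpG dyad onto the C position.

    A call at the G of a genomic CG (position p where genome[p-1:p+1] == CG)
    is folded into the dyad at p-1.  Calls whose genomic context is not part
    of a CG are preserved untouched and reported in the warning list.  Total
    methylated/unmethylated counts over CG-context calls are conserved.
    """
    merged_counts: dict[tuple[str, int], list[int]] = {}
    passthrough: list[CpGCall] = []
    warnings: list[str] = []
    for call in track:
        seq = genome[call.chrom]
        p = call.pos
        if p + 1 < len(seq) and seq[p] == "C" and seq[p + 1] == "G":
            key = (call.chrom, p)
        elif p >= 1 and seq[p - 1] == "C" and seq[p] == "G":
            key = (call.chrom, p - 1)
        else:
            warnings.append(
                f"{call.chrom}:{p} is not part of a CG dinucleotide; left unmerged"
            )
            passthrough.append(call)
            continue
        bucket = merged_counts.setdefault(key, [0, 0])
        bucket[0] += call.n_meth
        bucket[1] += call.n_unmeth
    merged = [
        CpGCall.from_counts(chrom, pos, nm, nu)
        for (chrom, pos), (nm, nu) in merged_counts.items()
    ]
    return MergeResult(MethylationTrack(merged + passthrough), warnings)


def filter_coverage(track: MethylationTrack, min_cov: int = 5) -> MethylationTrack:
    """Retain only calls with coverage >= min_cov (default the 5x validity cut)."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    return MethylationTrack(c for c in track if c.coverage >= min_cov)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    with open(path) as fh:
        seqs = {title.split()[0]: seq for title, seq in SimpleFastaParser(fh)}
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def enumerate_cpg_sites(genome: GenomeSequence) -> dict[str, np.ndarray]:
    """0-based positions p with genome[p] == C and genome[p+1] == G, per chromosome."""
    out = {}
    for chrom in genome:
        arr = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        if arr.size < 2:
            out[chrom] = np.empty(0, dtype=np.int64)
            continue
        is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        out[chrom] = np.flatnonzero(is_cg).astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# BED region IO
# ---------------------------------------------------------------------------

def read_regions(path: str | Path) -> RegionSet:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else None
            score = float(fields[4]) if len(fields) > 4 else None
            regions.append(Region(fields[0], start, end, name, score))
    return RegionSet(regions)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            cols = [r.chrom, str(r.start), str(r.end)]
            if r.name is not None:
                cols.append(r.name)
                if r.score is not None:
                    cols.append(f"{r.score:g}")
            fh.write("\t".join(cols) + "\n")


def write_domains(domains: Sequence, path: str | Path) -> None:
    """Write called domains as BED5: name = kind (HypoMD/HyperMD), score = n_qualifying."""
    names = {"hypo": "HypoMD", "hyper": "HyperMD"}
    with open(path, "w") as fh:
        for d in domains:
            kind = getattr(d.kind, "value", d.kind)
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{names[kind]}\t{d.n_qualifying}\n"
            )


# ---------------------------------------------------------------------------
# clone matrices (bisulfite PCR clone panels)
# ---------------------------------------------------------------------------

def clone_matrix_rate(matrix: pd.DataFrame) -> pd.Series:
    """Per-site methylation rate from a clones x sites matrix.

    Entries are 1 (methylated), 0 (unmethylated) or NaN (missing).  Rate is
    100 * methylated / informative clones; sites with zero informative clones
    come back as NaN (undetermined).
    """
    if matrix.size == 0:
        raise ValidationError("empty clone matrix")
    values = matrix.to_numpy(dtype=float)
    bad = values[~np.isnan(values)]
    if not np.isin(bad, (0.0, 1.0)).all():
        raise ValidationError("clone matrix entries must be 0, 1 or missing")
    informative = np.sum(~np.isnan(values), axis=0)
    meth = np.nansum(values, axis=0)
    with np.errstate(invalid="ignore"):
        rates = np.where(informative > 0, 100.0 * meth / informative, np.nan)
    return pd.Series(rates, index=matrix.columns, name="rate")
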