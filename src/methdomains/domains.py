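"""Segmentation of a methylation track into hypo- and hypermethylated domains.

A hypomethylated domain (HypoMD) is any stretch of ten or more hypomethylated
CpG dyads (methylation rate < 40%) containing no more than four interleaving
non-hypomethylated (rate >= 40%) or undetermined dyads; a hypermethylated
domain (HyperMD) is defined analogously with rate > 60% and its complement.
An "undetermined" dyad is a genomic CG with no valid call after the coverage
filter (unsampled, unmappable, or coverage below the cut).

The interleaving limit is read as a TOTAL budget per domain (a
consecutive-run variant is available via ``CallerParams.interleave_mode``).
Scanning is greedy left-to-right: among feasible segments the leftmost start
wins, then the longest extension; the next search resumes after the emitted
segment.  ``call_domains_bruteforce`` is an independent reference
implementation of the same selection rule by exhaustive interval
enumeration, used to cross-check the scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GenomeSequence, MethylationTrack, Region, RegionSet, enumerate_cpg_sites

__all__ = [
    "DyadClass",
    "DomainKind",
    "Domain",
    "CallerParams",
    "classify_dyads",
    "call_domains",
    "call_domains_bruteforce",
    "call_all",
    "domain_summaries",
]


class DyadClass(Enum):
    QUALIFYING = "qualifying"
    NONQUALIFYING = "nonqualifying"
    UNDETERMINED = "undetermined"


class DomainKind(Enum):
    HYPO = "hypo"
    HYPER = "hyper"


@dataclass(frozen=True)
class CallerParams:
    """Stretch-definition parameters.

    Thresholds are strict: a dyad qualifies for a HypoMD iff rate < 40
    and for a HyperMD iff rate > 60; rates exactly at a threshold are
    non-qualifying for both kinds.
    """

    min_qualifying: int = 10
    max_interleaved: int = 4
    hypo_threshold: float = 40.0
    hyper_threshold: float = 60.0
    min_cov: int = 5
    interleave_mode: str = "total"  # or "run": limit on consecutive bad dyads

    def __post_init__(self) -> None:
        if not (0 < self.hypo_threshold < 100 and 0 < self.hyper_threshold < 100):
            raise ValueError("thresholds must lie in (0, 100)")
        if self.min_qualifying < 1 or self.max_interleaved < 0:
            raise ValueError("invalid stretch parameters")
        if self.interleave_mode not in ("total", "run"):
            raise ValueError("interleave_mode must be 'total' or 'run'")


@dataclass(frozen=True)
class Domain:
    """A called domain: [start, end) covers first to last qualifying dyad + 2."""

    chrom: str
    start: int
    end: int
    kind: DomainKind
    n_qualifying: int
    n_interleaved: int
    mean_rate: float = float("nan")


def _qualifies(rate: float, kind: DomainKind, params: CallerParams) -> bool:
    if kind == DomainKind.HYPO:
        return rate < params.hypo_threshold
    return rate > params.hyper_threshold


def classify_dyads(
    track: MethylationTrack,
    cpg_sites: dict[str, np.ndarray],
    kind: DomainKind,
    params: CallerParams = CallerParams(),
) -> dict[str, list[tuple[int, DyadClass]]]:
    """Assign every genomic CG exactly one class relative to ``kind``.

    ``track`` must already be coverage-filtered; every call must sit on a
    genomic CG listed in ``cpg_sites`` (anything else is a consistency error).
    """
    out: dict[str, list[tuple[int, DyadClass]]] = {}
    for chrom, sites in cpg_sites.items():
        calls = {c.pos: c for c in track.calls(chrom)}
        site_set = set(int(p) for p in sites)
        stray = set(calls) - site_set
        if stray:
            raise ValueError(
                f"calls at non-CpG positions on {chrom}: {sorted(stray)[:5]}"
            )
        classified = []
        for pos in sites:
            pos = int(pos)
            call = calls.get(pos)
            if call is None:
                cls = DyadClass.UNDETERMINED
            elif _qualifies(call.rate, kind, params):
                cls = DyadClass.QUALIFYING
            else:
                cls = DyadClass.NONQUALIFYING
            classified.append((pos, cls))
        out[chrom] = classified
    for chrom in track.chroms:
        if chrom not in cpg_sites and track.calls(chrom):
            raise ValueError(f"calls on {chrom} but no CpG sites given")
    return out


def _scan_chrom(
    classified: Sequence[tuple[int, DyadClass]],
    kind: DomainKind,
    params: CallerParams,
    chrom: str,
    rates: dict[int, float] | None,
) -> list[Domain]:
    positions = [p for p, _ in classified]
    if positions != sorted(positions):
        raise ValueError("classified dyads must be sorted by position")
    classes = [c for _, c in classified]
    n = len(classes)
    qual_idx = [i for i, c in enumerate(classes) if c == DyadClass.QUALIFYING]
    run_mode = params.interleave_mode == "run"

    domains: list[Domain] = []
    ptr = 0
    while ptr < len(qual_idx):
        s = qual_idx[ptr]
        n_q = 0
        n_bad = 0
        run = 0
        best = None  # (end_index, n_q, n_bad)
        j = s
        while j < n:
            if classes[j] == DyadClass.QUALIFYING:
                n_q += 1
                run = 0
                if n_q >= params.min_qualifying and (
                    run_mode or n_bad <= params.max_interleaved
                ):
                    best = (j, n_q, n_bad)
            else:
                n_bad += 1
                run += 1
                if run_mode:
                    if run > params.max_interleaved:
                        break
                elif n_bad > params.max_interleaved:
                    break
            j += 1
        if best is None:
            ptr += 1
            continue
        end_idx, n_q, n_bad = best
        start = positions[s]
        end = positions[end_idx] + 2
        mean_rate = float("nan")
        if rates is not None:
            inside = [
                rates[positions[i]]
                for i in range(s, end_idx + 1)
                if positions[i] in rates
            ]
            if inside:
                mean_rate = float(np.mean(inside))
        domains.append(
            Domain(chrom, start, end, kind, n_q, n_bad, mean_rate)
        )
        while ptr < len(qual_idx) and qual_idx[ptr] <= end_idx:
            ptr += 1
    return domains


def call_domains(
    classified: dict[str, list[tuple[int, DyadClass]]] | Sequence[tuple[int, DyadClass]],
    kind: DomainKind,
    params: CallerParams = CallerParams(),
    rates: dict[str, dict[int, float]] | dict[int, float] | None = None,
) -> list[Domain]:
    """Greedy left-to-right domain caller over classified dyads.

    Accepts either a single chromosome's ordered (position, class) list
    (then ``rates`` maps position -> rate and the chromosome is unnamed) or
    the per-chromosome dict returned by :func:`classify_dyads`.
    """
    if isinstance(classified, dict):
        out: list[Domain] = []
        for chrom in sorted(classified):
            chrom_rates = rates.get(chrom) if rates else None
            out.extend(_scan_chrom(classified[chrom], kind, params, chrom, chrom_rates))
        return out
    return _scan_chrom(classified, kind, params, ".", rates)


def call_domains_bruteforce(
    classified: Sequence[tuple[int, DyadClass]],
    kind: DomainKind,
    params: CallerParams = CallerParams(),
    chrom: str = ".",
) -> list[Domain]:
    """Reference caller: exhaustive interval enumeration, leftmost-longest.

    Enumerates every index interval satisfying (a) qualifying endpoints,
    (b) >= min_qualifying qualifying dyads, (c) <= max_interleaved other
    dyads (total-budget mode only), then repeatedly selects the feasible
    interval with the smallest start (longest on ties) and resumes strictly
    after it.  O(n^2) with prefix sums; for cross-checking the scanner.
    """
    if params.interleave_mode != "total":
        raise ValueError("bruteforce oracle supports total-budget mode only")
    positions = [p for p, _ in classified]
    classes = [c for _, c in classified]
    n = len(classes)
    is_q = np.array([c == DyadClass.QUALIFYING for c in classes], dtype=np.int64)
    cum_q = np.concatenate([[0], np.cumsum(is_q)])

    feasible: list[tuple[int, int]] = []
    for i in range(n):
        if not is_q[i]:
            continue
        for j in range(i, n):
            if not is_q[j]:
                continue
            q = cum_q[j + 1] - cum_q[i]
            bad = (j - i + 1) - q
            if bad > params.max_interleaved:
                break  # bad count only grows with j
            if q >= params.min_qualifying:
                feasible.append((i, j))

    domains: list[Domain] = []
    lo = 0
    while True:
        candidates = [(i, j) for i, j in feasible if i >= lo]
        if not candidates:
            break
        i0 = min(i for i, _ in candidates)
        j0 = max(j for i, j in candidates if i == i0)
        q = int(cum_q[j0 + 1] - cum_q[i0])
        domains.append(
            Domain(chrom, positions[i0], positions[j0] + 2, kind, q, (j0 - i0 + 1) - q)
        )
        lo = j0 + 1
    return domains


@dataclass
class CallResult:
    hypo: list[Domain]
    hyper: list[Domain]
    overlaps: list[tuple[str, int, int]] = field(default_factory=list)


def call_all(
    track: MethylationTrack,
    genome: GenomeSequence,
    params: CallerParams = CallerParams(),
) -> CallResult:
    """Call HypoMDs and HyperMDs independently; report (never resolve) overlaps."""
    sites = enumerate_cpg_sites(genome)
    rates = {
        chrom: {c.pos: c.rate for c in track.calls(chrom)} for chrom in track.chroms
    }
    hypo_cls = classify_dyads(track, sites, DomainKind.HYPO, params)
    hyper_cls = classify_dyads(track, sites, DomainKind.HYPER, params)
    hypo = call_domains(hypo_cls, DomainKind.HYPO, params, rates)
    hyper = call_domains(hyper_cls, DomainKind.HYPER, params, rates)
    overlaps = []
    for a in hypo:
        for b in hyper:
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                overlaps.append((a.chrom, max(a.start, b.start), min(a.end, b.end)))
    return CallResult(hypo, hyper, overlaps)


def domain_summaries(
    domains: Iterable[Domain],
    track: MethylationTrack,
    genome: GenomeSequence,
) -> pd.DataFrame:
    """Per-domain length, GC content, CpG density (per kb) and mean rate."""
    rows = []
    for d in domains:
        seq = genome.fetch(d.chrom, d.start, d.end)
        length = d.end - d.start
        gc = (seq.count("G") + seq.count("C")) / length
        n_cg = sum(
            1 for i in range(length - 1) if seq[i] == "C" and seq[i + 1] == "G"
        )
        calls = [c.rate for c in track.calls(d.chrom) if d.start <= c.pos < d.end]
        rows.append(
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "kind": d.kind.value,
                "length": length,
                "gc": gc,
                "cpg_per_kb": n_cg / (length / 1000.0),
                "mean_rate": float(np.mean(calls)) if calls else float("nan"),
                "n_qualifying": d.n_qualifying,
                "n_interleaved": d.n_interleaved,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "kind", "length", "gc",
            "cpg_per_kb", "mean_rate", "n_qualifying", "n_interleaved",
        ],
    )


def domains_to_regions(domains: Iterable[Domain]) -> RegionSet:
    names = {DomainKind.HYPO: "HypoMD", DomainKind.HYPER: "HyperMD"}
    return RegionSet(
        Region(d.chrom, d.start, d.end, names[d.kind], d.n_qualifying)
        for d in domains
    )
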