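"""Endogenous-vs-ectopic methylation comparison for reintegrated fragments.

Genomic fragments (MspI-captured, optionally M.SssI pre-methylated) are
reintegrated into embryos; bisulfite sequencing of the integrated copies
yields per-CpG ectopic methylation calls.  This module matches each
fragment CpG back to its endogenous methylation call, stratifies by domain
of origin, DNase-hypersensitivity and library, and quantifies the
endogenous/ectopic relationship with rank correlations (Spearman's rho and
tie-corrected Kendall's tau-b — rates are heavily tied at 0 and 100) and
1%-bin histograms.

Per-CpG ectopic evidence from multiple integration events is pooled by
summing read counts at the same genomic position (``pool_matched``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomeSequence, MethylationTrack, RegionSet, ValidationError

__all__ = [
    "FragmentRecord",
    "MatchedCpG",
    "MatchReport",
    "CorrelationReport",
    "match_cpgs",
    "pool_matched",
    "correlate",
    "rate_histogram",
    "fragment_state_stratify",
    "fragment_feature_correlation",
    "read_fragment_table",
    "write_fragment_table",
]


@dataclass(frozen=True)
class EctopicCall:
    """One CpG's ectopic evidence at an offset within a fragment."""

    offset: int
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def rate(self) -> float:
        return 100.0 * self.n_meth / self.coverage if self.coverage else 0.0


@dataclass
class FragmentRecord:
    """An integrated genomic fragment and its per-CpG ectopic calls."""

    id: str
    chrom: str
    start: int
    end: int
    premethylated: bool
    cpg_calls: list[EctopicCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        for call in self.cpg_calls:
            if not 0 <= call.offset < self.end - self.start:
                raise ValidationError(
                    f"fragment {self.id}: offset {call.offset} outside fragment"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def library(self) -> str:
        return "premethylated" if self.premethylated else "unmethylated"

    @property
    def cpg_density_per_kb(self) -> float:
        return len(self.cpg_calls) / (self.length / 1000.0)

    @property
    def mean_ectopic_rate(self) -> float:
        rates = [c.rate for c in self.cpg_calls if c.coverage > 0]
        return float(np.mean(rates)) if rates else float("nan")


@dataclass(frozen=True)
class MatchedCpG:
    """A CpG observed both endogenously and on an integrated fragment."""

    chrom: str
    pos: int
    endogenous_rate: float
    ectopic_rate: float
    ectopic_n_meth: int
    ectopic_n_unmeth: int
    origin_state: str  # hypo | hyper | other
    dhs: str  # inside | outside | spanning-fragment
    library: str  # unmethylated | premethylated
    fragment_id: str | None = None


@dataclass
class MatchReport:
    matched: list[MatchedCpG]
    n_dropped_no_endogenous: int
    n_fragments: int
    n_spanning_fragments: int

    @property
    def fraction_contained(self) -> float:
        """Fraction of fragments wholly inside or outside DHS (paper: > 96%)."""
        if self.n_fragments == 0:
            return float("nan")
        return 1.0 - self.n_spanning_fragments / self.n_fragments


def _dhs_fragment_label(frag: FragmentRecord, dhs: RegionSet) -> str | None:
    """'spanning-fragment' if the fragment crosses a DHS boundary, else None."""
    for r in dhs.overlapping(frag.chrom, frag.start, frag.end):
        if not (r.start <= frag.start and frag.end <= r.end):
            return "spanning-fragment"
    return None


def match_cpgs(
    fragments: Iterable[FragmentRecord],
    endogenous: MethylationTrack,
    hypo_domains: RegionSet,
    hyper_domains: RegionSet,
    dhs: RegionSet,
    genome: GenomeSequence | None = None,
) -> MatchReport:
    """Pair every fragment CpG with its endogenous methylation call.

    CpGs lacking a valid endogenous call are dropped and counted.  A
    fragment crossing a DHS boundary labels all its CpGs 'spanning-fragment';
    otherwise each CpG is inside/outside by its own position.  Origin state
    comes from HypoMD/HyperMD membership of the CpG position.
    """
    matched: list[MatchedCpG] = []
    dropped = 0
    n_frag = 0
    n_span = 0
    for frag in fragments:
        n_frag += 1
        if genome is not None:
            if frag.chrom not in genome or frag.start < 0 or frag.end > genome.length(frag.chrom):
                raise ValidationError(
                    f"fragment {frag.id} outside genome bounds: "
                    f"{frag.chrom}:{frag.start}-{frag.end}"
                )
        span_label = _dhs_fragment_label(frag, dhs)
        if span_label:
            n_span += 1
        for call in frag.cpg_calls:
            pos = frag.start + call.offset
            endo = endogenous.get(frag.chrom, pos)
            if endo is None:
                dropped += 1
                continue
            if hypo_domains.contains(frag.chrom, pos):
                origin = "hypo"
            elif hyper_domains.contains(frag.chrom, pos):
                origin = "hyper"
            else:
                origin = "other"
            dhs_label = span_label or (
                "inside" if dhs.contains(frag.chrom, pos) else "outside"
            )
            matched.append(
                MatchedCpG(
                    chrom=frag.chrom,
                    pos=pos,
                    endogenous_rate=endo.rate,
                    ectopic_rate=call.rate,
                    ectopic_n_meth=call.n_meth,
                    ectopic_n_unmeth=call.n_unmeth,
                    origin_state=origin,
                    dhs=dhs_label,
                    library=frag.library,
                    fragment_id=frag.id,
                )
            )
    return MatchReport(matched, dropped, n_frag, n_span)


def pool_matched(matched: Iterable[MatchedCpG]) -> list[MatchedCpG]:
    """Pool ectopic evidence per (chrom, pos, library) by summing read counts."""
    buckets: dict[tuple[str, int, str], list[MatchedCpG]] = {}
    for m in matched:
        buckets.setdefault((m.chrom, m.pos, m.library), []).append(m)
    pooled = []
    for (chrom, pos, library), group in sorted(buckets.items()):
        nm = sum(g.ectopic_n_meth for g in group)
        nu = sum(g.ectopic_n_unmeth for g in group)
        cov = nm + nu
        dhs = ("spanning-fragment" if any(g.dhs == "spanning-fragment" for g in group)
               else group[0].dhs)
        pooled.append(
            MatchedCpG(
                chrom=chrom,
                pos=pos,
                endogenous_rate=group[0].endogenous_rate,
                ectopic_rate=100.0 * nm / cov if cov else 0.0,
                ectopic_n_meth=nm,
                ectopic_n_unmeth=nu,
                origin_state=group[0].origin_state,
                dhs=dhs,
                library=library,
                fragment_id=None,
            )
        )
    return pooled


@dataclass
class CorrelationReport:
    spearman_rho: float
    kendall_tau: float
    n: int
    stratum: str = ""
    defined: bool = True


def _rank_correlations(x: np.ndarray, y: np.ndarray, stratum: str) -> CorrelationReport:
    if len(x) < 2:
        raise ValueError("need >= 2 pairs to correlate")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationReport(float("nan"), float("nan"), len(x), stratum, False)
    rho = stats.spearmanr(x, y).statistic
    tau = stats.kendalltau(x, y, variant="b").statistic
    return CorrelationReport(float(rho), float(tau), len(x), stratum)


def correlate(
    matched: Sequence[MatchedCpG],
    stratum: Callable[[MatchedCpG], bool] | None = None,
    label: str = "",
) -> CorrelationReport:
    """Spearman rho and Kendall tau-b of (endogenous, ectopic) rate pairs."""
    sel = [m for m in matched if stratum is None or stratum(m)]
    x = np.array([m.endogenous_rate for m in sel])
    y = np.array([m.ectopic_rate for m in sel])
    return _rank_correlations(x, y, label)


def rate_histogram(rates: Sequence[float], bin_width: float = 1.0) -> np.ndarray:
    """Histogram of percent rates over [0, 100] bins of ``bin_width`` (default 1%).

    Bins are [0,1), ..., [99,100] with 100.0 assigned to the last bin;
    counts always sum to the number of rates.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size and (rates.min() < 0 or rates.max() > 100):
        raise ValueError("rates must lie in [0, 100]")
    n_bins = int(round(100.0 / bin_width))
    if rates.size == 0:
        return np.zeros(n_bins, dtype=np.int64)
    idx = np.minimum((rates / bin_width).astype(np.int64), n_bins - 1)
    return np.bincount(idx, minlength=n_bins).astype(np.int64)


def fragment_state_stratify(
    matched: Sequence[MatchedCpG],
    hypo_below: float = 40.0,
    hyper_above: float = 60.0,
) -> tuple[dict[tuple[str, str], list[MatchedCpG]], int]:
    """Group matched CpGs by (fragment endogenous state, library).

    A fragment is endogenously hypomethylated if its mean matched-CpG
    endogenous rate is < 40%, hypermethylated if > 60%; middle-state
    fragments are excluded and counted.  Returns ({(state, library):
    CpGs}, n_excluded_fragments).
    """
    by_frag: dict[str, list[MatchedCpG]] = {}
    for m in matched:
        if m.fragment_id is None:
            raise ValueError("fragment-level stratification needs fragment ids")
        by_frag.setdefault(m.fragment_id, []).append(m)
    strata: dict[tuple[str, str], list[MatchedCpG]] = {}
    excluded = 0
    for frag_id, group in sorted(by_frag.items()):
        mean_endo = float(np.mean([m.endogenous_rate for m in group]))
        if mean_endo < hypo_below:
            state = "hypo"
        elif mean_endo > hyper_above:
            state = "hyper"
        else:
            excluded += 1
            continue
        strata.setdefault((state, group[0].library), []).extend(group)
    return strata, excluded


def fragment_feature_correlation(
    fragments: Sequence[FragmentRecord],
) -> dict[str, CorrelationReport]:
    """Correlate fragment mean ectopic rate with length and with CpG density."""
    usable = [f for f in fragments if f.cpg_calls and not np.isnan(f.mean_ectopic_rate)]
    if len(usable) < 2:
        raise ValueError("need >= 2 fragments with ectopic calls")
    rate = np.array([f.mean_ectopic_rate for f in usable])
    length = np.array([f.length for f in usable], dtype=float)
    density = np.array([f.cpg_density_per_kb for f in usable])
    return {
        "length": _rank_correlations(length, rate, "length"),
        "cpg_density": _rank_correlations(density, rate, "cpg_density"),
    }


# ---------------------------------------------------------------------------
# fragment table IO (TSV: id chrom start end library offset n_meth n_unmeth)
# ---------------------------------------------------------------------------

_FRAG_COLUMNS = ["id", "chrom", "start", "end", "library", "offset", "n_meth", "n_unmeth"]


def write_fragment_table(fragments: Iterable[FragmentRecord], path: str | Path) -> None:
    rows = []
    for f in fragments:
        for c in f.cpg_calls:
            rows.append((f.id, f.chrom, f.start, f.end, f.library,
                         c.offset, c.n_meth, c.n_unmeth))
    pd.DataFrame(rows, columns=_FRAG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fragment_table(path: str | Path) -> list[FragmentRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_FRAG_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"fragment table missing columns: {sorted(missing)}")
    fragments = []
    for (fid, chrom, start, end, library), group in df.groupby(
        ["id", "chrom", "start", "end", "library"], sort=True
    ):
        calls = [
            EctopicCall(int(r.offset), int(r.n_meth), int(r.n_unmeth))
            for r in group.itertuples()
        ]
        fragments.append(
            FragmentRecord(str(fid), str(chrom), int(start), int(end),
                           library == "premethylated", calls)
        )
    return fragments
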