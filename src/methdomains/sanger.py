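"""Methylation and editing rates from Sanger trace peak heights.

After bisulfite conversion and PCR, a methylated cytosine reads as C and an
unmethylated one as T, so the per-CpG methylation rate is estimated directly
from chromatogram peak heights as C / (C + T) x 100%.

For in-situ methylome editing via homology-directed repair, the repair
template carries PAM substitutions (5'-NGG-3' -> 5'-NGC-3'), so the locus
editing rate is read from the native-DNA trace as the relative height of the
mutated base (C) versus the native base (G) at each PAM third position,
averaged over PAM sites.  The editing-normalized methylation rate
(methylation rate / editing rate) expresses methylation on edited alleles
only; quotients above 100% are capped and flagged.

CpG sites are annotated on the bisulfite-converted amplicon coordinate frame
and PAM sites on the unconverted frame, so the two peak tables are separate
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "TraceQuant",
    "read_peak_table",
    "methylation_rate",
    "methylation_rates",
    "editing_rate",
    "normalize_methylation",
    "quantify_locus",
]

_CHANNELS = ["A", "C", "G", "T"]


class UndeterminedSiteError(ValueError):
    """Both informative channels are zero at a required site."""


@dataclass
class PeakTable:
    """Ordered per-position A/C/G/T peak heights of one Sanger trace."""

    heights: pd.DataFrame  # index: position, columns A C G T

    def __post_init__(self) -> None:
        missing = [c for c in _CHANNELS if c not in self.heights.columns]
        if missing:
            raise ValueError(f"peak table missing channels: {missing}")
        if (self.heights[_CHANNELS] < 0).any().any():
            raise ValueError("peak heights must be non-negative")

    def height(self, position: int, base: str) -> float:
        if position not in self.heights.index:
            raise KeyError(f"position {position} not in peak table")
        return float(self.heights.at[position, base])

    def __len__(self) -> int:
        return len(self.heights)


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a TSV peak table with columns position, A, C, G, T."""
    df = pd.read_csv(path, sep="\t")
    if "position" not in df.columns:
        raise ValueError("peak table needs a 'position' column")
    return PeakTable(df.set_index("position"))


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    table.heights.reset_index(names="position").to_csv(path, sep="\t", index=False)


def methylation_rate(height_c: float, height_t: float) -> float:
    """Per-CpG methylation percent from bisulfite-trace peaks: 100*C/(C+T)."""
    total = height_c + height_t
    if total <= 0:
        raise UndeterminedSiteError("C + T peak height is zero")
    return 100.0 * height_c / total


def methylation_rates(
    trace: PeakTable, cpg_sites: Sequence[int]
) -> tuple[pd.Series, list[int]]:
    """Rates at annotated CpG positions; zero-signal sites come back as NaN
    and are listed as undetermined."""
    rates = {}
    undetermined = []
    for pos in cpg_sites:
        c = trace.height(pos, "C")
        t = trace.height(pos, "T")
        if c + t <= 0:
            rates[pos] = float("nan")
            undetermined.append(pos)
        else:
            rates[pos] = methylation_rate(c, t)
    return pd.Series(rates, name="methylation_rate"), undetermined


def editing_rate(
    trace: PeakTable,
    pam_sites: Sequence[int],
    edited_base: str = "C",
    native_base: str = "G",
    aggregate: str = "mean",
) -> tuple[float, pd.Series, list[int]]:
    """Locus editing percent from PAM third-base peaks on the native trace.

    Per site: 100 * h_edited / (h_edited + h_native); the locus rate
    aggregates sites by unweighted mean (or median).  Zero-signal sites are
    skipped with a warning list; all sites skipped is an error.
    """
    if not pam_sites:
        raise ValueError("need at least one annotated PAM site")
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    per_site = {}
    skipped = []
    for pos in pam_sites:
        e = trace.height(pos, edited_base)
        nv = trace.height(pos, native_base)
        if e + nv <= 0:
            skipped.append(pos)
            continue
        per_site[pos] = 100.0 * e / (e + nv)
    if not per_site:
        raise UndeterminedSiteError("all PAM sites had zero signal")
    values = np.array(list(per_site.values()))
    locus = float(np.mean(values) if aggregate == "mean" else np.median(values))
    return locus, pd.Series(per_site, name="editing_rate"), skipped


def normalize_methylation(
    rate_percent: float, editing_percent: float, cap: bool = True
) -> tuple[float, bool]:
    """Editing-normalized methylation percent and an overflow flag.

    100 * (rate/100) / (editing/100); at low editing the quotient can exceed
    100%, in which case it is capped at 100 with the flag set (or returned
    raw when cap=False).
    """
    if editing_percent <= 0:
        raise ValueError("editing rate must be positive")
    value = 100.0 * rate_percent / editing_percent
    if value > 100.0:
        return (100.0, True) if cap else (value, True)
    return value, False


@dataclass
class TraceQuant:
    """Full per-locus readout of a methylome-editing experiment."""

    methylation: pd.Series  # per-CpG percent (NaN = undetermined)
    undetermined_cpgs: list[int]
    editing_rate: float | None
    per_pam: pd.Series | None
    skipped_pams: list[int]
    normalized: pd.Series | None  # per-CpG editing-normalized percent
    capped: list[int] = field(default_factory=list)


def quantify_locus(
    bisulfite_trace: PeakTable,
    cpg_sites: Sequence[int],
    native_trace: PeakTable | None = None,
    pam_sites: Sequence[int] | None = None,
    aggregate: str = "mean",
    cap: bool = True,
) -> TraceQuant:
    """Methylation, editing and normalized rates for one edited locus.

    Without a native trace + PAM annotation, methylation rates are computed
    but normalization is refused (normalized = None).
    """
    meth, undetermined = methylation_rates(bisulfite_trace, cpg_sites)
    if native_trace is None or not pam_sites:
        return TraceQuant(meth, undetermined, None, None, [], None)
    locus_editing, per_pam, skipped = editing_rate(
        native_trace, pam_sites, aggregate=aggregate
    )
    normalized = {}
    capped = []
    for pos, rate in meth.items():
        if np.isnan(rate):
            normalized[pos] = float("nan")
            continue
        value, overflow = normalize_methylation(rate, locus_editing, cap=cap)
        normalized[pos] = value
        if overflow:
            capped.append(pos)
    return TraceQuant(
        meth,
        undetermined,
        locus_editing,
        per_pam,
        skipped,
        pd.Series(normalized, name="normalized_rate"),
        capped,
    )
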