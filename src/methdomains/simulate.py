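"""Synthetic inputs for the whole pipeline, from stated distributions and seeds.

The generator emulates the structure of a vertebrate methylome without any
real sequencing data: a hypermethylated background genome punctuated by
CpG-dense hypomethylated islands; bimodal per-CpG methylation rates
(Beta(1,9) near 0% inside islands, Beta(9,1) near 100% outside) observed
through finite sequencing coverage (negative-binomial, mean 8x, so a
realistic fraction of dyads fails the 5x validity filter); MspI (C^CGG)
fragment capture with 40-220 bp size selection and 144 bp adapter extension;
ectopic methylation readouts under three competing integration models; and
Sanger peak tables with known methylation/editing truth.

Integration models:

* ``maintenance`` — the ectopic state equals the library state
  (unmethylated or M.SssI pre-methylated), flipped per CpG with a small
  gain rate (gamma, from unmethylated) or loss rate (delta, from
  pre-methylated), independent of the endogenous state.
* ``sequence_determined`` — the ectopic rate recapitulates the endogenous
  true rate up to bounded Gaussian noise.
* ``default_hypermethylation`` — every CpG is driven toward 100%
  regardless of library and endogenous state.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CpGCall, GenomeSequence, MethylationTrack, Region, RegionSet
from .ectopic import EctopicCall, FragmentRecord
from .sanger import PeakTable

__all__ = [
    "GenomeSpec",
    "MethylomeSpec",
    "IntegrationModel",
    "TrueMethylome",
    "generate_genome",
    "simulate_methylome",
    "digest_mspi",
    "msp1_capture",
    "CaptureFragment",
    "simulate_integration",
    "simulate_trace",
    "SimulatedTrace",
    "classifier_segments",
]

_DEFAULT_MOTIFS = (("TGATAA", 2.0, 0.2),)  # (motif, island /kb, background /kb)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Layout of a synthetic genome: hypermethylated background with
    embedded CpG-dense hypomethylated islands.

    ``background_cpg_per_kb`` approximates the genome-wide CpG density of a
    fish genome (~20/kb); islands carry ``island_density_multiplier`` times
    that density.  Motifs are planted by substitution at the given per-kb
    rates inside and outside islands (CpG-free motifs leave the density
    signal untouched).

    ``n_cpg_rich_hyper`` additionally embeds patches with island-level CpG
    density that stay hypermethylated (they are not part of the island truth
    set).  Real genomes contain such regions — they are what makes an
    MspI capture sample hypo- and hypermethylated CpGs about equally — but
    they are off by default so that the island/background density contrast
    is exactly the configured multiplier.
    """

    n_chrom: int = 1
    chrom_length: int = 100_000
    gc_fraction: float = 0.40
    n_islands: int = 10
    island_length: int = 1000
    background_cpg_per_kb: float = 20.0
    island_density_multiplier: float = 5.0
    n_cpg_rich_hyper: int = 0  # CpG-dense but hypermethylated patches
    motifs: tuple[tuple[str, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_cpg_per_kb <= 0 or self.island_density_multiplier <= 0:
            raise ValueError("densities must be positive")
        if self.island_length >= self.chrom_length:
            raise ValueError("island length must be below chromosome length")


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def _strip_cg(arr: np.ndarray, rng: np.random.Generator) -> None:
    """Destroy accidental CG dinucleotides so density is fully controlled."""
    cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    idx = np.flatnonzero(cg) + 1
    arr[idx] = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=idx.size)


def _plant_cgs(
    arr: np.ndarray,
    start: int,
    end: int,
    rate_per_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli-plant CG dinucleotides in [start, end); returns planted positions."""
    candidates = start + np.flatnonzero(rng.random(max(end - start - 1, 0)) < rate_per_bp)
    kept = []
    prev = -2
    for p in candidates:
        if p >= prev + 2:
            kept.append(p)
            prev = p
    kept = np.array(kept, dtype=np.int64)
    arr[kept] = ord("C")
    arr[kept + 1] = ord("G")
    return kept


def _plant_motifs(
    arr: np.ndarray,
    start: int,
    end: int,
    motif: str,
    rate_per_kb: float,
    blocked: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Substitute ``motif`` at ~rate_per_kb inside [start, end), avoiding
    windows that touch a planted CG (``blocked`` marks planted positions)."""
    m = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    length = end - start - len(m)
    if length <= 0:
        return
    n = rng.poisson(rate_per_kb * (end - start) / 1000.0)
    if n == 0:
        return
    positions = rng.integers(start, start + length, size=3 * n)
    placed = 0
    for p in positions:
        if placed >= n:
            break
        lo, hi = max(p - 1, 0), min(p + len(m) + 1, arr.size)
        if blocked[lo:hi].any():
            continue
        arr[p : p + len(m)] = m
        blocked[p : p + len(m)] = True
        placed += 1


def _layout_islands(
    rng: np.random.Generator, chrom_length: int, n_islands: int, island_length: int
) -> list[tuple[int, int]]:
    """Place non-overlapping islands, one per equal-width slot with a random
    offset (keeps >= 1 island-length margin at the chromosome ends)."""
    if n_islands == 0:
        return []
    slot = chrom_length // n_islands
    if slot < 2 * island_length:
        raise ValueError(
            f"cannot fit {n_islands} islands of {island_length} bp in "
            f"{chrom_length} bp"
        )
    islands = []
    for i in range(n_islands):
        offset = rng.integers(island_length // 2, slot - island_length)
        start = i * slot + int(offset)
        islands.append((start, start + island_length))
    return islands


def generate_genome(spec: GenomeSpec) -> tuple[GenomeSequence, RegionSet]:
    """Synthesize a genome and the truth set of hypomethylated islands."""
    rng = np.random.default_rng(spec.seed)
    seqs: dict[str, str] = {}
    regions: list[Region] = []
    bg_rate = spec.background_cpg_per_kb / 1000.0
    island_rate = bg_rate * spec.island_density_multiplier
    if island_rate >= 0.5:
        raise ValueError("island CpG rate too high to realize")
    for ci in range(spec.n_chrom):
        chrom = f"chr{ci + 1}"
        arr = _random_bases(rng, spec.chrom_length, spec.gc_fraction)
        _strip_cg(arr, rng)
        n_dense = spec.n_islands + spec.n_cpg_rich_hyper
        dense = _layout_islands(
            rng, spec.chrom_length, n_dense, spec.island_length
        )
        # interleave island / hyper-patch assignment along the chromosome
        kinds = (["island", "patch"] * n_dense)[:n_dense]
        if spec.n_cpg_rich_hyper == 0:
            kinds = ["island"] * n_dense
        elif kinds.count("island") != spec.n_islands:
            kinds = ["island"] * spec.n_islands + ["patch"] * spec.n_cpg_rich_hyper
            rng.shuffle(kinds)
        islands = [iv for iv, kd in zip(dense, kinds) if kd == "island"]
        blocked = np.zeros(arr.size, dtype=bool)
        cursor = 0
        segments: list[tuple[int, int, str]] = []
        for (s, e), kd in zip(dense, kinds):
            segments.append((cursor, s, "bg"))
            segments.append((s, e, kd))
            cursor = e
        segments.append((cursor, spec.chrom_length, "bg"))
        for s, e, kd in segments:
            if e - s < 2:
                continue
            planted = _plant_cgs(
                arr, s, e, island_rate if kd != "bg" else bg_rate, rng
            )
            blocked[planted] = True
            blocked[np.minimum(planted + 1, arr.size - 1)] = True
        for motif, island_rate_kb, bg_rate_kb in spec.motifs:
            for s, e, kd in segments:
                rate = island_rate_kb if kd == "island" else bg_rate_kb
                _plant_motifs(arr, s, e, motif, rate, blocked, rng)
        # motif substitution may butt a C against a G; keep unplanted CGs out
        planted_c = blocked.copy()
        cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G")) & ~planted_c[:-1]
        arr[np.flatnonzero(cg) + 1] = ord("T")
        seqs[chrom] = arr.tobytes().decode("ascii")
        regions.extend(Region(chrom, s, e, "island") for s, e in islands)
    return GenomeSequence(seqs), RegionSet(regions)


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethylomeSpec:
    """Bimodal per-CpG methylation with finite coverage.

    Rates (percent) are Beta-distributed per state: Beta(1,9)*100 inside
    hypomethylated islands (mean 10%), Beta(9,1)*100 in the background
    (mean 90%).  Coverage is negative-binomial with mean 8 reads, the
    post-filter WGBS mean coverage being emulated, so part of the dyads
    falls below the 5x validity cut and becomes undetermined.
    """

    hypo_beta: tuple[float, float] = (1.0, 9.0)
    hyper_beta: tuple[float, float] = (9.0, 1.0)
    coverage_mean: float = 8.0
    coverage_dispersion: float = 4.0  # negative-binomial n parameter
    seed: int = 0


@dataclass
class TrueMethylome:
    """Ground-truth per-CpG rates behind a simulated methylome."""

    positions: dict[str, np.ndarray]
    true_rates: dict[str, np.ndarray]  # percent
    is_island: dict[str, np.ndarray]

    def rate_at(self, chrom: str, pos: int) -> float:
        idx = np.searchsorted(self.positions[chrom], pos)
        if idx >= self.positions[chrom].size or self.positions[chrom][idx] != pos:
            raise KeyError(f"{chrom}:{pos} is not a CpG site")
        return float(self.true_rates[chrom][idx])

    def to_track(self, coverage: int = 10_000) -> MethylationTrack:
        """Exact-rate track (counts scaled to ``coverage``) for analyses
        against the truth rather than a noisy re-measurement."""
        calls = []
        for chrom, pos in self.positions.items():
            for p, r in zip(pos, self.true_rates[chrom]):
                nm = int(round(r / 100.0 * coverage))
                calls.append(CpGCall.from_counts(chrom, int(p), nm, coverage - nm))
        return MethylationTrack(calls)


def simulate_methylome(
    genome: GenomeSequence,
    islands: RegionSet,
    spec: MethylomeSpec = MethylomeSpec(),
) -> tuple[MethylationTrack, TrueMethylome]:
    """Draw true rates and observed counts for every genomic CpG.

    Returns the observed (unfiltered) track — CpGs with zero drawn coverage
    are omitted, as an extractor would — and the underlying truth.
    """
    from .io import enumerate_cpg_sites

    rng = np.random.default_rng(spec.seed)
    sites = enumerate_cpg_sites(genome)
    calls: list[CpGCall] = []
    positions: dict[str, np.ndarray] = {}
    rates: dict[str, np.ndarray] = {}
    is_island: dict[str, np.ndarray] = {}
    nb_n = spec.coverage_dispersion
    nb_p = nb_n / (nb_n + spec.coverage_mean)
    for chrom, pos in sites.items():
        island_mask = np.zeros(pos.size, dtype=bool)
        for r in islands.regions(chrom):
            island_mask |= (pos >= r.start) & (pos < r.end)
        true = np.where(
            island_mask,
            rng.beta(*spec.hypo_beta, size=pos.size),
            rng.beta(*spec.hyper_beta, size=pos.size),
        ) * 100.0
        cov = rng.negative_binomial(nb_n, nb_p, size=pos.size)
        n_meth = rng.binomial(cov, true / 100.0)
        positions[chrom] = pos.copy()
        rates[chrom] = true
        is_island[chrom] = island_mask
        for p, c, nm in zip(pos, cov, n_meth):
            if c > 0:
                calls.append(CpGCall.from_counts(chrom, int(p), int(nm), int(c - nm)))
    return MethylationTrack(calls), TrueMethylome(positions, rates, is_island)


# ---------------------------------------------------------------------------
# MspI capture (RRBS-style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaptureFragment:
    chrom: str
    start: int
    end: int
    extended_length: int

    @property
    def length(self) -> int:
        return self.end - self.start


def digest_mspi(genome: GenomeSequence) -> dict[str, list[tuple[int, int]]]:
    """Full MspI digestion: cut C^CGG inside every CCGG occurrence.

    Returns all resulting intervals per chromosome, terminal pieces
    included, so the fragments tile each chromosome exactly.
    """
    out = {}
    for chrom in genome:
        seq = genome[chrom]
        cuts = [m.start() + 1 for m in re.finditer("CCGG", seq)]
        bounds = [0] + cuts + [len(seq)]
        out[chrom] = [
            (a, b) for a, b in zip(bounds, bounds[1:]) if b > a
        ]
    return out


def msp1_capture(
    genome: GenomeSequence,
    size_min: int = 40,
    size_max: int = 220,
    adapter_extension: int = 144,
) -> list[CaptureFragment]:
    """Size-selected internal MspI fragments (both ends cut), as captured
    for RRBS-style library preparation: 40-220 bp retained, reported with
    adapter-extended length (+144 bp -> 184-364 bp)."""
    fragments = []
    for chrom, pieces in digest_mspi(genome).items():
        if len(pieces) < 3:
            continue  # no internal fragment without >= 2 cuts
        for start, end in pieces[1:-1]:
            length = end - start
            if size_min <= length <= size_max:
                fragments.append(
                    CaptureFragment(chrom, start, end, length + adapter_extension)
                )
    return fragments


# ---------------------------------------------------------------------------
# integration readout simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegrationModel:
    """Competing models for the methylation state of reintegrated fragments.

    ``loss_rate`` (delta) and ``gain_rate`` (gamma) are per-CpG flip
    probabilities under maintenance; ``noise_scale`` is the Gaussian sd (in
    percentage points) of the sequence-determined recapitulation; ectopic
    coverage emulates the deep pooled-embryo bisulfite assay (mean read
    depths of a few hundred per CpG).
    """

    mode: str = "maintenance"  # maintenance | sequence_determined | default_hypermethylation
    loss_rate: float = 0.02
    gain_rate: float = 0.02
    noise_scale: float = 5.0
    coverage_mean: float = 250.0
    coverage_dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (
            "maintenance", "sequence_determined", "default_hypermethylation"
        ):
            raise ValueError(f"unknown integration mode {self.mode!r}")
        if not (0 <= self.loss_rate <= 1 and 0 <= self.gain_rate <= 1):
            raise ValueError("flip rates must lie in [0, 1]")


def simulate_integration(
    fragments: Sequence[CaptureFragment],
    truth: TrueMethylome,
    library: str,
    model: IntegrationModel = IntegrationModel(),
) -> list[FragmentRecord]:
    """Ectopic methylation calls for integrated fragments under ``model``.

    ``library`` is 'unmethylated' (PCR-amplified) or 'premethylated'
    (M.SssI-treated before injection).
    """
    if library not in ("unmethylated", "premethylated"):
        raise ValueError("library must be 'unmethylated' or 'premethylated'")
    rng = np.random.default_rng(model.seed)
    nb_n = model.coverage_dispersion
    nb_p = nb_n / (nb_n + model.coverage_mean)
    records = []
    for i, frag in enumerate(fragments):
        pos = truth.positions[frag.chrom]
        lo = np.searchsorted(pos, frag.start)
        hi = np.searchsorted(pos, frag.end)
        cpg_pos = pos[lo:hi]
        endo = truth.true_rates[frag.chrom][lo:hi]
        n = cpg_pos.size
        if model.mode == "maintenance":
            if library == "unmethylated":
                ect = np.where(rng.random(n) < model.gain_rate, 100.0, 0.0)
            else:
                ect = np.where(rng.random(n) < model.loss_rate, 0.0, 100.0)
        elif model.mode == "sequence_determined":
            ect = np.clip(endo + rng.normal(0.0, model.noise_scale, n), 0.0, 100.0)
        else:  # default_hypermethylation
            ect = rng.beta(9.0, 1.0, n) * 100.0
        cov = rng.negative_binomial(nb_n, nb_p, size=n)
        n_meth = rng.binomial(cov, ect / 100.0)
        calls = [
            EctopicCall(int(p - frag.start), int(nm), int(c - nm))
            for p, c, nm in zip(cpg_pos, cov, n_meth)
            if c > 0
        ]
        records.append(
            FragmentRecord(
                id=f"frag{i:06d}",
                chrom=frag.chrom,
                start=frag.start,
                end=frag.end,
                premethylated=(library == "premethylated"),
                cpg_calls=calls,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Sanger trace simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTrace:
    bisulfite_trace: PeakTable
    cpg_sites: list[int]
    native_trace: PeakTable
    pam_sites: list[int]
    true_rates: np.ndarray
    true_editing: float


def simulate_trace(
    true_rates: Sequence[float],
    editing_rate: float,
    noise_scale: float = 0.0,
    seed: int = 0,
    n_pam: int = 6,
    base_height: float = 1000.0,
) -> SimulatedTrace:
    """Peak tables whose C/T (bisulfite frame) and C/G (native frame, PAM
    third base) height ratios encode the given truth, with multiplicative
    lognormal noise of the given relative scale (0 = exact)."""
    true_rates = np.asarray(true_rates, dtype=float)
    if true_rates.size and (true_rates.min() < 0 or true_rates.max() > 100):
        raise ValueError("rates must lie in [0, 100]")
    if not 0 <= editing_rate <= 100:
        raise ValueError("editing rate must lie in [0, 100]")
    rng = np.random.default_rng(seed)

    def noisy(h: np.ndarray) -> np.ndarray:
        if noise_scale <= 0:
            return h
        return h * rng.lognormal(0.0, noise_scale / 100.0, size=h.shape)

    n = true_rates.size
    bis = pd.DataFrame(
        0.0, index=pd.RangeIndex(n, name="position"), columns=list("ACGT")
    )
    bis["C"] = noisy(base_height * true_rates / 100.0)
    bis["T"] = noisy(base_height * (1.0 - true_rates / 100.0))
    nat = pd.DataFrame(
        0.0, index=pd.RangeIndex(n_pam, name="position"), columns=list("ACGT")
    )
    nat["C"] = noisy(np.full(n_pam, base_height * editing_rate / 100.0))
    nat["G"] = noisy(np.full(n_pam, base_height * (1.0 - editing_rate / 100.0)))
    return SimulatedTrace(
        PeakTable(bis), list(range(n)), PeakTable(nat), list(range(n_pam)),
        true_rates, editing_rate,
    )


# ---------------------------------------------------------------------------
# classifier preset: labeled island / background segments
# ---------------------------------------------------------------------------

def classifier_segments(
    n_per_class: int = 2000,
    seed: int = 0,
    gc_fraction: float = 0.40,
    median_length: float = 1000.0,
    length_sigma: float = 0.6,
    length_range: tuple[int, int] = (200, 5000),
    background_density_mean: float = 15.0,
    island_density_mean: float = 45.0,
    density_shape: float = 4.0,
    motifs: tuple[tuple[str, float, float], ...] = _DEFAULT_MOTIFS,
) -> tuple[list[str], list[str]]:
    """Island-like (hypomethylated) and background-like (hypermethylated)
    sequence segments for classifier studies.

    Real domain classes are not separable by length or GC content and differ
    only in the median of their (overlapping) CpG density distributions, so
    both classes share one length distribution (lognormal, median ~1 kb) and
    one GC fraction, while per-segment CpG densities are Gamma draws with a
    three-fold difference in mean.  Islands additionally carry the
    planted-motif enrichment.  With the default CpG-free motif, CpG masking
    removes most of the density signal but leaves the motif signal intact.
    """
    rng = np.random.default_rng(seed)

    def make(density_mean: float, motif_col: int) -> list[str]:
        seqs = []
        for _ in range(n_per_class):
            length = int(
                np.clip(
                    rng.lognormal(np.log(median_length), length_sigma),
                    *length_range,
                )
            )
            density = rng.gamma(density_shape, density_mean / density_shape)
            cpg_rate = min(density / 1000.0, 0.4)
            arr = _random_bases(rng, length, gc_fraction)
            _strip_cg(arr, rng)
            blocked = np.zeros(length, dtype=bool)
            planted = _plant_cgs(arr, 0, length, cpg_rate, rng)
            blocked[planted] = True
            blocked[np.minimum(planted + 1, length - 1)] = True
            for motif, i_rate, b_rate in motifs:
                rate = (i_rate, b_rate)[motif_col]
                _plant_motifs(arr, 0, length, motif, rate, blocked, rng)
            cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G")) & ~blocked[:-1]
            arr[np.flatnonzero(cg) + 1] = ord("T")
            seqs.append(arr.tobytes().decode("ascii"))
        return seqs

    islands = make(island_density_mean, 0)
    backgrounds = make(background_density_mean, 1)
    return islands, backgrounds
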