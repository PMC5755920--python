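import numpy as np
import pytest

from methdomains.domains import CallerParams, call_all
from methdomains.io import GenomeSequence, enumerate_cpg_sites, filter_coverage
from methdomains.simulate import (
    GenomeSpec,
    IntegrationModel,
    MethylomeSpec,
    classifier_segments,
    digest_mspi,
    generate_genome,
    msp1_capture,
    simulate_integration,
    simulate_methylome,
    simulate_trace,
)


class TestGenerateGenome:
    def test_deterministic_under_seed(self):
        a, ra = generate_genome(GenomeSpec(seed=9))
        b, rb = generate_genome(GenomeSpec(seed=9))
        assert a["chr1"] == b["chr1"] and ra == rb

    def test_density_ratio_near_multiplier(self):
        spec = GenomeSpec(
            chrom_length=100_000, n_islands=10, island_length=1000,
            island_density_multiplier=5.0, seed=3,
        )
        genome, islands = generate_genome(spec)
        sites = enumerate_cpg_sites(genome)["chr1"]
        inside = sum(islands.contains("chr1", int(p)) for p in sites)
        outside = len(sites) - inside
        ratio = (inside / 10_000) / (outside / 90_000)
        assert 3.5 <= ratio <= 6.5

    def test_infeasible_layout_is_error(self):
        with pytest.raises(ValueError, match="fit"):
            generate_genome(GenomeSpec(chrom_length=10_000, n_islands=10,
                                       island_length=900))

    def test_cpg_rich_hyper_patches_not_in_truth(self):
        spec = GenomeSpec(chrom_length=200_000, n_islands=10,
                          n_cpg_rich_hyper=10, seed=4)
        genome, islands = generate_genome(spec)
        assert len(islands) == 10


class TestSimulateMethylome:
    def test_island_rates_low_background_high(self):
        genome, islands = generate_genome(GenomeSpec(seed=1))
        spec = MethylomeSpec(coverage_mean=100.0, seed=2)
        track, truth = simulate_methylome(genome, islands, spec)
        island_rates = truth.true_rates["chr1"][truth.is_island["chr1"]]
        bg_rates = truth.true_rates["chr1"][~truth.is_island["chr1"]]
        assert island_rates.mean() == pytest.approx(10.0, abs=2.0)  # Beta(1,9)
        assert bg_rates.mean() == pytest.approx(90.0, abs=2.0)      # Beta(9,1)

    def test_finite_coverage_leaves_undetermined_dyads(self):
        genome, islands = generate_genome(GenomeSpec(seed=1))
        track, truth = simulate_methylome(genome, islands, MethylomeSpec(seed=2))
        n_sites = truth.positions["chr1"].size
        n_valid = len(filter_coverage(track, 5))
        # NB(mean 8, n=4): P(cov < 5) is substantial but not dominant
        assert 0.05 < 1 - n_valid / n_sites < 0.6

    def test_caller_recovers_islands_at_deep_coverage(self):
        genome, islands = generate_genome(
            GenomeSpec(chrom_length=400_000, n_islands=40, seed=5)
        )
        track, _ = simulate_methylome(genome, islands,
                                      MethylomeSpec(coverage_mean=30.0, seed=6))
        result = call_all(filter_coverage(track, 5), genome, CallerParams())
        truth_bp = {
            (c, p) for r in islands for c, p in
            ((r.chrom, q) for q in range(r.start, r.end))
        }
        called_bp = {
            (d.chrom, p) for d in result.hypo for p in range(d.start, d.end)
        }
        recovered = len(truth_bp & called_bp) / len(truth_bp)
        assert recovered >= 0.90

    def test_exact_truth_track(self):
        genome, islands = generate_genome(GenomeSpec(seed=1))
        _, truth = simulate_methylome(genome, islands, MethylomeSpec(seed=2))
        track = truth.to_track()
        pos0 = int(truth.positions["chr1"][0])
        assert track.get("chr1", pos0).rate == pytest.approx(
            truth.rate_at("chr1", pos0), abs=0.01
        )


class TestMspICapture:
    def test_toy_digestion(self):
        genome = GenomeSequence({"t": "TTCCGGAAACCGGTT"})
        pieces = digest_mspi(genome)["t"]
        assert pieces == [(0, 3), (3, 10), (10, 15)]
        seq = genome["t"]
        assert "".join(seq[a:b] for a, b in pieces) == seq
        assert seq[3:10] == "CGGAAAC"  # C^CGG cut convention

    def test_fragments_tile_chromosome(self):
        genome, _ = generate_genome(GenomeSpec(seed=7))
        for chrom, pieces in digest_mspi(genome).items():
            seq = genome[chrom]
            assert "".join(seq[a:b] for a, b in pieces) == seq

    def test_size_selection_and_extension(self):
        # internal fragments of 30, 40, 220 and 221 bp
        parts = ["T" * 10]
        for size in (30, 40, 220, 221):
            parts.append("CCGG" + "A" * (size - 4))
        parts.append("CCGG" + "T" * 10)
        genome = GenomeSequence({"c": "".join(parts)})
        frags = msp1_capture(genome)
        assert sorted(f.length for f in frags) == [40, 220]
        assert sorted(f.extended_length for f in frags) == [184, 364]

    def test_genome_without_ccgg_yields_nothing(self):
        assert msp1_capture(GenomeSequence({"c": "ATATATAT" * 100})) == []


@pytest.fixture(scope="module")
def world():
    genome, islands = generate_genome(
        GenomeSpec(chrom_length=1_000_000, n_islands=80,
                   n_cpg_rich_hyper=80, seed=11)
    )
    _, truth = simulate_methylome(genome, islands, MethylomeSpec(seed=12))
    frags = msp1_capture(genome)
    return truth, frags


class TestSimulateIntegration:
    def test_maintenance_without_gain_keeps_all_zero(self, world):
        truth, frags = world
        model = IntegrationModel(mode="maintenance", gain_rate=0.0, seed=1)
        recs = simulate_integration(frags, truth, "unmethylated", model)
        rates = [c.rate for r in recs for c in r.cpg_calls]
        assert rates and max(rates) == 0.0

    def test_premethylated_without_loss_keeps_all_hundred(self, world):
        truth, frags = world
        model = IntegrationModel(mode="maintenance", loss_rate=0.0, seed=1)
        recs = simulate_integration(frags, truth, "premethylated", model)
        rates = [c.rate for r in recs for c in r.cpg_calls]
        assert rates and min(rates) == 100.0

    def test_default_hypermethylation_ignores_library(self, world):
        truth, frags = world
        model = IntegrationModel(mode="default_hypermethylation", seed=1)
        for library in ("unmethylated", "premethylated"):
            recs = simulate_integration(frags, truth, library, model)
            rates = np.array([c.rate for r in recs for c in r.cpg_calls])
            assert rates.mean() > 80.0

    def test_deterministic_under_seed(self, world):
        truth, frags = world
        model = IntegrationModel(seed=3)
        a = simulate_integration(frags[:20], truth, "unmethylated", model)
        b = simulate_integration(frags[:20], truth, "unmethylated", model)
        assert [r.cpg_calls for r in a] == [r.cpg_calls for r in b]

    def test_unknown_library_rejected(self, world):
        truth, frags = world
        with pytest.raises(ValueError):
            simulate_integration(frags, truth, "mock", IntegrationModel())


class TestSimulateTrace:
    def test_noise_free_recovery_is_exact(self):
        sim = simulate_trace([75.0], editing_rate=50.0, noise_scale=0.0)
        c = sim.bisulfite_trace.height(0, "C")
        t = sim.bisulfite_trace.height(0, "T")
        assert 100 * c / (c + t) == 75.0
        e = sim.native_trace.height(0, "C")
        g = sim.native_trace.height(0, "G")
        assert 100 * e / (e + g) == 50.0

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(21)
        truth = rng.uniform(5, 95, size=100)
        sim = simulate_trace(truth, editing_rate=80.0, noise_scale=5.0, seed=22)
        recovered = np.array(
            [
                100 * sim.bisulfite_trace.height(i, "C")
                / (sim.bisulfite_trace.height(i, "C") + sim.bisulfite_trace.height(i, "T"))
                for i in sim.cpg_sites
            ]
        )
        assert np.median(np.abs(recovered - truth)) <= 5.0

    def test_deterministic_under_seed(self):
        a = simulate_trace([10, 50, 90], 30.0, noise_scale=10.0, seed=5)
        b = simulate_trace([10, 50, 90], 30.0, noise_scale=10.0, seed=5)
        assert a.bisulfite_trace.heights.equals(b.bisulfite_trace.heights)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_trace([120.0], 50.0)


class TestClassifierSegments:
    def test_deterministic_and_shaped(self):
        a_pos, a_neg = classifier_segments(n_per_class=20, seed=2)
        b_pos, b_neg = classifier_segments(n_per_class=20, seed=2)
        assert a_pos == b_pos and a_neg == b_neg
        assert len(a_pos) == len(a_neg) == 20

    def test_islands_are_cpg_denser(self):
        pos, neg = classifier_segments(n_per_class=100, seed=3)
        density = lambda seqs: np.mean(
            [1000 * s.count("CG") / len(s) for s in seqs]
        )
        assert density(pos) > 2 * density(neg)
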