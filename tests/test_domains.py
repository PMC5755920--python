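import numpy as np
import pytest

from methdomains.domains import (
    CallerParams,
    DomainKind,
    DyadClass,
    call_all,
    call_domains,
    call_domains_bruteforce,
    classify_dyads,
    domain_summaries,
)
from methdomains.io import GenomeSequence, enumerate_cpg_sites

from conftest import make_track

Q = DyadClass.QUALIFYING
N = DyadClass.NONQUALIFYING
U = DyadClass.UNDETERMINED


def seq_track(pattern, spacing=10):
    """Classified track from a string like 'QQQNQ' at regular spacing."""
    lut = {"Q": Q, "N": N, "U": U}
    return [(i * spacing, lut[ch]) for i, ch in enumerate(pattern)]


def random_classified(rng, n):
    classes = rng.choice([Q, N, U], size=n, p=[0.55, 0.25, 0.20])
    positions = np.cumsum(rng.integers(2, 50, size=n))
    return list(zip(positions.tolist(), classes.tolist()))


# ---------------------------------------------------------------------------
# dyad classification
# ---------------------------------------------------------------------------

class TestClassifyDyads:
    @pytest.mark.parametrize(
        "rate, kind, expected",
        [
            (39.9, DomainKind.HYPO, Q),
            (40.0, DomainKind.HYPO, N),   # threshold is strict
            (60.0, DomainKind.HYPER, N),
            (60.1, DomainKind.HYPER, Q),
        ],
    )
    def test_threshold_strictness(self, rate, kind, expected):
        n_meth = int(round(rate * 10))
        track = make_track([("chr1", 0, n_meth, 1000 - n_meth)])
        sites = {"chr1": np.array([0, 5])}
        classified = classify_dyads(track, sites, kind)["chr1"]
        assert classified[0][1] == expected
        assert classified[1][1] == U  # CG without a call is undetermined

    def test_call_off_cpg_site_is_error(self):
        track = make_track([("chr1", 3, 5, 0)])
        with pytest.raises(ValueError, match="non-CpG"):
            classify_dyads(track, {"chr1": np.array([0])}, DomainKind.HYPO)


# ---------------------------------------------------------------------------
# stretch caller
# ---------------------------------------------------------------------------

class TestCallDomains:
    def test_ten_qualifying_make_a_domain(self):
        (d,) = call_domains(seq_track("Q" * 10), DomainKind.HYPO)
        assert (d.n_qualifying, d.n_interleaved) == (10, 0)
        assert (d.start, d.end) == (0, 92)  # last C position + 2

    def test_nine_qualifying_do_not(self):
        assert call_domains(seq_track("Q" * 9), DomainKind.HYPO) == []

    def test_five_interleaved_split_into_two_domains(self):
        domains = call_domains(seq_track("Q" * 12 + "N" * 5 + "Q" * 12), DomainKind.HYPO)
        assert [d.n_qualifying for d in domains] == [12, 12]
        assert all(d.n_interleaved == 0 for d in domains)

    def test_two_interleaved_bridge_one_domain(self):
        (d,) = call_domains(seq_track("Q" * 6 + "N" * 2 + "Q" * 6), DomainKind.HYPO)
        assert (d.n_qualifying, d.n_interleaved) == (12, 2)

    def test_undetermined_counts_against_budget(self):
        (d,) = call_domains(seq_track("Q" * 6 + "U" * 4 + "Q" * 6), DomainKind.HYPO)
        assert d.n_interleaved == 4
        assert call_domains(seq_track("Q" * 6 + "U" * 5 + "Q" * 6), DomainKind.HYPO) == []

    def test_domains_start_and_end_on_qualifying(self, rng):
        for _ in range(50):
            classified = random_classified(rng, 120)
            lut = dict(classified)
            for d in call_domains(classified, DomainKind.HYPO):
                assert lut[d.start] == Q
                assert lut[d.end - 2] == Q

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            call_domains([(10, Q), (5, Q)], DomainKind.HYPO)

    def test_greedy_matches_bruteforce_oracle(self, rng):
        params = CallerParams()
        for _ in range(200):
            classified = random_classified(rng, int(rng.integers(1, 150)))
            greedy = call_domains(classified, DomainKind.HYPO, params)
            oracle = call_domains_bruteforce(classified, DomainKind.HYPO, params)
            assert [(d.start, d.end, d.n_qualifying, d.n_interleaved) for d in greedy] == [
                (d.start, d.end, d.n_qualifying, d.n_interleaved) for d in oracle
            ]

    def test_no_domain_extendable_by_one_dyad(self, rng):
        params = CallerParams()
        for _ in range(50):
            classified = random_classified(rng, 150)
            positions = [p for p, _ in classified]
            classes = [c for _, c in classified]
            for d in call_domains(classified, DomainKind.HYPO, params):
                i = positions.index(d.start)
                j = positions.index(d.end - 2)
                for ni, nj in ((i - 1, j), (i, j + 1)):
                    if ni < 0 or nj >= len(classes):
                        continue
                    seg = classes[ni : nj + 1]
                    q = seg.count(Q)
                    bad = len(seg) - q
                    feasible = (
                        seg[0] == Q and seg[-1] == Q
                        and q >= params.min_qualifying
                        and bad <= params.max_interleaved
                    )
                    assert not feasible, "domain extendable by one dyad"

    def test_budget_monotonicity_of_feasible_coverage(self, rng):
        # Raising the interleave budget grows the set of feasible segments,
        # so the qualifying dyads covered by ANY feasible segment can only
        # grow.  (The greedy left-to-right segmentation itself is not
        # monotone: a longer first domain can strand a later dyad.)
        def feasible_coverage(classes, budget, min_q=10):
            n = len(classes)
            covered = set()
            for i in range(n):
                if classes[i] != Q:
                    continue
                q = bad = 0
                for j in range(i, n):
                    if classes[j] == Q:
                        q += 1
                        if q >= min_q and bad <= budget:
                            covered.update(
                                k for k in range(i, j + 1) if classes[k] == Q
                            )
                    else:
                        bad += 1
                        if bad > budget:
                            break
            return covered

        for _ in range(20):
            classes = [c for _, c in random_classified(rng, 80)]
            prev: set = set()
            for budget in (0, 2, 4, 6):
                cov = feasible_coverage(classes, budget)
                assert prev <= cov
                prev = cov

    def test_consecutive_run_mode(self):
        params = CallerParams(interleave_mode="run", max_interleaved=2)
        # runs of 2 are bridged regardless of total count
        pattern = "Q" * 4 + "NN" + "Q" * 4 + "NN" + "Q" * 4
        (d,) = call_domains(seq_track(pattern), DomainKind.HYPO, params)
        assert (d.n_qualifying, d.n_interleaved) == (12, 4)


# ---------------------------------------------------------------------------
# combined calling and summaries
# ---------------------------------------------------------------------------

def uniform_cg_genome(n_cg, spacer="AT" * 4):
    seq = ("CG" + spacer) * n_cg
    return GenomeSequence({"chr1": seq})


class TestCallAll:
    def test_all_unmethylated_gives_one_hypomd(self):
        genome = uniform_cg_genome(12)
        sites = enumerate_cpg_sites(genome)["chr1"]
        track = make_track([("chr1", int(p), 0, 10) for p in sites])
        result = call_all(track, genome)
        assert len(result.hypo) == 1 and result.hyper == []
        assert result.hypo[0].n_qualifying == 12
        assert result.hypo[0].mean_rate == 0.0

    def test_all_methylated_gives_one_hypermd(self):
        genome = uniform_cg_genome(12)
        sites = enumerate_cpg_sites(genome)["chr1"]
        track = make_track([("chr1", int(p), 10, 0) for p in sites])
        result = call_all(track, genome)
        assert len(result.hyper) == 1 and result.hypo == []

    def test_alternating_rates_give_neither(self):
        genome = uniform_cg_genome(40)
        sites = enumerate_cpg_sites(genome)["chr1"]
        track = make_track(
            [("chr1", int(p), 0 if i % 2 else 10, 10 if i % 2 else 0)
             for i, p in enumerate(sites)]
        )
        result = call_all(track, genome)
        assert result.hypo == [] and result.hyper == []


class TestDomainSummaries:
    def test_pure_cg_domain(self):
        genome = GenomeSequence({"chr1": "CG" * 500})
        sites = enumerate_cpg_sites(genome)["chr1"]
        track = make_track([("chr1", int(p), 0, 10) for p in sites])
        result = call_all(track, genome)
        summary = domain_summaries(result.hypo, track, genome)
        row = summary.iloc[0]
        assert row["gc"] == 1.0
        assert row["cpg_per_kb"] == pytest.approx(500, rel=0.01)
        assert row["mean_rate"] == 0.0

    def test_empty_domain_list(self, toy_track, toy_genome):
        assert len(domain_summaries([], toy_track, toy_genome)) == 0
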