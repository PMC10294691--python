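"""PWM construction, scoring, scanning, scrambling, centrality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonkit.model import BindingSite, GenomicInterval, Peak
from regulonkit.motif import (
    PWM,
    build_pwm,
    centrality_profile,
    encode,
    genome_background,
    reverse_complement,
    scan_genome,
    scramble_sites,
    scrambled_null_overlap,
)

dna = st.text(alphabet="ACGT", min_size=4, max_size=12)


def brute_force_scan(pwm, genome, top_k):
    """Independent oracle: rescore every window on both strands explicitly."""
    hits = []
    w = pwm.width
    for i in range(len(genome) - w + 1):
        window = genome[i : i + w]
        hits.append((pwm.score(window), i, "+"))
        hits.append((pwm.score(reverse_complement(window)), i, "-"))
    hits.sort(key=lambda t: (-round(t[0], 9), t[1], t[2]))
    return hits[:top_k]


class TestBuildPWM:
    def test_pure_sites_probability_one(self):
        pwm = build_pwm(["AA", "AA"], pseudocount=0)
        assert pwm.probabilities[0, 0] == 1.0
        assert pwm.probabilities[1, 0] == 1.0

    def test_counts_reflect_input(self):
        pwm = build_pwm(["AC", "AG", "AT"], pseudocount=0.5)
        np.testing.assert_array_equal(pwm.counts[0], [3, 0, 0, 0])
        np.testing.assert_array_equal(pwm.counts[1], [0, 1, 1, 1])

    def test_probability_columns_sum_to_one(self, table1):
        _, sites, _ = table1
        pwm = build_pwm(sites)
        np.testing.assert_allclose(pwm.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_consensus_matches_independent_tally(self, table1):
        # brute-force per-column nucleotide tally over the 59 fixture 18-mers
        _, sites, _ = table1
        tally_consensus = ""
        for j in range(18):
            col = [s.sequence[j] for s in sites]
            tally_consensus += max("ACGT", key=col.count)
        pwm = build_pwm(sites)
        assert pwm.consensus == tally_consensus
        # direct-repeat pho-box structure: two TGTCA-like half-sites 11 bp apart
        assert tally_consensus[:4] == "TGTC" and tally_consensus[11:15] == "TGTC"

    def test_single_site_rejected(self):
        with pytest.raises(ValueError, match=">= 2 sites"):
            build_pwm(["ACGT"])

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed lengths"):
            build_pwm(["ACGT", "ACG"])

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            build_pwm(["ACGN", "ACGT"])

    def test_finite_log_odds_with_pseudocount(self, table1):
        _, sites, _ = table1
        pwm = build_pwm(sites, pseudocount=0.5)
        assert np.isfinite(pwm.log_odds).all()


class TestScore:
    def test_two_mer_closed_form(self):
        # p(A)=0.5 both positions, uniform bg: score("AA") = 2*log2(0.5/0.25)
        counts = np.array([[2, 2, 0, 0], [2, 0, 2, 0]], dtype=float)
        pwm = PWM(counts, pseudocount=0)
        assert pwm.score("AA") == pytest.approx(2.0)

    def test_uniform_pwm_scores_zero(self):
        pwm = PWM(np.ones((4, 4)), pseudocount=0)
        for seq in ("ACGT", "TTTT", "GATC"):
            assert pwm.score(seq) == pytest.approx(0.0)

    def test_consensus_is_maximal(self, table1):
        _, sites, _ = table1
        pwm = build_pwm(sites)
        assert pwm.score(pwm.consensus) == pytest.approx(pwm.max_score)

    def test_length_mismatch(self):
        pwm = build_pwm(["ACGT", "ACGT"])
        with pytest.raises(ValueError, match="length"):
            pwm.score("ACG")

    def test_strand_consistency_identity(self, table1):
        # score of seq against the reverse-complement PWM equals score of
        # revcomp(seq) against the forward PWM
        _, sites, _ = table1
        pwm = build_pwm(sites)
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=pwm.width))
            assert pwm.reverse_complement().score(seq) == pytest.approx(
                pwm.score(reverse_complement(seq))
            )

    def test_background_expected_score_nonpositive(self):
        # E[score] under the background equals -KL <= 0
        rng = np.random.default_rng(1)
        pwm = build_pwm(["TGTCAT", "TGACAT", "TTTCAT", "AGTCAT"], pseudocount=0.5)
        seqs = rng.choice(list("ACGT"), size=(10_000, pwm.width))
        scores = [pwm.score("".join(s)) for s in seqs]
        assert np.mean(scores) <= 0


class TestScan:
    def test_planted_consensus_found(self):
        rng = np.random.default_rng(2)
        background = "".join(rng.choice(list("ACGT"), size=500))
        consensus = "TGTCATAAAACTGTCATA"
        genome = background[:200] + consensus + background[200:]
        pwm = build_pwm([consensus, consensus], pseudocount=0.5)
        (hit,) = scan_genome(pwm, genome, top_k=1)
        assert hit.position == 200

    def test_palindromic_pwm_strand_ties(self):
        pwm = build_pwm(["ACGT", "ACGT"], pseudocount=0.5)  # self-revcomp
        genome = "AAACGTAA"
        hits = scan_genome(pwm, genome, top_k=4)
        top2 = hits[:2]
        assert {h.strand for h in top2} == {"+", "-"}
        assert top2[0].position == top2[1].position == 2
        assert top2[0].score == pytest.approx(top2[1].score)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        genome = "".join(rng.choice(list("ACGT"), size=1000))
        pwm = build_pwm(["TGTCA", "TGACA", "TGTCA"], pseudocount=0.5)
        hits = scan_genome(pwm, genome, top_k=10)
        oracle = brute_force_scan(pwm, genome, 10)
        assert [(h.position, h.strand) for h in hits] == [(p, s) for _, p, s in oracle]
        for h, (score, _, _) in zip(hits, oracle):
            assert h.score == pytest.approx(score)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        site_a=st.text(alphabet="ACGT", min_size=5, max_size=5),
        site_b=st.text(alphabet="ACGT", min_size=5, max_size=5),
    )
    def test_scan_oracle_property(self, seed, site_a, site_b):
        rng = np.random.default_rng(seed)
        genome = "".join(rng.choice(list("ACGT"), size=300))
        pwm = build_pwm([site_a, site_b], pseudocount=0.5)
        hits = scan_genome(pwm, genome, top_k=5)
        oracle = brute_force_scan(pwm, genome, 5)
        assert [(h.position, h.strand) for h in hits] == [(p, s) for _, p, s in oracle]

    def test_short_genome_rejected(self):
        pwm = build_pwm(["ACGT", "ACGT"])
        with pytest.raises(ValueError, match="shorter"):
            scan_genome(pwm, "ACG", top_k=1)


class TestScramble:
    def test_mononucleotide_invariance(self):
        assert scramble_sites(["AAAA"], seed=0) == ["AAAA"]

    def test_multiset_preserved(self):
        sites = ["TGTCATAAAACTGTCATA", "GGTCACATTACGTTCATG"]
        for original, scrambled in zip(sites, scramble_sites(sites, seed=1)):
            assert sorted(original) == sorted(scrambled)

    def test_seed_determinism(self):
        sites = ["TGTCAT", "ACGTAC", "TTATGC"]
        assert scramble_sites(sites, seed=42) == scramble_sites(sites, seed=42)

    def test_overall_composition_exact(self, table1):
        _, sites, _ = table1
        pooled = "".join(s.sequence for s in sites)
        scrambled = "".join(scramble_sites(sites, seed=7))
        assert sorted(pooled) == sorted(scrambled)


class TestScrambledNullOverlap:
    def setup_method(self):
        rng = np.random.default_rng(4)
        self.genome = "".join(rng.choice(list("ACGT"), size=2000))
        self.sites = ["TGTCATAAAACTGTCATA"] * 5

    def test_whole_genome_fraction_one(self):
        regions = [GenomicInterval("g", 0, 2000)]
        frac = scrambled_null_overlap(self.sites, self.genome, regions, top_k=20, seed=0)
        assert frac == 1.0

    def test_empty_regions_fraction_zero(self):
        frac = scrambled_null_overlap(self.sites, self.genome, [], top_k=20, seed=0)
        assert frac == 0.0

    def test_matches_membership_oracle(self):
        regions = [GenomicInterval("g", 100, 400), GenomicInterval("g", 900, 1300)]
        from regulonkit.motif import build_pwm as _b, scan_genome as _s, scramble_sites as _p

        frac = scrambled_null_overlap(self.sites, self.genome, regions, top_k=50, seed=5)
        scrambled = _p(self.sites, seed=5)
        pwm = _b(scrambled, pseudocount=0.5)
        hits = _s(pwm, self.genome, top_k=50)
        inside = sum(
            any(r.start <= h.midpoint(pwm.width) < r.end for r in regions) for h in hits
        )
        assert frac == pytest.approx(inside / 50)

    def test_at_rich_motif_enriched_in_at_domains(self, sim_study):
        config, study = sim_study
        from regulonkit.motif import genome_background
        from regulonkit.occupancy import genome_fraction

        frac = scrambled_null_overlap(
            [p.site for p in study.peaks if p.site],
            study.genome,
            study.silencers,
            top_k=500,
            seed=2,
            background=genome_background(study.genome),
        )
        silencer_frac = genome_fraction(study.silencers, config.genome_length)
        assert frac > silencer_frac  # composition alone drives the enrichment


class TestCentrality:
    def test_single_site_offsets(self):
        site = BindingSite("A" * 18, position=91)
        p = Peak(id="p", contig="c", center=100, score=1.0, site=site)
        profile = centrality_profile([p], half_range=20)
        covered = dict(zip(profile.offsets.tolist(), profile.coverage.tolist()))
        assert all(covered[o] == 1 for o in range(-9, 9))
        assert covered[-10] == 0 and covered[9] == 0

    def test_two_identical_placements_stack(self):
        site = BindingSite("A" * 18, position=91)
        peaks = [
            Peak(id=f"p{i}", contig="c", center=100, score=1.0, site=site) for i in range(2)
        ]
        profile = centrality_profile(peaks, half_range=20)
        assert profile.coverage.max() == 2

    def test_skips_and_counts_unplaced(self):
        p1 = Peak(id="p1", contig="c", center=100, score=1.0)
        profile = centrality_profile([p1])
        assert profile.n_skipped == 1
        assert profile.coverage.sum() == 0

    def test_simulated_sites_centrally_enriched(self, sim_study):
        _, study = sim_study
        profile = centrality_profile(study.peaks, half_range=50)
        assert abs(profile.peak_offset()) <= 20

    def test_total_site_bases_conserved(self, sim_study):
        _, study = sim_study
        profile = centrality_profile(study.peaks, half_range=50)
        placed = sum(1 for p in study.peaks if p.site and p.site.position is not None)
        assert profile.coverage.sum() == placed * 18


def test_meme_serialization_round_trips_probabilities(table1):
    _, sites, _ = table1
    pwm = build_pwm(sites)
    text = pwm.to_meme("pho_box")
    assert "MOTIF pho_box" in text
    rows = [l for l in text.splitlines() if l and l[0].isdigit()]
    parsed = np.array([[float(x) for x in r.split()] for r in rows])
    np.testing.assert_allclose(parsed, pwm.probabilities, atol=5e-7)


def test_genome_background_frequencies():
    bg = genome_background("AACG")
    np.testing.assert_allclose(bg, [0.5, 0.25, 0.25, 0.0])
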