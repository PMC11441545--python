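"""IES screen: candidate calling, retention, TDRs, haplotype concordance."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dualism import ies
from dualism.simulate.genome import random_sequence
from conftest import make_sam


@pytest.fixture
def reference():
    rng = np.random.default_rng(0)
    return {"c1": random_sequence(rng, 2000, (0.25,) * 4)}


def _reads_with_insert(reference, n_with, n_without, ins_len=20, junction=1000):
    """Construct reads around a junction: carriers have an I op there."""
    ref = reference["c1"]
    reads = []
    for i in range(n_with):
        start = junction - 500
        ins = "G" * ins_len
        seq = ref[start:junction] + ins + ref[junction : junction + 500]
        reads.append((f"with{i}", "c1", start, f"500M{ins_len}I500M", seq, {"HP": 1}))
    for i in range(n_without):
        start = junction - 480
        seq = ref[start : start + 960]
        reads.append((f"without{i}", "c1", start, "960M", seq, {"HP": 2}))
    return reads


class TestCallCandidates:
    def test_basic_insertion_retention_half(self, reference, tmp_path):
        sam = make_sam(tmp_path / "a.sam", {"c1": 2000}, _reads_with_insert(reference, 3, 3))
        cands = ies.call_indel_candidates(sam, reference)
        assert len(cands) == 1
        c = cands[0]
        assert (c.type, c.junction_pos, c.length) == ("ins", 1000, 20)
        assert c.retention == 0.5

    def test_below_min_break_coverage_no_candidate(self, reference, tmp_path):
        sam = make_sam(tmp_path / "a.sam", {"c1": 2000}, _reads_with_insert(reference, 2, 5))
        assert ies.call_indel_candidates(sam, reference) == []

    def test_below_min_length_no_candidate(self, reference, tmp_path):
        sam = make_sam(
            tmp_path / "a.sam", {"c1": 2000}, _reads_with_insert(reference, 5, 5, ins_len=10)
        )
        assert ies.call_indel_candidates(sam, reference) == []

    def test_deletion_needs_min_del_coverage(self, reference, tmp_path):
        ref = reference["c1"]
        def del_reads(n):
            reads = []
            for i in range(n):
                seq = ref[500:1000] + ref[1020:1520]
                reads.append((f"d{i}", "c1", 500, "500M20D500M", seq))
            return reads
        sam = make_sam(tmp_path / "four.sam", {"c1": 2000}, del_reads(4))
        assert ies.call_indel_candidates(sam, reference) == []
        sam = make_sam(tmp_path / "five.sam", {"c1": 2000}, del_reads(5))
        cands = ies.call_indel_candidates(sam, reference)
        assert len(cands) == 1 and cands[0].type == "del" and cands[0].length == 20

    def test_unknown_contig_rejected(self, reference, tmp_path):
        sam = make_sam(tmp_path / "a.sam", {"cX": 2000}, [("r", "cX", 0, "100M", "A" * 100)])
        with pytest.raises(ValueError, match="absent"):
            ies.call_indel_candidates(sam, {"c1": reference["c1"]})

    def test_min_length_monotonicity(self, mic_mac_sams, diploid):
        """Raising the length cutoff never increases the candidate count."""
        counts = [
            len(
                ies.call_indel_candidates(
                    mic_mac_sams["MIC"], diploid.reference, min_length=m
                )
            )
            for m in (15, 20, 30)
        ]
        assert counts == sorted(counts, reverse=True)


class TestRetention:
    def test_values(self):
        assert ies.retention_score(5, 5) == 0.5
        assert ies.retention_score(0, 7) == 0.0
        with pytest.raises(ValueError):
            ies.retention_score(0, 0)

    def test_monoallelic_indels_retention_near_half(self, mic_mac_sams, diploid):
        """Balanced 40x diploid: mean candidate retention ~= 0.5, and
        per-candidate retention matches the truth-computed fraction
        within binomial error."""
        cands = ies.call_indel_candidates(mic_mac_sams["MIC"], diploid.reference)
        rets = [c.retention for c in cands if c.retention is not None]
        assert len(rets) >= 50
        assert abs(np.mean(rets) - 0.5) < 0.05
        for c in cands:
            n = c.n_with + c.n_without
            assert abs(c.retention - 0.5) < 4 * np.sqrt(0.25 / n)


class TestCompare:
    def test_identical_scores_p_at_least_half(self):
        assert ies.wilcoxon_one_sided([0.0] * 20) >= 0.5

    def test_uniform_shift_strongly_significant(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.2, 0.6, size=20)
        a = [ies.IndelCandidate("c1", 100 * i, "ins", 20, n_with=int(20 * (b + 0.4)), n_without=int(20 * (1 - b - 0.4) + 0.5)) for i, b in enumerate(base)]
        # direct check on the statistic: 20 positive differences
        p = ies.wilcoxon_one_sided(list(base + 0.4 - base))
        assert p < 0.001

    def test_matching_by_position_and_length(self):
        a = [ies.IndelCandidate("c1", 100, "ins", 20, n_with=5, n_without=5)]
        b = [
            ies.IndelCandidate("c1", 104, "ins", 22, n_with=5, n_without=5),
            ies.IndelCandidate("c1", 500, "ins", 20, n_with=5, n_without=5),
            ies.IndelCandidate("c1", 102, "del", 20, n_with=5, n_without=5),
        ]
        comp = ies.compare_libraries(a, b, match_tol=10)
        assert len(comp.shared) == 1
        assert comp.shared[0][1].junction_pos == 104
        assert len(comp.unique_b) == 2

    def test_flag_mic_unique_high(self):
        uniq = [
            ies.IndelCandidate("c1", 1, "ins", 20, n_with=4, n_without=0),
            ies.IndelCandidate("c1", 200, "ins", 20, n_with=5, n_without=5),
        ]
        comp = ies.compare_libraries(uniq, [], match_tol=10)
        flagged, mean_cov = ies.flag_mic_unique_high(comp, retention_threshold=0.9)
        assert [c.junction_pos for c in flagged] == [1]
        assert mean_cov == 4.0

    def test_no_mic_unique_no_flags(self):
        a = [ies.IndelCandidate("c1", 100, "ins", 20, n_with=5, n_without=5)]
        comp = ies.compare_libraries(a, a, match_tol=10)
        flagged, mean_cov = ies.flag_mic_unique_high(comp)
        assert flagged == [] and mean_cov is None


class TestTdr:
    def test_left_flank_match(self):
        ref = {"c1": "AAAACCGATAGGGGTTTT"}
        # junction at 10: left flank ...CCGATA; insert ends with GATA
        c = ies.IndelCandidate("c1", 10, "ins", 8, insert_seq="TTTT" + "GATA")
        ann = ies.detect_tdr(c, ref, max_tdr=6)
        assert ann.tdr_len == 4 and ann.tdr_seq == "GATA" and ann.contains_ta

    def test_no_match_len_zero(self):
        ref = {"c1": "AAAAAAAAAACCCCCCCCCC"}
        c = ies.IndelCandidate("c1", 10, "ins", 6, insert_seq="GGGGGG")
        ann = ies.detect_tdr(c, ref, max_tdr=6)
        assert ann.tdr_len == 0 and not ann.contains_ta

    def test_two_sided_max(self):
        #           0123456789
        ref = {"c1": "GGGGGTTAAA"}
        # insert prefix TTA matches right flank (3); suffix G matches left (1)
        c = ies.IndelCandidate("c1", 5, "ins", 6, insert_seq="TTACCG")
        ann = ies.detect_tdr(c, ref, max_tdr=6)
        assert ann.tdr_len == 3 and ann.tdr_seq == "TTA"

    def test_expected_distribution_closed_form(self):
        d = ies.expected_tdr_distribution((0.25,) * 4, max_tdr=10)
        p = 0.25
        assert d[0] == pytest.approx(0.75 * 0.75)
        assert d[1] == pytest.approx((1 - p**2) ** 2 - (1 - p) ** 2)
        assert d.sum() == pytest.approx(1.0)

    def test_degenerate_single_base_all_mass_at_cap(self):
        d = ies.expected_tdr_distribution((1.0, 0.0, 0.0, 0.0), max_tdr=5)
        assert d[5] == pytest.approx(1.0)

    def test_monte_carlo_matches_expectation(self):
        """TDR lengths at random junctions follow the two-sided-max
        geometric law (chi-square over bins)."""
        rng = np.random.default_rng(6)
        freqs = (0.35, 0.15, 0.15, 0.35)
        max_tdr = 10
        n = 100_000
        probs = np.array(freqs)
        def side(n):
            a = rng.choice(4, size=(n, max_tdr), p=probs)
            b = rng.choice(4, size=(n, max_tdr), p=probs)
            alive = np.ones(n, dtype=bool)
            run = np.zeros(n, dtype=int)
            for k in range(max_tdr):
                alive &= a[:, k] == b[:, k]
                run += alive
            return run
        lengths = np.maximum(side(n), side(n))
        obs = np.bincount(lengths, minlength=max_tdr + 1)
        exp = ies.expected_tdr_distribution(freqs, max_tdr) * n
        keep = 7  # pool sparse tail
        chi2, p = stats.chisquare(
            np.append(obs[:keep], obs[keep:].sum()),
            np.append(exp[:keep], exp[keep:].sum()),
        )
        assert p > 0.01

    def test_simulated_tdr_candidates_enriched(self, diploid):
        """Generator TDR-bounded insertions exceed the random expectation."""
        truth_lengths = [r.tdr_len for r in diploid.truth.insertions()]
        n = len(truth_lengths)
        exp = ies.expected_tdr_distribution(diploid.config.base_freqs, 20)
        expected_ge3 = n * exp[3:].sum()
        observed_ge3 = sum(1 for t in truth_lengths if t >= 3)
        assert observed_ge3 > expected_ge3 + 3 * np.sqrt(expected_ge3)


class TestHaplotypeConcordance:
    def test_perfect_split_fisher(self):
        from collections import Counter

        c = ies.IndelCandidate(
            "c1", 100, "ins", 20, n_with=5, n_without=5,
            hp_with=Counter({1: 5}), hp_without=Counter({2: 5}),
        )
        conc, p, n = ies.haplotype_concordance(c)
        assert conc == 1.0 and n == 10
        assert p == pytest.approx(2 / 252, rel=1e-6)  # hypergeometric [[5,0],[0,5]]

    def test_independent_haplotype_concordance_half(self):
        from collections import Counter

        c = ies.IndelCandidate(
            "c1", 100, "ins", 20, n_with=20, n_without=20,
            hp_with=Counter({1: 10, 2: 10}), hp_without=Counter({1: 10, 2: 10}),
        )
        conc, p, _ = ies.haplotype_concordance(c)
        assert conc == 0.5 and p == 1.0

    def test_untagged_reads_give_none(self):
        c = ies.IndelCandidate("c1", 100, "ins", 20, n_with=5, n_without=5)
        assert ies.haplotype_concordance(c) is None

    def test_simulated_monoallelic_median_concordance(self, mic_mac_sams, diploid):
        cands = ies.call_indel_candidates(mic_mac_sams["MAC"], diploid.reference)
        concs = [r[0] for r in map(ies.haplotype_concordance, cands) if r]
        assert np.median(concs) > 0.95


class TestVcfTagging:
    def test_majority_vote_matches_hp(self, diploid, small_config, tmp_path):
        """Reads tagged from the phased VCF agree with their true haplotype."""
        from dualism.simulate import simulate_long_reads
        import pysam

        plain = tmp_path / "untagged.sam"
        simulate_long_reads(diploid, "MAC", small_config, plain, with_hp_tags=False)
        tagged = tmp_path / "tagged.sam"
        n = ies.assign_haplotypes_from_vcf(plain, diploid.paths["vcf"], tagged)
        assert n > 0
        total = agree = 0
        with pysam.AlignmentFile(str(tagged), "r") as af:
            for read in af:
                if not read.has_tag("HP"):
                    continue
                true_hap = int(read.query_name.split("_h")[1].split("_")[0])
                total += 1
                agree += read.get_tag("HP") == true_hap
        assert total > 100 and agree / total > 0.99


class TestClassification:
    def test_truth_based_labels(self, mic_mac_sams, diploid):
        cands_mic = ies.call_indel_candidates(mic_mac_sams["MIC"], diploid.reference)
        cands_mac = ies.call_indel_candidates(mic_mac_sams["MAC"], diploid.reference)
        for c in cands_mic:
            ies.haplotype_concordance(c)
        comp = ies.compare_libraries(cands_mic, cands_mac)
        labels = ies.classify_candidates(comp)
        shared_labels = [labels[id(ca)] for ca, _ in comp.shared]
        frac_hap = np.mean(
            [l == "haplotype-linked polymorphism" for l in shared_labels]
        )
        assert frac_hap > 0.9
        assert "putative IES" not in set(shared_labels)

    def test_true_ies_labelled_putative(self, tmp_path):
        """A germline-limited insert (MIC-only, retention 1.0) is flagged."""
        from dualism.config import SimulationConfig
        from dualism.simulate import simulate_diploid_genome, simulate_long_reads

        cfg = SimulationConfig(
            genome_length=100_000, n_contigs=1, n_true_ies=4,
            indel_rate=1e-4, coverage_per_library=30, read_length=3000, seed=44,
        )
        dg = simulate_diploid_genome(cfg, tmp_path)
        mic, mac = tmp_path / "mic.sam", tmp_path / "mac.sam"
        simulate_long_reads(dg, "MIC", cfg, mic)
        simulate_long_reads(dg, "MAC", cfg, mac)
        cm = ies.call_indel_candidates(mic, dg.reference)
        ca = ies.call_indel_candidates(mac, dg.reference)
        for c in cm:
            ies.haplotype_concordance(c)
        comp = ies.compare_libraries(cm, ca)
        labels = ies.classify_candidates(comp)
        ies_positions = {r.pos for r in dg.truth.indel_records if r.is_true_ies}
        hits = [
            c for c in comp.unique_a
            if any(abs(c.junction_pos - p) <= 10 for p in ies_positions)
        ]
        assert len(hits) == 4
        assert all(labels[id(c)] == "putative IES" for c in hits)

    def test_low_coverage_indeterminate(self):
        a = [ies.IndelCandidate("c1", 100, "ins", 20, n_with=3, n_without=0)]
        comp = ies.compare_libraries(a, [], match_tol=10)
        labels = ies.classify_candidates(comp, low_cov_threshold=10)
        assert labels[id(a[0])] == "indeterminate (low coverage)"


@settings(max_examples=30, deadline=None)
@given(
    st.integers(min_value=0, max_value=50),
    st.integers(min_value=0, max_value=50),
)
def test_retention_bounds_property(n_with, n_without):
    if n_with + n_without == 0:
        with pytest.raises(ValueError):
            ies.retention_score(n_with, n_without)
    else:
        r = ies.retention_score(n_with, n_without)
        assert 0.0 <= r <= 1.0
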