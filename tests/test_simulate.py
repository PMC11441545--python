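"""Synthetic-data generator: determinism, truth consistency, and the
statistical structure the downstream analyses assume."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from dualism.config import SimulationConfig
from dualism.io_utils import read_fasta, read_phased_snps
from dualism.simulate import (
    simulate_6mA_calls,
    simulate_diploid_genome,
    simulate_genic_genome,
    simulate_long_reads,
    simulate_nucleosome_fragments,
    simulate_transcripts_and_splices,
)


class TestDiploidGenome:
    def test_snp_density_matches_heterozygosity(self, diploid, small_config):
        total = sum(len(s) for s in diploid.reference.values())
        density = len(diploid.truth.snp_records) / total
        assert abs(density - small_config.het_snp_rate) < 0.0005

    def test_no_indels_when_rate_zero(self):
        cfg = SimulationConfig(genome_length=50_000, n_contigs=1, indel_rate=0.0, seed=1)
        dg = simulate_diploid_genome(cfg)
        assert dg.truth.indel_records == []
        # haplotypes differ by SNPs only: equal length
        for contig in dg.reference:
            assert len(dg.layouts["MAC"][2][contig].seq) == len(dg.reference[contig])

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(genome_length=60_000, n_contigs=2, seed=7)
        for sub in ("a", "b"):
            simulate_diploid_genome(cfg, tmp_path / sub)
        for name in ("reference.fasta", "haplotype2.fasta", "snps.vcf"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_too_small_genome_raises(self):
        cfg = SimulationConfig(genome_length=2000, n_contigs=2, indel_rate=0.05, seed=1)
        with pytest.raises(ValueError):
            simulate_diploid_genome(cfg)

    def test_vcf_round_trip(self, diploid):
        snps = read_phased_snps(diploid.paths["vcf"])
        truth = {(s.contig, s.pos, s.ref, s.alt, s.haplotype) for s in diploid.truth.snp_records}
        assert set(snps) == truth

    def test_truth_replay_against_haplotype_fasta(self, diploid):
        """Applying the truth SNPs/indels to the reference reproduces
        haplotype 2 exactly (round-trip audit)."""
        hap2 = read_fasta(diploid.paths["haplotype2"])
        for contig, ref in diploid.reference.items():
            events = sorted(
                [
                    r
                    for r in diploid.truth.indel_records
                    if r.contig == contig and not r.is_true_ies
                ],
                key=lambda r: r.pos,
            )
            snps = {
                s.pos: s.alt for s in diploid.truth.snp_records if s.contig == contig
            }
            pieces = []
            pos = 0
            for r in events:
                pieces.append(ref[pos : r.pos])
                if r.type == "ins":
                    pieces.append(r.seq)
                    pos = r.pos
                else:
                    pos = r.pos + r.length
            pieces.append(ref[pos:])
            rebuilt = list("".join(pieces))
            # SNP substitution: positions are in reference coordinates;
            # shift by preceding indels
            shift = 0
            events_i = 0
            out = []
            # simpler: substitute on the reference first, then apply indels
            refmut = list(ref)
            for p, alt in snps.items():
                refmut[p] = alt
            pieces = []
            pos = 0
            for r in events:
                pieces.append("".join(refmut[pos : r.pos]))
                if r.type == "ins":
                    pieces.append(r.seq)
                    pos = r.pos
                else:
                    pos = r.pos + r.length
            pieces.append("".join(refmut[pos:]))
            assert "".join(pieces) == hap2[contig]

    def test_tdr_insertions_duplicate_flank_and_contain_ta(self, diploid):
        n_tdr = 0
        for r in diploid.truth.insertions():
            if r.tdr_len > 0:
                n_tdr += 1
                flank = diploid.reference[r.contig][r.pos - r.tdr_len : r.pos]
                assert r.seq[-r.tdr_len :] == flank
                assert "TA" in flank
        assert n_tdr > 0

    def test_true_ies_only_in_mic_template(self):
        cfg = SimulationConfig(
            genome_length=100_000, n_contigs=1, n_true_ies=5, indel_rate=1e-4, seed=3
        )
        dg = simulate_diploid_genome(cfg)
        ies = [r for r in dg.truth.indel_records if r.is_true_ies]
        assert len(ies) == 5
        for r in ies:
            assert r.retention_truth == {"MIC": 1.0, "MAC": 0.0}
            # present on both MIC haplotypes: both MIC layouts longer
            for hap in (1, 2):
                assert len(dg.layouts["MIC"][hap][r.contig].seq) > len(
                    dg.layouts["MAC"][hap][r.contig].seq
                ) - 1


class TestLongReads:
    def test_mean_depth_matches_coverage(self, mic_mac_sams, diploid, small_config):
        """Pileup-oracle: mean per-base depth ~ configured coverage."""
        depth = {c: np.zeros(len(s)) for c, s in diploid.reference.items()}
        with pysam.AlignmentFile(str(mic_mac_sams["MIC"]), "r") as af:
            for read in af:
                depth[read.reference_name][
                    read.reference_start : read.reference_end
                ] += 1
        means = [d.mean() for d in depth.values()]
        assert abs(np.mean(means) - small_config.coverage_per_library) < 2

    def test_insertions_encoded_as_cigar_i_ops(self, mic_mac_sams, diploid):
        """Reads spanning a haplotype-2 insertion carry an I op of the
        true length at the true junction."""
        ins = {
            (r.contig, r.pos): r.length
            for r in diploid.truth.insertions()
            if not r.is_true_ies
        }
        seen = set()
        with pysam.AlignmentFile(str(mic_mac_sams["MAC"]), "r") as af:
            for read in af:
                if read.get_tag("HP") != 2:
                    continue
                ref_pos = read.reference_start
                for op, ln in read.cigartuples:
                    if op == 1:
                        key = (read.reference_name, ref_pos)
                        if key in ins:
                            assert ins[key] == ln
                            seen.add(key)
                    elif op in (0, 2):
                        ref_pos += ln
        assert len(seen) >= 0.9 * len(ins)

    def test_hp_tag_matches_source_haplotype(self, mic_mac_sams):
        with pysam.AlignmentFile(str(mic_mac_sams["MIC"]), "r") as af:
            for read in af:
                hap = int(read.query_name.split("_h")[1].split("_")[0])
                assert read.get_tag("HP") == hap

    def test_zero_coverage_rejected(self, diploid, small_config, tmp_path):
        import dataclasses

        cfg = dataclasses.replace(small_config, coverage_per_library=0)
        with pytest.raises(ValueError):
            simulate_long_reads(diploid, "MIC", cfg, tmp_path / "x.sam")


class TestNucleosomes:
    def test_mic_zero_jitter_spacing_exact(self):
        cfg = SimulationConfig(nucleosome_jitter_sd=0.0, seed=5)
        mids = simulate_nucleosome_fragments(
            {"c1": 20_000}, None, "MIC", cfg, fragments_per_center=1.0
        )
        pos = sorted({m for _, m in mids})
        gaps = np.diff(pos)
        # centers sit exactly on the period grid (unoccupied centers can
        # leave multiple-of-period gaps)
        assert all(g % cfg.nucleosome_period == 0 for g in gaps)
        assert np.bincount(gaps).argmax() == cfg.nucleosome_period

    def test_mac_mode_requires_genes(self):
        cfg = SimulationConfig(seed=5)
        with pytest.raises(ValueError):
            simulate_nucleosome_fragments({"c1": 10_000}, None, "MAC", cfg)

    def test_empty_contigs_empty_output(self):
        cfg = SimulationConfig(seed=5)
        assert simulate_nucleosome_fragments({}, None, "MIC", cfg) == []

    def test_mac_centers_phase_locked_to_cds_starts(self):
        """Circular mean of (center - CDS start) mod period concentrates
        at the configured anchor offset."""
        cfg = SimulationConfig(seed=6, nucleosome_jitter_sd=5.0)
        contigs, genes = simulate_genic_genome(cfg, n_contigs=40, genes_per_contig=2)
        clens = {c: len(s) for c, s in contigs.items()}
        mids = simulate_nucleosome_fragments(clens, genes, "MAC", cfg)
        period = cfg.nucleosome_period
        angles = []
        by_contig = {}
        for c, m in mids:
            by_contig.setdefault(c, []).append(m)
        for g in genes:
            for m in by_contig.get(g.contig, []):
                if g.start <= m < g.end:
                    off = (m - g.start) if g.strand == "+" else (g.end - 1 - m)
                    angles.append(2 * np.pi * (off % period) / period)
        z = np.mean(np.exp(1j * np.array(angles)))
        est = (np.angle(z) % (2 * np.pi)) * period / (2 * np.pi)
        assert abs(est - cfg.mac_anchor_offset % period) < 10
        assert abs(z) > 0.5  # strongly concentrated


class TestSixma:
    def test_hemi_fraction_one_means_no_double_stranded_dyads(self):
        cfg = SimulationConfig(seed=8, sixma_fraction_of_ApT=0.3)
        contigs, genes = simulate_genic_genome(cfg, n_contigs=30, genes_per_contig=2)
        calls = simulate_6mA_calls(contigs, genes, cfg)
        dyads = {}
        for b in calls:
            key = (b.contig, b.start if b.strand == "+" else b.start - 1)
            dyads.setdefault(key, set()).add(b.strand)
        assert all(len(s) == 1 for s in dyads.values())

    def test_sense_bias_ratio(self):
        cfg = SimulationConfig(seed=9, sixma_fraction_of_ApT=0.5)
        contigs, genes = simulate_genic_genome(cfg, n_contigs=120, genes_per_contig=3)
        calls = simulate_6mA_calls(contigs, genes, cfg)
        by_gene_strand = {"sense": 0, "anti": 0}
        gene_lookup = [(g.contig, g.start, g.end, g.strand) for g in genes]
        for b in calls:
            for c, s, e, strand in gene_lookup:
                if c == b.contig and s <= b.start < e:
                    key = "sense" if b.strand == strand else "anti"
                    by_gene_strand[key] += 1
                    break
        n = by_gene_strand["sense"] + by_gene_strand["anti"]
        assert n > 3000
        ratio = by_gene_strand["sense"] / max(by_gene_strand["anti"], 1)
        # binomial sampling around 34:1
        se = 34 * np.sqrt(35 / n) * 2
        assert abs(ratio - 34) < max(6, 3 * se)

    def test_zero_fraction_empty(self):
        cfg = SimulationConfig(seed=8, sixma_fraction_of_ApT=0.0)
        contigs, genes = simulate_genic_genome(cfg, n_contigs=5, genes_per_contig=2)
        assert simulate_6mA_calls(contigs, genes, cfg) == []


class TestTranscripts:
    def test_no_inframe_uga_in_guard_region(self):
        cfg = SimulationConfig(seed=10)
        sim = simulate_transcripts_and_splices(cfg, n_transcripts=300, introns_per_transcript=0)
        for t in sim.transcripts:
            cds = t.seq[: t.stop_pos + 3]
            guard = cds[-(cfg.guard_len + 3) : -3]
            codons = [guard[i : i + 3] for i in range(0, len(guard), 3)]
            assert "TGA" not in codons

    def test_polya_at_least_minimum(self):
        cfg = SimulationConfig(seed=10)
        sim = simulate_transcripts_and_splices(cfg, n_transcripts=100, introns_per_transcript=0)
        assert all(t.polya_len >= cfg.polya_min for t in sim.transcripts)
        assert all(t.seq.endswith("A" * cfg.polya_min) for t in sim.transcripts)

    def test_intron_length_mode_is_17(self):
        cfg = SimulationConfig(seed=12)
        sim = simulate_transcripts_and_splices(cfg, n_transcripts=500, introns_per_transcript=2)
        lengths = [f.length for f in sim.introns]
        vals, counts = np.unique(lengths, return_counts=True)
        assert vals[np.argmax(counts)] == 17
        assert min(lengths) >= 16 and max(lengths) <= 40

    def test_utr_length_mean(self):
        cfg = SimulationConfig(seed=13)
        sim = simulate_transcripts_and_splices(cfg, n_transcripts=5000, introns_per_transcript=0)
        mean = np.mean([t.utr_len for t in sim.transcripts])
        assert abs(mean - cfg.utr_len_mean) < 2

    def test_intron_coordinates_match_genomic_sequence(self):
        """Excising the recorded introns from the genomic copy restores
        a sequence containing the transcript CDS."""
        cfg = SimulationConfig(seed=14)
        sim = simulate_transcripts_and_splices(cfg, n_transcripts=20, introns_per_transcript=2)
        by_contig = {}
        for f in sim.introns:
            by_contig.setdefault(f.contig, []).append((f.start, f.end))
        for t in sim.transcripts:
            contig = t.name.replace("tx", "txg")
            seq = sim.contigs[contig]
            pieces, pos = [], 0
            for s, e in sorted(by_contig.get(contig, [])):
                pieces.append(seq[pos:s])
                pos = e
            pieces.append(seq[pos:])
            spliced = "".join(pieces)
            cds = t.seq[: t.stop_pos + 3]
            assert cds in spliced
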