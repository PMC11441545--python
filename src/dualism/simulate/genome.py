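"""Diploid genome simulation.

The reference plays the role of a MAC assembly; haplotype 1 equals the
reference and haplotype 2 carries heterozygous SNPs plus monoallelic
indels relative to it.  A configurable subset of insertions is built so
that the insert terminus duplicates the adjacent reference flank (a
TA-containing terminal direct repeat, the signature of mobile-element
integration).  Optional "true IES" inserts are present on *both*
haplotypes of the MIC template but absent from the MAC template, which
is what a germline-limited sequence would look like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dualism.config import SimulationConfig
from dualism.io_utils import write_fasta, write_phased_vcf
from dualism.truth import GeneTruth, IndelTruth, SnpTruth, TruthSet

BASES = "ACGT"
BASE_IDX = {b: i for i, b in enumerate(BASES)}


def random_sequence(rng: np.random.Generator, length: int, freqs) -> str:
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=list(freqs))])


@dataclass
class Layout:
    """A haplotype sequence plus its alignment to the reference.

    ``blocks`` are matched segments (hap_start, hap_end, ref_start);
    gaps between consecutive blocks are insertions (hap advances) or
    deletions (ref advances) relative to the reference.
    """

    seq: str
    blocks: list[tuple[int, int, int]]

    def ref_span(self) -> int:
        hs, he, rs = self.blocks[-1]
        return rs + (he - hs)


def _build_layout(ref_seq: str, events: list[tuple[int, str, int, str]]) -> Layout:
    """Assemble a haplotype from sorted non-overlapping (pos, type, len, seq) events."""
    pieces: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    cur_ref = 0
    cur_hap = 0
    for pos, etype, length, seq in events:
        if pos > cur_ref:
            pieces.append(ref_seq[cur_ref:pos])
            blocks.append((cur_hap, cur_hap + (pos - cur_ref), cur_ref))
            cur_hap += pos - cur_ref
            cur_ref = pos
        if etype == "ins":
            pieces.append(seq)
            cur_hap += length
        else:  # del
            cur_ref += length
    if cur_ref < len(ref_seq):
        pieces.append(ref_seq[cur_ref:])
        blocks.append((cur_hap, cur_hap + (len(ref_seq) - cur_ref), cur_ref))
    return Layout(seq="".join(pieces), blocks=blocks)


def _apply_snps(layout: Layout, snps: list[tuple[int, str]]) -> Layout:
    """Substitute alt alleles (ref_pos, alt_base) into a layout's sequence."""
    if not snps:
        return layout
    seq = list(layout.seq)
    starts = [b[2] for b in layout.blocks]
    import bisect

    for pos, alt in snps:
        i = bisect.bisect_right(starts, pos) - 1
        hs, he, rs = layout.blocks[i]
        if rs <= pos < rs + (he - hs):
            seq[hs + (pos - rs)] = alt
    return Layout(seq="".join(seq), blocks=layout.blocks)


@dataclass
class DiploidGenome:
    reference: dict[str, str]
    # layouts[library][haplotype][contig]; MIC layouts include true-IES inserts
    layouts: dict[str, dict[int, dict[str, Layout]]]
    truth: TruthSet
    config: SimulationConfig
    paths: dict[str, Path] = field(default_factory=dict)


def simulate_diploid_genome(
    config: SimulationConfig, outdir: str | Path | None = None
) -> DiploidGenome:
    """Simulate the diploid reference, haplotypes, phased VCF and truth set."""
    rng = np.random.default_rng(config.seed)
    contig_len = config.genome_length // config.n_contigs
    margin = max(100, config.indel_min_len * 4)
    n_indel_features = (
        int(config.genome_length * config.indel_rate) + config.n_true_ies
    )
    # each indel needs ~margin of exclusive space plus contig-edge margins
    required = 2 * margin + margin * (n_indel_features // config.n_contigs + 1)
    if contig_len < required:
        raise ValueError(
            f"genome_length {config.genome_length} too small for the requested features"
        )

    reference: dict[str, str] = {}
    truth = TruthSet()
    mac_layouts: dict[int, dict[str, Layout]] = {1: {}, 2: {}}
    mic_layouts: dict[int, dict[str, Layout]] = {1: {}, 2: {}}

    n_indels_total = rng.binomial(config.genome_length, config.indel_rate)
    n_ies_total = config.n_true_ies

    for ci in range(config.n_contigs):
        contig = f"ctg{ci:03d}"
        ref_seq = random_sequence(rng, contig_len, config.base_freqs)
        reference[contig] = ref_seq

        # --- place indel + IES events with a minimum separation
        n_indels = n_indels_total // config.n_contigs + (
            1 if ci < n_indels_total % config.n_contigs else 0
        )
        n_ies = n_ies_total // config.n_contigs + (
            1 if ci < n_ies_total % config.n_contigs else 0
        )
        ta_positions = _find_ta(ref_seq)
        used: list[tuple[int, int]] = []
        events_h2: list[tuple[int, str, int, str]] = []
        events_ies: list[tuple[int, str, int, str]] = []

        def _free(start: int, end: int) -> bool:
            return all(end + margin <= s or start >= e + margin for s, e in used)

        for k in range(n_indels + n_ies):
            is_ies = k >= n_indels
            length = config.indel_min_len + (rng.geometric(config.indel_len_decay) - 1)
            is_ins = is_ies or (rng.random() < config.indel_ins_fraction)
            is_tdr = is_ins and not is_ies and rng.random() < config.tdr_fraction
            placed = False
            for _ in range(200):
                if is_tdr and len(ta_positions):
                    tdr_len = 3 + int(rng.geometric(0.45) - 1)
                    tdr_len = min(tdr_len, length - 1)
                    t = int(ta_positions[rng.integers(len(ta_positions))])
                    off = int(rng.integers(0, max(1, tdr_len - 1)))
                    pos = t + 2 + off
                else:
                    tdr_len = 0
                    pos = int(rng.integers(margin, contig_len - margin))
                span = (pos, pos + (length if not is_ins else 0))
                if not (margin <= pos < contig_len - margin - length):
                    continue
                if _free(span[0], span[1]):
                    used.append(span)
                    placed = True
                    break
            if not placed:
                raise ValueError("could not place all requested indels; genome too small")
            if is_ins:
                seq = random_sequence(rng, length, config.base_freqs)
                if tdr_len > 0:
                    seq = seq[:-tdr_len] + ref_seq[pos - tdr_len : pos]
                rec = IndelTruth(
                    contig=contig,
                    pos=pos,
                    type="ins",
                    length=length,
                    haplotype=0 if is_ies else 2,
                    seq=seq,
                    tdr_len=tdr_len,
                    is_true_ies=is_ies,
                    retention_truth=(
                        {"MIC": 1.0, "MAC": 0.0} if is_ies else {"MIC": 0.5, "MAC": 0.5}
                    ),
                )
                (events_ies if is_ies else events_h2).append((pos, "ins", length, seq))
            else:
                rec = IndelTruth(
                    contig=contig,
                    pos=pos,
                    type="del",
                    length=length,
                    haplotype=2,
                    retention_truth={"MIC": 0.5, "MAC": 0.5},
                )
                events_h2.append((pos, "del", length, ""))
            truth.indel_records.append(rec)

        # --- heterozygous SNPs outside indel footprints
        snp_mask = rng.random(contig_len) < config.het_snp_rate
        blocked = np.zeros(contig_len, dtype=bool)
        for s, e in used:
            blocked[max(0, s - 2) : min(contig_len, e + 2)] = True
        snp_positions = np.nonzero(snp_mask & ~blocked)[0]
        snps_h2: list[tuple[int, str]] = []
        for pos in snp_positions:
            ref_base = ref_seq[pos]
            alt = BASES[(BASE_IDX[ref_base] + int(rng.integers(1, 4))) % 4]
            snps_h2.append((int(pos), alt))
            truth.snp_records.append(
                SnpTruth(contig=contig, pos=int(pos), ref=ref_base, alt=alt, haplotype=2)
            )

        events_h2.sort(key=lambda e: e[0])
        events_ies.sort(key=lambda e: e[0])
        events_h2_mic = sorted(events_h2 + events_ies, key=lambda e: e[0])

        mac_layouts[1][contig] = _build_layout(ref_seq, [])
        mac_layouts[2][contig] = _apply_snps(_build_layout(ref_seq, events_h2), snps_h2)
        if n_ies_total > 0:
            mic_layouts[1][contig] = _build_layout(ref_seq, events_ies)
            mic_layouts[2][contig] = _apply_snps(
                _build_layout(ref_seq, events_h2_mic), snps_h2
            )
        else:
            mic_layouts[1][contig] = mac_layouts[1][contig]
            mic_layouts[2][contig] = mac_layouts[2][contig]

    dg = DiploidGenome(
        reference=reference,
        layouts={"MAC": mac_layouts, "MIC": mic_layouts},
        truth=truth,
        config=config,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dg.paths["reference"] = outdir / "reference.fasta"
        write_fasta(dg.paths["reference"], reference.items())
        for hap in (1, 2):
            p = outdir / f"haplotype{hap}.fasta"
            write_fasta(p, ((c, l.seq) for c, l in mac_layouts[hap].items()))
            dg.paths[f"haplotype{hap}"] = p
        dg.paths["vcf"] = outdir / "snps.vcf"
        write_phased_vcf(
            dg.paths["vcf"],
            {c: len(s) for c, s in reference.items()},
            [(s.contig, s.pos, s.ref, s.alt, s.haplotype) for s in truth.snp_records],
        )
    return dg


def _find_ta(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.nonzero((arr[:-1] == ord("T")) & (arr[1:] == ord("A")))[0]


# ---------------------------------------------------------------------------
# Genic genomes (for gene prediction, nucleosome and 6mA analyses)


def intergenic_base_freqs(config: SimulationConfig) -> tuple[float, float, float, float]:
    gc = config.utr_gc  # intergenic/UTR share the same AT-rich composition
    return ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)


ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
STOPS_STD = {"TAA", "TAG", "TGA"}

# Average eukaryotic amino-acid frequencies (mol%), used to give the
# simulated proteome a realistic composition rather than a maximum-
# entropy one.
AA_FREQS = {
    "A": 7.0, "R": 5.5, "N": 4.5, "D": 5.3, "C": 1.5, "Q": 4.0, "E": 6.5,
    "G": 6.5, "H": 2.5, "I": 5.5, "L": 9.5, "K": 6.0, "M": 2.2, "F": 4.0,
    "P": 5.0, "S": 7.5, "T": 5.5, "W": 1.2, "Y": 3.2, "V": 6.5,
}

_T27_AA = {}


def _codon_to_aa_t27(codon: str) -> str:
    if not _T27_AA:
        from Bio.Data import CodonTable

        fwd = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
        fwd["TAA"] = "Q"
        fwd["TAG"] = "Q"
        fwd["TGA"] = "W"
        _T27_AA.update(fwd)
    return _T27_AA[codon]


def codon_usage(config: SimulationConfig) -> dict[str, float]:
    """Coding codon usage for the ambiguous-stop code.

    Codon weight = amino-acid frequency (table 27: UAA/UAG = Gln,
    UGA = Trp) times a position-specific GC weighting
    (``cds_gc_by_pos``), whose spread gives coding sequence its 3-base
    periodicity.  The UGA (DNA: TGA) entry is then fixed to its
    Trp-coding share ``uga_trp_freq``."""
    fs = []
    for gc in config.cds_gc_by_pos:
        fs.append({"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2})
    w = {}
    for cod in ALL_CODONS:
        if cod in ("TAA", "TAG"):  # UAA/UAG are kept as rare in coding use
            continue
        aa = _codon_to_aa_t27(cod)
        w[cod] = AA_FREQS[aa] * fs[0][cod[0]] * fs[1][cod[1]] * fs[2][cod[2]]
    tga = w.pop("TGA")
    total = sum(w.values())
    usage = {cod: (1 - config.uga_trp_freq) * v / total for cod, v in w.items()}
    usage["TGA"] = config.uga_trp_freq
    return usage


def guard_usage(config: SimulationConfig) -> dict[str, float]:
    """Codon usage within the guard region: UGA excluded, renormalized."""
    usage = {k: v for k, v in codon_usage(config).items() if k != "TGA"}
    total = sum(usage.values())
    return {k: v / total for k, v in usage.items()}


def sample_cds(
    rng: np.random.Generator, config: SimulationConfig, n_interior: int | None = None
) -> str:
    """One CDS: ATG + geometric number of interior codons + 7 guard codons + TGA."""
    usage = codon_usage(config)
    guard = guard_usage(config)
    codons, cw = zip(*usage.items())
    gcodons, gw = zip(*guard.items())
    n_guard = config.guard_len // 3
    if n_interior is None:
        floor = config.cds_len_min_codons
        mean_extra = max(config.cds_len_mean_codons - n_guard - floor, 1.0)
        n_interior = floor + int(rng.geometric(1.0 / (mean_extra + 1.0)) - 1)
    body = [
        codons[i]
        for i in rng.choice(len(codons), size=n_interior, p=np.array(cw) / sum(cw))
    ]
    tail = [
        gcodons[i]
        for i in rng.choice(len(gcodons), size=n_guard, p=np.array(gw) / sum(gw))
    ]
    return "ATG" + "".join(body) + "".join(tail) + "TGA"


def simulate_genic_genome(
    config: SimulationConfig,
    n_contigs: int,
    genes_per_contig: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[GeneTruth]]:
    """Contigs of AT-rich intergenic sequence with embedded genes.

    Each gene follows the generative model of the ambiguous-stop gene
    predictor: ATG start, interior codons from the coding usage (UGA
    emitted as Trp at its configured share), a guard region of
    ``guard_len`` nt with no in-frame UGA, and a terminal UGA stop.
    Genes are placed on either strand with equal probability.
    """
    from dualism.io_utils import revcomp

    if rng is None:
        rng = np.random.default_rng(config.seed)
    ig_freqs = intergenic_base_freqs(config)
    ig_mean = config.intergenic_len_mean
    contigs: dict[str, str] = {}
    genes: list[GeneTruth] = []
    for ci in range(n_contigs):
        contig = f"gctg{ci:05d}"
        parts = [random_sequence(rng, max(20, int(rng.exponential(ig_mean))), ig_freqs)]
        pos = len(parts[0])
        for gi in range(genes_per_contig):
            cds = sample_cds(rng, config)
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(cds if strand == "+" else revcomp(cds))
            genes.append(
                GeneTruth(
                    contig=contig,
                    strand=strand,
                    start=pos,
                    end=pos + len(cds),
                    gene_id=f"{contig}.g{gi + 1}",
                )
            )
            pos += len(cds)
            ig = random_sequence(rng, max(20, int(rng.exponential(ig_mean))), ig_freqs)
            parts.append(ig)
            pos += len(ig)
        contigs[contig] = "".join(parts)
    return contigs, genes


def genes_to_gff(genes: list[GeneTruth], source: str = "dualism-sim"):
    from dualism.io_utils import GffFeature

    feats = []
    for g in genes:
        feats.append(
            GffFeature(
                contig=g.contig,
                source=source,
                type="gene",
                start=g.start,
                end=g.end,
                score=None,
                strand=g.strand,
                frame=".",
                attributes={"ID": g.gene_id},
            )
        )
        feats.append(
            GffFeature(
                contig=g.contig,
                source=source,
                type="CDS",
                start=g.start,
                end=g.end,
                score=None,
                strand=g.strand,
                frame="0",
                attributes={"ID": g.gene_id + ".cds", "Parent": g.gene_id},
            )
        )
    return feats
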