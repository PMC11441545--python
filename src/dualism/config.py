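"""Simulation configuration.

The defaults describe the statistical structure of the *Loxodes magnus*
data that the downstream analyses assume: a diploid genome at ~0.6%
heterozygosity carrying monoallelic insertions of at least 15 bp (a
subset bounded by TA-containing terminal direct repeats), long reads
from separate MIC and MAC libraries, nucleosomal fragments spaced
~160 bp apart (gene-anchored only in the MAC), hemimethylated 6mA at
ApT dyads with a strong sense-strand bias, and transcripts in the
ambiguous stop/sense genetic code (UGA = Trp internally, stop
terminally) with short AT-rich 3'-UTRs and short 3n-depleted introns.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def default_intron_length_weights(depletion_3n: float = 0.5) -> dict[int, float]:
    """Categorical intron-length distribution over 16..40 bp.

    Mode at 17 bp with an exponential fall-off; lengths that are a
    multiple of three are down-weighted by ``depletion_3n``, mirroring
    the 3n-intron depletion seen in ciliate genomes.
    """
    import math

    weights: dict[int, float] = {}
    for length in range(16, 41):
        if length < 17:
            w = 0.55
        else:
            w = math.exp(-(length - 17) / 3.2)
        if length % 3 == 0:
            w *= depletion_3n
        weights[length] = w
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic diploid genome and its libraries.

    All rates are per base; lengths are in bases. The same config object
    (including ``seed``) always produces byte-identical output files.
    """

    genome_length: int = 1_000_000
    n_contigs: int = 4
    # genome-wide base frequencies (A, C, G, T); ~30% GC, AT-rich
    base_freqs: tuple[float, float, float, float] = (0.35, 0.15, 0.15, 0.35)
    het_snp_rate: float = 0.006
    indel_rate: float = 5e-4
    indel_min_len: int = 15
    indel_len_decay: float = 0.1  # geometric parameter for length above the minimum
    indel_ins_fraction: float = 0.5  # share of indels that are insertions
    tdr_fraction: float = 0.25
    n_true_ies: int = 0  # optional germline-limited inserts on both MIC haplotypes
    read_length: int = 5000
    coverage_per_library: float = 40.0
    read_error_rate: float = 0.0
    nucleosome_period: int = 160
    nucleosome_jitter_sd: float = 10.0
    mac_anchor_offset: int = 60  # first nucleosome center downstream of CDS start
    mac_anchor_to_genes: bool = True
    mac_tlen_range: tuple[int, int] = (96, 136)
    mic_tlen_range: tuple[int, int] = (126, 166)
    sixma_fraction_of_ApT: float = 0.03
    sixma_sense_bias: float = 34.0
    sixma_hemi_fraction: float = 1.0
    gene_density: float = 0.5  # fraction of the genome covered by genes
    cds_len_mean_codons: float = 150.0
    cds_len_min_codons: int = 60  # interior-codon floor; real gene sets lack tiny ORFs
    intergenic_len_mean: float = 200.0
    uga_trp_freq: float = 0.01  # share of coding codons that are UGA-as-Trp
    cds_gc: float = 0.335
    # GC content by codon position; the spread gives CDS its 3-base
    # periodicity (mean must equal cds_gc)
    cds_gc_by_pos: tuple[float, float, float] = (0.42, 0.335, 0.25)
    utr_gc: float = 0.186
    intron_len_weights: dict[int, float] = field(default_factory=default_intron_length_weights)
    utr_len_mean: float = 53.0
    polya_min: int = 7
    guard_len: int = 21  # nt before the stop with no in-frame UGA (7 codons)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")
        if self.indel_min_len < 1:
            raise ValueError("indel_min_len must be >= 1")
        for name in (
            "het_snp_rate",
            "indel_rate",
            "tdr_fraction",
            "read_error_rate",
            "sixma_fraction_of_ApT",
            "sixma_hemi_fraction",
            "indel_ins_fraction",
            "gene_density",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.guard_len % 3 != 0:
            raise ValueError("guard_len must be a whole number of codons")
        w = sum(self.intron_len_weights.values())
        if abs(w - 1.0) > 1e-6:
            self.intron_len_weights = {
                k: v / w for k, v in self.intron_len_weights.items()
            }
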