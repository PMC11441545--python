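"""Ground-truth containers emitted by the simulator.

Every downstream stage is scored against these records: haplotype of
each indel, true gene models and introns, nucleosome centers, and
methylated positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SnpTruth:
    contig: str
    pos: int  # 0-based reference coordinate
    ref: str
    alt: str
    haplotype: int  # haplotype carrying the alternate allele (1 or 2)


@dataclass
class IndelTruth:
    contig: str
    pos: int  # 0-based reference junction (ins) or deletion start
    type: str  # "ins" | "del"
    length: int
    haplotype: int  # 0 for true IES (both MIC haplotypes), else 1/2
    seq: str = ""  # inserted sequence (ins only)
    tdr_len: int = 0
    is_true_ies: bool = False
    # expected retention per library, e.g. {"MIC": 1.0, "MAC": 0.0} for a
    # true IES, 0.5/0.5 for a monoallelic indel at balanced coverage
    retention_truth: dict[str, float] = field(default_factory=dict)


@dataclass
class GeneTruth:
    contig: str
    strand: str
    start: int  # 0-based half-open genomic CDS span (introns included)
    end: int
    introns: list[tuple[int, int]] = field(default_factory=list)
    gene_id: str = ""


@dataclass
class TruthSet:
    snp_records: list[SnpTruth] = field(default_factory=list)
    indel_records: list[IndelTruth] = field(default_factory=list)
    gene_records: list[GeneTruth] = field(default_factory=list)
    nucleosome_centers: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    methylation_truth: list[tuple[str, int, str]] = field(default_factory=list)

    def insertions(self) -> list[IndelTruth]:
        return [r for r in self.indel_records if r.type == "ins"]

    def deletions(self) -> list[IndelTruth]:
        return [r for r in self.indel_records if r.type == "del"]
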