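"""Light wrappers around the standard genomics file formats.

FASTA is handled through Biopython, SAM and VCF through pysam.
GFF3 and BED records are simple enough that they are kept as small
dataclasses with direct readers/writers (no sqlite feature database is
needed for the flat gene/CDS/intron tables used here).

Internal coordinates are 0-based half-open throughout the package;
GFF3 and VCF are converted to/from their 1-based conventions at the
file boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load an entire (small) FASTA into a name -> sequence dict."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def iter_seqs(path: str | Path) -> Iterator[str]:
    """Iterate raw sequences from FASTA or FASTQ (optionally gzipped)."""
    p = str(path)
    fmt = "fastq" if p.rstrip(".gz").endswith(("fastq", "fq")) else "fasta"
    opener = gzip.open if p.endswith(".gz") else open
    with opener(p, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq).upper()


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# GFF3


@dataclass
class GffFeature:
    """One GFF3 feature; start/end are 0-based half-open in memory."""

    contig: str
    source: str
    type: str
    start: int
    end: int
    score: float | None
    strand: str
    frame: str
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    def attr_string(self) -> str:
        return ";".join(f"{k}={v}" for k, v in self.attributes.items())


def write_gff3(path: str | Path, features: Iterable[GffFeature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            score = "." if f.score is None else f"{f.score:g}"
            fh.write(
                "\t".join(
                    [
                        f.contig,
                        f.source,
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        score,
                        f.strand,
                        f.frame,
                        f.attr_string() or ".",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GffFeature]:
    feats: list[GffFeature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                continue
            attrs: dict[str, str] = {}
            if len(cols) > 8 and cols[8] != ".":
                for kv in cols[8].split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        attrs[k] = v
            feats.append(
                GffFeature(
                    contig=cols[0],
                    source=cols[1],
                    type=cols[2],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    score=None if cols[5] == "." else float(cols[5]),
                    strand=cols[6],
                    frame=cols[7],
                    attributes=attrs,
                )
            )
    return feats


# ---------------------------------------------------------------------------
# BED (6-column, stranded; used for 6mA calls and midpoints)


@dataclass
class BedRecord:
    contig: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


def write_bed(path: str | Path, records: Iterable[BedRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n"
            )


def read_bed(path: str | Path) -> list[BedRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            c = line.rstrip("\n").split("\t")
            out.append(
                BedRecord(
                    contig=c[0],
                    start=int(c[1]),
                    end=int(c[2]),
                    name=c[3] if len(c) > 3 else ".",
                    score=float(c[4]) if len(c) > 4 and c[4] != "." else 0.0,
                    strand=c[5] if len(c) > 5 else ".",
                )
            )
    return out


# ---------------------------------------------------------------------------
# SAM helpers


def sam_header(contigs: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
        }
    )


def open_sam_writer(path: str | Path, contigs: dict[str, int]) -> pysam.AlignmentFile:
    return pysam.AlignmentFile(str(path), "w", header=sam_header(contigs))


def open_sam_reader(path: str | Path) -> pysam.AlignmentFile:
    return pysam.AlignmentFile(str(path), "r", check_sq=False)


# ---------------------------------------------------------------------------
# VCF (phased SNPs)


VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_phased_vcf(
    path: str | Path,
    contigs: dict[str, int],
    records: Iterable[tuple[str, int, str, str, int]],
) -> None:
    """Write phased heterozygous SNPs.

    ``records`` yields (contig, pos0, ref, alt, alt_haplotype) with
    alt_haplotype in {1, 2}; genotype is emitted as ``1|0`` when
    haplotype 1 carries the alternate allele, else ``0|1``.
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for contig, pos0, ref, alt, hap in records:
            gt = "1|0" if hap == 1 else "0|1"
            fh.write(f"{contig}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")


def read_phased_snps(path: str | Path) -> list[tuple[str, int, str, str, int]]:
    """Read phased SNPs back as (contig, pos0, ref, alt, alt_haplotype)."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            if len(rec.ref) != 1 or len(rec.alts or ()) != 1 or len(rec.alts[0]) != 1:
                continue
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or not sample.phased:
                continue
            if tuple(gt) == (1, 0):
                hap = 1
            elif tuple(gt) == (0, 1):
                hap = 2
            else:
                continue
            out.append((rec.contig, rec.pos - 1, rec.ref, rec.alts[0], hap))
    return out
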