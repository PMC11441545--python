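"""Empirical intron annotation, intronless assembly, and lift-back.

Loxodes introns are too short (16-40 bp, mode 17) to model inside the
gene predictor, so they are annotated empirically from spliced RNA-seq
alignments, excised to form an artificial "intronless" assembly for
decoding, and the resulting gene coordinates are lifted back to the
original assembly with the introns re-inserted as features.
"""

from __future__ import annotations

import bisect
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from dualism.ghmm import GeneModel
from dualism.io_utils import BedRecord, GffFeature, open_sam_reader

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Intron annotation from spliced alignments


def annotate_introns(
    alignments: str | Path,
    min_ratio: float = 0.2,
    min_reads: int = 10,
    max_len: int = 40,
    min_len: int = 10,
) -> list[GffFeature]:
    """Accept introns from alignment gaps flagged as splices (CIGAR N).

    An intron is accepted iff its spliced support is >= ``min_reads``,
    its length lies in [min_len, max_len], and the splice ratio —
    spliced / (spliced + reads spanning both boundaries unspliced) —
    is >= ``min_ratio``.  Overlapping accepted introns on the same
    strand are resolved by keeping the better supported one.
    """
    spliced: dict[tuple[str, int, int, str], int] = defaultdict(int)
    blocks_by_contig: dict[str, list[tuple[int, int]]] = defaultdict(list)
    with open_sam_reader(alignments) as af:
        for read in af:
            if read.is_unmapped or read.cigartuples is None:
                continue
            contig = read.reference_name
            strand = read.get_tag("XS") if read.has_tag("XS") else (
                "-" if read.is_reverse else "+"
            )
            ref_pos = read.reference_start
            block_start = ref_pos
            for op, ln in read.cigartuples:
                if op in (0, 7, 8):
                    ref_pos += ln
                elif op == 3:  # N: splice
                    blocks_by_contig[contig].append((block_start, ref_pos))
                    spliced[(contig, ref_pos, ref_pos + ln, strand)] += 1
                    ref_pos += ln
                    block_start = ref_pos
                elif op == 2:
                    ref_pos += ln
            if ref_pos > block_start:
                blocks_by_contig[contig].append((block_start, ref_pos))

    for blocks in blocks_by_contig.values():
        blocks.sort()

    accepted: list[GffFeature] = []
    for (contig, start, end, strand), n_spliced in sorted(spliced.items()):
        length = end - start
        if length < min_len or length > max_len or n_spliced < min_reads:
            continue
        blocks = blocks_by_contig.get(contig, [])
        # unspliced support: contiguous aligned blocks covering both
        # boundaries (one base on each side of the intron)
        n_unspliced = sum(1 for bs, be in blocks if bs <= start - 1 and be >= end + 1)
        ratio = n_spliced / (n_spliced + n_unspliced)
        if ratio < min_ratio:
            continue
        accepted.append(
            GffFeature(
                contig=contig,
                source="dualism",
                type="intron",
                start=start,
                end=end,
                score=float(n_spliced),
                strand=strand,
                frame=".",
                attributes={
                    "ID": f"intron:{contig}:{start}-{end}",
                    "spliced_reads": str(n_spliced),
                    "unspliced_reads": str(n_unspliced),
                    "ratio": f"{ratio:.3f}",
                },
            )
        )

    # resolve same-strand overlaps: keep the better-supported intron
    accepted.sort(key=lambda f: (f.contig, f.start))
    kept: list[GffFeature] = []
    for feat in accepted:
        if kept and kept[-1].contig == feat.contig and kept[-1].strand == feat.strand and feat.start < kept[-1].end:
            if (feat.score or 0) > (kept[-1].score or 0):
                logger.warning(
                    "overlapping introns at %s:%d-%d; keeping better-supported",
                    feat.contig,
                    feat.start,
                    feat.end,
                )
                kept[-1] = feat
            continue
        kept.append(feat)
    return kept


# ---------------------------------------------------------------------------
# Intronless assembly and coordinate map


@dataclass
class CoordinateMap:
    """Strictly monotone mapping from intronless to original coordinates.

    ``segments[new_contig]`` is an ordered list of
    (new_start, orig_contig, orig_start, length) blocks; positions inside
    a block map by offset.  Round-tripping any retained base is the
    identity.
    """

    segments: dict[str, list[tuple[int, str, int, int]]] = field(default_factory=dict)
    removed_introns: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    dropped_contigs: list[str] = field(default_factory=list)

    def to_original(self, new_contig: str, pos: int) -> tuple[str, int]:
        blocks = self.segments[new_contig]
        starts = [b[0] for b in blocks]
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            raise KeyError(f"position {pos} before first block of {new_contig}")
        new_start, orig_contig, orig_start, length = blocks[i]
        if pos >= new_start + length:
            raise KeyError(f"position {pos} beyond {new_contig}")
        return orig_contig, orig_start + (pos - new_start)

    def map_interval(
        self, new_contig: str, start: int, end: int
    ) -> list[tuple[str, int, int]]:
        """Map [start, end) to original-coordinate pieces, split at
        excised-intron joins."""
        blocks = self.segments[new_contig]
        out: list[tuple[str, int, int]] = []
        for new_start, orig_contig, orig_start, length in blocks:
            s = max(start, new_start)
            e = min(end, new_start + length)
            if s < e:
                out.append((orig_contig, orig_start + (s - new_start), orig_start + (e - new_start)))
        return out


def _n_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def build_intronless(
    genome: dict[str, str],
    introns: list[GffFeature],
    masks: list[BedRecord] | None = None,
    min_contig: int = 1000,
) -> tuple[dict[str, str], CoordinateMap]:
    """Excise introns, split contigs at N-gaps and masked intervals,
    and drop pieces shorter than ``min_contig``."""
    introns_by_contig: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for f in introns:
        introns_by_contig[f.contig].append((f.start, f.end))
    breaks_by_contig: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for m in masks or []:
        breaks_by_contig[m.contig].append((m.start, m.end))

    out: dict[str, str] = {}
    cmap = CoordinateMap()
    for contig, seq in genome.items():
        breaks = sorted(breaks_by_contig.get(contig, []) + _n_runs(seq))
        merged: list[tuple[int, int]] = []
        for s, e in breaks:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        # contiguous segments between breakpoints
        segments: list[tuple[int, int]] = []
        pos = 0
        for s, e in merged + [(len(seq), len(seq))]:
            if s > pos:
                segments.append((pos, s))
            pos = max(pos, e)
        introns_sorted = sorted(introns_by_contig.get(contig, []))
        piece_idx = 0
        for seg_start, seg_end in segments:
            local_introns = [
                (s, e) for s, e in introns_sorted if s >= seg_start and e <= seg_end
            ]
            pieces = []
            blocks = []
            new_pos = 0
            pos = seg_start
            for s, e in local_introns:
                if s > pos:
                    pieces.append(seq[pos:s])
                    blocks.append((new_pos, contig, pos, s - pos))
                    new_pos += s - pos
                pos = e
            if seg_end > pos:
                pieces.append(seq[pos:seg_end])
                blocks.append((new_pos, contig, pos, seg_end - pos))
                new_pos += seg_end - pos
            new_seq = "".join(pieces)
            name = contig if len(segments) == 1 else f"{contig}_p{piece_idx}"
            piece_idx += 1
            if len(new_seq) < min_contig:
                cmap.dropped_contigs.append(name)
                continue
            out[name] = new_seq
            cmap.segments[name] = blocks
            cmap.removed_introns[name] = local_introns
    return out, cmap


def lift_back(
    genes: list[GeneModel], cmap: CoordinateMap
) -> list[GffFeature]:
    """Translate decoded genes to original coordinates, re-splitting CDS
    around excised introns (each mapped piece becomes one CDS segment)."""
    feats: list[GffFeature] = []
    for gi, gene in enumerate(genes):
        pieces = cmap.map_interval(gene.contig, gene.cds_start, gene.cds_end)
        if not pieces:
            continue
        orig_contig = pieces[0][0]
        gene_id = f"gene{gi + 1:05d}"
        feats.append(
            GffFeature(
                contig=orig_contig,
                source="dualism",
                type="gene",
                start=pieces[0][1],
                end=pieces[-1][2],
                score=gene.score,
                strand=gene.strand,
                frame=".",
                attributes={"ID": gene_id},
            )
        )
        for pi, (c, s, e) in enumerate(pieces):
            feats.append(
                GffFeature(
                    contig=c,
                    source="dualism",
                    type="CDS",
                    start=s,
                    end=e,
                    score=None,
                    strand=gene.strand,
                    frame=".",
                    attributes={"ID": f"{gene_id}.cds{pi}", "Parent": gene_id},
                )
            )
        for pi in range(len(pieces) - 1):
            feats.append(
                GffFeature(
                    contig=orig_contig,
                    source="dualism",
                    type="intron",
                    start=pieces[pi][2],
                    end=pieces[pi + 1][1],
                    score=None,
                    strand=gene.strand,
                    frame=".",
                    attributes={"ID": f"{gene_id}.intron{pi}", "Parent": gene_id},
                )
            )
    return feats


def flag_repeat_overlaps(
    genes: list[GffFeature], masks: list[BedRecord]
) -> list[GffFeature]:
    """Genes lying entirely within a masked (low-complexity) interval.

    Mirrors ``bedtools intersect -f 1.0`` semantics: only full
    containment counts; partial overlap does not flag a gene.
    """
    by_contig: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for m in masks:
        by_contig[m.contig].append((m.start, m.end))
    flagged = []
    for g in genes:
        if g.type != "gene":
            continue
        if any(s <= g.start and g.end <= e for s, e in by_contig.get(g.contig, [])):
            flagged.append(g)
    return flagged
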