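"""Nucleosomal fragment and 6mA call simulation.

MIC-mode nucleosome arrays are regularly spaced but independent of gene
coordinates (condensed, transcription-independent chromatin); MAC-mode
arrays are phased to CDS starts (transcription-coupled).  6mA calls are
placed at ApT dyads inside gene bodies with probability peaking in the
linkers between nucleosomes (anti-phase to the nucleosome centers),
with a strong sense-strand bias and configurable hemimethylation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam

from dualism.config import SimulationConfig
from dualism.io_utils import BedRecord, open_sam_writer, write_bed
from dualism.truth import GeneTruth

# MIC 6mA is nearly absent: the per-dyad methylation probability is scaled
# by this factor in MIC mode (~0.00013% vs 0.85% of ApT in the two nuclei).
MIC_6MA_SCALE = 2e-4


def _array_centers_mic(
    rng: np.random.Generator, contig_len: int, config: SimulationConfig
) -> np.ndarray:
    phase = rng.integers(0, config.nucleosome_period)
    base = np.arange(phase, contig_len, config.nucleosome_period, dtype=float)
    return base


def _array_centers_mac(gene: GeneTruth, config: SimulationConfig) -> np.ndarray:
    period = config.nucleosome_period
    n = max(0, (gene.end - gene.start - config.mac_anchor_offset) // period)
    k = np.arange(n, dtype=float)
    if gene.strand == "+":
        return gene.start + config.mac_anchor_offset + k * period
    return gene.end - 1 - config.mac_anchor_offset - k * period


def simulate_nucleosome_fragments(
    contig_lengths: dict[str, int],
    genes: list[GeneTruth] | None,
    mode: str,
    config: SimulationConfig,
    sam_path: str | Path | None = None,
    bed_path: str | Path | None = None,
    rng: np.random.Generator | None = None,
    fragments_per_center: float = 2.0,
) -> list[tuple[str, int]]:
    """Emit paired-end fragment records and a midpoint BED; return midpoints.

    Fragment template lengths are drawn from a window wider than the
    library's nominal nucleosomal size range, so that template-length
    filtering downstream has something to reject.
    """
    if mode not in ("MIC", "MAC"):
        raise ValueError(f"mode must be MIC or MAC, got {mode!r}")
    if mode == "MAC" and not genes:
        raise ValueError("MAC mode requires gene annotations for anchoring")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 13 if mode == "MIC" else 17])
        )
    lo, hi = config.mic_tlen_range if mode == "MIC" else config.mac_tlen_range
    jitter = config.nucleosome_jitter_sd
    midpoints: list[tuple[str, int]] = []
    frags: list[tuple[str, int, int]] = []  # (contig, left, tlen)

    def _emit(contig: str, centers: np.ndarray, contig_len: int) -> None:
        for c in centers:
            for _ in range(rng.poisson(fragments_per_center)):
                m = int(round(c + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)))
                tlen = int(rng.integers(lo - 30, hi + 31))
                left = m - (tlen - 1) // 2
                if left < 0 or left + tlen > contig_len:
                    continue
                midpoints.append((contig, m))
                frags.append((contig, left, tlen))

    if mode == "MIC":
        for contig, clen in contig_lengths.items():
            _emit(contig, _array_centers_mic(rng, clen, config), clen)
    else:
        for gene in genes:
            clen = contig_lengths[gene.contig]
            _emit(gene.contig, _array_centers_mac(gene, config), clen)

    if sam_path is not None:
        writer = open_sam_writer(sam_path, contig_lengths)
        recs = []
        for i, (contig, left, tlen) in enumerate(frags):
            tid = writer.header.get_tid(contig)
            name = f"frag_{mode}_{i:08d}"
            half = tlen // 2
            r1 = pysam.AlignedSegment(writer.header)
            r1.query_name = name
            r1.flag = 99
            r1.reference_id = tid
            r1.reference_start = left
            r1.mapping_quality = 60
            r1.cigartuples = [(0, half)]
            r1.query_sequence = "A" * half
            r1.next_reference_id = tid
            r1.next_reference_start = left + tlen - half
            r1.template_length = tlen
            r2 = pysam.AlignedSegment(writer.header)
            r2.query_name = name
            r2.flag = 147
            r2.reference_id = tid
            r2.reference_start = left + tlen - half
            r2.mapping_quality = 60
            r2.cigartuples = [(0, half)]
            r2.query_sequence = "A" * half
            r2.next_reference_id = tid
            r2.next_reference_start = left
            r2.template_length = -tlen
            recs.extend([r1, r2])
        recs.sort(key=lambda a: (a.reference_id, a.reference_start))
        for a in recs:
            writer.write(a)
        writer.close()
    if bed_path is not None:
        write_bed(
            bed_path,
            [BedRecord(contig=c, start=m, end=m + 1, name=f"mid{i}") for i, (c, m) in enumerate(midpoints)],
        )
    return midpoints


def simulate_6mA_calls(
    contigs: dict[str, str],
    genes: list[GeneTruth],
    config: SimulationConfig,
    library: str = "MAC",
    bed_path: str | Path | None = None,
    rng: np.random.Generator | None = None,
) -> list[BedRecord]:
    """Place 6mA calls at ApT dyads in gene bodies, anti-phase to nucleosomes.

    Placement probability is proportional to 1 − cos(2π(pos − anchor)/period),
    peaking at linker midpoints.  The sense strand of a hemimethylated dyad
    is chosen with odds ``sixma_sense_bias`` : 1; a ``1 − sixma_hemi_fraction``
    share of methylated dyads carries calls on both strands.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    period = config.nucleosome_period
    frac = config.sixma_fraction_of_ApT * (MIC_6MA_SCALE if library == "MIC" else 1.0)
    odds = config.sixma_sense_bias
    calls: list[BedRecord] = []
    dyad_id = 0
    for gene in genes:
        seq = contigs[gene.contig]
        body = seq[gene.start : gene.end]
        arr = np.frombuffer(body.encode(), dtype=np.uint8)
        apt = np.nonzero((arr[:-1] == ord("A")) & (arr[1:] == ord("T")))[0]
        if len(apt) == 0:
            continue
        pos = apt + gene.start  # genomic position of the plus-strand A
        if gene.strand == "+":
            anchor = gene.start + config.mac_anchor_offset
            weight = 1.0 - np.cos(2 * np.pi * (pos - anchor) / period)
        else:
            anchor = gene.end - 1 - config.mac_anchor_offset
            weight = 1.0 - np.cos(2 * np.pi * (anchor - pos) / period)
        p = np.clip(frac * weight, 0.0, 1.0)  # mean over phase = frac
        hit = rng.random(len(pos)) < p
        for gp in pos[hit]:
            dyad_id += 1
            full = rng.random() >= config.sixma_hemi_fraction
            if full:
                strands = ["+", "-"]
            else:
                sense = rng.random() < odds / (odds + 1.0)
                gene_sense_strand = gene.strand
                strand = gene_sense_strand if sense else ("+" if gene_sense_strand == "-" else "-")
                strands = [strand]
            for strand in strands:
                # plus-strand call sits on the A; minus-strand on the T (the
                # A of the opposite strand), one base to the right
                cpos = int(gp) if strand == "+" else int(gp) + 1
                calls.append(
                    BedRecord(
                        contig=gene.contig,
                        start=cpos,
                        end=cpos + 1,
                        name=f"dyad{dyad_id}",
                        score=1.0,
                        strand=strand,
                    )
                )
    if bed_path is not None:
        write_bed(bed_path, calls)
    return calls
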