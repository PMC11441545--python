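"""Truth-derived long-read alignments.

Reads are substrings of the haplotype sequences; their alignments to
the reference are derived directly from the known haplotype layout, so
no external aligner is involved.  CIGAR I/D operations encode the
haplotype indels a read spans; heterozygous SNPs appear as mismatches
within M operations.  Each read carries a WhatsHap-style integer ``HP``
tag with its source haplotype.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam

from dualism.config import SimulationConfig
from dualism.io_utils import open_sam_writer, write_fasta
from dualism.simulate.genome import BASES, DiploidGenome, Layout


def _cigar_for_interval(layout: Layout, hs: int, he: int):
    """CIGAR ops + reference start for haplotype interval [hs, he)."""
    ops: list[tuple[int, int]] = []  # (op, length): 0=M, 1=I, 2=D
    ref_start = None
    prev_block_end_hap = None
    prev_block_end_ref = None
    for bhs, bhe, brs in layout.blocks:
        if bhe <= hs:
            prev_block_end_hap, prev_block_end_ref = bhe, brs + (bhe - bhs)
            continue
        if bhs >= he:
            break
        # gap between previous block and this one
        if prev_block_end_hap is not None and ops:
            ins_len = bhs - prev_block_end_hap
            del_len = brs - prev_block_end_ref
            if ins_len > 0:
                ops.append((1, ins_len))
            if del_len > 0:
                ops.append((2, del_len))
        m_start = max(bhs, hs)
        m_end = min(bhe, he)
        if ref_start is None:
            ref_start = brs + (m_start - bhs)
            if not ops and m_start > hs:
                # read begins inside an insertion: drop the dangling bases
                hs = m_start
        if m_end > m_start:
            ops.append((0, m_end - m_start))
        prev_block_end_hap, prev_block_end_ref = bhe, brs + (bhe - bhs)
    # merge adjacent same-op entries
    merged: list[tuple[int, int]] = []
    for op, ln in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    # trailing/leading I or D are meaningless in an alignment; trim them
    while merged and merged[0][0] != 0:
        if merged[0][0] == 1:
            hs += merged[0][1]
        merged.pop(0)
    while merged and merged[-1][0] != 0:
        merged.pop()
    return merged, ref_start, hs


def simulate_long_reads(
    genome: DiploidGenome,
    library: str,
    config: SimulationConfig,
    sam_path: str | Path,
    fasta_path: str | Path | None = None,
    rng: np.random.Generator | None = None,
    with_hp_tags: bool = True,
) -> int:
    """Emit SAM-dialect alignments (+ reads FASTA) for one library.

    Reads are drawn alternately from the two haplotypes at half the
    library coverage each.  Returns the number of reads written.
    """
    if library not in genome.layouts:
        raise ValueError(f"unknown library {library!r}")
    if config.coverage_per_library <= 0:
        raise ValueError("coverage_per_library must be > 0")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7 if library == "MIC" else 11])
        )
    layouts = genome.layouts[library]
    contig_lengths = {c: len(s) for c, s in genome.reference.items()}
    writer = open_sam_writer(sam_path, contig_lengths)
    fasta_records: list[tuple[str, str]] = []
    n_reads = 0
    read_len = config.read_length
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)

    records = []
    for contig in genome.reference:
        for hap in (1, 2):
            layout = layouts[hap][contig]
            hap_len = len(layout.seq)
            eff_len = max(1, hap_len - read_len)
            n = int(round(config.coverage_per_library / 2 * hap_len / read_len))
            starts = rng.integers(0, eff_len + 1, size=n)
            for si, hs in enumerate(sorted(starts.tolist())):
                he = min(hs + read_len, hap_len)
                cigar, ref_start, hs_adj = _cigar_for_interval(layout, hs, he)
                if not cigar or ref_start is None:
                    continue
                read_span = sum(ln for op, ln in cigar if op != 2)
                seq = layout.seq[hs_adj : hs_adj + read_span]
                if config.read_error_rate > 0:
                    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                    err = np.nonzero(rng.random(len(arr)) < config.read_error_rate)[0]
                    if len(err):
                        shifts = rng.integers(1, 4, size=len(err))
                        for e, sh in zip(err, shifts):
                            cur = BASES.index(chr(arr[e]))
                            arr[e] = base_arr[(cur + sh) % 4]
                        seq = arr.tobytes().decode()
                name = f"{library}_{contig}_h{hap}_{n_reads:07d}"
                a = pysam.AlignedSegment(writer.header)
                a.query_name = name
                a.query_sequence = seq
                a.flag = 0
                a.reference_id = writer.header.get_tid(contig)
                a.reference_start = ref_start
                a.mapping_quality = 60
                a.cigartuples = cigar
                if with_hp_tags:
                    a.set_tag("HP", hap, value_type="i")
                records.append(a)
                fasta_records.append((name, seq))
                n_reads += 1
    records.sort(key=lambda a: (a.reference_id, a.reference_start))
    for a in records:
        writer.write(a)
    writer.close()
    if fasta_path is not None:
        write_fasta(fasta_path, fasta_records)
    return n_reads
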