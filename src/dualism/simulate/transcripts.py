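"""Transcript and spliced-alignment simulation for the ambiguous-stop code.

Each transcript is a CDS in the karyorelict genetic code (internal UGA
codons read as Trp, no in-frame UGA within the guard region before the
terminal stop UGA), followed by a short AT-rich 3'-UTR (exponential
length) and a poly-A tail.  Genomic copies carry short introns drawn
from the configured categorical length distribution (16-40 bp, mode 17,
3n classes down-weighted); spliced RNA alignments support each intron
with configurable spliced/unspliced read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from dualism.config import SimulationConfig
from dualism.io_utils import GffFeature, open_sam_writer, write_fasta, write_gff3
from dualism.simulate.genome import random_sequence, sample_cds, intergenic_base_freqs


@dataclass
class TranscriptRecord:
    name: str
    seq: str  # full transcript including poly-A
    stop_pos: int  # 0-based index of the stop codon's first base
    utr_len: int
    polya_len: int


@dataclass
class TranscriptSim:
    transcripts: list[TranscriptRecord]
    contigs: dict[str, str]
    introns: list[GffFeature]
    paths: dict[str, Path] = field(default_factory=dict)


def _utr_freqs(config: SimulationConfig):
    gc = config.utr_gc
    return ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)


def simulate_transcripts_and_splices(
    config: SimulationConfig,
    n_transcripts: int,
    introns_per_transcript: int = 2,
    n_spliced: int = 15,
    n_unspliced: int = 3,
    read_len: int = 100,
    outdir: str | Path | None = None,
    rng: np.random.Generator | None = None,
) -> TranscriptSim:
    """Simulate transcripts, genomic copies with introns, and spliced reads."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    lengths = np.array(sorted(config.intron_len_weights))
    weights = np.array([config.intron_len_weights[int(l)] for l in lengths])
    weights = weights / weights.sum()
    ig_freqs = intergenic_base_freqs(config)

    transcripts: list[TranscriptRecord] = []
    contigs: dict[str, str] = {}
    introns: list[GffFeature] = []
    sam_records: list[tuple[str, int, list[tuple[int, int]], int]] = []
    flank = max(read_len, 60)

    for ti in range(n_transcripts):
        name = f"tx{ti:06d}"
        cds = sample_cds(rng, config)
        utr_len = int(rng.exponential(config.utr_len_mean))
        utr = random_sequence(rng, utr_len, _utr_freqs(config))
        polya_len = config.polya_min + int(rng.geometric(0.3) - 1)
        seq = cds + utr + "A" * polya_len
        transcripts.append(
            TranscriptRecord(
                name=name,
                seq=seq,
                stop_pos=len(cds) - 3,
                utr_len=utr_len,
                polya_len=polya_len,
            )
        )

        # genomic copy: flank + CDS with introns + flank
        contig = f"txg{ti:06d}"
        n_introns = introns_per_transcript
        body = cds
        if n_introns > 0 and len(cds) > 6 + n_introns * (read_len // 2):
            # choose insertion points within the CDS, well separated
            points = sorted(
                int(p)
                for p in rng.choice(
                    np.arange(3, len(cds) - 3),
                    size=n_introns,
                    replace=False,
                )
            )
            ok = all(b - a >= flank for a, b in zip(points, points[1:]))
            if not ok:
                points = [
                    3 + (i + 1) * (len(cds) - 6) // (n_introns + 1)
                    for i in range(n_introns)
                ]
            pieces = []
            prev = 0
            for point in points:
                ilen = int(rng.choice(lengths, p=weights))
                iseq = "GT" + random_sequence(rng, ilen - 4, ig_freqs) + "AG"
                pieces.append(cds[prev:point])
                pieces.append(iseq)
                prev = point
            pieces.append(cds[prev:])
            body = "".join(pieces)
            # intron genomic coordinates from the assembled pieces
            prev = 0
            cursor = flank
            intron_coords = []
            for pi, point in enumerate(points):
                cursor += point - prev
                ilen_pi = len(pieces[2 * pi + 1])
                intron_coords.append((cursor, cursor + ilen_pi))
                cursor += ilen_pi
                prev = point
            for istart, iend in intron_coords:
                introns.append(
                    GffFeature(
                        contig=contig,
                        source="dualism-sim",
                        type="intron",
                        start=istart,
                        end=iend,
                        score=None,
                        strand="+",
                        frame=".",
                        attributes={"ID": f"{contig}.i{len(introns)}"},
                    )
                )
                # spliced reads: M across the junction with an N over the intron
                for ri in range(n_spliced):
                    left = int(rng.integers(20, read_len - 20))
                    start = istart - left
                    right = read_len - left
                    sam_records.append(
                        (
                            contig,
                            start,
                            [(0, left), (3, iend - istart), (0, right)],
                            +1,
                        )
                    )
                for ri in range(n_unspliced):
                    left = int(rng.integers(20, read_len - 20))
                    start = istart - left
                    sam_records.append((contig, start, [(0, read_len)], 0))
        contigs[contig] = (
            random_sequence(rng, flank, ig_freqs)
            + body
            + random_sequence(rng, flank, ig_freqs)
        )

    sim = TranscriptSim(transcripts=transcripts, contigs=contigs, introns=introns)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sim.paths["transcripts"] = outdir / "transcripts.fasta"
        write_fasta(sim.paths["transcripts"], [(t.name, t.seq) for t in transcripts])
        sim.paths["stops"] = outdir / "stops.tsv"
        with open(sim.paths["stops"], "w") as fh:
            fh.write("transcript_id\tstop_pos\n")
            for t in transcripts:
                fh.write(f"{t.name}\t{t.stop_pos}\n")
        sim.paths["genome"] = outdir / "genomic.fasta"
        write_fasta(sim.paths["genome"], contigs.items())
        sim.paths["introns"] = outdir / "true_introns.gff3"
        write_gff3(sim.paths["introns"], introns)
        sim.paths["rnaseq"] = outdir / "rnaseq.sam"
        _write_spliced_sam(
            sim.paths["rnaseq"], {c: len(s) for c, s in contigs.items()}, sam_records, contigs
        )
    return sim


def _write_spliced_sam(path, contig_lengths, records, contigs) -> None:
    writer = open_sam_writer(path, contig_lengths)
    recs = []
    for i, (contig, start, cigar, spliced) in enumerate(records):
        if start < 0:
            continue
        a = pysam.AlignedSegment(writer.header)
        a.query_name = f"rna_{i:08d}"
        a.flag = 0
        a.reference_id = writer.header.get_tid(contig)
        a.reference_start = start
        a.mapping_quality = 60
        a.cigartuples = cigar
        qlen = sum(ln for op, ln in cigar if op in (0, 1))
        ref_len = sum(ln for op, ln in cigar if op in (0, 2, 3))
        if start + ref_len > contig_lengths[contig]:
            continue
        # reconstruct the read sequence from the reference (error-free)
        seq_parts = []
        pos = start
        for op, ln in cigar:
            if op == 0:
                seq_parts.append(contigs[contig][pos : pos + ln])
                pos += ln
            elif op == 3:
                pos += ln
        a.query_sequence = "".join(seq_parts)
        a.set_tag("XS", "+")
        recs.append(a)
    recs.sort(key=lambda a: (a.reference_id, a.reference_start))
    for a in recs:
        writer.write(a)
    writer.close()
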