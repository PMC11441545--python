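"""Poly-A transcript statistics for the ambiguous stop/sense code.

The signal that motivates the gene model's guard region: coding UGA
(and UAA) codons are depleted for ~20 codon positions immediately
upstream of the true stop UGA, while UAG shows no depletion; 3'-UTRs
are short and AT-rich; and upstream base composition carries the
3-base periodicity of codon structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from dualism.io_utils import GffFeature

STOP_TRIPLETS = ("TGA", "TAA", "TAG")


@dataclass
class AnnotatedTranscript:
    name: str
    seq: str  # poly-A trimmed
    polya_len: int
    stop_pos: int  # 0-based index of the stop codon's first base

    def __post_init__(self) -> None:
        if self.seq[self.stop_pos : self.stop_pos + 3] != "TGA":
            raise ValueError(f"{self.name}: codon at stop_pos is not TGA")

    @property
    def utr_len(self) -> int:
        return len(self.seq) - (self.stop_pos + 3)


def detect_polya(
    seq: str, min_tail: int = 7, max_mismatch: int = 0
) -> tuple[str, int] | None:
    """Longest terminal poly-A run (allowing ``max_mismatch`` non-A bases).

    Returns (trimmed sequence, tail length) or None when the terminal
    run is shorter than ``min_tail``.  Internal A-runs do not count.
    """
    seq = seq.upper()
    mismatches = 0
    tail = 0
    i = len(seq) - 1
    last_a = len(seq)
    while i >= 0:
        if seq[i] == "A":
            last_a = i
        else:
            mismatches += 1
            if mismatches > max_mismatch:
                break
        i -= 1
    tail = len(seq) - last_a  # tail starts at the 5'-most A of the suffix
    if tail < min_tail:
        return None
    return seq[: len(seq) - tail], tail


def load_transcripts(
    fasta: dict[str, str], stop_positions: dict[str, int], min_tail: int = 7
) -> list[AnnotatedTranscript]:
    """Build annotated transcripts from sequences and known stop positions,
    rejecting those without a qualifying poly-A tail."""
    out = []
    for name, seq in fasta.items():
        if name not in stop_positions:
            continue
        res = detect_polya(seq, min_tail=min_tail)
        if res is None:
            continue
        trimmed, tail = res
        try:
            out.append(
                AnnotatedTranscript(
                    name=name, seq=trimmed, polya_len=tail, stop_pos=stop_positions[name]
                )
            )
        except ValueError:
            # terminal A-run extended into an A-rich UTR past the annotated
            # stop; the record is internally inconsistent and is dropped
            continue
    return out


def read_stop_table(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(int)))


# ---------------------------------------------------------------------------
# Statistics


@dataclass
class UtrStats:
    lengths: np.ndarray
    mean: float
    median: float
    cds_gc: float
    utr_gc: float


def _gc(seq: str) -> tuple[int, int]:
    return seq.count("G") + seq.count("C"), len(seq)


def utr_stats(transcripts: list[AnnotatedTranscript]) -> UtrStats:
    """3'-UTR lengths (stop codon excluded) and CDS vs UTR GC content."""
    lengths = np.array([t.utr_len for t in transcripts])
    gc_cds = n_cds = gc_utr = n_utr = 0
    for t in transcripts:
        g, n = _gc(t.seq[: t.stop_pos + 3])
        gc_cds += g
        n_cds += n
        g, n = _gc(t.seq[t.stop_pos + 3 :])
        gc_utr += g
        n_utr += n
    return UtrStats(
        lengths=lengths,
        mean=float(lengths.mean()) if len(lengths) else float("nan"),
        median=float(np.median(lengths)) if len(lengths) else float("nan"),
        cds_gc=gc_cds / n_cds if n_cds else float("nan"),
        utr_gc=gc_utr / n_utr if n_utr else float("nan"),
    )


def composition_profile(
    transcripts: list[AnnotatedTranscript], window: int = 60
) -> pd.DataFrame:
    """Per-position base frequencies at offsets [-window, +window] relative
    to the stop codon's first base."""
    offsets = np.arange(-window, window + 1)
    counts = np.zeros((len(offsets), 4), dtype=np.int64)
    totals = np.zeros(len(offsets), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for t in transcripts:
        for k, off in enumerate(offsets):
            pos = t.stop_pos + off
            if 0 <= pos < len(t.seq):
                b = t.seq[pos]
                if b in base_idx:
                    counts[k, base_idx[b]] += 1
                    totals[k] += 1
    with np.errstate(invalid="ignore"):
        freqs = counts / np.maximum(totals, 1)[:, None]
    df = pd.DataFrame(freqs, columns=list("ACGT"))
    df.insert(0, "offset", offsets)
    return df


def codon_depletion_profile(
    transcripts: list[AnnotatedTranscript], max_offset_codons: int = 40
) -> pd.DataFrame:
    """Counts of UGA/UAA/UAG at in-frame codon offsets upstream of the stop.

    Offset −1 is the codon immediately before the stop.  With a guard
    region of g codons in force, UGA counts are zero at offsets −1..−g.
    """
    offsets = np.arange(-max_offset_codons, 0)
    counts = {s: np.zeros(len(offsets), dtype=np.int64) for s in STOP_TRIPLETS}
    n_covered = np.zeros(len(offsets), dtype=np.int64)
    for t in transcripts:
        for k, off in enumerate(offsets):
            start = t.stop_pos + 3 * off
            if start < 0:
                continue
            codon = t.seq[start : start + 3]
            n_covered[k] += 1
            if codon in counts:
                counts[codon][k] += 1
    df = pd.DataFrame({"offset_codons": offsets, "n_transcripts": n_covered})
    for s in STOP_TRIPLETS:
        df[s] = counts[s]
    return df


@dataclass
class IntronLengthReport:
    histogram: pd.Series
    mean: float
    mode: int
    fraction_le_25: float
    depletion_3n: float | None
    degenerate: bool = False


def intron_length_report(introns: list[GffFeature]) -> IntronLengthReport:
    """Length histogram with the 3n-depletion ratio.

    The 3n ratio compares the observed share of lengths divisible by 3
    with the expectation interpolated from the mean of the two flanking
    non-3n length classes; values < 1 indicate depletion.  The report is
    flagged degenerate when fewer than 3 length classes are present.
    """
    lengths = np.array([f.length for f in introns])
    if len(lengths) == 0:
        raise ValueError("no introns supplied")
    hist = pd.Series(lengths).value_counts().sort_index()
    mode = int(hist.idxmax())
    degenerate = len(hist) < 3
    depletion = None
    if not degenerate:
        obs_3n = 0.0
        exp_3n = 0.0
        for length, count in hist.items():
            if length % 3 == 0:
                obs_3n += count
                flank = [
                    hist.get(length - 1, 0),
                    hist.get(length + 1, 0),
                ]
                exp_3n += float(np.mean(flank))
        if exp_3n > 0:
            depletion = obs_3n / exp_3n
    return IntronLengthReport(
        histogram=hist,
        mean=float(lengths.mean()),
        mode=mode,
        fraction_le_25=float((lengths <= 25).mean()),
        depletion_3n=depletion,
        degenerate=degenerate,
    )
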