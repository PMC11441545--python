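"""k-mer spectra and two-library comparison.

Canonical k-mer counting (k odd so no k-mer is its own reverse
complement), joint MIC-vs-MAC spectra with shared/unique fractions, and
a simplified genome-size estimate from the dominant coverage peak of
the spectrum.  Counting is in-memory and hash-based, sized for the
tens-of-Mbp scale of the synthetic data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dualism.io_utils import iter_seqs

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def canonical(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


@dataclass
class KmerSpectrum:
    k: int
    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def multiplicity_histogram(self) -> Counter:
        """freq -> number of distinct k-mers observed at that frequency."""
        hist: Counter = Counter()
        for c in self.counts.values():
            hist[c] += 1
        return hist


def count_kmers(reads: str | Path | list[str], k: int = 21) -> KmerSpectrum:
    """Count canonical k-mers over every window of unambiguous bases.

    ``reads`` may be a FASTA/FASTQ path (optionally gzipped) or a list
    of sequences.  Windows containing non-ACGT characters are skipped;
    reads shorter than k contribute nothing.
    """
    if k < 3 or k % 2 == 0:
        raise ValueError("k must be odd and >= 3")
    seqs = reads if isinstance(reads, list) else iter_seqs(reads)
    counts: Counter = Counter()
    allowed = frozenset("ACGT")
    for seq in seqs:
        seq = seq.upper()
        if len(seq) < k:
            continue
        if set(seq) <= allowed:
            for i in range(len(seq) - k + 1):
                counts[canonical(seq[i : i + k])] += 1
        else:
            # split on ambiguous characters and count clean stretches
            for part in _clean_parts(seq, allowed):
                for i in range(len(part) - k + 1):
                    counts[canonical(part[i : i + k])] += 1
    return KmerSpectrum(k=k, counts=counts)


def _clean_parts(seq: str, allowed: frozenset) -> list[str]:
    parts, cur = [], []
    for ch in seq:
        if ch in allowed:
            cur.append(ch)
        elif cur:
            parts.append("".join(cur))
            cur = []
    if cur:
        parts.append("".join(cur))
    return parts


@dataclass
class JointSpectrum:
    k: int
    matrix: np.ndarray  # (cap+1, cap+1) counts of distinct k-mers by (freq A, freq B)
    cap: int
    unique_a: Counter  # freq-in-A histogram of k-mers absent from B
    unique_b: Counter
    shared: Counter  # combined-frequency histogram of shared k-mers
    n_distinct_union: int
    freqs: dict[str, tuple[int, int]] = field(default_factory=dict, repr=False)


def joint_spectrum(a: KmerSpectrum, b: KmerSpectrum, cap: int = 400) -> JointSpectrum:
    """Classify k-mers as unique to one library or shared, with a joint
    frequency matrix truncated at ``cap`` per axis (overflow pooled in
    the last bin)."""
    if a.k != b.k:
        raise ValueError("spectra have different k")
    matrix = np.zeros((cap + 1, cap + 1), dtype=np.int64)
    unique_a: Counter = Counter()
    unique_b: Counter = Counter()
    shared: Counter = Counter()
    freqs: dict[str, tuple[int, int]] = {}
    for kmer, fa in a.counts.items():
        fb = b.counts.get(kmer, 0)
        freqs[kmer] = (fa, fb)
        matrix[min(fa, cap), min(fb, cap)] += 1
        if fb == 0:
            unique_a[fa] += 1
        else:
            shared[fa + fb] += 1
    for kmer, fb in b.counts.items():
        if kmer not in a.counts:
            freqs[kmer] = (0, fb)
            matrix[0, min(fb, cap)] += 1
            unique_b[fb] += 1
    return JointSpectrum(
        k=a.k,
        matrix=matrix,
        cap=cap,
        unique_a=unique_a,
        unique_b=unique_b,
        shared=shared,
        n_distinct_union=len(freqs),
        freqs=freqs,
    )


def summary_fractions(
    j: JointSpectrum, min_combined: int = 5, min_each: int = 5
) -> tuple[float, float]:
    """(pct unique to one library, pct seen >= min_each in each library),
    both as percentages of k-mers with combined frequency >= min_combined."""
    denom = 0
    n_unique = 0
    n_high = 0
    for (fa, fb) in j.freqs.values():
        if fa + fb < min_combined:
            continue
        denom += 1
        if fa == 0 or fb == 0:
            n_unique += 1
        if fa >= min_each and fb >= min_each:
            n_high += 1
    if denom == 0:
        return (0.0, 0.0)
    return (100.0 * n_unique / denom, 100.0 * n_high / denom)


def estimate_genome_size(s: KmerSpectrum, min_freq: int = 5) -> tuple[int, float]:
    """Simplified genome-size estimate from the dominant spectrum peak.

    The peak coverage is the most populated multiplicity >= ``min_freq``
    of the frequency histogram; the size estimate is the total k-mer
    mass above the cutoff divided by the peak coverage.  This is a
    coverage-peak heuristic, not a mixture-model fit.
    """
    hist = s.multiplicity_histogram()
    eligible = {f: n for f, n in hist.items() if f >= min_freq}
    if not eligible:
        raise ValueError("unresolvable spectrum: no peak above min_freq")
    # smooth with a width-3 box filter so the peak is not set by
    # single-frequency shot noise
    fmax = max(eligible)
    arr = np.zeros(fmax + 2)
    for f, n in eligible.items():
        arr[f] = n
    smooth = np.convolve(arr, np.ones(3) / 3, mode="same")
    peak = int(np.argmax(smooth[min_freq:]) + min_freq)
    mass = sum(f * n for f, n in eligible.items())
    return peak, mass / peak


def spectra_to_tsv(path: str | Path, s: KmerSpectrum) -> None:
    hist = s.multiplicity_histogram()
    with open(path, "w") as fh:
        fh.write("frequency\tn_distinct_kmers\n")
        for f in sorted(hist):
            fh.write(f"{f}\t{hist[f]}\n")


def matrix_to_tsv(path: str | Path, j: JointSpectrum) -> None:
    np.savetxt(path, j.matrix, fmt="%d", delimiter="\t")
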