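"""IES screening from long-read alignments.

Detects insertion/deletion candidates from CIGAR I/D operations,
computes per-library retention scores (the fraction of reads at a
junction that carry the variant), compares MIC vs MAC retention with a
one-sided Wilcoxon signed-rank test, annotates terminal direct repeats
(TDRs) with a closed-form random-sequence expectation, and tests
whether candidate indels track the SNP-based haplotype of their reads
(the signature of a monoallelic polymorphism rather than a true IES).

Retention is ~1 for germline-limited sequence in MIC reads and ~0 in
MAC reads, but ~0.5 in both libraries for a heterozygous monoallelic
indel in a diploid — which is what distinguishes the two hypotheses.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from scipy import stats

from dualism.io_utils import open_sam_reader, read_phased_snps

SPAN_ANCHOR = 15  # bases a read must cover on each side of a junction to span it


# ---------------------------------------------------------------------------
# Data types


@dataclass
class TDRAnnotation:
    tdr_len: int
    tdr_seq: str
    contains_ta: bool

    def __post_init__(self) -> None:
        if self.contains_ta and self.tdr_len < 2:
            raise ValueError("contains_ta requires tdr_len >= 2")


@dataclass
class IndelCandidate:
    contig: str
    junction_pos: int  # 0-based reference coordinate
    type: str  # "ins" | "del"
    length: int
    insert_seq: str = ""
    n_with: int = 0
    n_without: int = 0
    tdr: TDRAnnotation | None = None
    # haplotype tag counts among reads with / without the variant
    hp_with: Counter = field(default_factory=Counter)
    hp_without: Counter = field(default_factory=Counter)
    concordance: float | None = None
    fisher_p: float | None = None

    @property
    def retention(self) -> float | None:
        denom = self.n_with + self.n_without
        return self.n_with / denom if denom > 0 else None

    @property
    def spanning_coverage(self) -> int:
        return self.n_with + self.n_without


def retention_score(n_with: int, n_without: int) -> float:
    """Fraction of reads bearing the variant; requires some coverage."""
    if n_with + n_without <= 0:
        raise ValueError("retention undefined with zero spanning reads")
    return n_with / (n_with + n_without)


@dataclass
class LibraryComparison:
    shared: list[tuple[IndelCandidate, IndelCandidate]]
    unique_a: list[IndelCandidate]
    unique_b: list[IndelCandidate]
    score_differences: list[float]
    wilcoxon_p: float
    mean_retention_a: float | None
    mean_retention_b: float | None
    mean_retention_shared_a: float | None
    mean_retention_shared_b: float | None


# ---------------------------------------------------------------------------
# Candidate calling


def _iter_indel_events(alignments: str | Path | pysam.AlignmentFile):
    """Yield per-read spans and indel events from a SAM-dialect file."""
    af = (
        alignments
        if isinstance(alignments, pysam.AlignmentFile)
        else open_sam_reader(alignments)
    )
    last = (-1, -1)
    for read in af:
        if read.is_unmapped or read.cigartuples is None:
            continue
        key = (read.reference_id, read.reference_start)
        if key < last:
            raise ValueError("alignments must be sorted by contig and position")
        last = key
        contig = read.reference_name
        hp = read.get_tag("HP") if read.has_tag("HP") else None
        ref_pos = read.reference_start
        q_pos = 0
        events = []
        for op, ln in read.cigartuples:
            if op in (0, 7, 8):  # M/=/X
                ref_pos += ln
                q_pos += ln
            elif op == 1:  # I
                seq = read.query_sequence[q_pos : q_pos + ln] if read.query_sequence else ""
                events.append(("ins", ref_pos, ln, seq))
                q_pos += ln
            elif op in (2, 3):  # D / N
                events.append(("del", ref_pos, ln, ""))
                ref_pos += ln
            elif op in (4, 5):  # clip
                if op == 4:
                    q_pos += ln
        yield contig, read.reference_start, ref_pos, hp, events
    if not isinstance(alignments, pysam.AlignmentFile):
        af.close()


def call_indel_candidates(
    alignments: str | Path,
    reference: dict[str, str],
    min_break_coverage: int = 3,
    min_del_coverage: int = 5,
    min_length: int = 15,
    cluster_tol: int = 10,
) -> list[IndelCandidate]:
    """Call indel candidates from sorted alignments.

    I ops of length >= ``min_length`` supported by >= ``min_break_coverage``
    reads become insertion candidates; D ops need >= ``min_del_coverage``.
    Events whose junctions and lengths agree within ``cluster_tol`` are
    merged (junction/length = support-weighted mode).  ``n_without``
    counts reads spanning the junction with >= 15 bases of alignment on
    each side that do not carry the variant.
    """
    # per contig: read spans and raw events
    spans: dict[str, list[tuple[int, int, int | None, int]]] = defaultdict(list)
    raw: dict[tuple[str, str], list[tuple[int, int, str, int | None, int]]] = defaultdict(list)
    read_idx = 0
    for contig, start, end, hp, events in _iter_indel_events(alignments):
        if contig not in reference:
            raise ValueError(f"contig {contig!r} absent from reference")
        spans[contig].append((start, end, hp, read_idx))
        for etype, pos, ln, seq in events:
            if ln >= min_length:
                raw[(contig, etype)].append((pos, ln, seq, hp, read_idx))
        read_idx += 1

    candidates: list[IndelCandidate] = []
    for (contig, etype), events in raw.items():
        events.sort(key=lambda e: e[0])
        clusters: list[list[tuple[int, int, str, int | None, int]]] = []
        for ev in events:
            placed = False
            if clusters:
                ref_ev = clusters[-1][0]
                if abs(ev[0] - ref_ev[0]) <= cluster_tol and abs(ev[1] - ref_ev[1]) <= cluster_tol:
                    clusters[-1].append(ev)
                    placed = True
            if not placed:
                clusters.append([ev])
        min_support = min_break_coverage if etype == "ins" else min_del_coverage
        starts = np.array([s for s, _, _, _ in spans[contig]])
        ends = np.array([e for _, e, _, _ in spans[contig]])
        hps = [h for _, _, h, _ in spans[contig]]
        gidx = [g for _, _, _, g in spans[contig]]
        for cluster in clusters:
            if len(cluster) < min_support:
                continue
            pos_mode = Counter(e[0] for e in cluster).most_common(1)[0][0]
            len_mode = Counter(e[1] for e in cluster).most_common(1)[0][0]
            seq = next(
                (e[2] for e in cluster if e[1] == len_mode and e[2]), ""
            )
            carrier_idx = {e[4] for e in cluster}
            spanning = np.nonzero(
                (starts <= pos_mode - SPAN_ANCHOR) & (ends >= pos_mode + SPAN_ANCHOR)
            )[0]
            n_without = 0
            hp_with: Counter = Counter()
            hp_without: Counter = Counter()
            for e in cluster:
                if e[3] is not None:
                    hp_with[e[3]] += 1
            for i in spanning:
                li = int(i)
                if gidx[li] in carrier_idx:
                    continue
                n_without += 1
                if hps[li] is not None:
                    hp_without[hps[li]] += 1
            candidates.append(
                IndelCandidate(
                    contig=contig,
                    junction_pos=pos_mode,
                    type=etype,
                    length=len_mode,
                    insert_seq=seq,
                    n_with=len(cluster),
                    n_without=n_without,
                    hp_with=hp_with,
                    hp_without=hp_without,
                )
            )
    candidates.sort(key=lambda c: (c.contig, c.junction_pos))
    return candidates


# ---------------------------------------------------------------------------
# Library comparison


def wilcoxon_one_sided(differences: list[float]) -> float:
    """One-sided Wilcoxon signed-rank P for the differences being > 0.

    Zero differences are dropped before ranking (classical Wilcoxon);
    exact null distribution for n <= 25 without ties, normal
    approximation with continuity correction otherwise.
    """
    d = np.asarray([x for x in differences if x != 0.0])
    if len(d) == 0:
        return 1.0
    method = "exact" if len(d) <= 25 and len(set(np.abs(d))) == len(d) else "approx"
    res = stats.wilcoxon(
        d, alternative="greater", zero_method="wilcox", correction=True, method=method
    )
    return float(res.pvalue)


def compare_libraries(
    a: list[IndelCandidate], b: list[IndelCandidate], match_tol: int = 10
) -> LibraryComparison:
    """Match candidates across libraries and test retention(A) > retention(B)."""
    by_contig_b: dict[tuple[str, str], list[IndelCandidate]] = defaultdict(list)
    for c in b:
        by_contig_b[(c.contig, c.type)].append(c)
    for v in by_contig_b.values():
        v.sort(key=lambda c: c.junction_pos)
    used_b: set[int] = set()
    shared: list[tuple[IndelCandidate, IndelCandidate]] = []
    unique_a: list[IndelCandidate] = []
    for ca in a:
        pool = by_contig_b.get((ca.contig, ca.type), [])
        best = None
        for cb in pool:
            if id(cb) in used_b:
                continue
            if abs(cb.junction_pos - ca.junction_pos) <= match_tol and abs(
                cb.length - ca.length
            ) <= match_tol:
                d = abs(cb.junction_pos - ca.junction_pos)
                if best is None or d < best[0]:
                    best = (d, cb)
        if best is not None:
            used_b.add(id(best[1]))
            shared.append((ca, best[1]))
        else:
            unique_a.append(ca)
    unique_b = [cb for cb in b if id(cb) not in used_b]
    diffs = [
        ca.retention - cb.retention
        for ca, cb in shared
        if ca.retention is not None and cb.retention is not None
    ]
    p = wilcoxon_one_sided(diffs)

    def _mean(cands: list[IndelCandidate]) -> float | None:
        vals = [c.retention for c in cands if c.retention is not None]
        return float(np.mean(vals)) if vals else None

    return LibraryComparison(
        shared=shared,
        unique_a=unique_a,
        unique_b=unique_b,
        score_differences=diffs,
        wilcoxon_p=p,
        mean_retention_a=_mean(a),
        mean_retention_b=_mean(b),
        mean_retention_shared_a=_mean([ca for ca, _ in shared]),
        mean_retention_shared_b=_mean([cb for _, cb in shared]),
    )


def flag_mic_unique_high(
    comparison: LibraryComparison,
    retention_threshold: float = 0.9,
    low_cov_threshold: float = 10.0,
) -> tuple[list[IndelCandidate], float | None]:
    """MIC-unique candidates with retention above threshold, plus their
    mean spanning coverage (true IESs would look like this; at low
    coverage they are more likely mispredictions)."""
    flagged = [
        c
        for c in comparison.unique_a
        if c.retention is not None and c.retention > retention_threshold
    ]
    mean_cov = float(np.mean([c.spanning_coverage for c in flagged])) if flagged else None
    return flagged, mean_cov


# ---------------------------------------------------------------------------
# Terminal direct repeats


def detect_tdr(
    candidate: IndelCandidate, reference: dict[str, str], max_tdr: int = 20
) -> TDRAnnotation:
    """Longest terminal repeat between the insert terminus and the flank.

    Both junction sides are tested — the insert's suffix against the
    reference immediately left of the junction, and the insert's prefix
    against the reference immediately right — and the longer match is
    reported.  The same two-sided-max rule is used by
    :func:`expected_tdr_distribution` so observed and expected lengths
    are commensurable.
    """
    if candidate.type != "ins" or not candidate.insert_seq:
        raise ValueError("TDR detection requires an insertion with insert_seq")
    ref = reference[candidate.contig]
    j = candidate.junction_pos
    ins = candidate.insert_seq
    limit = min(max_tdr, len(ins))
    left = 0
    while (
        left < limit
        and j - left - 1 >= 0
        and ins[-(left + 1)] == ref[j - left - 1]
    ):
        left += 1
    right = 0
    while right < limit and j + right < len(ref) and ins[right] == ref[j + right]:
        right += 1
    if left >= right:
        tdr_len, tdr_seq = left, ins[len(ins) - left :] if left else ""
    else:
        tdr_len, tdr_seq = right, ins[:right]
    return TDRAnnotation(
        tdr_len=tdr_len, tdr_seq=tdr_seq, contains_ta="TA" in tdr_seq
    )


def expected_tdr_distribution(base_freqs, max_tdr: int = 20) -> np.ndarray:
    """P(TDR length = k) at a random junction under the two-sided-max rule.

    With per-position match probability p = sum(f_b^2), each side's match
    length is geometric (P(side >= k) = p^k); the reported length is the
    maximum of the two independent sides, with remaining mass pooled at
    ``max_tdr``.  Returns an array over lengths 0..max_tdr summing to 1.
    """
    p = float(sum(f * f for f in base_freqs))
    out = np.zeros(max_tdr + 1)
    for k in range(max_tdr):
        out[k] = (1 - p ** (k + 1)) ** 2 - (1 - p**k) ** 2
    out[max_tdr] = 1 - (1 - p**max_tdr) ** 2
    return out


# ---------------------------------------------------------------------------
# Haplotype concordance


def haplotype_concordance(
    candidate: IndelCandidate,
) -> tuple[float, float, int] | None:
    """Concordance between variant carriage and read haplotype.

    Builds the 2x2 table (carries variant x haplotype) from the
    candidate's tagged read counts; concordance is the better of the two
    phase assignments; the P value is the two-sided Fisher exact
    probability.  Returns None when no informative (tagged) reads exist.
    Untagged reads are excluded throughout.
    """
    a1, a2 = candidate.hp_with.get(1, 0), candidate.hp_with.get(2, 0)
    b1, b2 = candidate.hp_without.get(1, 0), candidate.hp_without.get(2, 0)
    n = a1 + a2 + b1 + b2
    if n == 0:
        return None
    concordance = max(a1 + b2, a2 + b1) / n
    _, fisher_p = stats.fisher_exact([[a1, a2], [b1, b2]], alternative="two-sided")
    candidate.concordance = concordance
    candidate.fisher_p = float(fisher_p)
    return concordance, float(fisher_p), n


def assign_haplotypes_from_vcf(
    alignments: str | Path,
    vcf_path: str | Path,
    out_sam: str | Path,
) -> int:
    """Tag untagged reads with the haplotype consistent with the majority
    of the phased SNPs they cover (ties/uninformative reads left untagged).
    Writes a new SAM; returns the number of reads tagged."""
    snps = read_phased_snps(vcf_path)
    by_contig: dict[str, list[tuple[int, str, str, int]]] = defaultdict(list)
    for contig, pos, ref, alt, hap in snps:
        by_contig[contig].append((pos, ref, alt, hap))
    for v in by_contig.values():
        v.sort()
    n_tagged = 0
    with open_sam_reader(alignments) as af:
        writer = pysam.AlignmentFile(str(out_sam), "w", header=af.header)
        import bisect

        for read in af:
            if read.is_unmapped or read.has_tag("HP"):
                writer.write(read)
                continue
            contig_snps = by_contig.get(read.reference_name, [])
            if not contig_snps:
                writer.write(read)
                continue
            positions = [s[0] for s in contig_snps]
            lo = bisect.bisect_left(positions, read.reference_start)
            hi = bisect.bisect_right(positions, read.reference_end or read.reference_start)
            votes = Counter()
            if hi > lo:
                seq = read.query_sequence
                pairs = dict(
                    (rp, qp)
                    for qp, rp in read.get_aligned_pairs(matches_only=True)
                )
                for pos, ref, alt, hap in contig_snps[lo:hi]:
                    qp = pairs.get(pos)
                    if qp is None or seq is None:
                        continue
                    base = seq[qp]
                    if base == alt:
                        votes[hap] += 1
                    elif base == ref:
                        votes[1 if hap == 2 else 2] += 1
            if votes:
                top = votes.most_common(2)
                if len(top) == 1 or top[0][1] > top[1][1]:
                    read.set_tag("HP", top[0][0], value_type="i")
                    n_tagged += 1
            writer.write(read)
        writer.close()
    return n_tagged


# ---------------------------------------------------------------------------
# Classification


def classify_candidates(
    comparison: LibraryComparison,
    concordance_threshold: float = 0.9,
    retention_band: float = 0.2,
    retention_threshold: float = 0.9,
    low_cov_threshold: float = 10.0,
) -> dict[int, str]:
    """Label every candidate as haplotype-linked polymorphism, putative
    IES, or indeterminate (low coverage).

    Haplotype-linked: concordance >= threshold and retention within
    0.5 +/- band in both libraries.  Putative IES: unique to the MIC
    (library A) with retention > ``retention_threshold`` and adequate
    spanning coverage.  Everything else: indeterminate.
    Returns ``id(candidate) -> label`` covering the A-library candidates.
    """
    labels: dict[int, str] = {}
    for ca, cb in comparison.shared:
        ra, rb = ca.retention, cb.retention
        conc = ca.concordance
        if (
            conc is not None
            and conc >= concordance_threshold
            and ra is not None
            and rb is not None
            and abs(ra - 0.5) <= retention_band
            and abs(rb - 0.5) <= retention_band
        ):
            labels[id(ca)] = "haplotype-linked polymorphism"
        elif ca.spanning_coverage < low_cov_threshold:
            labels[id(ca)] = "indeterminate (low coverage)"
        else:
            labels[id(ca)] = "indeterminate (low coverage)" if ra is None else "indeterminate"
    for ca in comparison.unique_a:
        ra = ca.retention
        if (
            ra is not None
            and ra > retention_threshold
            and ca.spanning_coverage >= low_cov_threshold
        ):
            labels[id(ca)] = "putative IES"
        else:
            labels[id(ca)] = "indeterminate (low coverage)"
    return labels
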