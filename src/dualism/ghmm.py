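"""Generalized HMM gene prediction for the ambiguous UGA stop/Trp code.

Karyorelict nuclear genomes (NCBI translation table 27) use UGA both as
the only stop codon and, internally, as tryptophan.  The model gives
the UGA codon a probabilistic coding state whose emission mass equals
its observed Trp-coding usage, and enforces a guard region — a fixed
stretch of 21 nt (7 codons) immediately before the stop — in which no
in-frame UGA is permitted.  Start (ATG), CDS, guard and stop states are
mirrored on the reverse strand and decoded in a single joint Viterbi
path, so overlapping genes on opposite strands are disallowed.

Durations: CDS interior and intergenic lengths are geometric (state
self-transitions); the guard has a fixed duration of exactly 7 codons.
Decoding is in log space with deterministic tie-breaking (lower state
index, then lower coordinate, wins).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dualism.io_utils import revcomp
from dualism.truth import GeneTruth

BASES = "ACGT"
NEG_INF = float("-inf")

CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
TGA = CODON_INDEX["TGA"]


def _revcomp_codon_index() -> list[int]:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = []
    for c in CODONS:
        rc = "".join(comp[b] for b in reversed(c))
        out.append(CODON_INDEX[rc])
    return out


RC_CODON = _revcomp_codon_index()


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class GhmmParams:
    """Trained emission and transition parameters.

    ``codon_emissions[TGA]`` carries the UGA-as-Trp usage; the guard
    table has zero UGA mass and is renormalized over the 63 remaining
    codons.  Transition probabilities encode geometric CDS/intergenic
    length distributions and a symmetric strand prior.
    """

    codon_emissions: np.ndarray  # 64 probabilities
    guard_emissions: np.ndarray  # 64 probabilities, [TGA] == 0
    intergenic_base_freqs: np.ndarray  # 4 probabilities (A, C, G, T)
    p_intergenic_self: float
    q_cds_self: float
    guard_len_nt: int = 21

    def __post_init__(self) -> None:
        for name in ("codon_emissions", "guard_emissions", "intergenic_base_freqs"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if abs(self.codon_emissions.sum() - 1) > 1e-6:
            raise ValueError("codon_emissions must sum to 1")
        if abs(self.guard_emissions.sum() - 1) > 1e-6:
            raise ValueError("guard_emissions must sum to 1")
        if self.guard_emissions[TGA] != 0.0:
            raise ValueError("guard_emissions must have zero UGA mass")
        if self.guard_len_nt % 3 != 0:
            raise ValueError("guard_len_nt must be a whole number of codons")

    @property
    def n_guard_codons(self) -> int:
        return self.guard_len_nt // 3

    @property
    def p_gene_start(self) -> float:
        """Per-strand gene start probability out of the intergenic state."""
        return (1.0 - self.p_intergenic_self) / 2.0

    def to_json(self, path: str | Path) -> None:
        obj = {
            "codon_emissions": dict(zip(CODONS, self.codon_emissions.tolist())),
            "guard_emissions": dict(zip(CODONS, self.guard_emissions.tolist())),
            "intergenic_base_freqs": dict(
                zip(BASES, self.intergenic_base_freqs.tolist())
            ),
            "p_intergenic_self": self.p_intergenic_self,
            "q_cds_self": self.q_cds_self,
            "guard_len_nt": self.guard_len_nt,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GhmmParams":
        obj = json.loads(Path(path).read_text())
        return cls(
            codon_emissions=[obj["codon_emissions"][c] for c in CODONS],
            guard_emissions=[obj["guard_emissions"][c] for c in CODONS],
            intergenic_base_freqs=[obj["intergenic_base_freqs"][b] for b in BASES],
            p_intergenic_self=obj["p_intergenic_self"],
            q_cds_self=obj["q_cds_self"],
            guard_len_nt=obj["guard_len_nt"],
        )


@dataclass
class GeneModel:
    contig: str
    strand: str
    cds_start: int  # 0-based half-open genomic span
    cds_end: int
    introns: list[tuple[int, int]] = field(default_factory=list)
    score: float = 0.0

    @property
    def cds_length(self) -> int:
        return (self.cds_end - self.cds_start) - sum(e - s for s, e in self.introns)


# ---------------------------------------------------------------------------
# Training


def extract_cds(gene: GeneTruth, contigs: dict[str, str]) -> str:
    """Spliced, strand-oriented CDS sequence of a gene."""
    seq = contigs[gene.contig]
    pieces = []
    pos = gene.start
    for istart, iend in sorted(gene.introns):
        pieces.append(seq[pos:istart])
        pos = iend
    pieces.append(seq[pos : gene.end])
    cds = "".join(pieces)
    return cds if gene.strand == "+" else revcomp(cds)


def _valid_cds(cds: str, n_guard: int) -> bool:
    if len(cds) % 3 != 0 or len(cds) < 3 * (2 + n_guard):
        return False
    if not cds.startswith("ATG") or not cds.endswith("TGA"):
        return False
    guard = cds[-3 * (n_guard + 1) : -3]
    return all(guard[i : i + 3] != "TGA" for i in range(0, len(guard), 3))


def fit_ghmm(
    genes: list[GeneTruth],
    contigs: dict[str, str],
    pseudocount: float = 1.0,
    guard_len_nt: int = 21,
) -> GhmmParams:
    """Estimate emissions and transitions from annotated genes.

    Codon emissions come from interior codons (between the start codon
    and the guard region) with ``pseudocount`` added per codon; the UGA
    entry is therefore its observed Trp-coding frequency.  Guard
    emissions come from the final guard codons with UGA forced to zero.
    Intergenic base frequencies come from the complement of the gene
    spans; geometric self-transition probabilities are matched to the
    mean interior-CDS and intergenic lengths.
    """
    n_guard = guard_len_nt // 3
    if len(genes) < 20:
        raise ValueError("need at least 20 training genes")
    codon_counts = np.zeros(64)
    guard_counts = np.zeros(64)
    interior_lengths = []
    n_used = 0
    for gene in genes:
        cds = extract_cds(gene, contigs)
        if not _valid_cds(cds, n_guard):
            warnings.warn(f"skipping invalid training gene {gene.gene_id or gene.start}")
            continue
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        interior = codons[1 : -(n_guard + 1)]
        for c in interior:
            codon_counts[CODON_INDEX[c]] += 1
        for c in codons[-(n_guard + 1) : -1]:
            guard_counts[CODON_INDEX[c]] += 1
        interior_lengths.append(len(interior))
        n_used += 1
    if n_used < 20:
        raise ValueError("fewer than 20 valid training genes")

    codon_emissions = (codon_counts + pseudocount) / (
        codon_counts.sum() + pseudocount * 64
    )
    guard_counts[TGA] = 0.0
    guard_emissions = np.zeros(64)
    nz = np.arange(64) != TGA
    guard_emissions[nz] = (guard_counts[nz] + pseudocount) / (
        guard_counts[nz].sum() + pseudocount * 63
    )

    # intergenic composition and mean segment length from the complement
    base_counts = np.zeros(4)
    ig_lengths = []
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append((g.start, g.end))
    for contig, seq in contigs.items():
        spans = sorted(by_contig.get(contig, []))
        pos = 0
        for s, e in spans + [(len(seq), len(seq))]:
            if s > pos:
                seg = seq[pos:s]
                ig_lengths.append(len(seg))
                for i, b in enumerate(BASES):
                    base_counts[i] += seg.count(b)
            pos = max(pos, e)
    if base_counts.sum() == 0:
        base_counts[:] = 1.0
    intergenic = (base_counts + pseudocount) / (base_counts.sum() + 4 * pseudocount)

    mean_interior = float(np.mean(interior_lengths)) if interior_lengths else 1.0
    q = mean_interior / (mean_interior + 1.0)
    mean_ig = float(np.mean(ig_lengths)) if ig_lengths else 100.0
    p_ig = mean_ig / (mean_ig + 1.0)
    return GhmmParams(
        codon_emissions=codon_emissions,
        guard_emissions=guard_emissions,
        intergenic_base_freqs=intergenic,
        p_intergenic_self=p_ig,
        q_cds_self=q,
        guard_len_nt=guard_len_nt,
    )


# ---------------------------------------------------------------------------
# Viterbi decoding

# state codes used in backpointers for the intergenic entry
_FROM_IG = 0
_FROM_FWD_STOP = 1
_FROM_REV_CAT_RC = 2
_FROM_REV_CAT_RG = 3


def viterbi_decode(contig: str, seq: str, params: GhmmParams) -> list[GeneModel]:
    """Joint maximum-probability parse of one contig over both strands.

    Returns the decoded genes; every gene begins ATG, ends UGA, has
    length divisible by 3 and no in-frame UGA within the guard region
    (the guard emission table assigns it probability zero).
    """
    L = len(seq)
    ngc = params.n_guard_codons
    min_gene = 3 * (2 + ngc)
    if L < min_gene:
        return []

    with np.errstate(divide="ignore"):
        codon_log = np.log(params.codon_emissions)
        guard_log = np.log(params.guard_emissions)
        ig_log = np.log(params.intergenic_base_freqs)
    rc_codon_log = codon_log[RC_CODON]
    rc_guard_log = guard_log[RC_CODON]
    log_pig = math.log(params.p_intergenic_self)
    log_pgene = math.log(params.p_gene_start)
    log_q = math.log(params.q_cds_self)
    log_1mq = math.log1p(-params.q_cds_self)

    # per-position encodings
    enc = np.full(L, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        enc[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    valid3 = np.zeros(max(L - 2, 0), dtype=bool)
    cidx = np.zeros(max(L - 2, 0), dtype=np.int64)
    if L >= 3:
        ok = (enc[:-2] >= 0) & (enc[1:-1] >= 0) & (enc[2:] >= 0)
        valid3 = ok
        cidx = np.where(ok, enc[:-2] * 16 + enc[1:-1] * 4 + enc[2:], 0)
    ig_emit = np.where(enc >= 0, ig_log[np.maximum(enc, 0)], NEG_INF)

    cod_e = np.where(valid3, codon_log[cidx], NEG_INF).tolist()
    grd_e = np.where(valid3, guard_log[cidx], NEG_INF).tolist()
    rcod_e = np.where(valid3, rc_codon_log[cidx], NEG_INF).tolist()
    rgrd_e = np.where(valid3, rc_guard_log[cidx], NEG_INF).tolist()
    ATG = CODON_INDEX["ATG"]
    TCA = CODON_INDEX["TCA"]
    CAT = CODON_INDEX["CAT"]
    is_atg = (valid3 & (cidx == ATG)).tolist()
    is_tga = (valid3 & (cidx == TGA)).tolist()
    is_tca = (valid3 & (cidx == TCA)).tolist()
    is_cat = (valid3 & (cidx == CAT)).tolist()
    ig_emit = ig_emit.tolist()

    NI = NEG_INF
    IG = [NI] * (L + 1)
    IG_bp = [0] * (L + 1)
    FS = [NI] * (L + 1)
    FC = [NI] * (L + 1)
    FC_bp = [0] * (L + 1)  # 0: from FS, 1: from FC
    FG = [[NI] * (L + 1) for _ in range(ngc)]
    FG1_bp = [0] * (L + 1)  # 0: from FS, 1: from FC
    RS = [NI] * (L + 1)
    RG = [[NI] * (L + 1) for _ in range(ngc)]
    RC_ = [NI] * (L + 1)
    RC_bp = [0] * (L + 1)  # 0: from RG[last], 1: from RC
    IG[0] = 0.0

    for i in range(1, L + 1):
        # intergenic
        best = IG[i - 1] + ig_emit[i - 1] + log_pig
        bp = _FROM_IG
        if i >= 3:
            j = i - 3
            if is_tga[j]:
                v = FG[ngc - 1][j]
                if v > best:
                    best, bp = v, _FROM_FWD_STOP
            if is_cat[j]:
                v = RC_[j] + log_1mq
                if v > best:
                    best, bp = v, _FROM_REV_CAT_RC
                v = RG[ngc - 1][j] + log_1mq
                if v > best:
                    best, bp = v, _FROM_REV_CAT_RG
        IG[i], IG_bp[i] = best, bp
        if i < 3:
            continue
        j = i - 3
        # forward gene
        if is_atg[j]:
            FS[i] = IG[j] + log_pgene
        src_fs, src_fc = FS[j], FC[j]
        if src_fs >= src_fc:
            FC[i] = src_fs + log_q + cod_e[j]
            FC_bp[i] = 0
            FG[0][i] = src_fs + log_1mq + grd_e[j]
            FG1_bp[i] = 0
        else:
            FC[i] = src_fc + log_q + cod_e[j]
            FC_bp[i] = 1
            FG[0][i] = src_fc + log_1mq + grd_e[j]
            FG1_bp[i] = 1
        for g in range(1, ngc):
            FG[g][i] = FG[g - 1][j] + grd_e[j]
        # reverse gene (genome order: stop', guard', cds', start')
        if is_tca[j]:
            RS[i] = IG[j] + log_pgene
        RG[0][i] = RS[j] + rgrd_e[j]
        for g in range(1, ngc):
            RG[g][i] = RG[g - 1][j] + rgrd_e[j]
        src_rg, src_rc = RG[ngc - 1][j] + log_q, RC_[j] + log_q
        if src_rg >= src_rc:
            RC_[i] = src_rg + rcod_e[j]
            RC_bp[i] = 0
        else:
            RC_[i] = src_rc + rcod_e[j]
            RC_bp[i] = 1

    # traceback from IG[L]
    genes: list[GeneModel] = []
    i = L
    while i > 0:
        bp = IG_bp[i]
        if bp == _FROM_IG:
            i -= 1
            continue
        end = i
        if bp == _FROM_FWD_STOP:
            j = i - 3  # stop codon start
            for _ in range(ngc):
                j -= 3  # guard codons
            # j is now at the position right after the FS/FC chain: FG[0]
            # entered from FS[j-?]... walk the FC chain
            src = FG1_bp[j + 3]
            k = j
            while src == 1:  # came from FC
                src = FC_bp[k]
                k -= 3
            # k is position where FS held the value: FS at k
            start = k - 3
            genes.append(
                GeneModel(
                    contig=contig,
                    strand="+",
                    cds_start=start,
                    cds_end=end,
                    score=IG[end] - IG[start],
                )
            )
            i = start
        else:
            j = i - 3  # CAT (reverse start codon) start
            if bp == _FROM_REV_CAT_RC:
                k = j
                src = RC_bp[k]
                while src == 1:
                    k -= 3
                    src = RC_bp[k]
                k -= 3  # RG[last] position
            else:
                k = j
            for _ in range(ngc):
                k -= 3
            # k is where RS held its value; TCA occupies [k-3, k)
            start = k - 3
            genes.append(
                GeneModel(
                    contig=contig,
                    strand="-",
                    cds_start=start,
                    cds_end=end,
                    score=IG[end] - IG[start],
                )
            )
            i = start
    genes.reverse()
    return genes


def path_log_probability(seq: str, params: GhmmParams) -> float:
    """Log-probability of the best parse (the Viterbi path value)."""
    return _viterbi_value(seq, params)


def _viterbi_value(seq: str, params: GhmmParams) -> float:
    """Best-path log-probability only (no traceback)."""
    # Delegates to the same DP as viterbi_decode but returns IG[L].
    L = len(seq)
    ngc = params.n_guard_codons
    with np.errstate(divide="ignore"):
        codon_log = np.log(params.codon_emissions)
        guard_log = np.log(params.guard_emissions)
        ig_log = np.log(params.intergenic_base_freqs)
    rc_codon_log = codon_log[RC_CODON]
    rc_guard_log = guard_log[RC_CODON]
    log_pig = math.log(params.p_intergenic_self)
    log_pgene = math.log(params.p_gene_start)
    log_q = math.log(params.q_cds_self)
    log_1mq = math.log1p(-params.q_cds_self)
    enc = [BASES.index(b) if b in BASES else -1 for b in seq]
    IG = [NEG_INF] * (L + 1)
    FS = [NEG_INF] * (L + 1)
    FC = [NEG_INF] * (L + 1)
    FG = [[NEG_INF] * (L + 1) for _ in range(ngc)]
    RS = [NEG_INF] * (L + 1)
    RG = [[NEG_INF] * (L + 1) for _ in range(ngc)]
    RC_ = [NEG_INF] * (L + 1)
    IG[0] = 0.0
    for i in range(1, L + 1):
        e = ig_log[enc[i - 1]] if enc[i - 1] >= 0 else NEG_INF
        best = IG[i - 1] + e + log_pig
        if i >= 3:
            j = i - 3
            cod = (
                enc[j] * 16 + enc[j + 1] * 4 + enc[j + 2]
                if min(enc[j], enc[j + 1], enc[j + 2]) >= 0
                else -1
            )
            if cod == TGA:
                best = max(best, FG[ngc - 1][j])
            if cod == CODON_INDEX["CAT"]:
                best = max(best, RC_[j] + log_1mq, RG[ngc - 1][j] + log_1mq)
            IG[i] = best
            if cod >= 0:
                if cod == CODON_INDEX["ATG"]:
                    FS[i] = IG[j] + log_pgene
                FC[i] = max(FS[j], FC[j]) + log_q + codon_log[cod]
                FG[0][i] = max(FS[j], FC[j]) + log_1mq + guard_log[cod]
                for g in range(1, ngc):
                    FG[g][i] = FG[g - 1][j] + guard_log[cod]
                if cod == CODON_INDEX["TCA"]:
                    RS[i] = IG[j] + log_pgene
                RG[0][i] = RS[j] + rc_guard_log[cod]
                for g in range(1, ngc):
                    RG[g][i] = RG[g - 1][j] + rc_guard_log[cod]
                RC_[i] = max(RG[ngc - 1][j], RC_[j]) + log_q + rc_codon_log[cod]
        else:
            IG[i] = best
    return IG[L]


# ---------------------------------------------------------------------------
# Translation (table 27)

_STANDARD = {}


def _standard_table() -> dict[str, str]:
    global _STANDARD
    if not _STANDARD:
        from Bio.Data import CodonTable

        fwd = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
        fwd["TAA"] = "Q"
        fwd["TAG"] = "Q"
        fwd["TGA"] = "W"
        _STANDARD = fwd
    return _STANDARD


def translate_t27(cds: str) -> str:
    """Translate under the karyorelict code: UAA/UAG = Gln, UGA = Trp
    internally but stop as the final codon (which is not included in
    the returned protein)."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    table = _standard_table()
    protein = []
    n = len(cds) // 3
    for i in range(n):
        codon = cds[3 * i : 3 * i + 3]
        if i == n - 1 and codon == "TGA":
            break  # terminal stop
        protein.append(table.get(codon, "X"))
    return "".join(protein)
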