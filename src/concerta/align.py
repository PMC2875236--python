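"""Protein-guided codon alignment and region-wise identity.

Alignment strategy mirrors standard practice for coding gene families:
proteins are aligned first (Needleman–Wunsch with affine gaps, BLOSUM62;
more than two sequences via progressive alignment over a UPGMA guide tree
built on protein p-distances) and every protein gap is then expanded to a
``---`` codon gap, so degapping any row reproduces its input CDS exactly.
Non-coding regions (promoters, introns, 3' ends) are aligned as
nucleotides with the same machinery.

All dynamic programming runs through one numba-compiled Gotoh kernel on a
precomputed position-score matrix; traceback ties are broken
diagonal > up > left, so alignments are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit
from scipy.cluster.hierarchy import linkage

from .codons import CodonError, translate
from .seqs import GeneRecord

logger = logging.getLogger(__name__)

_NEG = np.float32(-1e30)

# protein scoring: BLOSUM62 as shipped with Biopython
_B62 = substitution_matrices.load("BLOSUM62")
PROT_ALPHABET = str(_B62.alphabet)
PROT_MATRIX = np.asarray(_B62, dtype=np.float32)

NUC_ALPHABET = "ACGTN"


def nuc_matrix(match: float = 1.0, mismatch: float = -1.0) -> np.ndarray:
    """Nucleotide scoring: match +1, mismatch configurable, N scores 0."""
    m = np.full((5, 5), mismatch, dtype=np.float32)
    np.fill_diagonal(m, match)
    m[4, :] = 0.0
    m[:, 4] = 0.0
    return m


def _encode(seq: str, alphabet: str, unknown: str) -> np.ndarray:
    lut = np.full(128, alphabet.index(unknown), dtype=np.int64)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _gotoh_fill(S, go, ge):  # pragma: no cover - exercised via callers
    La, Lb = S.shape
    H = np.empty((La + 1, Lb + 1), np.float32)
    E = np.empty((La + 1, Lb + 1), np.float32)
    F = np.empty((La + 1, Lb + 1), np.float32)
    P = np.zeros((La + 1, Lb + 1), np.uint8)
    H[0, 0] = 0.0
    E[0, 0] = _NEG
    F[0, 0] = _NEG
    for j in range(1, Lb + 1):
        H[0, j] = -(go + (j - 1) * ge)
        E[0, j] = H[0, j]
        F[0, j] = _NEG
    for i in range(1, La + 1):
        H[i, 0] = -(go + (i - 1) * ge)
        F[i, 0] = H[i, 0]
        E[i, 0] = _NEG
        for j in range(1, Lb + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - ge
            if e_ext > e_open:
                e = e_ext
                eb = np.uint8(4)
            else:
                e = e_open
                eb = np.uint8(0)
            E[i, j] = e
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - ge
            if f_ext > f_open:
                f = f_ext
                fb = np.uint8(8)
            else:
                f = f_open
                fb = np.uint8(0)
            F[i, j] = f
            d = H[i - 1, j - 1] + S[i - 1, j - 1]
            if d >= f and d >= e:
                h = d
                c = np.uint8(0)
            elif f >= e:
                h = f
                c = np.uint8(1)
            else:
                h = e
                c = np.uint8(2)
            H[i, j] = h
            P[i, j] = c | eb | fb
    return H[La, Lb], P


def _traceback(P: np.ndarray) -> list[tuple[int, int]]:
    """Column pairs (index or -1 for gap) of the optimal global alignment."""
    i, j = P.shape[0] - 1, P.shape[1] - 1
    state = 0  # 0=H, 1=F (gap in B, consume A), 2=E (gap in A, consume B)
    pairs: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if i == 0:
            pairs.append((-1, j - 1))
            j -= 1
            continue
        if j == 0:
            pairs.append((i - 1, -1))
            i -= 1
            continue
        p = int(P[i, j])
        if state == 0:
            c = p & 3
            if c == 0:
                pairs.append((i - 1, j - 1))
                i -= 1
                j -= 1
            else:
                state = c  # enter F (1) or E (2)
        elif state == 1:
            pairs.append((i - 1, -1))
            state = 1 if p & 8 else 0
            i -= 1
        else:
            pairs.append((-1, j - 1))
            state = 2 if p & 4 else 0
            j -= 1
    pairs.reverse()
    return pairs


def _align_score_matrix(S: np.ndarray, gap_open: float, gap_extend: float) -> list[tuple[int, int]]:
    go = np.float32(gap_open)
    ge = np.float32(gap_extend)
    _, P = _gotoh_fill(np.ascontiguousarray(S, dtype=np.float32), go, ge)
    return _traceback(P)


def pairwise_align(
    a: str,
    b: str,
    *,
    alphabet: str,
    submat: np.ndarray,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    unknown: str | None = None,
) -> tuple[str, str]:
    """Global affine-gap alignment of two sequences; returns aligned strings."""
    unknown = unknown or ("N" if alphabet == NUC_ALPHABET else "X")
    ea = _encode(a, alphabet, unknown)
    eb = _encode(b, alphabet, unknown)
    S = submat[np.ix_(ea, eb)]
    pairs = _align_score_matrix(S, gap_open, gap_extend)
    ra = "".join(a[i] if i >= 0 else "-" for i, _ in pairs)
    rb = "".join(b[j] if j >= 0 else "-" for _, j in pairs)
    return ra, rb


def align_nucleotides(a: str, b: str, *, match: float = 1.0, mismatch: float = -1.0,
                      gap_open: float = 4.0, gap_extend: float = 0.5) -> tuple[str, str]:
    return pairwise_align(a, b, alphabet=NUC_ALPHABET, submat=nuc_matrix(match, mismatch),
                          gap_open=gap_open, gap_extend=gap_extend)


# -- progressive MSA ----------------------------------------------------------

def _profile_counts(rows: list[str], alphabet: str, unknown: str) -> np.ndarray:
    n = len(alphabet)
    L = len(rows[0])
    C = np.zeros((L, n), dtype=np.float32)
    for row in rows:
        e = _encode(row.replace("-", unknown), alphabet, unknown)
        gap = np.frombuffer(row.encode("ascii"), dtype=np.uint8) == ord("-")
        keep = ~gap
        C[np.nonzero(keep)[0], e[keep]] += 1.0
    return C


def _merge_profiles(rows_a: list[str], rows_b: list[str], alphabet: str, submat: np.ndarray,
                    gap_open: float, gap_extend: float, unknown: str) -> list[str]:
    Ca = _profile_counts(rows_a, alphabet, unknown)
    Cb = _profile_counts(rows_b, alphabet, unknown)
    S = (Ca @ submat @ Cb.T) / (len(rows_a) * len(rows_b))
    pairs = _align_score_matrix(S, gap_open, gap_extend)
    out_a = ["".join(r[i] if i >= 0 else "-" for i, _ in pairs) for r in rows_a]
    out_b = ["".join(r[j] if j >= 0 else "-" for _, j in pairs) for r in rows_b]
    return out_a + out_b


def aligned_p_distance(row_a: str, row_b: str) -> float:
    """Proportion of mismatches over columns where both rows have a base."""
    a = np.frombuffer(row_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(row_b.encode("ascii"), dtype=np.uint8)
    both = (a != ord("-")) & (b != ord("-"))
    n = int(both.sum())
    if n == 0:
        raise ValueError("no shared non-gap columns")
    return float((a[both] != b[both]).sum() / n)


def progressive_msa(
    seqs: Sequence[str],
    *,
    alphabet: str,
    submat: np.ndarray,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> list[str]:
    """Progressive global MSA over a UPGMA guide tree on p-distances.

    Deterministic: guide built with average linkage on pairwise-alignment
    p-distances, ties resolved by scipy's stable ordering; profile-profile
    scores are average substitution scores over non-gap symbol pairs.
    """
    unknown = "N" if alphabet == NUC_ALPHABET else "X"
    k = len(seqs)
    if k == 0:
        raise ValueError("no sequences to align")
    if k == 1:
        return [seqs[0]]
    if k == 2:
        a, b = pairwise_align(seqs[0], seqs[1], alphabet=alphabet, submat=submat,
                              gap_open=gap_open, gap_extend=gap_extend)
        return [a, b]
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ra, rb = pairwise_align(seqs[i], seqs[j], alphabet=alphabet, submat=submat,
                                    gap_open=gap_open, gap_extend=gap_extend)
            dist[i, j] = dist[j, i] = aligned_p_distance(ra, rb)
    condensed = dist[np.triu_indices(k, 1)]
    Z = linkage(condensed, method="average")
    clusters: dict[int, tuple[list[str], list[int]]] = {
        i: ([seqs[i]], [i]) for i in range(k)
    }
    for step, (ia, ib, _, _) in enumerate(Z):
        rows_a, mem_a = clusters.pop(int(ia))
        rows_b, mem_b = clusters.pop(int(ib))
        merged = _merge_profiles(rows_a, rows_b, alphabet, submat, gap_open, gap_extend, unknown)
        clusters[k + step] = (merged, mem_a + mem_b)
    rows, members = clusters.popitem()[1]
    order = np.argsort(members)
    return [rows[i] for i in order]


# -- codon alignment ----------------------------------------------------------

@dataclass
class CodonAlignment:
    """In-frame aligned coding sequences (gap codon ``---``)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        L = len(self.rows[0])
        if L % 3 != 0 or any(len(r) != L for r in self.rows):
            raise ValueError("codon alignment rows must share a length divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    def index(self, gene_id: str) -> int:
        return self.ids.index(gene_id)

    def codon(self, i: int, c: int) -> str:
        return self.rows[i][3 * c : 3 * c + 3]

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def colmap(self, i: int) -> np.ndarray:
        """Alignment nucleotide column -> 0-based CDS offset, -1 at gaps."""
        row = np.frombuffer(self.rows[i].encode("ascii"), dtype=np.uint8)
        out = np.full(len(row), -1, dtype=np.int64)
        nongap = row != ord("-")
        out[nongap] = np.arange(int(nongap.sum()))
        return out

    def codon_colmap(self, i: int) -> np.ndarray:
        """Alignment codon column -> 0-based input codon index, -1 at gaps."""
        cm = self.colmap(i)
        first = cm[0::3]
        return np.where(first >= 0, first // 3, -1)


def align_codons(
    cds_list: Sequence[str],
    ids: Sequence[str] | None = None,
    *,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> CodonAlignment:
    """Protein-guided codon alignment of two or more translatable CDSs.

    Terminal stop codons, when present, are kept as a final codon column
    (gap-padded for sequences without one) so that degapping reproduces
    every input byte-for-byte.
    """
    if len(cds_list) < 2:
        raise ValueError("need at least 2 coding sequences")
    ids = list(ids) if ids is not None else [f"seq{i+1}" for i in range(len(cds_list))]
    proteins: list[str] = []
    stops: list[str] = []
    for gid, cds in zip(ids, cds_list):
        try:
            prot, internal = translate(cds, strip_terminal_stop=True)
        except CodonError as exc:
            raise CodonError(f"sequence {gid!r}: {exc}") from exc
        if internal:
            raise CodonError(f"sequence {gid!r}: internal stop codon")
        proteins.append(prot)
        stops.append(cds[-3:] if len(cds) == 3 * len(prot) + 3 else "")
    prot_rows = progressive_msa(proteins, alphabet=PROT_ALPHABET, submat=PROT_MATRIX,
                                gap_open=gap_open, gap_extend=gap_extend)
    rows = []
    for cds, prow in zip(cds_list, prot_rows):
        codons = []
        k = 0
        for aa in prow:
            if aa == "-":
                codons.append("---")
            else:
                codons.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows.append("".join(codons))
    if any(stops):
        rows = [row + (st if st else "---") for row, st in zip(rows, stops)]
    return CodonAlignment(ids=list(ids), rows=rows)


# -- percent identity ---------------------------------------------------------

@dataclass(frozen=True)
class IdentityReport:
    gene_i: str
    gene_j: str
    region: str
    n_compared: int
    n_match: int

    @property
    def identity(self) -> float:
        return 100.0 * self.n_match / self.n_compared


def identity_from_rows(row_i: str, row_j: str, *, gene_i: str = "i", gene_j: str = "j",
                       region: str = "all") -> IdentityReport:
    """Percent identity over columns where both rows carry a base.

    Columns with a gap in either row are excluded from numerator and
    denominator; N never matches anything (including N).
    """
    a = np.frombuffer(row_i.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(row_j.encode("ascii"), dtype=np.uint8)
    if len(a) != len(b):
        raise ValueError("rows have different aligned lengths")
    both = (a != ord("-")) & (b != ord("-"))
    n = int(both.sum())
    if n == 0:
        raise ValueError(f"no compared columns between {gene_i} and {gene_j}")
    match = (a == b) & both & (a != ord("N"))
    return IdentityReport(gene_i, gene_j, region, n, int(match.sum()))


def percent_identity(rec_i: GeneRecord, rec_j: GeneRecord, region: str = "cds",
                     **nuc_kwargs) -> IdentityReport:
    """Align one region of two gene records and report percent identity.

    ``region='cds'`` uses the protein-guided codon aligner; any other
    annotated region is aligned as nucleotides.
    """
    if region == "cds":
        aln = align_codons([rec_i.cds(), rec_j.cds()], [rec_i.id, rec_j.id])
        ra, rb = aln.rows
    else:
        ra, rb = align_nucleotides(rec_i.region_seq(region), rec_j.region_seq(region), **nuc_kwargs)
    return identity_from_rows(ra, rb, gene_i=rec_i.id, gene_j=rec_j.id, region=region)


# -- whole-gene nucleotide alignment ------------------------------------------

@dataclass
class NucAlignment:
    """A nucleotide multiple alignment with per-row gene-coordinate maps.

    ``colmaps[i][c]`` is the gene coordinate of row *i* at column *c*, or 0
    (never a valid coordinate) where the row is gapped.
    """

    ids: list[str]
    rows: list[str]
    colmaps: list[np.ndarray]

    def __post_init__(self) -> None:
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows) or any(len(c) != L for c in self.colmaps):
            raise ValueError("alignment rows/colmaps must share one length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def index(self, gene_id: str) -> int:
        return self.ids.index(gene_id)

    @classmethod
    def from_prealigned(cls, records: Sequence[GeneRecord]) -> "NucAlignment":
        rows = [r.sequence for r in records]
        colmaps = []
        for rec in records:
            cm = np.zeros(len(rec.sequence), dtype=np.int64)
            off = 0
            for c, base in enumerate(rec.sequence):
                if base != "-":
                    cm[c] = rec.coord(off)
                    off += 1
            colmaps.append(cm)
        return cls([r.id for r in records], rows, colmaps)

    @classmethod
    def from_rows(cls, ids: Sequence[str], rows: Sequence[str]) -> "NucAlignment":
        """Coordinate maps default to 1-based ungapped positions."""
        colmaps = []
        for row in rows:
            cm = np.zeros(len(row), dtype=np.int64)
            pos = 0
            for c, base in enumerate(row):
                if base != "-":
                    pos += 1
                    cm[c] = pos
            colmaps.append(cm)
        return cls(list(ids), list(rows), colmaps)


def align_family(records: Sequence[GeneRecord], *, match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = 4.0, gap_extend: float = 0.5) -> NucAlignment:
    """Align whole genes region-by-region and concatenate.

    When every record carries the same region annotations, each shared
    region is aligned separately (keeping DP matrices small and region
    boundaries honest) and the blocks are concatenated in gene order.
    Unannotated records are aligned as whole nucleotide sequences.
    """
    submat = nuc_matrix(match, mismatch)
    ids = [r.id for r in records]
    names_sets = [tuple(sorted(rg.name for rg in r.regions)) for r in records]
    if records[0].regions and all(ns == names_sets[0] for ns in names_sets):
        ordered = sorted(records[0].regions, key=lambda rg: records[0].offset(rg.start))
        blocks: list[list[str]] = []
        blockmaps: list[list[np.ndarray]] = []
        for rg in ordered:
            seqs = [rec.region_seq(rg.name) for rec in records]
            rows = progressive_msa(seqs, alphabet=NUC_ALPHABET, submat=submat,
                                   gap_open=gap_open, gap_extend=gap_extend)
            maps = []
            for rec, row in zip(records, rows):
                r = rec.region(rg.name)
                coords = [rec.coord(o) for o in range(rec.offset(r.start), rec.offset(r.end) + 1)]
                cm = np.zeros(len(row), dtype=np.int64)
                k = 0
                for c, base in enumerate(row):
                    if base != "-":
                        cm[c] = coords[k]
                        k += 1
                maps.append(cm)
            blocks.append(rows)
            blockmaps.append(maps)
        rows = ["".join(b[i] for b in blocks) for i in range(len(records))]
        colmaps = [np.concatenate([bm[i] for bm in blockmaps]) for i in range(len(records))]
        return NucAlignment(ids, rows, colmaps)
    rows = progressive_msa([r.sequence for r in records], alphabet=NUC_ALPHABET, submat=submat,
                           gap_open=gap_open, gap_extend=gap_extend)
    colmaps = []
    for rec, row in zip(records, rows):
        cm = np.zeros(len(row), dtype=np.int64)
        off = 0
        for c, base in enumerate(row):
            if base != "-":
                cm[c] = rec.coord(off)
                off += 1
        colmaps.append(cm)
    return NucAlignment(ids, rows, colmaps)
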