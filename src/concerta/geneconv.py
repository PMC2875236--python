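"""Gene-conversion detection by permutation of polymorphic sites.

The scan condenses a nucleotide multiple alignment to its polymorphic
columns, scores each sequence pair's match/mismatch vector over those
sites, and extracts maximal-scoring fragments — with the default mismatch
penalty of 0 these are maximal runs of consecutive matching polymorphic
sites; with a penalty g > 0 the Ruzzo–Tompa all-maximal-scoring-
subsequences algorithm is used.  Significance comes from jointly permuting
the order of the polymorphic columns (site patterns kept intact across
sequences) and recording, per permutation, the best fragment score over
all pairs; the global p-value is therefore family-wise over pairs.

Multiple fragments per pair are recovered by iterative masking: the sites
of each significant fragment are removed and the pair re-scanned until no
significant fragment remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from numba import njit

from .align import NucAlignment
from .seqs import GeneRecord, span_length

logger = logging.getLogger(__name__)

_GAP = ord("-")
_N = ord("N")


class NoTestSignal(ValueError):
    """The alignment carries no usable polymorphism for a conversion test."""


@dataclass
class PolymorphicProfile:
    """Polymorphic columns of an alignment and the bases at them."""

    ids: list[str]
    site_cols: np.ndarray   # alignment columns, strictly increasing
    bases: np.ndarray       # (n_seqs, n_sites) uint8
    aln_length: int

    @property
    def n_sites(self) -> int:
        return self.site_cols.size

    def match_vector(self, i: int, j: int) -> np.ndarray:
        return self.bases[i] == self.bases[j]


def condense(aln: NucAlignment) -> PolymorphicProfile:
    """Extract polymorphic columns (gap- or N-containing columns dropped).

    A column is polymorphic iff at least two distinct bases occur among
    all sequences.  With only two sequences every variable column is a
    pairwise mismatch and the test degenerates; a warning is issued and
    the scan proceeds.
    """
    if len(aln.rows) < 3:
        logger.warning("conversion scan on %d sequences: every variable column is a "
                       "pairwise mismatch; interpret with caution", len(aln.rows))
    M = np.vstack([np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in aln.rows])
    clean = ~np.any((M == _GAP) | (M == _N), axis=0)
    poly = clean & np.any(M != M[0], axis=0)
    cols = np.nonzero(poly)[0]
    if cols.size == 0:
        raise NoTestSignal("no polymorphic sites in alignment")
    return PolymorphicProfile(ids=list(aln.ids), site_cols=cols, bases=M[:, cols],
                              aln_length=aln.length)


# -- fragment search ----------------------------------------------------------

@dataclass(frozen=True)
class RawFragment:
    """A candidate fragment in polymorphic-site index space (inclusive)."""

    first_site: int
    last_site: int
    score: float
    n_mismatch: int

    @property
    def n_poly(self) -> int:
        return self.last_site - self.first_site + 1


def ruzzo_tompa(x: np.ndarray) -> list[tuple[int, int, float]]:
    """All maximal-scoring subsequences of *x*; returns (start, end, score).

    Linear-time algorithm of Ruzzo & Tompa (1999); ends are inclusive.
    """
    # each entry: [L_cum, R_cum, start, end]; cumulative sums bracket the run
    I: list[list[float]] = []
    cum = 0.0
    for k, v in enumerate(x):
        cum_prev = cum
        cum += float(v)
        if v <= 0:
            continue
        cand = [cum_prev, cum, k, k]
        while True:
            # find rightmost j with L_j < cand's L
            j = None
            for t in range(len(I) - 1, -1, -1):
                if I[t][0] < cand[0]:
                    j = t
                    break
            if j is None:
                I.append(cand)
                break
            if I[j][1] >= cand[1]:
                I.append(cand)
                break
            # merge: extend I[j] to cover cand, pop deeper entries
            merged = [I[j][0], cand[1], int(I[j][2]), int(cand[3])]
            I = I[:j]
            cand = merged
    return [(int(s), int(e), r - l) for l, r, s, e in I]


def _runs_of_matches(mv: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal runs of consecutive True values; score = run length."""
    if not mv.any():
        return []
    padded = np.concatenate(([False], mv, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    return [(int(s), int(e), float(e - s + 1)) for s, e in zip(starts, ends)]


def pair_fragments(profile: PolymorphicProfile, i: int, j: int, *, g: float = 0.0,
                   sites: np.ndarray | None = None) -> list[RawFragment]:
    """Maximal-scoring fragments of the pair's match vector.

    *sites* optionally restricts the scan to a subset of polymorphic-site
    indices (used by iterative masking); fragment endpoints are reported
    in the full profile's site-index space.
    """
    mv = profile.match_vector(i, j)
    idx = np.arange(profile.n_sites) if sites is None else np.asarray(sites)
    mv = mv[idx]
    if g == 0.0:
        raw = _runs_of_matches(mv)
    else:
        x = np.where(mv, 1.0, -float(g))
        raw = ruzzo_tompa(x)
    out = []
    for s, e, score in raw:
        n_mis = int((~mv[s : e + 1]).sum())
        out.append(RawFragment(int(idx[s]), int(idx[e]), score, n_mis))
    return out


@njit(cache=True)
def _kadane_rows(X):  # pragma: no cover - exercised via permutation_test
    """Maximum subsequence sum per row (0 if all negative)."""
    k, m = X.shape
    out = np.zeros(k)
    for r in range(k):
        best = 0.0
        cur = 0.0
        for c in range(m):
            cur += X[r, c]
            if cur < 0.0:
                cur = 0.0
            elif cur > best:
                best = cur
        out[r] = best
    return out


def _null_max_scores(bases: np.ndarray, pair_idx: list[tuple[int, int]], n_perm: int,
                     g: float, rng: np.random.Generator) -> np.ndarray:
    """(n_pairs, n_perm) best fragment score per pair per permutation."""
    M = np.vstack([bases[i] == bases[j] for i, j in pair_idx])
    m = M.shape[1]
    out = np.empty((len(pair_idx), n_perm))
    for p in range(n_perm):
        perm = rng.permutation(m)
        Mp = M[:, perm]
        if g == 0.0:
            c = np.cumsum(Mp, axis=1)
            reset = np.maximum.accumulate(np.where(~Mp, c, 0), axis=1)
            out[:, p] = (c - reset).max(axis=1)
        else:
            X = np.where(Mp, 1.0, -float(g))
            out[:, p] = _kadane_rows(X)
    return out


# -- reported fragments -------------------------------------------------------

@dataclass(frozen=True)
class ConversionFragment:
    """A detected conversion tract with coordinates in both genes."""

    gene_i: str
    gene_j: str
    begin_i: int
    end_i: int
    begin_j: int
    end_j: int
    length_i: int
    length_j: int
    n_poly: int
    n_mismatch: int
    score: float
    global_p: float
    pair_p: float           # per-pair permutation p, not multiplicity-corrected
    aln_begin: int          # alignment columns (0-based, inclusive) for masking
    aln_end: int


def _extend_endpoints(profile: PolymorphicProfile, frag: RawFragment) -> tuple[int, int]:
    """Fragment span in alignment columns, ends extended halfway to the
    neighbouring polymorphic site (rounded toward the fragment); terminal
    fragments extend to the alignment ends."""
    cols = profile.site_cols
    ca, cb = int(cols[frag.first_site]), int(cols[frag.last_site])
    if frag.first_site == 0:
        begin = 0
    else:
        prev = int(cols[frag.first_site - 1])
        begin = ca - (ca - prev) // 2
    if frag.last_site == profile.n_sites - 1:
        end = profile.aln_length - 1
    else:
        nxt = int(cols[frag.last_site + 1])
        end = cb + (nxt - cb) // 2
    return begin, end


def _gene_span(aln: NucAlignment, row: int, begin_col: int, end_col: int) -> tuple[int, int, int]:
    cm = aln.colmaps[row]
    seg = cm[begin_col : end_col + 1]
    nz = seg[seg != 0]
    if nz.size == 0:
        return 0, 0, 0
    b, e = int(nz[0]), int(nz[-1])
    return b, e, span_length(b, e)


def permutation_test(aln: NucAlignment, *, n_perm: int = 1000, seed: int | None = None,
                     g: float = 0.0, report_threshold: float = 0.05,
                     max_fragments_per_pair: int = 20) -> list[ConversionFragment]:
    """Scan all sequence pairs for significant conversion fragments.

    The null permutes polymorphic-column order jointly for all sequences;
    each permutation contributes its maximum fragment score over all pairs,
    so ``global_p`` is family-wise.  ``global_p = (1 + #{null >= score}) /
    (n_perm + 1)`` and fragments with ``global_p <= report_threshold`` are
    reported, iteratively masking found sites within each pair.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    profile = condense(aln)
    k = len(aln.ids)
    pair_idx = list(combinations(range(k), 2))
    rng = np.random.default_rng(seed)
    null_pair = _null_max_scores(profile.bases, pair_idx, n_perm, g, rng)
    null_global = null_pair.max(axis=0)

    def global_p(score: float) -> float:
        return (1.0 + float((null_global >= score).sum())) / (n_perm + 1.0)

    fragments: list[ConversionFragment] = []
    for p_i, (i, j) in enumerate(pair_idx):
        available = np.arange(profile.n_sites)
        for _ in range(max_fragments_per_pair):
            if available.size == 0:
                break
            cands = pair_fragments(profile, i, j, g=g, sites=available)
            if not cands:
                break
            best = max(cands, key=lambda f: (f.score, -f.first_site))
            gp = global_p(best.score)
            if gp > report_threshold:
                break
            pp = (1.0 + float((null_pair[p_i] >= best.score).sum())) / (n_perm + 1.0)
            bcol, ecol = _extend_endpoints(profile, best)
            bi, ei, li = _gene_span(aln, i, bcol, ecol)
            bj, ej, lj = _gene_span(aln, j, bcol, ecol)
            fragments.append(ConversionFragment(
                gene_i=aln.ids[i], gene_j=aln.ids[j],
                begin_i=bi, end_i=ei, begin_j=bj, end_j=ej,
                length_i=li, length_j=lj,
                n_poly=best.n_poly, n_mismatch=best.n_mismatch,
                score=best.score, global_p=gp, pair_p=pp,
                aln_begin=bcol, aln_end=ecol,
            ))
            keep = (available < best.first_site) | (available > best.last_site)
            available = available[keep]
    fragments.sort(key=lambda f: (f.gene_i, f.gene_j, f.global_p, f.begin_i))
    return fragments


def report_table(fragments: list[ConversionFragment],
                 records: list[GeneRecord] | None = None) -> pd.DataFrame:
    """Fragment table in the two-gene layout (second gene parenthesised)."""
    sizes = {}
    if records:
        sizes = {r.id: span_length(r.start_coord, r.end_coord) for r in records}
    rows = []
    for f in fragments:
        rows.append({
            "Gene1": f.gene_i,
            "Gene2": f.gene_j,
            "p-value": f"{f.global_p:.4f}",
            "Begin": f"{f.begin_i}({f.begin_j})",
            "End": f"{f.end_i}({f.end_j})",
            "Length [bp]": f"{f.length_i}({f.length_j})",
            "Entire gene size [bp]": (
                f"{sizes.get(f.gene_i, '')}({sizes.get(f.gene_j, '')})" if sizes else ""
            ),
        })
    cols = ["Gene1", "Gene2", "p-value", "Begin", "End", "Length [bp]", "Entire gene size [bp]"]
    return pd.DataFrame(rows, columns=cols)
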