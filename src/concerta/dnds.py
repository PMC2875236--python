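"""Nei–Gojobori synonymous/nonsynonymous analysis with Jukes–Cantor correction.

Implements the classic unweighted counting method: synonymous (S) and
nonsynonymous (N) site totals averaged over the two sequences, pathway-
averaged difference counts (Sd, Nd), proportions Ps = Sd/S and Pn = Nd/N,
Jukes–Cantor multiple-hit correction d = -(3/4)·ln(1 - (4/3)p), and a
codon-bootstrap Z-test for purifying selection (H1: dN < dS).

Gap, N-containing and stop codons are removed pairwise by codon.  The
bootstrap resamples codon columns jointly for the two sequences, so the
variance of (dS - dN) respects their covariance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .align import CodonAlignment
from .codons import codon_differences, codon_sites, is_sense

logger = logging.getLogger(__name__)


class SaturationError(ValueError):
    """Raised when a proportion of differences is beyond the JC domain (p >= 3/4)."""


class NoComparableCodonsError(ValueError):
    pass


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor corrected distance; defined for 0 <= p < 3/4."""
    if p < 0:
        raise ValueError(f"proportion {p} < 0")
    if p >= 0.75:
        raise SaturationError(f"p = {p} is at or beyond saturation (3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class PairCounts:
    """Site and difference counts for one sequence pair."""

    gene_i: str
    gene_j: str
    n_codons_compared: int
    S: float
    N: float
    Sd: float
    Nd: float
    se_Ps: float = float("nan")
    se_Pn: float = float("nan")

    @property
    def Ps(self) -> float:
        return self.Sd / self.S

    @property
    def Pn(self) -> float:
        return self.Nd / self.N


@dataclass(frozen=True)
class DnDsResult:
    """JC-corrected distances, dN/dS and the purifying-selection Z-test."""

    counts: PairCounts
    dS: float
    dN: float
    omega: float
    se_dS: float
    se_dN: float
    se_diff: float
    Z: float
    p_value: float
    B: int
    seed: int | None
    omega_infinite: bool = False
    omega_undefined: bool = False
    two_tailed: bool = False

    @property
    def testable(self) -> bool:
        return not self.omega_undefined and np.isfinite(self.Z)


def _pair_arrays(aln: CodonAlignment, i: int, j: int):
    """Per-codon-column (s_avg, n_avg, sd, nd) over pairwise-kept columns."""
    s_avg, n_avg, sd, nd, cols = [], [], [], [], []
    for c in range(aln.n_codons):
        ca, cb = aln.codon(i, c), aln.codon(j, c)
        if not (is_sense(ca) and is_sense(cb)):
            continue
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        d_s, d_n = codon_differences(ca, cb)
        s_avg.append((sa + sb) / 2.0)
        n_avg.append((na + nb) / 2.0)
        sd.append(d_s)
        nd.append(d_n)
        cols.append(c)
    if not cols:
        raise NoComparableCodonsError(
            f"no comparable codons between rows {i} and {j} (gaps/Ns/stops everywhere)"
        )
    return (np.array(s_avg), np.array(n_avg), np.array(sd), np.array(nd), np.array(cols))


def _bootstrap_props(s, n, sd, nd, B: int, rng: np.random.Generator):
    """Bootstrap codon columns; returns (Ps_b, Pn_b) arrays of length B."""
    m = len(s)
    counts = rng.multinomial(m, np.full(m, 1.0 / m), size=B).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        Ps_b = (counts @ sd) / (counts @ s)
        Pn_b = (counts @ nd) / (counts @ n)
    return Ps_b, Pn_b


def count_pair(aln: CodonAlignment, i: int, j: int, *, B: int = 1000,
               seed: int | None = None) -> PairCounts:
    """Ps/Pn counts for rows *i*, *j* with bootstrap standard errors.

    Codon columns containing a gap, an ambiguous base or a stop codon in
    either row are dropped (pairwise deletion by codon).
    """
    s, n, sd, nd, _ = _pair_arrays(aln, i, j)
    se_ps = se_pn = float("nan")
    if B and B >= 2:
        rng = np.random.default_rng(seed)
        Ps_b, Pn_b = _bootstrap_props(s, n, sd, nd, B, rng)
        se_ps = float(np.nanstd(Ps_b, ddof=1))
        se_pn = float(np.nanstd(Pn_b, ddof=1))
    return PairCounts(
        gene_i=aln.ids[i], gene_j=aln.ids[j], n_codons_compared=len(s),
        S=float(s.sum()), N=float(n.sum()), Sd=float(sd.sum()), Nd=float(nd.sum()),
        se_Ps=se_ps, se_Pn=se_pn,
    )


def _dnds_from_arrays(aln_ids, i, j, s, n, sd, nd, B, seed, two_tailed) -> DnDsResult:
    S, N, Sd, Nd = s.sum(), n.sum(), sd.sum(), nd.sum()
    Ps, Pn = Sd / S, Nd / N
    dS, dN = jukes_cantor(Ps), jukes_cantor(Pn)

    omega_inf = omega_undef = False
    if dS == 0.0 and dN == 0.0:
        omega = float("nan")
        omega_undef = True
    elif dS == 0.0:
        omega = float("inf")
        omega_inf = True
    else:
        omega = dN / dS

    rng = np.random.default_rng(seed)
    Ps_b, Pn_b = _bootstrap_props(s, n, sd, nd, B, rng)
    ok = (Ps_b < 0.75) & (Pn_b < 0.75) & np.isfinite(Ps_b) & np.isfinite(Pn_b)
    n_bad = B - int(ok.sum())
    if n_bad:
        logger.warning("%d/%d bootstrap replicates saturated; dropped", n_bad, B)
    with np.errstate(invalid="ignore"):
        dS_b = -0.75 * np.log1p(-4.0 * Ps_b[ok] / 3.0)
        dN_b = -0.75 * np.log1p(-4.0 * Pn_b[ok] / 3.0)
    se_dS = float(np.std(dS_b, ddof=1)) if len(dS_b) > 1 else float("nan")
    se_dN = float(np.std(dN_b, ddof=1)) if len(dN_b) > 1 else float("nan")
    se_diff = float(np.std(dS_b - dN_b, ddof=1)) if len(dS_b) > 1 else float("nan")

    if omega_undef or se_diff == 0.0 or not np.isfinite(se_diff):
        Z = p = float("nan")
    else:
        Z = (dS - dN) / se_diff
        p = float(2.0 * norm.sf(abs(Z))) if two_tailed else float(norm.sf(Z))
    counts = PairCounts(
        gene_i=aln_ids[i], gene_j=aln_ids[j], n_codons_compared=len(s),
        S=float(S), N=float(N), Sd=float(Sd), Nd=float(Nd),
        se_Ps=float(np.nanstd(Ps_b, ddof=1)), se_Pn=float(np.nanstd(Pn_b, ddof=1)),
    )
    return DnDsResult(counts=counts, dS=dS, dN=dN, omega=omega,
                      se_dS=se_dS, se_dN=se_dN, se_diff=se_diff, Z=float(Z),
                      p_value=float(p), B=B, seed=seed,
                      omega_infinite=omega_inf, omega_undefined=omega_undef,
                      two_tailed=two_tailed)


def dnds(aln: CodonAlignment, i: int, j: int, *, B: int = 1000, seed: int | None = None,
         two_tailed: bool = False) -> DnDsResult:
    """dS, dN, dN/dS and the one-tailed purifying-selection Z-test.

    The null distribution of Z uses the bootstrap SE of (dS - dN) from B
    joint codon-column resamples; p is the upper normal tail of Z, so small
    p supports dN < dS (purifying selection).
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap replicates")
    s, n, sd, nd, _ = _pair_arrays(aln, i, j)
    return _dnds_from_arrays(aln.ids, i, j, s, n, sd, nd, B, seed, two_tailed)


@dataclass(frozen=True)
class WindowResult:
    start_codon: int       # alignment codon-column index of window start
    end_codon: int         # inclusive
    result: DnDsResult | None
    untestable: bool

    @property
    def omega(self) -> float:
        return self.result.omega if self.result else float("nan")


def windowed_dnds(aln: CodonAlignment, i: int, j: int, *, window_codons: int = 60,
                  step_codons: int = 20, B: int = 200, seed: int | None = None) -> list[WindowResult]:
    """Sliding-window dN/dS scan over the pair's compared codons.

    Windows slide over the pairwise-kept codon columns; windows where dS=0
    (or with an undefined omega) are flagged untestable.  A window longer
    than the alignment degrades to a single full-length window.
    """
    if window_codons < 10:
        raise ValueError("window must be at least 10 codons")
    if step_codons < 1:
        raise ValueError("step must be >= 1 codon")
    s, n, sd, nd, cols = _pair_arrays(aln, i, j)
    m = len(s)
    if window_codons > m:
        logger.warning("window (%d codons) exceeds compared codons (%d); using one window",
                       window_codons, m)
        window_codons = m
    out: list[WindowResult] = []
    starts = range(0, m - window_codons + 1, step_codons)
    for w, lo in enumerate(starts):
        hi = lo + window_codons
        sl = slice(lo, hi)
        child = None if seed is None else int(np.random.SeedSequence([seed, w]).generate_state(1)[0] % (2**31))
        if sd[sl].sum() == 0.0:
            out.append(WindowResult(int(cols[lo]), int(cols[hi - 1]), None, True))
            continue
        try:
            res = _dnds_from_arrays(aln.ids, i, j, s[sl], n[sl], sd[sl], nd[sl], B, child, False)
        except SaturationError:
            out.append(WindowResult(int(cols[lo]), int(cols[hi - 1]), None, True))
            continue
        out.append(WindowResult(int(cols[lo]), int(cols[hi - 1]), res,
                                res.omega_undefined or res.omega_infinite))
    return out
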