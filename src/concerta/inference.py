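"""Decision procedures for concerted evolution in duplicated gene families.

Three analyses, in the order a study would run them:

* orthologue/paralogue assignment from 5' promoter identity — orthologues
  keep locus-specific promoters across species, so cross-species
  reciprocal best promoter matches above an identity floor are called
  orthologue pairs;
* concerted evolution vs purifying selection — both homogenise coding
  sequence, but only concerted evolution also homogenises synonymous
  sites and non-coding DNA, so within-species (paralogue) synonymous
  divergence Ps far below between-species (orthologue) Ps indicates
  concerted evolution; comparisons where Ps approaches saturation
  (≈0.4–0.7) are declared indeterminate;
* mosaic analysis — dN/dS of the coding regions left after masking
  significant conversion tracts, per contiguous segment and pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .align import CodonAlignment, align_nucleotides, identity_from_rows
from .dnds import DnDsResult, PairCounts, _dnds_from_arrays, _pair_arrays
from .geneconv import ConversionFragment
from .seqs import GeneRecord

logger = logging.getLogger(__name__)


# -- orthologue/paralogue assignment ------------------------------------------

@dataclass
class HomologyMap:
    ids: list[str]
    species: dict[str, str]
    identity: dict[tuple[str, str], float]     # promoter % identity per pair
    ortholog_pairs: list[tuple[str, str]]      # cross-species reciprocal best
    paralog_sets: dict[str, list[str]]         # species -> gene ids

    def promoter_identity(self, a: str, b: str) -> float:
        return self.identity[(a, b) if (a, b) in self.identity else (b, a)]


def _promoter_seq(rec: GeneRecord, window_bp: int) -> str | None:
    if rec.has_region("promoter"):
        seq = rec.region_seq("promoter")
        return seq[-window_bp:] if len(seq) > window_bp else seq
    if rec.start_coord < 0:
        # derive: window_bp bases directly upstream of the start codon
        end = rec.offset(-1)
        start = max(0, end + 1 - window_bp)
        return rec.sequence[start : end + 1]
    return None


def assign_homology(records: list[GeneRecord], *, promoter_window_bp: int = 1100,
                    identity_floor: float = 50.0) -> HomologyMap:
    """Orthologue pairs from reciprocal best promoter identity.

    Promoters are the annotated 'promoter' regions (or the window directly
    upstream of the start codon), compared pairwise with the nucleotide
    aligner.  Cross-species pairs that are reciprocal best matches with
    identity above *identity_floor* become orthologue pairs; genes without
    a promoter are excluded with a warning.
    """
    usable: list[GeneRecord] = []
    proms: dict[str, str] = {}
    for rec in records:
        p = _promoter_seq(rec, promoter_window_bp)
        if p is None:
            logger.warning("gene %s has no promoter annotation; excluded from homology", rec.id)
            continue
        usable.append(rec)
        proms[rec.id] = p
    if len({r.species for r in usable}) < 2:
        raise ValueError("homology assignment needs genes from at least 2 species")
    ident: dict[tuple[str, str], float] = {}
    for a, b in combinations(usable, 2):
        ra, rb = align_nucleotides(proms[a.id], proms[b.id])
        ident[(a.id, b.id)] = identity_from_rows(ra, rb, gene_i=a.id, gene_j=b.id,
                                                 region="promoter").identity

    def pid(x: str, y: str) -> float:
        return ident[(x, y)] if (x, y) in ident else ident[(y, x)]

    species = {r.id: r.species for r in usable}
    pairs: list[tuple[str, str]] = []
    for a, b in combinations(usable, 2):
        if a.species == b.species:
            continue
        if pid(a.id, b.id) < identity_floor:
            continue
        # reciprocal best across the two species
        best_for_a = max((r for r in usable if r.species == b.species),
                         key=lambda r: pid(a.id, r.id))
        best_for_b = max((r for r in usable if r.species == a.species),
                         key=lambda r: pid(b.id, r.id))
        if best_for_a.id == b.id and best_for_b.id == a.id:
            pairs.append((a.id, b.id))
    paralogs: dict[str, list[str]] = {}
    for r in usable:
        paralogs.setdefault(r.species, []).append(r.id)
    return HomologyMap(ids=[r.id for r in usable], species=species, identity=ident,
                       ortholog_pairs=pairs, paralog_sets=paralogs)


# -- concerted vs purifying decision ------------------------------------------

@dataclass(frozen=True)
class EvolutionVerdict:
    mode: str                       # concerted | purifying_only | saturated_indeterminate
    ps_paralog_min: float
    ps_paralog_max: float
    ps_ortholog_min: float
    ps_ortholog_max: float
    ratio: float                    # max paralog Ps / min ortholog Ps
    ratio_threshold: float
    saturation_low: float
    notes: list[str] = field(default_factory=list)


def classify_mode(ps_paralog: list[float], ps_ortholog: list[float], *,
                  ratio_threshold: float = 0.5,
                  saturation_band: tuple[float, float] = (0.4, 0.7),
                  tandem_head_to_tail: bool = False) -> EvolutionVerdict:
    """Concerted evolution vs purifying selection from Ps contrasts.

    Concerted evolution is called when the largest within-species
    (paralogue) Ps is at most ``ratio_threshold`` times the smallest
    between-species (orthologue) Ps; any contributing Ps at or above the
    saturation band's lower edge makes the verdict indeterminate.  The
    mechanism note (gene conversion vs unequal crossover) comes from the
    declared genomic organisation, not from sequence.
    """
    if not ps_paralog or not ps_ortholog:
        raise ValueError("need at least one paralogue and one orthologue Ps value")
    sat_low = saturation_band[0]
    notes = []
    if tandem_head_to_tail:
        notes.append("tandem head-to-tail organisation declared: unequal crossover "
                     "is a plausible homogenisation mechanism")
    else:
        notes.append("no tandem organisation declared: gene conversion is the "
                     "plausible homogenisation mechanism")
    pmax, pmin = max(ps_paralog), min(ps_paralog)
    omax, omin = max(ps_ortholog), min(ps_ortholog)
    ratio = pmax / omin if omin > 0 else float("inf")
    if any(p >= sat_low for p in ps_paralog + ps_ortholog):
        mode = "saturated_indeterminate"
        notes.append(f"a contributing Ps is at or above the saturation bound {sat_low}")
    elif pmax <= ratio_threshold * omin:
        mode = "concerted"
    else:
        mode = "purifying_only"
    return EvolutionVerdict(mode=mode, ps_paralog_min=pmin, ps_paralog_max=pmax,
                            ps_ortholog_min=omin, ps_ortholog_max=omax, ratio=ratio,
                            ratio_threshold=ratio_threshold, saturation_low=sat_low,
                            notes=notes)


# -- mosaic (tract-masked) analysis -------------------------------------------

@dataclass(frozen=True)
class UnconvertedSegment:
    gene_i: str
    gene_j: str
    label: str                      # "fragment1", ..., or "combined"
    codon_cols: tuple[int, int]     # alignment codon-column span (inclusive)
    size_bp_i: int
    size_bp_j: int
    counts: PairCounts
    result: DnDsResult
    combined: bool = False


@dataclass(frozen=True)
class MosaicReport:
    gene_i: str
    gene_j: str
    whole_gene_converted: bool
    segments: list[UnconvertedSegment]
    masked_codons: int
    total_codons: int


def mosaic_dnds(aln: CodonAlignment, i: int, j: int,
                fragments: list[ConversionFragment], *,
                cds_coords_i: list[int] | None = None,
                cds_coords_j: list[int] | None = None,
                p_threshold: float = 0.05, B: int = 1000,
                min_segment_codons: int = 10,
                seed: int | None = None) -> MosaicReport:
    """dN/dS of the coding region left after masking conversion tracts.

    Codon columns of the pair whose bases fall inside any significant
    fragment (``global_p < p_threshold`` for this gene pair, coordinates
    matched through the CDS coordinate maps) are masked; the surviving
    codons are partitioned into maximal contiguous segments, each analysed
    separately and once more pooled ("combined").  Segments shorter than
    *min_segment_codons* are too small for a meaningful dN/dS and are
    dropped (between adjacent tracts the survivors are typically the
    pair's own difference positions, which carry no usable signal); if no
    analysable segment remains the pair is reported whole-gene converted.
    """
    gi, gj = aln.ids[i], aln.ids[j]
    sig = [f for f in fragments
           if {f.gene_i, f.gene_j} == {gi, gj} and f.global_p < p_threshold]
    s, n, sd, nd, cols = _pair_arrays(aln, i, j)

    cm_i = aln.colmap(i)
    coords_i = cds_coords_i or list(range(1, int(cm_i.max()) + 2))
    cm_j = aln.colmap(j)
    coords_j = cds_coords_j or list(range(1, int(cm_j.max()) + 2))

    def codon_masked(c: int) -> bool:
        for f in sig:
            lo_i, hi_i = (f.begin_i, f.end_i) if f.gene_i == gi else (f.begin_j, f.end_j)
            lo_j, hi_j = (f.begin_j, f.end_j) if f.gene_i == gi else (f.begin_i, f.end_i)
            for nt in range(3 * c, 3 * c + 3):
                oi, oj = cm_i[nt], cm_j[nt]
                if oi >= 0 and lo_i <= coords_i[oi] <= hi_i:
                    return True
                if oj >= 0 and lo_j <= coords_j[oj] <= hi_j:
                    return True
        return False

    keep = np.array([not codon_masked(int(c)) for c in cols])
    masked = int((~keep).sum())
    if not keep.any():
        logger.info("pair %s/%s: entire gene converted, no unconverted codons", gi, gj)
        return MosaicReport(gi, gj, True, [], masked, len(cols))

    kept_idx = np.nonzero(keep)[0]
    # contiguous runs in codon-column space
    breaks = np.nonzero(np.diff(cols[kept_idx]) > 1)[0]
    segments_idx = [idx for idx in np.split(kept_idx, breaks + 1)
                    if len(idx) >= min_segment_codons]
    if not segments_idx:
        logger.info("pair %s/%s: no unconverted segment of >= %d codons; "
                    "treating as whole-gene converted", gi, gj, min_segment_codons)
        return MosaicReport(gi, gj, True, [], masked, len(cols))
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(segments_idx) + 1)]

    def seg_sizes(idx: np.ndarray) -> tuple[int, int]:
        nts = np.concatenate([np.arange(3 * c, 3 * c + 3) for c in cols[idx]])
        return int((cm_i[nts] >= 0).sum()), int((cm_j[nts] >= 0).sum())

    from .dnds import SaturationError

    segs: list[UnconvertedSegment] = []
    for k, idx in enumerate(segments_idx):
        try:
            res = _dnds_from_arrays(aln.ids, i, j, s[idx], n[idx], sd[idx], nd[idx],
                                    B, children[k] if seed is not None else None, False)
        except SaturationError:
            logger.warning("pair %s/%s segment %d saturated; skipped", gi, gj, k + 1)
            continue
        bp_i, bp_j = seg_sizes(idx)
        segs.append(UnconvertedSegment(gi, gj, f"fragment{k + 1}",
                                       (int(cols[idx[0]]), int(cols[idx[-1]])),
                                       bp_i, bp_j, res.counts, res))
    if len(segs) > 1:
        pooled = np.concatenate(segments_idx)
        try:
            res = _dnds_from_arrays(aln.ids, i, j, s[pooled], n[pooled], sd[pooled],
                                    nd[pooled], B, children[-1] if seed is not None else None,
                                    False)
            bp_i, bp_j = seg_sizes(pooled)
            segs.append(UnconvertedSegment(gi, gj, "combined",
                                           (int(cols[pooled[0]]), int(cols[pooled[-1]])),
                                           bp_i, bp_j, res.counts, res, combined=True))
        except SaturationError:
            logger.warning("pair %s/%s combined segment saturated; skipped", gi, gj)
    return MosaicReport(gi, gj, not segs, segs, masked, len(cols))
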