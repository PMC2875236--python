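"""End-to-end orchestration: identity -> homology -> conversion -> dN/dS ->
mosaic -> verdict -> tree, with one master seed and table outputs that
mirror the layouts molecular-evolution papers print."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import align, geneconv, inference, njtree, seqs
from .dnds import DnDsResult, SaturationError, dnds as pair_dnds

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: str
    regions: str | None = None
    outdir: str = "concerta_out"
    prealigned: bool = False
    do_identity: bool = True
    do_homology: bool = True
    do_geneconv: bool = True
    do_dnds: bool = True
    do_mosaic: bool = True
    do_tree: bool = True
    mismatch_penalty: float = 0.0   # g of the conversion scan; >0 allows mismatches in tracts
    n_perm: int = 1000
    boot: int = 1000
    tree_boot: int = 100
    p_mask: float = 0.05
    report_threshold: float = 0.05
    ratio_threshold: float = 0.5
    saturation_band: tuple[float, float] = (0.4, 0.7)
    promoter_window: int = 1100
    identity_floor: float = 50.0
    seed: int = 0


def _child_seeds(master: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(master).spawn(n)]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all enabled stages; returns (and writes) a JSON-able summary.

    Identical config and seed give byte-identical outputs.  Stage failures
    abort with a stage-named error; outputs written so far are retained.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(cfg), indent=2, default=list) + "\n")
    seed_geneconv, seed_dnds, seed_mosaic, seed_tree = _child_seeds(cfg.seed, 4)
    summary: dict = {"schema_version": 1, "seed": cfg.seed}

    records = seqs.read_fasta(cfg.fasta)
    if len(records) < 2:
        raise ValueError("pipeline: need >=2 sequences")
    if cfg.regions:
        seqs.read_regions(cfg.regions, records)
    annotated = all(r.regions for r in records)

    # -- alignments ----------------------------------------------------------
    try:
        fam_aln = (align.NucAlignment.from_prealigned(records) if cfg.prealigned
                   else align.align_family(records))
    except Exception as exc:
        raise RuntimeError(f"stage alignment: {exc}") from exc
    cds_list, cds_ids, cds_coords = [], [], {}
    if annotated:
        for r in records:
            cds_list.append(r.cds())
            cds_ids.append(r.id)
            cds_coords[r.id] = r.cds_coords()
        caln = align.align_codons(cds_list, cds_ids)
    else:
        caln = None
        logger.warning("no region annotations: coding-sequence stages skipped")

    # -- identity ------------------------------------------------------------
    if cfg.do_identity:
        region_names = (["cds"] + sorted({rg.name for rg in records[0].regions}
                                         - {"cds"})) if annotated else []
        tables = {}
        for region in region_names:
            ids = [r.id for r in records]
            mat = pd.DataFrame(np.nan, index=ids, columns=ids)
            for a, b in combinations(records, 2):
                try:
                    rep = align.percent_identity(a, b, region)
                except Exception as exc:
                    raise RuntimeError(f"stage identity ({region}): {exc}") from exc
                mat.loc[a.id, b.id] = mat.loc[b.id, a.id] = round(rep.identity, 1)
            tables[region] = mat
            mat.to_csv(out / f"identity_{region}.tsv", sep="\t", na_rep="-")
        summary["identity"] = {k: v.to_dict() for k, v in tables.items()}

    # -- homology ------------------------------------------------------------
    homology = None
    if cfg.do_homology:
        try:
            homology = inference.assign_homology(
                records, promoter_window_bp=cfg.promoter_window,
                identity_floor=cfg.identity_floor)
            summary["homology"] = {
                "ortholog_pairs": homology.ortholog_pairs,
                "paralog_sets": homology.paralog_sets,
                "promoter_identity": {f"{a}~{b}": round(v, 1)
                                      for (a, b), v in homology.identity.items()},
            }
            pd.DataFrame([{"gene_a": a, "gene_b": b,
                           "promoter_identity": round(homology.promoter_identity(a, b), 1)}
                          for a, b in homology.ortholog_pairs]
                         ).to_csv(out / "homology.tsv", sep="\t", index=False)
        except ValueError as exc:
            logger.warning("stage homology skipped: %s", exc)
            summary["homology"] = {"skipped": str(exc)}

    # -- gene conversion -----------------------------------------------------
    fragments: list[geneconv.ConversionFragment] = []
    if cfg.do_geneconv:
        try:
            fragments = geneconv.permutation_test(
                fam_aln, n_perm=cfg.n_perm, seed=seed_geneconv,
                g=cfg.mismatch_penalty, report_threshold=cfg.report_threshold)
        except geneconv.NoTestSignal as exc:
            logger.warning("stage geneconv: %s", exc)
        geneconv.report_table(fragments, records).to_csv(
            out / "geneconv.tsv", sep="\t", index=False)
        summary["conversion_fragments"] = [asdict(f) for f in fragments]

    # -- Ps/Pn and dN/dS -----------------------------------------------------
    pair_results: dict[tuple[str, str], DnDsResult] = {}
    if cfg.do_dnds and caln is not None:
        rows3, rows4 = [], []
        pair_seeds = _child_seeds(seed_dnds, len(cds_ids) * (len(cds_ids) - 1) // 2)
        for k, (i, j) in enumerate(combinations(range(len(cds_ids)), 2)):
            try:
                res = pair_dnds(caln, i, j, B=cfg.boot, seed=pair_seeds[k])
            except SaturationError as exc:
                logger.warning("dnds %s/%s: %s", cds_ids[i], cds_ids[j], exc)
                continue
            pair_results[(cds_ids[i], cds_ids[j])] = res
            c = res.counts
            rows3.append({"Gene1": c.gene_i, "Gene2": c.gene_j,
                          "Ps(SE)": f"{c.Ps:.4f}({c.se_Ps:.4f})",
                          "Pn(SE)": f"{c.Pn:.4f}({c.se_Pn:.4f})"})
            rows4.append({"Gene1": c.gene_i, "Gene2": c.gene_j,
                          "dN/dS": f"{res.omega:.4f}",
                          "p-value (Z-test)": f"{res.p_value:.4f}"})
        pd.DataFrame(rows3).to_csv(out / "ps_pn.tsv", sep="\t", index=False)
        pd.DataFrame(rows4).to_csv(out / "dnds.tsv", sep="\t", index=False)
        summary["dnds"] = {f"{a}~{b}": {"Ps": r.counts.Ps, "Pn": r.counts.Pn,
                                        "dS": r.dS, "dN": r.dN, "omega": r.omega,
                                        "Z": r.Z, "p": r.p_value}
                           for (a, b), r in pair_results.items()}

    # -- mosaic analysis of unconverted regions ------------------------------
    if cfg.do_mosaic and caln is not None and fragments:
        mosaic_rows = []
        summary_mosaic = {}
        within = [(a, b) for a, b in combinations(cds_ids, 2)
                  if records[[r.id for r in records].index(a)].species
                  == records[[r.id for r in records].index(b)].species]
        mseeds = _child_seeds(seed_mosaic, max(len(within), 1))
        for k, (a, b) in enumerate(within):
            if not any({f.gene_i, f.gene_j} == {a, b} and f.global_p < cfg.p_mask
                       for f in fragments):
                continue
            rep = inference.mosaic_dnds(
                caln, cds_ids.index(a), cds_ids.index(b), fragments,
                cds_coords_i=cds_coords[a], cds_coords_j=cds_coords[b],
                p_threshold=cfg.p_mask, B=cfg.boot, seed=mseeds[k])
            summary_mosaic[f"{a}~{b}"] = {
                "whole_gene_converted": rep.whole_gene_converted,
                "segments": [{"label": s.label, "size_bp": [s.size_bp_i, s.size_bp_j],
                              "Ps": s.counts.Ps, "dN": s.result.dN, "dS": s.result.dS,
                              "omega": s.result.omega, "p": s.result.p_value,
                              "combined": s.combined} for s in rep.segments]}
            for s in rep.segments:
                mosaic_rows.append({
                    "Gene1": a, "Gene2": b, "Fragment": s.label,
                    "Size of non-converted region [bp]": f"{s.size_bp_i}({s.size_bp_j})",
                    "Ps": f"{s.counts.Ps:.4f}", "dN": f"{s.result.dN:.4f}",
                    "dS": f"{s.result.dS:.4f}", "dN/dS": f"{s.result.omega:.4f}",
                    "p-value (Z-test)": f"{s.result.p_value:.4f}"
                                        + ("*" if s.result.p_value >= 0.05 else "")})
        pd.DataFrame(mosaic_rows).to_csv(out / "mosaic.tsv", sep="\t", index=False)
        summary["mosaic"] = summary_mosaic

    # -- verdicts ------------------------------------------------------------
    if homology is not None and pair_results:
        def ps_of(a: str, b: str) -> float | None:
            r = pair_results.get((a, b)) or pair_results.get((b, a))
            return r.counts.Ps if r else None

        verdicts = {}
        for sp, genes in homology.paralog_sets.items():
            for a, b in combinations(genes, 2):
                ps_par = ps_of(a, b)
                orth = {x: y for x, y in homology.ortholog_pairs}
                orth.update({y: x for x, y in homology.ortholog_pairs})
                ps_orth = [p for g in (a, b)
                           if g in orth and (p := ps_of(g, orth[g])) is not None]
                if ps_par is None or not ps_orth:
                    continue
                v = inference.classify_mode([ps_par], ps_orth,
                                            ratio_threshold=cfg.ratio_threshold,
                                            saturation_band=cfg.saturation_band)
                verdicts[f"{a}~{b}"] = asdict(v)
        summary["verdicts"] = verdicts

    # -- NJ tree -------------------------------------------------------------
    if cfg.do_tree and caln is not None:
        prots = [r.protein() for r in records]
        prot_rows = align.progressive_msa(prots, alphabet=align.PROT_ALPHABET,
                                          submat=align.PROT_MATRIX)
        tree = njtree.bootstrap_support([r.id for r in records], prot_rows,
                                        B=cfg.tree_boot, seed=seed_tree)
        njtree.write_newick(tree, out / "tree.nwk")
        summary["tree"] = njtree.to_newick(tree)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
    return summary
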