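"""End-to-end orchestration: scan -> containment -> coverage -> enrichment
-> chromatin association -> cross-species sharing, with a machine-readable
manifest. Reruns on identical inputs are byte-identical."""

from __future__ import annotations

import glob
import hashlib
import json
import os
import re
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from temotif import __version__, io as tio
from temotif.chromatin import (
    SummitRegionSet,
    accessible_motif_fractions,
    accessibility_fisher,
    bound_motif_fractions,
    build_summit_regions,
    fraction_frame,
    top_te_contributors,
)
from temotif.enrichment import (
    coverage_frame,
    coverage_table,
    enrichment_frame,
    filter_enriched,
    genes_with_te_motifs,
    motif_census,
    motif_te_enrichment,
)
from temotif.intervals import feature_partition, promoter_windows
from temotif.motifs import MotifHit, background_from_fasta, log_odds, scan_genome
from temotif.orthology import (
    OrthologMap,
    bound_shared,
    family_similarity,
    promoter_te_motif_genes,
    shared_ortholog_test,
)


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Thresholds default to the analysis' standard printed values; every one
    is overridable for sensitivity analyses.
    """

    bundle_dir: str
    out_dir: str
    promoter_bp: int = 2500
    scan_p: float = 1e-4
    pseudocount: float = 0.1
    enrich_min_te_bp: int = 20000
    enrich_min_fold: float = 20.0
    enrich_max_p: float = 1e-12
    atac_min_sites: int = 3000
    atac_min_pct: float = 10.0
    chip_min_regions: int = 500
    chip_min_pct: float = 5.0
    summit_flank: int = 50
    seed: int = 0


def _read_species(d: str):
    genome = tio.read_fasta(os.path.join(d, "genome.fa"))
    tes = tio.read_te_table(os.path.join(d, "tes.bed"))
    genes, operons = tio.read_gff_genes(os.path.join(d, "genes.gff"))
    sizes = {c: len(s) for c, s in genome.items()}
    bad = sorted(set(tes["chrom"]) - set(sizes))
    bad += sorted({g.span.chrom for g in genes} - set(sizes))
    if bad:
        raise ValueError(f"chromosome names not in genome: {bad}")
    return genome, sizes, tes, genes, operons


def _read_summit_files(bundle_dir: str, pattern: str) -> Dict[str, Dict[str, list]]:
    """Map label -> stage -> summit list from ``{pattern}_{stage}_summits.bed``."""
    out: Dict[str, Dict[str, list]] = {}
    rx = re.compile(rf"{pattern}_(.+)_summits\.bed$")
    for path in sorted(glob.glob(os.path.join(bundle_dir, f"{pattern}_*_summits.bed"))):
        m = rx.search(os.path.basename(path))
        if not m:
            continue
        key = m.group(1)
        if pattern == "chip":
            label, _, stage = key.rpartition("_")
        else:
            label, stage = "atac", key
        out.setdefault(label, {})[stage] = tio.read_summits(path)
    return out


def _scan_all(genome, pwms, bg, scan_p, pseudocount) -> List[MotifHit]:
    hits: List[MotifHit] = []
    for pwm in sorted(pwms, key=lambda p: p.motif_id):
        sm = log_odds(pwm, bg, pseudocount=pseudocount)
        hits.extend(scan_genome(genome, sm, p_threshold=scan_p))
    return hits


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute every stage on a bundle directory; returns the manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    bundle = config.bundle_dir
    genome, sizes, tes, genes, operons = _read_species(bundle)
    pwms = tio.read_cisbp_chen(os.path.join(bundle, "motifs.chen"))
    bg = background_from_fasta(genome)
    manifest: Dict[str, object] = {
        "version": __version__,
        "config": asdict(config),
        "background": [round(float(f), 6) for f in bg.freqs],
        "stages": {},
        "outputs": {},
    }
    outputs: Dict[str, str] = {}

    def emit(name: str, fname: str, writer) -> None:
        path = os.path.join(config.out_dir, fname)
        writer(path)
        outputs[name] = fname

    # stage 1: scan + TE containment
    hits = _scan_all(genome, pwms, bg, config.scan_p, config.pseudocount)
    records = motif_te_enrichment(hits, tes, sum(sizes.values()))  # annotates hits
    te_hits = [h for h in hits if h.te_type is not None]
    emit("hits", "hits.bed", lambda p: tio.write_hits_bed(hits, p))
    emit("te_hits", "te_hits.bed", lambda p: tio.write_hits_bed(te_hits, p))
    manifest["stages"]["scan"] = {"n_hits": len(hits), "n_te_hits": len(te_hits)}

    # stage 2: coverage partition
    te_set = tio.te_interval_set(tes)
    part = feature_partition(sizes, genes, operons, te_set, config.promoter_bp)
    cov = coverage_frame(coverage_table(part))
    emit("coverage", "coverage.tsv", lambda p: cov.to_csv(p, sep="\t", index=False))
    manifest["stages"]["coverage"] = {"n_classes": len(cov)}

    # stage 3: enrichment + filter cascade + gene lists
    passing = filter_enriched(
        records, config.enrich_min_te_bp, config.enrich_min_fold, config.enrich_max_p
    )
    enr = enrichment_frame(records)
    emit("enrichment", "enrichment.tsv", lambda p: enr.to_csv(p, sep="\t", index=False))
    fold_matrix = enr.pivot(index="motif_id", columns="te_type", values="fold")
    emit(
        "fold_matrix", "fold_matrix.tsv",
        lambda p: fold_matrix.to_csv(p, sep="\t"),
    )
    with_te, total, census_pct = motif_census(records)
    wins = promoter_windows(genes, None, config.promoter_bp, sizes, collapse_operons=False)
    enriched_motifs = {r.motif_id for r in passing}
    gene_sets, union = genes_with_te_motifs(
        wins, [h for h in te_hits if h.motif_id in enriched_motifs]
    )
    gene_rows = pd.DataFrame(
        [(m, g) for m in sorted(gene_sets) for g in sorted(gene_sets[m])],
        columns=["motif_id", "gene_id"],
    )
    emit("gene_lists", "enriched_promoter_genes.tsv",
         lambda p: gene_rows.to_csv(p, sep="\t", index=False))
    manifest["stages"]["enrichment"] = {
        "n_records": len(records),
        "n_passing": len(passing),
        "census_with_te": with_te,
        "census_total": total,
        "census_pct": round(census_pct, 1),
        "genes_with_enriched_te_motifs": len(union),
    }

    # stage 4: chromatin association
    atac_files = _read_summit_files(bundle, "atac")
    chip_files = _read_summit_files(bundle, "chip")
    frac_acc = []
    frac_bound = []
    fisher_rows = []
    if atac_files:
        atac = build_summit_regions(
            atac_files["atac"], sizes, config.summit_flank, label="atac"
        )
        frac_acc = accessible_motif_fractions(
            hits, atac, config.atac_min_sites, config.atac_min_pct
        )
        acc_df = fraction_frame(frac_acc)
        emit("accessible_fractions", "accessible_fractions.tsv",
             lambda p: acc_df.to_csv(p, sep="\t", index=False))
        chip_sets: Dict[str, SummitRegionSet] = {}
        for tf in sorted(chip_files):
            chip_sets[tf] = build_summit_regions(
                chip_files[tf], sizes, config.summit_flank, label=tf
            )
        hits_by_motif: Dict[str, List[MotifHit]] = {}
        motif_to_tf: Dict[str, str] = {}
        for h in hits:
            hits_by_motif.setdefault(h.motif_id, []).append(h)
            motif_to_tf[h.motif_id] = h.tf_name
        if chip_sets:
            frac_bound = bound_motif_fractions(
                hits_by_motif, chip_sets, motif_to_tf,
                config.chip_min_regions, config.chip_min_pct,
            )
            bound_df = fraction_frame(frac_bound)
            emit("bound_fractions", "bound_fractions.tsv",
                 lambda p: bound_df.to_csv(p, sep="\t", index=False))
            for motif_id in sorted(hits_by_motif):
                tf = motif_to_tf[motif_id]
                if tf not in chip_sets:
                    continue
                fr = accessibility_fisher(chip_sets[tf], atac, hits_by_motif[motif_id], tf)
                (a, b), (c, d) = fr.table
                fisher_rows.append(
                    dict(motif_id=motif_id, tf_name=tf, te_acc=a, te_noacc=b,
                         note_acc=c, note_noacc=d, pvalue=fr.pvalue,
                         degenerate=fr.degenerate)
                )
            fisher_df = pd.DataFrame(fisher_rows)
            emit("fisher", "accessibility_fisher.tsv",
                 lambda p: fisher_df.to_csv(p, sep="\t", index=False))
        manifest["stages"]["chromatin"] = {
            "n_accessible_rows": len(frac_acc),
            "n_bound_rows": len(frac_bound),
            "n_fisher_rows": len(fisher_rows),
        }

    # stage 5: cross-species sharing
    b_dir = os.path.join(bundle, "species_b")
    if os.path.isdir(b_dir):
        genome_b, sizes_b, tes_b, genes_b, _op_b = _read_species(b_dir)
        bg_b = background_from_fasta(genome_b)
        hits_b = _scan_all(genome_b, pwms, bg_b, config.scan_p, config.pseudocount)
        motif_te_enrichment(hits_b, tes_b, sum(sizes_b.values()))  # annotate
        te_hits_b = [h for h in hits_b if h.te_type is not None]
        wins_b = promoter_windows(genes_b, None, config.promoter_bp, sizes_b,
                                  collapse_operons=False)
        omap = OrthologMap(
            tio.read_ortholog_map(os.path.join(bundle, "orthologs.tsv"))
        )
        sets_a, hits_by_gene_a = promoter_te_motif_genes(wins, te_hits)
        sets_b, _hits_by_gene_b = promoter_te_motif_genes(wins_b, te_hits_b)
        chip_sets = {}
        for tf in sorted(chip_files):
            chip_sets[tf] = build_summit_regions(
                chip_files[tf], sizes, config.summit_flank, label=tf
            )
        tf_of = {p.motif_id: p.tf_name for p in pwms}
        share_rows = []
        for motif_id in sorted(set(sets_a) | set(sets_b)):
            res = shared_ortholog_test(
                sets_a.get(motif_id, set()), sets_b.get(motif_id, set()),
                omap, motif_id,
            )
            fam_a = {
                g: {h.te_family for h in hs if h.te_family}
                for g, hs in hits_by_gene_a.get(motif_id, {}).items()
            }
            fam_b = {
                g: {h.te_family for h in hs if h.te_family}
                for g, hs in _hits_by_gene_b.get(motif_id, {}).items()
            }
            family_similarity(res, fam_a, fam_b)
            bound_shared(res, hits_by_gene_a.get(motif_id, {}),
                         chip_sets.get(tf_of.get(motif_id, "")))
            share_rows.append(
                dict(motif_id=motif_id, N=res.N, K=res.K, n=res.n, k=res.k,
                     pvalue=res.pvalue, stars=res.stars,
                     family_similar=res.family_similar,
                     family_different=res.family_different,
                     bound_shared=res.bound_shared)
            )
        share_df = pd.DataFrame(share_rows)
        emit("ortholog_sharing", "ortholog_sharing.tsv",
             lambda p: share_df.to_csv(p, sep="\t", index=False))
        manifest["stages"]["orthology"] = {"n_motifs": len(share_rows)}

    manifest["outputs"] = {
        name: {"file": fname, "sha256": _sha256(os.path.join(config.out_dir, fname))}
        for name, fname in sorted(outputs.items())
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
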