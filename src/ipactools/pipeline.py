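"""End-to-end orchestration: annotate -> cluster -> categorize -> distances ->
null/FDR -> classify -> signals -> UTR stats -> orphan clustering -> reports.

Every intermediate is a flat TSV/BED readable on its own; a manifest records
the config, seed and content hashes so reruns are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import __version__
from .classification import (
    ClassificationConfig,
    IPACClass,
    a_ipac_antisense_breakdown,
    class_summary,
    classify_ipacs,
    write_records_tsv,
)
from .downstream_inference import (
    cluster_so,
    expression_correlation,
    inter_pac_distance,
    read_evidence_bed,
    verify_clusters,
    write_clusters_tsv,
)
from .errors import IpacError
from .genome_model import load_annotation, load_chrom_sizes
from .neighborhood import (
    neighbor_contexts,
    rel_position_histogram,
    write_contexts_tsv,
    write_histogram_tsv,
)
from .null_model import (
    fdr_curve,
    sample_background,
    select_cutoff,
    write_background_bed,
    write_curve_tsv,
)
from .pac_annotation import (
    AnnotatedPAC,
    RegionCategory,
    annotate_pacs,
    category_summary,
    select_ipacs,
    write_annotated_tsv,
)
from .pat_processing import (
    PAC,
    CleavageSite,
    cluster_sites,
    filter_min_support,
    read_sites_bed,
    write_pacs_tsv,
)
from .signal_analysis import (
    composition_profile,
    pas_class_counts,
    write_profile_tsv,
)
from .utr_extension import assign_se_to_genes, mean_extension, utr_length_stats


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the published procedure."""

    gff3: str = ""
    tags_bed: str = ""
    fasta: Optional[str] = None
    chrom_sizes: Optional[str] = None
    outdir: str = "ipac_run"
    extension_nt: int = 50
    cluster_max_gap: int = 24
    min_tags: int = 3
    fdr_step: int = 20
    fdr_max_distance: int = 2000
    fdr_alpha: float = 0.1
    fdr_denominator: str = "all"
    se_cutoff_nt: Optional[int] = 700  # None -> derive from the FDR curve
    antisense_proximal_cutoff_nt: int = 200
    sense_promoter_cutoff_nt: int = 700
    sense_anchor: str = "stop_codon"
    priming_window_nt: int = 20
    priming_a_frac: float = 0.50
    priming_ag_frac: float = 0.60
    so_near_gene_exclusion_nt: int = 2000
    so_linkage_nt: Optional[int] = None  # None -> derive from UTR stats
    profile_up: int = 300
    profile_down: int = 100
    pas_window: tuple[int, int] = (-50, -1)
    match_window_nt: int = 50
    n_background: Optional[int] = None  # None -> number of IPACs
    evidence: list[dict] = field(default_factory=list)  # name/path/window/anchor_mode
    seed: int = 1


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed so adding stages never perturbs earlier ones."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_genome(cfg: PipelineConfig):
    if cfg.fasta is None:
        return None
    from pyfaidx import Fasta

    return Fasta(cfg.fasta, sequence_always_upper=True)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    os.makedirs(cfg.outdir, exist_ok=True)
    out = lambda name: os.path.join(cfg.outdir, name)  # noqa: E731
    summary: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise IpacError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # annotate ----------------------------------------------------------
    sizes = load_chrom_sizes(cfg.chrom_sizes) if cfg.chrom_sizes else None
    ann = stage("annotate")(
        lambda: load_annotation(cfg.gff3, cfg.extension_nt, chrom_lengths=sizes)
    )
    ann.intergenic_to_bed6(out("intergenic.bed"))

    # cluster -----------------------------------------------------------
    def _cluster():
        sites = read_sites_bed(cfg.tags_bed)
        pacs = filter_min_support(
            cluster_sites(sites, cfg.cluster_max_gap), cfg.min_tags
        )
        return pacs

    pacs = stage("cluster")(_cluster)
    write_pacs_tsv(pacs, out("pacs.tsv"))
    summary["n_pacs"] = len(pacs)

    # categorize --------------------------------------------------------
    annotated = stage("categorize")(lambda: annotate_pacs(pacs, ann))
    write_annotated_tsv(annotated, out("pacs_annotated.tsv"))
    category_summary(annotated).to_csv(out("category_summary.tsv"), sep="\t", index=False)
    ipacs = select_ipacs(annotated)
    summary["n_ipacs"] = len(ipacs)

    # distances ---------------------------------------------------------
    contexts = stage("distances")(
        lambda: neighbor_contexts(ipacs, ann, cfg.sense_anchor)
    )
    write_contexts_tsv(ipacs, contexts, out("neighbor_contexts.tsv"))
    edges, counts, frac = rel_position_histogram(contexts)
    write_histogram_tsv(edges, counts, out("rel_pos_histogram.tsv"))
    summary["frac_rel_pos_first_decile"] = frac

    # null model --------------------------------------------------------
    def _null():
        n_bg = cfg.n_background if cfg.n_background is not None else max(len(ipacs), 1)
        bg = sample_background(ann, n_bg, stage_seed(cfg.seed, "background"))
        bg_ipacs = [
            AnnotatedPAC(
                PAC(b.chrom, b.strand, b.pos, b.pos, [CleavageSite(b.chrom, b.pos, b.strand, 1)]),
                RegionCategory.INTERGENIC,
            )
            for b in bg
        ]
        bg_ctx = neighbor_contexts(bg_ipacs, ann, cfg.sense_anchor)
        ip_d = [c.d5s for c in contexts if c.d5s is not None]
        bg_d = [c.d5s for c in bg_ctx if c.d5s is not None]
        curve = fdr_curve(
            ip_d, bg_d, cfg.fdr_step, cfg.fdr_max_distance, cfg.fdr_denominator
        )
        return bg, curve

    bg, curve = stage("null")(_null)
    write_background_bed(bg, out("background.bed"))
    write_curve_tsv(curve, out("fdr_curve.tsv"))
    derived_cutoff = select_cutoff(curve, cfg.fdr_alpha)
    summary["derived_se_cutoff_nt"] = derived_cutoff
    se_cutoff = cfg.se_cutoff_nt if cfg.se_cutoff_nt is not None else derived_cutoff

    # classify ----------------------------------------------------------
    genome = _load_genome(cfg)
    ccfg = ClassificationConfig(
        se_cutoff_nt=se_cutoff,
        antisense_proximal_cutoff_nt=cfg.antisense_proximal_cutoff_nt,
        sense_promoter_cutoff_nt=cfg.sense_promoter_cutoff_nt,
        sense_anchor=cfg.sense_anchor,
        priming_window_nt=cfg.priming_window_nt,
        priming_a_frac=cfg.priming_a_frac,
        priming_ag_frac=cfg.priming_ag_frac,
    )
    if genome is None and any(i.antisense_gene for i in ipacs):
        raise IpacError(
            "stage 'classify' requires a FASTA (priming filter); pass fasta=..."
        )
    records = stage("classify")(lambda: classify_ipacs(ipacs, contexts, ccfg, genome))
    write_records_tsv(records, out("ipac_classes.tsv"))
    class_summary(records).to_csv(out("class_summary.tsv"), sep="\t", index=False)
    a_ipac_antisense_breakdown(records, ann).to_csv(
        out("a_ipac_breakdown.tsv"), sep="\t", index=False
    )
    summary["class_counts"] = {
        cls.value: sum(1 for r in records if r.label is cls) for cls in IPACClass
    }

    # signals -----------------------------------------------------------
    if genome is not None:
        for cls in (IPACClass.SE, IPACClass.A, IPACClass.SO):
            sites = [
                (r.ipac.pac.chrom, r.ipac.pac.dominant_site, r.ipac.pac.strand)
                for r in records
                if r.label is cls
            ]
            if not sites:
                continue
            prof = composition_profile(sites, genome, cfg.profile_up, cfg.profile_down)
            write_profile_tsv(prof, out(f"profile_{cls.value}.tsv"))
            summary.setdefault("pas_counts", {})[cls.value] = pas_class_counts(
                sites, genome, cfg.pas_window
            )

    # UTR stats ---------------------------------------------------------
    def _utr():
        se_map = assign_se_to_genes(
            [r for r in records if r.label is IPACClass.SE], ann
        )
        stats = utr_length_stats(annotated, se_map, ann)
        return se_map, stats

    se_map, ustats = stage("utr")(_utr)
    ustats.rank_medians.to_csv(out("utr_rank_medians.tsv"), sep="\t", index=False)
    summary["utr"] = {
        "median_before": ustats.median_before,
        "median_after": ustats.median_after,
        "mean_before": ustats.mean_before,
        "mean_after": ustats.mean_after,
        "wilcoxon_p": ustats.wilcoxon_p,
        "mean_extension_nt": mean_extension(se_map, ann, annotated),
        "n_newly_terminated_genes": len(ustats.newly_terminated_genes),
    }

    # orphan clustering + evidence -------------------------------------
    def _so():
        if cfg.so_linkage_nt is not None:
            linkage = cfg.so_linkage_nt
        elif ustats.after.size and se_map:
            n_genes = len({r.gene_id for r in ustats.records if r.phase == "after"})
            mean_pacs = ustats.after.size / max(n_genes, 1)
            linkage = inter_pac_distance(float(np.mean(ustats.after)), mean_pacs)
        else:
            linkage = 431
        so_records = [r for r in records if r.label is IPACClass.SO]
        clusters, excluded = cluster_so(
            so_records, cfg.so_near_gene_exclusion_nt, linkage
        )
        return clusters, excluded, linkage

    clusters, n_excluded, linkage = stage("so")(_so)
    summary["so"] = {
        "linkage_nt": linkage,
        "n_clusters": len(clusters),
        "n_excluded_near_genes": n_excluded,
    }
    for ev_spec in cfg.evidence:
        ev = read_evidence_bed(
            ev_spec["path"],
            ev_spec["name"],
            int(ev_spec.get("window", 0)),
            ev_spec.get("anchor_mode", "interval"),
        )
        summary["so"][f"verified_{ev.name}"] = verify_clusters(clusters, ev)
    write_clusters_tsv(clusters, out("so_clusters.tsv"))

    # A-IPAC expression correlation ------------------------------------
    def _correlate():
        gene_tags: dict[str, int] = {}
        for a in annotated:
            if a.host_gene:
                gene_tags[a.host_gene] = gene_tags.get(a.host_gene, 0) + a.pac.total_tags
        xs, ys = [], []
        for r in records:
            if r.label is IPACClass.A and r.ipac.antisense_gene in gene_tags:
                xs.append(r.ipac.pac.total_tags)
                ys.append(gene_tags[r.ipac.antisense_gene])
        if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
            r_, p_ = expression_correlation(xs, ys)
            return {"n": len(xs), "pearson_r": r_, "p_value": p_}
        return {"n": len(xs), "pearson_r": None, "p_value": None}

    summary["a_ipac_expression"] = stage("correlate")(_correlate)

    # manifest ----------------------------------------------------------
    cfg_dict = dataclasses.asdict(cfg)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "summary": summary,
        "outputs": {},
    }
    for name in sorted(os.listdir(cfg.outdir)):
        p = os.path.join(cfg.outdir, name)
        if os.path.isfile(p) and name != "manifest.json":
            manifest["outputs"][name] = _sha256(p)
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
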