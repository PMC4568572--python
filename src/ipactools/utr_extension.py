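"""Recruit extension-class IPACs as 3'-UTR PACs and compare UTR lengths.

"Before" lengths use the annotated-region 3'-UTR PACs only; "after" adds the
recruited SE-IPACs.  Lengths are stop-codon-to-dominant-site distances; the
default length vectors are pooled per-PAC (a per-gene distal mode exists for
the alternative reading), and rank-wise medians are computed within genes
having exactly k PACs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import IPACClass, IPACRecord
from .genome_model import ExtendedAnnotation
from .pac_annotation import AnnotatedPAC, RegionCategory


@dataclass
class UTRLengthRecord:
    gene_id: str
    pac_rank: int
    utr_len_nt: int
    phase: str  # before | after
    source: str  # UTR3_PAC | SE_IPAC


def _utr_length(gene, dominant_site: int) -> Optional[int]:
    """Stop-codon cut to cleavage junction, transcription-oriented."""
    cut = gene.stop_codon_cut
    if cut is None:
        return None
    d = dominant_site - cut if gene.strand == "+" else cut - dominant_site
    return d if d >= 0 else None


def assign_se_to_genes(
    se_records: Sequence[IPACRecord], ann: ExtendedAnnotation
) -> dict[str, list[IPACRecord]]:
    """Attach each SE-IPAC to its 5' sense gene."""
    out: dict[str, list[IPACRecord]] = {}
    for r in se_records:
        if r.label is not IPACClass.SE:
            continue
        gid = r.context.gene5s
        assert gid is not None, f"{r.pac_id}: SE record without an upstream sense gene"
        out.setdefault(gid, []).append(r)
    return out


def _gene_pac_lengths(
    utr3_pacs: Sequence[AnnotatedPAC],
    se_map: dict[str, list[IPACRecord]],
    ann: ExtendedAnnotation,
) -> tuple[dict[str, list[tuple[int, str]]], dict[str, list[tuple[int, str]]], int]:
    """Per-gene (length, source) lists before/after; plus excluded-gene count."""
    before: dict[str, list[tuple[int, str]]] = {}
    excluded = 0
    for a in utr3_pacs:
        if a.category is not RegionCategory.UTR3 or a.host_gene is None:
            continue
        gene = ann.genes[a.host_gene]
        ln = _utr_length(gene, a.pac.dominant_site)
        if ln is None:
            excluded += 1
            continue
        before.setdefault(a.host_gene, []).append((ln, "UTR3_PAC"))
    after: dict[str, list[tuple[int, str]]] = {g: list(v) for g, v in before.items()}
    for gid, recs in se_map.items():
        gene = ann.genes[gid]
        for r in recs:
            ln = _utr_length(gene, r.ipac.pac.dominant_site)
            if ln is None:
                excluded += 1
                continue
            after.setdefault(gid, []).append((ln, "SE_IPAC"))
    return before, after, excluded


@dataclass
class UTRLengthStats:
    records: list[UTRLengthRecord]
    before: np.ndarray
    after: np.ndarray
    median_before: float
    median_after: float
    mean_before: float
    mean_after: float
    rank_medians: pd.DataFrame  # phase, n_pacs, rank, median_len
    wilcoxon_stat: float
    wilcoxon_p: float
    n_genes_excluded: int
    newly_terminated_genes: list[str]  # genes gaining their first PAC


def utr_length_stats(
    utr3_pacs: Sequence[AnnotatedPAC],
    se_map: dict[str, list[IPACRecord]],
    ann: ExtendedAnnotation,
    max_rank: int = 3,
    mode: str = "pooled",
) -> UTRLengthStats:
    """Before/after 3'-UTR length vectors with a rank-sum comparison.

    ``mode='pooled'`` compares all per-PAC lengths; ``mode='distal'``
    compares one (distal) length per gene.
    """
    before_map, after_map, excluded = _gene_pac_lengths(utr3_pacs, se_map, ann)

    records: list[UTRLengthRecord] = []
    rank_rows = []
    vectors = {}
    for phase, mapping in (("before", before_map), ("after", after_map)):
        pooled = []
        for gid, entries in mapping.items():
            entries = sorted(entries)
            for rank, (ln, source) in enumerate(entries, 1):
                records.append(UTRLengthRecord(gid, rank, ln, phase, source))
            if mode == "distal":
                pooled.append(entries[-1][0])
            else:
                pooled.extend(ln for ln, _ in entries)
        vectors[phase] = np.array(pooled, dtype=float)
        for k in range(1, max_rank + 1):
            genes_k = [
                sorted(v) for v in mapping.values() if len(v) == k
            ]
            for rank in range(1, k + 1):
                vals = [g[rank - 1][0] for g in genes_k]
                rank_rows.append(
                    {
                        "phase": phase,
                        "n_pacs": k,
                        "rank": rank,
                        "median_len": float(np.median(vals)) if vals else float("nan"),
                        "n_genes": len(genes_k),
                    }
                )

    bvec, avec = vectors["before"], vectors["after"]
    if bvec.size and avec.size:
        stat, p = stats.ranksums(avec, bvec)
    else:
        stat, p = float("nan"), float("nan")
    newly = sorted(set(after_map) - set(before_map))
    return UTRLengthStats(
        records=records,
        before=bvec,
        after=avec,
        median_before=float(np.median(bvec)) if bvec.size else float("nan"),
        median_after=float(np.median(avec)) if avec.size else float("nan"),
        mean_before=float(np.mean(bvec)) if bvec.size else float("nan"),
        mean_after=float(np.mean(avec)) if avec.size else float("nan"),
        rank_medians=pd.DataFrame(rank_rows),
        wilcoxon_stat=float(stat),
        wilcoxon_p=float(p),
        n_genes_excluded=excluded,
        newly_terminated_genes=newly,
    )


def mean_extension(
    se_map: dict[str, list[IPACRecord]],
    ann: ExtendedAnnotation,
    utr3_pacs: Sequence[AnnotatedPAC] = (),
) -> Optional[float]:
    """Mean nt gained beyond each extended gene's previous distal 3' end.

    The baseline is the gene's distal observed 3'-UTR PAC when one exists,
    else the annotated (pre-extension) transcript end.  Genes whose SE sites
    are all proximal to the baseline contribute 0.  None for an empty map.
    """
    if not se_map:
        return None
    distal_before: dict[str, int] = {}
    for a in utr3_pacs:
        if a.category is not RegionCategory.UTR3 or a.host_gene is None:
            continue
        gene = ann.genes[a.host_gene]
        ln = _utr_length(gene, a.pac.dominant_site)
        if ln is not None:
            distal_before[a.host_gene] = max(distal_before.get(a.host_gene, 0), ln)
    extensions = []
    for gid, recs in se_map.items():
        gene = ann.genes[gid]
        lens = [
            ln
            for r in recs
            if (ln := _utr_length(gene, r.ipac.pac.dominant_site)) is not None
        ]
        if not lens:
            continue
        if gid in distal_before:
            baseline = distal_before[gid]
        else:
            cut = gene.stop_codon_cut
            baseline = (
                abs(gene.cut3 - cut) if cut is not None else 0
            )  # annotated 3' end, pre-extension
        extensions.append(max(max(lens) - baseline, 0))
    return float(np.mean(extensions)) if extensions else None


def write_length_records_tsv(records: Sequence[UTRLengthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tpac_rank\tutr_len_nt\tphase\tsource\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.pac_rank}\t{r.utr_len_nt}\t{r.phase}\t{r.source}\n")


def write_summary_tsv(s: UTRLengthStats, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k in (
            "median_before",
            "median_after",
            "mean_before",
            "mean_after",
            "wilcoxon_stat",
            "wilcoxon_p",
            "n_genes_excluded",
        ):
            fh.write(f"{k}\t{getattr(s, k)}\n")
        fh.write(f"n_newly_terminated_genes\t{len(s.newly_terminated_genes)}\n")
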