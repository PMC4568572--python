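"""Assign each PAC to exactly one genomic category and extract the intergenic set.

The category is decided from the PAC's dominant cleavage site against
same-strand features of the extended annotation.  Isoform disagreement at
that position yields AMB; no same-strand feature overlap yields INTERGENIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .errors import IpacError
from .genome_model import ExtendedAnnotation, GeneModel, Isoform
from .pat_processing import PAC


class RegionCategory(str, Enum):
    UTR3 = "UTR3"
    INTERGENIC = "INTERGENIC"
    CDS = "CDS"
    INTRON = "INTRON"
    UTR5 = "UTR5"
    EXON = "EXON"
    PSEUDOGENIC_EXON = "PSEUDOGENIC_EXON"
    AMB = "AMB"


# within-gene precedence when a position overlaps features of several genes
_PRECEDENCE = [
    RegionCategory.UTR3,
    RegionCategory.CDS,
    RegionCategory.INTRON,
    RegionCategory.UTR5,
    RegionCategory.EXON,
    RegionCategory.PSEUDOGENIC_EXON,
]


@dataclass
class AnnotatedPAC:
    pac: PAC
    category: RegionCategory
    host_gene: Optional[str] = None
    antisense_gene: Optional[str] = None


def representative_base(pac: PAC) -> int:
    """Base index of the last transcribed nucleotide implied by the dominant
    cleavage junction (the base 5' of the cut in transcription direction)."""
    return pac.dominant_site - 1 if pac.strand == "+" else pac.dominant_site


def _isoform_category(
    iso: Isoform, gene: GeneModel, base: int, ext_end_cut: int
) -> Optional[RegionCategory]:
    """Category of *base* within one isoform, or None if outside it.

    The 3'-UTR category covers the annotated 3'-UTR plus the extension
    region beyond the annotated transcript end.
    """
    strand = gene.strand
    # extension region past the isoform's annotated end
    if strand == "+" and iso.end <= base < ext_end_cut:
        return RegionCategory.UTR3
    if strand == "-" and ext_end_cut <= base < iso.start:
        return RegionCategory.UTR3
    if not (iso.start <= base < iso.end):
        return None
    in_exon = any(s <= base < e for s, e in iso.exons)
    if not in_exon:
        return RegionCategory.INTRON
    if iso.cds:
        if any(s <= base < e for s, e in iso.cds):
            return RegionCategory.CDS
        cds_lo, cds_hi = iso.cds[0][0], iso.cds[-1][1]
        downstream = base >= cds_hi if strand == "+" else base < cds_lo
        return RegionCategory.UTR3 if downstream else RegionCategory.UTR5
    if gene.biotype == "pseudogene":
        return RegionCategory.PSEUDOGENIC_EXON
    return RegionCategory.EXON


def annotate_pac(pac: PAC, ann: ExtendedAnnotation) -> AnnotatedPAC:
    """Categorize one PAC against the extended annotation."""
    clen = ann.chrom_lengths.get(pac.chrom)
    if clen is None:
        raise IpacError(f"unknown chromosome {pac.chrom!r}")
    if not (0 <= pac.dominant_site <= clen):
        raise IpacError(
            f"{pac.pac_id}: dominant site {pac.dominant_site} outside {pac.chrom}"
        )
    base = representative_base(pac)
    hosts = ann.genes_overlapping_base(pac.chrom, pac.strand, base, extended=True)

    categories: set[RegionCategory] = set()
    host_id: Optional[str] = None
    for g in hosts:
        ext_cut = g.cut3_extended
        for iso in g.isoforms:
            cat = _isoform_category(iso, g, base, ext_cut)
            if cat is not None:
                categories.add(cat)
                host_id = host_id or g.gene_id
        # a base inside the extended span but outside all isoforms can only
        # be in the collapsed extension region, covered above per isoform
        if not categories and g.ext_start <= base < g.ext_end:
            categories.add(RegionCategory.UTR3)
            host_id = host_id or g.gene_id

    opposite = "-" if pac.strand == "+" else "+"
    as_base = pac.dominant_site if pac.strand == "+" else pac.dominant_site - 1
    as_hosts = ann.genes_overlapping_base(pac.chrom, opposite, as_base, extended=False)
    antisense_id = as_hosts[0].gene_id if as_hosts else None

    if not categories:
        return AnnotatedPAC(pac, RegionCategory.INTERGENIC, None, antisense_id)
    if len(categories) == 1:
        return AnnotatedPAC(pac, categories.pop(), host_id, antisense_id)
    return AnnotatedPAC(pac, RegionCategory.AMB, host_id, antisense_id)


def annotate_pacs(pacs: Sequence[PAC], ann: ExtendedAnnotation) -> list[AnnotatedPAC]:
    return [annotate_pac(p, ann) for p in pacs]


def select_ipacs(annotated: Sequence[AnnotatedPAC]) -> list[AnnotatedPAC]:
    """The INTERGENIC subset, order preserved."""
    return [a for a in annotated if a.category is RegionCategory.INTERGENIC]


def category_summary(annotated: Sequence[AnnotatedPAC]) -> pd.DataFrame:
    """Counts and percentages per category, for PACs and for tags."""
    if not annotated:
        return pd.DataFrame(
            columns=["category", "n_pac", "n_tags", "pct_pac", "pct_tags"]
        )
    rows = []
    total_pac = len(annotated)
    total_tags = sum(a.pac.total_tags for a in annotated)
    for cat in RegionCategory:
        subset = [a for a in annotated if a.category is cat]
        if not subset:
            continue
        n_tags = sum(a.pac.total_tags for a in subset)
        rows.append(
            {
                "category": cat.value,
                "n_pac": len(subset),
                "n_tags": n_tags,
                "pct_pac": 100.0 * len(subset) / total_pac,
                "pct_tags": 100.0 * n_tags / total_tags if total_tags else 0.0,
            }
        )
    return pd.DataFrame(rows)


def write_annotated_tsv(annotated: Sequence[AnnotatedPAC], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tpac_id\ttotal_tags\tstrand\tdominant_site"
            "\tcategory\thost_gene\tantisense_gene\n"
        )
        for a in annotated:
            p = a.pac
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.pac_id}\t{p.total_tags}\t{p.strand}"
                f"\t{p.dominant_site}\t{a.category.value}\t{a.host_gene or '.'}"
                f"\t{a.antisense_gene or '.'}\n"
            )
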