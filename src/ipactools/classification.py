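"""Ordered rule cascade labeling intergenic PACs.

Rules, applied in order to each IPAC:

1. within the extension cutoff of the 5' sense gene anchor -> SE
2. else, if an opposite-strand gene overlaps the dominant site: the
   internal-priming filter decides FILTERED_IP vs A
3. else, if near either antisense neighbor -> ANTISENSE_PROXIMAL
4. else, if near the 3' sense gene start -> SENSE_PROMOTER
5. else -> SO

This ordering makes the class counts additive over the IPAC set: A
candidates are drawn from non-SE IPACs and the proximal/orphan split applies
to the remainder.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .errors import PairingError
from .genome_model import ExtendedAnnotation
from .neighborhood import NeighborContext
from .pac_annotation import AnnotatedPAC, RegionCategory, _isoform_category
from .pat_processing import (
    PRIMING_A_FRAC,
    PRIMING_AG_FRAC,
    PRIMING_WINDOW_NT,
    internal_priming_filter,
)


class IPACClass(str, Enum):
    SE = "SE"
    A = "A"
    SO = "SO"
    SENSE_PROMOTER = "SENSE_PROMOTER"
    ANTISENSE_PROXIMAL = "ANTISENSE_PROXIMAL"
    FILTERED_IP = "FILTERED_IP"


@dataclass
class ClassificationConfig:
    se_cutoff_nt: int = 700
    antisense_proximal_cutoff_nt: int = 200
    sense_promoter_cutoff_nt: int = 700
    # optional variant: additionally exclude SO candidates near 3' antisense
    so_antisense_cutoff_nt: Optional[int] = None
    sense_anchor: str = "stop_codon"
    priming_window_nt: int = PRIMING_WINDOW_NT
    priming_a_frac: float = PRIMING_A_FRAC
    priming_ag_frac: float = PRIMING_AG_FRAC


@dataclass
class IPACRecord:
    ipac: AnnotatedPAC
    context: NeighborContext
    label: IPACClass
    rule: str = ""

    @property
    def pac_id(self) -> str:
        return self.ipac.pac.pac_id


def classify_ipacs(
    ipacs: Sequence[AnnotatedPAC],
    contexts: Sequence[NeighborContext],
    cfg: ClassificationConfig,
    genome,
) -> list[IPACRecord]:
    """Label every IPAC by the rule cascade; *genome* backs the priming filter."""
    if len(ipacs) != len(contexts):
        raise PairingError(
            f"{len(ipacs)} IPACs vs {len(contexts)} contexts: must align 1:1"
        )
    records: list[IPACRecord] = []
    for ipac, ctx in zip(ipacs, contexts):
        records.append(_classify_one(ipac, ctx, cfg, genome))
    return records


def _classify_one(
    ipac: AnnotatedPAC, ctx: NeighborContext, cfg: ClassificationConfig, genome
) -> IPACRecord:
    if ctx.d5s is not None and ctx.d5s < cfg.se_cutoff_nt:
        return IPACRecord(ipac, ctx, IPACClass.SE, "d5s<se_cutoff")
    if ipac.antisense_gene is not None:
        keep = internal_priming_filter(
            ipac.pac,
            genome,
            window_nt=cfg.priming_window_nt,
            a_frac=cfg.priming_a_frac,
            ag_frac=cfg.priming_ag_frac,
        )
        if keep:
            return IPACRecord(ipac, ctx, IPACClass.A, "antisense_overlap")
        return IPACRecord(ipac, ctx, IPACClass.FILTERED_IP, "antisense_overlap+ip")
    near_a = min(
        (d for d in (ctx.d5a, ctx.d3a) if d is not None), default=None
    )
    if near_a is not None and near_a < cfg.antisense_proximal_cutoff_nt:
        return IPACRecord(ipac, ctx, IPACClass.ANTISENSE_PROXIMAL, "min(d5a,d3a)<cutoff")
    if ctx.d3s is not None and ctx.d3s < cfg.sense_promoter_cutoff_nt:
        return IPACRecord(ipac, ctx, IPACClass.SENSE_PROMOTER, "d3s<cutoff")
    if (
        cfg.so_antisense_cutoff_nt is not None
        and ctx.d3a is not None
        and ctx.d3a < cfg.so_antisense_cutoff_nt
    ):
        return IPACRecord(ipac, ctx, IPACClass.ANTISENSE_PROXIMAL, "d3a<so_cutoff")
    return IPACRecord(ipac, ctx, IPACClass.SO, "remainder")


def class_summary(records: Sequence[IPACRecord]) -> pd.DataFrame:
    """Counts per class; A is reported both pre-filter (candidates) and post."""
    counts = Counter(r.label for r in records)
    total = len(records)
    rows = []
    for cls in IPACClass:
        n = counts.get(cls, 0)
        rows.append(
            {
                "class": cls.value,
                "n": n,
                "fraction": n / total if total else 0.0,
            }
        )
    a_candidates = counts.get(IPACClass.A, 0) + counts.get(IPACClass.FILTERED_IP, 0)
    rows.append(
        {"class": "A_candidates_prefilter", "n": a_candidates, "fraction": float("nan")}
    )
    rows.append({"class": "TOTAL", "n": total, "fraction": 1.0 if total else 0.0})
    return pd.DataFrame(rows)


def a_ipac_antisense_breakdown(
    records: Sequence[IPACRecord], ann: ExtendedAnnotation
) -> pd.DataFrame:
    """Where on the antisense host each A-IPAC lands, plus host biotypes."""
    region_counts: Counter = Counter()
    biotype_counts: Counter = Counter()
    for r in records:
        if r.label is not IPACClass.A:
            continue
        gid = r.ipac.antisense_gene
        if gid is None:
            continue
        g = ann.genes[gid]
        biotype_counts[g.biotype] += 1
        p = r.ipac.pac.dominant_site
        base = p if r.ipac.pac.strand == "+" else p - 1
        cats = set()
        for iso in g.isoforms:
            cat = _isoform_category(iso, g, base, g.cut3_extended)
            if cat is not None:
                cats.add(cat)
        bucket = "other"
        for want, name in (
            (RegionCategory.UTR3, "UTR3"),
            (RegionCategory.CDS, "CDS"),
            (RegionCategory.INTRON, "intron"),
            (RegionCategory.UTR5, "UTR5"),
        ):
            if cats == {want}:
                bucket = name
                break
        region_counts[bucket] += 1
    rows = [
        {"kind": "region", "key": k, "n": n} for k, n in sorted(region_counts.items())
    ] + [
        {"kind": "biotype", "key": k, "n": n} for k, n in sorted(biotype_counts.items())
    ]
    return pd.DataFrame(rows, columns=["kind", "key", "n"])


def write_records_tsv(records: Sequence[IPACRecord], path: str) -> None:
    def fmt(v):
        return "." if v is None else str(v)

    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tpac_id\ttotal_tags\tstrand\tdominant_site"
            "\tclass\trule\td5s\td3s\td5a\td3a\tantisense_gene\n"
        )
        for r in records:
            p = r.ipac.pac
            c = r.context
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.pac_id}\t{p.total_tags}\t{p.strand}"
                f"\t{p.dominant_site}\t{r.label.value}\t{r.rule}\t{fmt(c.d5s)}"
                f"\t{fmt(c.d3s)}\t{fmt(c.d5a)}\t{fmt(c.d3a)}\t{fmt(r.ipac.antisense_gene)}\n"
            )
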