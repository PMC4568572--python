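"""Distances from each intergenic PAC to its four neighboring genes.

"5'" and "3'" are defined in the IPAC's own strand orientation.  Sense
distances anchor at the upstream gene's stop codon (or extended transcript
end) and the downstream gene's transcript start; antisense distances use the
nearest opposite-strand gene's nearest extended boundary.  All distances are
junction arithmetic: an IPAC sitting exactly on a boundary is at distance 0,
and with the extended-end anchor d5s + d3s equals the intergenic length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import MissingAnchorError, ValidationError
from .genome_model import ExtendedAnnotation, gene_boundary
from .pac_annotation import AnnotatedPAC, RegionCategory


@dataclass
class NeighborContext:
    """The four signed-to-nonnegative distances plus intergenic geometry."""

    d5s: Optional[int] = None  # to 5' sense gene (stop codon or extended end)
    d3s: Optional[int] = None  # to 3' sense gene transcript start
    d5a: Optional[int] = None  # to 5' antisense gene (nearest extended boundary)
    d3a: Optional[int] = None  # to 3' antisense gene (nearest extended boundary)
    intergenic_len: Optional[int] = None
    rel_pos: Optional[float] = None
    gene5s: Optional[str] = None
    gene3s: Optional[str] = None
    gene5a: Optional[str] = None
    gene3a: Optional[str] = None


def neighbor_context(
    ipac: AnnotatedPAC,
    ann: ExtendedAnnotation,
    sense_anchor: str = "stop_codon",
) -> NeighborContext:
    """Compute the neighborhood of one intergenic PAC.

    ``sense_anchor`` selects the 5'-sense anchor: ``stop_codon`` (falling
    back to the extended end for non-coding genes) or ``tx_end_extended``.
    Distances to absent neighbors (chromosome ends) are None, never zero.
    """
    if ipac.category is not RegionCategory.INTERGENIC:
        raise ValidationError(f"{ipac.pac.pac_id}: not an intergenic PAC")
    if sense_anchor not in ("stop_codon", "tx_end_extended"):
        raise ValidationError(f"unknown sense_anchor {sense_anchor!r}")

    p = ipac.pac.dominant_site
    chrom, strand = ipac.pac.chrom, ipac.pac.strand
    sign = 1 if strand == "+" else -1
    ctx = NeighborContext()

    up = ann.nearest_gene_upstream(chrom, strand, p)
    if up is not None:
        try:
            anchor = gene_boundary(up, sense_anchor)
        except MissingAnchorError:
            anchor = gene_boundary(up, "tx_end_extended")
        ctx.d5s = sign * (p - anchor)
        ctx.gene5s = up.gene_id

    down = ann.nearest_gene_downstream(chrom, strand, p)
    if down is not None:
        ctx.d3s = sign * (gene_boundary(down, "tx_start") - p)
        ctx.gene3s = down.gene_id

    opposite = "-" if strand == "+" else "+"
    up_a = ann.nearest_gene_upstream(chrom, strand, p, gene_strand=opposite)
    if up_a is not None:
        boundary = up_a.ext_end if strand == "+" else up_a.ext_start
        ctx.d5a = max(sign * (p - boundary), 0)
        ctx.gene5a = up_a.gene_id
    down_a = ann.nearest_gene_downstream(chrom, strand, p, gene_strand=opposite)
    if down_a is not None:
        boundary = down_a.ext_start if strand == "+" else down_a.ext_end
        ctx.d3a = max(sign * (boundary - p), 0)
        ctx.gene3a = down_a.gene_id

    gap = ann.containing_intergenic_interval(chrom, strand, p)
    if gap is not None:
        a, b = gap
        ctx.intergenic_len = b - a
        if ctx.intergenic_len > 0 and up is not None and down is not None:
            d_from_5p = p - a if strand == "+" else b - p
            ctx.rel_pos = d_from_5p / ctx.intergenic_len
    return ctx


def neighbor_contexts(
    ipacs: Sequence[AnnotatedPAC],
    ann: ExtendedAnnotation,
    sense_anchor: str = "stop_codon",
) -> list[NeighborContext]:
    return [neighbor_context(i, ann, sense_anchor) for i in ipacs]


def rel_position_histogram(
    contexts: Sequence[NeighborContext], n_bins: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of normalized intergenic positions on [0, 1].

    Returns ``(bin_edges, counts, frac_first_decile)`` where the last value
    is the fraction of defined rel_pos values <= 0.1.
    """
    vals = np.array([c.rel_pos for c in contexts if c.rel_pos is not None], float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    frac = float(np.mean(vals <= 0.1)) if vals.size else float("nan")
    return edges, counts, frac


def write_contexts_tsv(
    ipacs: Sequence[AnnotatedPAC], contexts: Sequence[NeighborContext], path: str
) -> None:
    def fmt(v):
        return "." if v is None else (f"{v:.6g}" if isinstance(v, float) else str(v))

    with open(path, "w") as fh:
        fh.write("pac_id\td5s\td3s\td5a\td3a\tintergenic_len\trel_pos\n")
        for ipac, c in zip(ipacs, contexts):
            fh.write(
                f"{ipac.pac.pac_id}\t{fmt(c.d5s)}\t{fmt(c.d3s)}\t{fmt(c.d5a)}"
                f"\t{fmt(c.d3a)}\t{fmt(c.intergenic_len)}\t{fmt(c.rel_pos)}\n"
            )


def write_histogram_tsv(edges: np.ndarray, counts: np.ndarray, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tcount\n")
        for s, e, c in zip(edges[:-1], edges[1:], counts):
            fh.write(f"{s:.4f}\t{e:.4f}\t{int(c)}\n")
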