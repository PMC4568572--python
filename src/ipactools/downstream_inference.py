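"""Orphan-cluster inference, evidence association, and cross-sample comparison.

Orphan (SO) IPACs far from all genes are single-linkage clustered at the
within-gene inter-PAC distance to estimate how many novel transcripts they
could represent; clusters and sites are then associated with external
evidence interval sets (EST 3' ends, novel-gene intervals, transcribed
fragments, lncRNAs, small ORFs) through simple windowed overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .classification import IPACClass, IPACRecord
from .errors import ParameterError, ValidationError


def inter_pac_distance(mean_utr_len: float, mean_pacs_per_utr: float) -> int:
    """Estimated average distance between two PACs of one gene (nearest nt)."""
    if mean_utr_len <= 0 or mean_pacs_per_utr <= 0:
        raise ParameterError("inputs must be positive")
    return round(mean_utr_len / mean_pacs_per_utr)


@dataclass
class SOCluster:
    cluster_id: str
    members: list[IPACRecord]
    verified_by: list[str] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.members[0].ipac.pac.chrom

    @property
    def strand(self) -> str:
        return self.members[0].ipac.pac.strand

    @property
    def span(self) -> tuple[int, int]:
        positions = [m.ipac.pac.dominant_site for m in self.members]
        return min(positions), max(positions)

    @property
    def dominant(self) -> IPACRecord:
        """Member with the most tags (smaller coordinate on ties)."""
        return max(
            self.members,
            key=lambda m: (m.ipac.pac.total_tags, -m.ipac.pac.dominant_site),
        )


def cluster_so(
    so_records: Sequence[IPACRecord],
    near_gene_exclusion_nt: int = 2000,
    linkage_nt: int = 431,
) -> tuple[list[SOCluster], int]:
    """Cluster orphan IPACs after excluding those near any gene.

    An SO-IPAC whose minimum neighbor distance (either strand, either side)
    is below ``near_gene_exclusion_nt`` is excluded first; the remainder is
    single-linkage clustered at ``linkage_nt`` per chrom+strand.  Returns
    (clusters, n_excluded).
    """
    if near_gene_exclusion_nt < 0 or linkage_nt < 0:
        raise ParameterError("distances must be >= 0")
    kept: list[IPACRecord] = []
    excluded = 0
    for r in so_records:
        if r.label is not IPACClass.SO:
            raise ValidationError(f"{r.pac_id}: not an SO record")
        c = r.context
        dists = [d for d in (c.d5s, c.d3s, c.d5a, c.d3a) if d is not None]
        if dists and min(dists) < near_gene_exclusion_nt:
            excluded += 1
        else:
            kept.append(r)

    groups: dict[tuple[str, str], list[IPACRecord]] = {}
    for r in kept:
        groups.setdefault((r.ipac.pac.chrom, r.ipac.pac.strand), []).append(r)
    clusters: list[SOCluster] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda r: r.ipac.pac.dominant_site)
        run: list[IPACRecord] = []
        for r in members:
            if run and r.ipac.pac.dominant_site - run[-1].ipac.pac.dominant_site > linkage_nt:
                clusters.append(SOCluster(f"SOC{len(clusters) + 1:05d}", run))
                run = []
            run.append(r)
        if run:
            clusters.append(SOCluster(f"SOC{len(clusters) + 1:05d}", run))
    return clusters, excluded


# ---------------------------------------------------------------------------
# Evidence association


@dataclass
class EvidenceSet:
    """A named external interval/point set with an association window."""

    name: str
    intervals: list[tuple[str, int, int, str]]  # chrom, start, end, strand
    window_nt: int
    anchor_mode: str = "interval"  # point | interval | downstream

    def __post_init__(self) -> None:
        if self.window_nt < 0:
            raise ParameterError("window_nt must be >= 0")
        if self.anchor_mode not in ("point", "interval", "downstream"):
            raise ParameterError(f"unknown anchor_mode {self.anchor_mode!r}")


def read_evidence_bed(
    path: str, name: str, window_nt: int, anchor_mode: str = "interval"
) -> EvidenceSet:
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{ln}: BED needs >= 3 columns")
            strand = parts[5] if len(parts) >= 6 else "+"
            intervals.append((parts[0], int(parts[1]), int(parts[2]), strand))
    return EvidenceSet(name, intervals, window_nt, anchor_mode)


def _item_matches(chrom: str, pos: int, ev: EvidenceSet) -> bool:
    w = ev.window_nt
    for e_chrom, s, e, strand in ev.intervals:
        if e_chrom != chrom:
            continue
        if ev.anchor_mode == "point":
            if abs(pos - s) <= w:
                return True
        elif ev.anchor_mode == "interval":
            if s - w <= pos <= e + w:
                return True
        else:  # downstream: within w nt past the interval end, strand-aware
            if strand == "+":
                if e <= pos <= e + w:
                    return True
            elif s - w <= pos <= s:
                return True
    return False


def verify_against_evidence(
    items: Sequence[tuple[str, int]], ev: EvidenceSet
) -> list[bool]:
    """One flag per (chrom, position) item; monotone in the window size."""
    return [_item_matches(chrom, pos, ev) for chrom, pos in items]


def verify_clusters(clusters: Sequence[SOCluster], ev: EvidenceSet) -> int:
    """Flag clusters whose dominant member matches; returns the number verified."""
    n = 0
    for cl in clusters:
        dom = cl.dominant.ipac.pac
        if _item_matches(dom.chrom, dom.dominant_site, ev):
            if ev.name not in cl.verified_by:
                cl.verified_by.append(ev.name)
            n += 1
    return n


# ---------------------------------------------------------------------------
# Correlations and cross-sample comparison


def expression_correlation(x_counts, y_counts) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p value."""
    x = np.asarray(list(x_counts), dtype=float)
    y = np.asarray(list(y_counts), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("paired vectors of length >= 3 required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CrossSampleResult:
    shared_pairs: list[tuple[int, int]]  # (index in A, index in B)
    shared_fraction: float  # fraction of A matched in B
    count_correlation: Optional[float]
    count_correlation_p: Optional[float]


def cross_sample_match(
    ipacs_a: Sequence, ipacs_b: Sequence, match_window: int = 50
) -> CrossSampleResult:
    """One-to-one greedy nearest matching of two IPAC sets.

    Items are anything exposing ``chrom``, ``strand``, ``dominant_site`` and
    ``total_tags`` (``PAC`` works).  An item of A is shared when a
    same-strand item of B lies within ``match_window`` nt of its dominant
    site; pairs are assigned nearest-first, ties toward smaller coordinates.
    The fraction is asymmetric by definition: shared / |A|.
    """
    if match_window < 0:
        raise ParameterError("match_window must be >= 0")
    candidates = []
    by_cs_b: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for j, b in enumerate(ipacs_b):
        by_cs_b.setdefault((b.chrom, b.strand), []).append((b.dominant_site, j))
    for key in by_cs_b:
        by_cs_b[key].sort()
    import bisect

    for i, a in enumerate(ipacs_a):
        group = by_cs_b.get((a.chrom, a.strand), [])
        pos = a.dominant_site
        lo = bisect.bisect_left(group, (pos - match_window, -1))
        hi = bisect.bisect_right(group, (pos + match_window, len(ipacs_b)))
        for bpos, j in group[lo:hi]:
            d = abs(pos - bpos)
            if d <= match_window:
                candidates.append((d, pos, bpos, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _d, _pa, _pb, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    frac = len(pairs) / len(ipacs_a) if len(ipacs_a) else 0.0
    r = p = None
    if len(pairs) >= 3:
        xa = [ipacs_a[i].total_tags for i, _ in pairs]
        xb = [ipacs_b[j].total_tags for _, j in pairs]
        if np.std(xa) > 0 and np.std(xb) > 0:
            r, p = expression_correlation(xa, xb)
    return CrossSampleResult(pairs, frac, r, p)


def write_clusters_tsv(clusters: Sequence[SOCluster], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tchrom\tstrand\tspan_start\tspan_end\tn_members"
                 "\tdominant_pac\tverified_by\n")
        for cl in clusters:
            s, e = cl.span
            fh.write(
                f"{cl.cluster_id}\t{cl.chrom}\t{cl.strand}\t{s}\t{e}\t{len(cl.members)}"
                f"\t{cl.dominant.pac_id}\t{','.join(cl.verified_by) or '.'}\n"
            )
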