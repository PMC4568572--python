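"""Poly(A)-tag processing: site clustering, support filtering, priming filter.

Cleavage positions are junction coordinates (see :mod:`ipactools.genome_model`).
Sites within ``max_gap`` nt of each other chain into poly(A) site clusters
(PACs) by single linkage; clusters with fewer than ``min_tags`` supporting
tags are dropped; candidate antisense clusters with genomically A/G-rich
downstream sequence are discarded as internal-priming artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import ParameterError, ValidationError

DEFAULT_MAX_GAP = 24
DEFAULT_MIN_TAGS = 3
PRIMING_WINDOW_NT = 20
PRIMING_A_FRAC = 0.50
PRIMING_AG_FRAC = 0.60


@dataclass(frozen=True)
class CleavageSite:
    chrom: str
    pos: int
    strand: str
    n_tags: int = 1

    def __post_init__(self) -> None:
        if self.n_tags < 1:
            raise ValidationError(f"site {self.chrom}:{self.pos}: n_tags < 1")
        if self.strand not in "+-":
            raise ValidationError(f"site {self.chrom}:{self.pos}: bad strand")


@dataclass
class PAC:
    """A poly(A) site cluster."""

    chrom: str
    strand: str
    start: int
    end: int
    sites: list[CleavageSite] = field(default_factory=list)
    pac_id: str = ""

    @property
    def total_tags(self) -> int:
        return sum(s.n_tags for s in self.sites)

    @property
    def dominant_site(self) -> int:
        """Position of the member with maximal tag count.

        Ties break toward the transcription-direction distal member.
        """
        best = max(s.n_tags for s in self.sites)
        tied = [s.pos for s in self.sites if s.n_tags == best]
        return max(tied) if self.strand == "+" else min(tied)


def merge_duplicate_sites(sites: Iterable[CleavageSite]) -> list[CleavageSite]:
    """Sum tag counts of sites sharing (chrom, pos, strand)."""
    acc: dict[tuple[str, int, str], int] = {}
    for s in sites:
        key = (s.chrom, s.pos, s.strand)
        acc[key] = acc.get(key, 0) + s.n_tags
    return [
        CleavageSite(chrom, pos, strand, n)
        for (chrom, pos, strand), n in sorted(acc.items())
    ]


def cluster_sites(
    sites: Sequence[CleavageSite], max_gap: int = DEFAULT_MAX_GAP
) -> list[PAC]:
    """Single-linkage clustering of cleavage sites per chrom+strand.

    Adjacent sorted sites whose positional gap is <= ``max_gap`` join the
    same PAC.  Output is sorted by (chrom, start, strand); input order is
    irrelevant.
    """
    if max_gap < 0:
        raise ParameterError("max_gap must be >= 0")
    merged = merge_duplicate_sites(sites)
    groups: dict[tuple[str, str], list[CleavageSite]] = {}
    for s in merged:
        groups.setdefault((s.chrom, s.strand), []).append(s)

    pacs: list[PAC] = []
    for (chrom, strand), members in groups.items():
        members.sort(key=lambda s: s.pos)
        run: list[CleavageSite] = []
        for s in members:
            if run and s.pos - run[-1].pos > max_gap:
                pacs.append(PAC(chrom, strand, run[0].pos, run[-1].pos, run))
                run = []
            run.append(s)
        if run:
            pacs.append(PAC(chrom, strand, run[0].pos, run[-1].pos, run))
    pacs.sort(key=lambda p: (p.chrom, p.start, p.strand))
    for i, p in enumerate(pacs):
        p.pac_id = f"PAC{i + 1:06d}"
    return pacs


def filter_min_support(pacs: Sequence[PAC], min_tags: int = DEFAULT_MIN_TAGS) -> list[PAC]:
    """Keep PACs with ``total_tags >= min_tags``; order preserved."""
    if min_tags < 1:
        raise ParameterError("min_tags must be >= 1")
    return [p for p in pacs if p.total_tags >= min_tags]


def downstream_window(
    pac: PAC, genome, window_nt: int = PRIMING_WINDOW_NT
) -> tuple[str, bool]:
    """Genomic sequence immediately 3' of the dominant site, strand-oriented.

    Returns ``(sequence, truncated)`` where *truncated* flags a window cut
    short by the chromosome end.  *genome* is a ``pyfaidx.Fasta``-like
    mapping of chrom -> sequence.
    """
    pos = pac.dominant_site
    rec = genome[pac.chrom]
    clen = len(rec)
    if pac.strand == "+":
        s, e = pos, min(pos + window_nt, clen)
        seq = str(rec[s:e]).upper()
    else:
        s, e = max(pos - window_nt, 0), pos
        seq = _revcomp(str(rec[s:e]).upper())
    return seq, len(seq) < window_nt


def internal_priming_filter(
    pac: PAC,
    genome,
    window_nt: int = PRIMING_WINDOW_NT,
    a_frac: float = PRIMING_A_FRAC,
    ag_frac: float = PRIMING_AG_FRAC,
) -> bool:
    """Return True to keep the PAC, False to discard as an artifact.

    Discard iff, over the downstream window, the A fraction strictly exceeds
    ``a_frac`` or the A+G fraction strictly exceeds ``ag_frac``.  Windows
    truncated at the chromosome end are evaluated over the available length.
    """
    seq, _truncated = downstream_window(pac, genome, window_nt)
    if not seq:
        return True
    n = len(seq)
    n_a = seq.count("A")
    n_ag = n_a + seq.count("G")
    return not (n_a / n > a_frac or n_ag / n > ag_frac)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# I/O


def read_sites_bed(path: str) -> list[CleavageSite]:
    """BED6 with one row per cleavage site; score column = tag count.

    The BED start coordinate is taken as the junction position.  Rows with a
    missing/zero score count as single tags (per-tag BED collapsed here).
    """
    sites: list[CleavageSite] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValidationError(f"{path}:{ln}: BED6 requires 6 columns")
            score = parts[4]
            n = int(float(score)) if score not in (".", "", "0") else 1
            sites.append(CleavageSite(parts[0], int(parts[1]), parts[5], max(n, 1)))
    return merge_duplicate_sites(sites)


def write_sites_bed(sites: Sequence[CleavageSite], path: str) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sorted(sites, key=lambda s: (s.chrom, s.pos, s.strand))):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\tsite_{i}\t{s.n_tags}\t{s.strand}\n")


def write_pacs_tsv(pacs: Sequence[PAC], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tpac_id\ttotal_tags\tstrand\tdominant_site\tn_sites\n")
        for p in pacs:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.pac_id}\t{p.total_tags}"
                f"\t{p.strand}\t{p.dominant_site}\t{len(p.sites)}\n"
            )


def read_pacs_tsv(path: str) -> list[PAC]:
    import csv

    pacs: list[PAC] = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            # one synthetic member site carrying the whole weight at the
            # dominant position; enough for every downstream computation
            site = CleavageSite(
                row["chrom"], int(row["dominant_site"]), row["strand"], int(row["total_tags"])
            )
            s, e = int(row["start"]), int(row["end"])
            pac = PAC(row["chrom"], row["strand"], s, e, [site])
            pac.pac_id = row["pac_id"]
            pacs.append(pac)
    return pacs
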