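"""Annotated-genome model: GFF3 parsing, 3'-UTR extension, intergenic intervals.

Coordinate conventions
----------------------
Internally everything is 0-based half-open.  Cleavage/poly(A) positions are
*junction* coordinates (cuts between bases) in ``[0, chrom_len]``; a junction
that coincides with a gene boundary is at distance 0 from that boundary, and
distances measured to the two flanking genes of an intergenic interval sum
exactly to the interval length.  GFF3 I/O follows the 1-based inclusive
convention of the format.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import gffutils

from .errors import (
    AnnotationParseError,
    LookupError_,
    MissingAnchorError,
    ValidationError,
)

GENE_ROOT_TYPES = ("gene", "pseudogene", "transposable_element_gene")

_TX_TYPE_TO_BIOTYPE = {
    "mRNA": "protein_coding",
    "ncRNA": "ncRNA",
    "lnc_RNA": "ncRNA",
    "lncRNA": "ncRNA",
    "miRNA": "miRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snoRNA": "snoRNA",
    "snRNA": "other",
    "pseudogenic_transcript": "pseudogene",
}

BIOTYPES = (
    "protein_coding",
    "ncRNA",
    "pseudogene",
    "transposable_element",
    "miRNA",
    "rRNA",
    "tRNA",
    "snoRNA",
    "other",
)


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class Isoform:
    """One transcript's feature intervals (0-based half-open)."""

    tx_id: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GeneModel:
    """A collapsed representative gene model.

    Multi-isoform genes collapse to the union of exons, outermost transcript
    bounds and the distal (transcription-direction furthest) stop codon; the
    raw isoforms are retained so that positions where isoforms disagree can
    be flagged downstream.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "other"
    isoforms: list[Isoform] = field(default_factory=list)
    # filled in by ExtendedAnnotation
    ext_start: int = -1
    ext_end: int = -1

    def __post_init__(self) -> None:
        if self.tx_end <= self.tx_start:
            raise ValidationError(
                f"gene {self.gene_id}: end ({self.tx_end}) <= start ({self.tx_start})"
            )
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.exons = _merge_intervals(self.exons) or [(self.tx_start, self.tx_end)]
        self.cds = _merge_intervals(self.cds)
        for s, e in self.exons:
            if s < self.tx_start or e > self.tx_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside transcript bounds"
                )
        if not self.isoforms:
            self.isoforms = [
                Isoform(
                    f"{self.gene_id}.0",
                    self.tx_start,
                    self.tx_end,
                    list(self.exons),
                    list(self.cds),
                )
            ]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between sorted exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def stop_codon_cut(self) -> Optional[int]:
        """Junction coordinate of the transcription-direction CDS end.

        ``None`` for non-coding genes.
        """
        if not self.cds:
            return None
        return self.cds[-1][1] if self.strand == "+" else self.cds[0][0]

    @property
    def cut5(self) -> int:
        """Junction coordinate of the transcription start."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def cut3(self) -> int:
        """Junction coordinate of the annotated transcription end."""
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def cut3_extended(self) -> int:
        """Junction coordinate of the extended transcription end."""
        return self.ext_end if self.strand == "+" else self.ext_start

    @property
    def span_extended(self) -> tuple[int, int]:
        return (self.ext_start, self.ext_end)


def gene_boundary(gene: GeneModel, anchor: str) -> int:
    """Return the requested boundary of *gene* as a genomic junction coordinate.

    ``anchor`` is one of ``stop_codon``, ``tx_end_extended``, ``tx_start``.
    Requesting ``stop_codon`` on a non-coding gene raises
    :class:`MissingAnchorError`; callers fall back to ``tx_end_extended``.
    """
    if anchor == "stop_codon":
        cut = gene.stop_codon_cut
        if cut is None:
            raise MissingAnchorError(f"gene {gene.gene_id} has no CDS (stop codon)")
        return cut
    if anchor == "tx_end_extended":
        if gene.ext_start < 0:
            raise ValidationError(f"gene {gene.gene_id}: extension not applied")
        return gene.cut3_extended
    if anchor == "tx_start":
        return gene.cut5
    raise ValidationError(f"unknown anchor {anchor!r}")


class ExtendedAnnotation:
    """An annotation with the 3'-UTR extension applied and interval indexes built."""

    def __init__(
        self,
        genes: Iterable[GeneModel],
        chrom_lengths: dict[str, int],
        extension_nt: int = 50,
    ) -> None:
        if extension_nt < 0:
            raise ValidationError("extension_nt must be >= 0")
        self.extension_nt = extension_nt
        self.chrom_lengths = dict(chrom_lengths)
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValidationError(f"duplicate gene id {g.gene_id}")
            if g.chrom not in self.chrom_lengths:
                self.chrom_lengths[g.chrom] = g.tx_end
            clen = self.chrom_lengths[g.chrom]
            if g.tx_end > clen:
                raise ValidationError(
                    f"gene {g.gene_id} extends past chromosome end ({g.tx_end} > {clen})"
                )
            if g.strand == "+":
                g.ext_start, g.ext_end = g.tx_start, min(g.tx_end + extension_nt, clen)
            else:
                g.ext_start, g.ext_end = max(g.tx_start - extension_nt, 0), g.tx_end
            self.genes[g.gene_id] = g
        self._build_indexes()

    # -- indexes ---------------------------------------------------------

    def _build_indexes(self) -> None:
        self._by_cs: dict[tuple[str, str], list[GeneModel]] = {}
        for g in self.genes.values():
            self._by_cs.setdefault((g.chrom, g.strand), []).append(g)
        self._keys: dict[tuple[str, str], dict[str, list]] = {}
        for cs, glist in self._by_cs.items():
            glist.sort(key=lambda g: (g.ext_start, g.ext_end))
            self._keys[cs] = {
                "by_ext_end": sorted(glist, key=lambda g: g.ext_end),
                "ext_end": sorted(g.ext_end for g in glist),
                "by_ext_start": glist,
                "ext_start": [g.ext_start for g in glist],
            }
        self._intergenic: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for chrom, clen in self.chrom_lengths.items():
            for strand in "+-":
                spans = _merge_intervals(
                    g.span_extended for g in self._by_cs.get((chrom, strand), [])
                )
                gaps, prev = [], 0
                for s, e in spans:
                    if s > prev:
                        gaps.append((prev, s))
                    prev = max(prev, e)
                if prev < clen:
                    gaps.append((prev, clen))
                self._intergenic[(chrom, strand)] = gaps

    # -- queries ---------------------------------------------------------

    def chroms(self) -> list[str]:
        return sorted(self.chrom_lengths)

    def genes_on(self, chrom: str, strand: str) -> list[GeneModel]:
        return list(self._by_cs.get((chrom, strand), []))

    def intergenic_intervals(self, chrom: str, strand: str) -> list[tuple[int, int]]:
        """Sorted disjoint gaps between extended same-strand gene spans."""
        if chrom not in self.chrom_lengths:
            raise LookupError_(f"unknown chromosome {chrom!r}")
        return list(self._intergenic[(chrom, strand)])

    def all_intergenic_intervals(self) -> Iterator[tuple[str, str, int, int]]:
        for (chrom, strand), gaps in sorted(self._intergenic.items()):
            for s, e in gaps:
                yield chrom, strand, s, e

    def containing_intergenic_interval(
        self, chrom: str, strand: str, pos: int
    ) -> Optional[tuple[int, int]]:
        """The same-strand intergenic interval whose closure contains junction *pos*."""
        gaps = self._intergenic.get((chrom, strand), [])
        i = bisect.bisect_right([g[0] for g in gaps], pos) - 1
        if i >= 0 and gaps[i][0] <= pos <= gaps[i][1]:
            return gaps[i]
        return None

    def nearest_gene_upstream(
        self, chrom: str, strand: str, pos: int, gene_strand: Optional[str] = None
    ) -> Optional[GeneModel]:
        """Nearest gene lying 5' of junction *pos* in the *strand* orientation.

        ``gene_strand`` selects which strand's genes to search (defaults to
        ``strand`` itself, i.e. sense neighbors).  A gene is "upstream" when
        its extended span ends at or before *pos* in the query orientation.
        """
        gs = gene_strand or strand
        keys = self._keys.get((chrom, gs))
        if keys is None:
            return None
        if strand == "+":
            i = bisect.bisect_right(keys["ext_end"], pos) - 1
            return keys["by_ext_end"][i] if i >= 0 else None
        i = bisect.bisect_left(keys["ext_start"], pos)
        return keys["by_ext_start"][i] if i < len(keys["by_ext_start"]) else None

    def nearest_gene_downstream(
        self, chrom: str, strand: str, pos: int, gene_strand: Optional[str] = None
    ) -> Optional[GeneModel]:
        """Nearest gene lying 3' of junction *pos* in the *strand* orientation."""
        gs = gene_strand or strand
        keys = self._keys.get((chrom, gs))
        if keys is None:
            return None
        if strand == "+":
            i = bisect.bisect_left(keys["ext_start"], pos)
            return keys["by_ext_start"][i] if i < len(keys["by_ext_start"]) else None
        i = bisect.bisect_right(keys["ext_end"], pos) - 1
        return keys["by_ext_end"][i] if i >= 0 else None

    def genes_overlapping_base(
        self, chrom: str, strand: str, base: int, extended: bool = True
    ) -> list[GeneModel]:
        """Genes on *strand* whose (extended) span contains base index *base*."""
        out = []
        for g in self._by_cs.get((chrom, strand), []):
            s, e = g.span_extended if extended else (g.tx_start, g.tx_end)
            if s <= base < e:
                out.append(g)
        return out

    # -- I/O -------------------------------------------------------------

    def to_gff3(self, path: str) -> None:
        """Write the collapsed (un-extended) models back to GFF3."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in self.chroms():
                fh.write(f"##sequence-region {chrom} 1 {self.chrom_lengths[chrom]}\n")
            for g in sorted(self.genes.values(), key=lambda g: (g.chrom, g.tx_start)):
                root = {
                    "pseudogene": "pseudogene",
                    "transposable_element": "transposable_element_gene",
                }.get(g.biotype, "gene")
                tx_type = "mRNA" if g.is_coding else _tx_type_for(g.biotype)
                attrs = f"ID={g.gene_id};biotype={g.biotype}"
                fh.write(
                    f"{g.chrom}\t.\t{root}\t{g.tx_start + 1}\t{g.tx_end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                tid = f"{g.gene_id}.1"
                fh.write(
                    f"{g.chrom}\t.\t{tx_type}\t{g.tx_start + 1}\t{g.tx_end}\t.\t{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
                )
                for s, e in g.exons:
                    fh.write(
                        f"{g.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={tid}\n"
                    )
                for s, e in g.cds:
                    fh.write(
                        f"{g.chrom}\t.\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\tParent={tid}\n"
                    )

    def intergenic_to_bed6(self, path: str) -> None:
        with open(path, "w") as fh:
            for i, (chrom, strand, s, e) in enumerate(self.all_intergenic_intervals()):
                fh.write(f"{chrom}\t{s}\t{e}\tintergenic_{i}\t0\t{strand}\n")


def _tx_type_for(biotype: str) -> str:
    for t, b in _TX_TYPE_TO_BIOTYPE.items():
        if b == biotype:
            return t
    return "ncRNA"


def load_chrom_sizes(path: str) -> dict[str, int]:
    """Two-column TSV: chrom <tab> length."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise AnnotationParseError(f"{path}:{ln}: expected 2 columns")
            out[parts[0]] = int(parts[1])
    return out


def load_annotation(
    gff3_path: str,
    extension_nt: int = 50,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> ExtendedAnnotation:
    """Parse a GFF3 file into an :class:`ExtendedAnnotation`.

    One representative model per gene: union of exons, outermost bounds,
    distal stop codon.  Coordinates become 0-based half-open internally; the
    extension is applied in transcription direction and clipped to the
    chromosome length.
    """
    try:
        db = gffutils.create_db(
            gff3_path,
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise AnnotationParseError(f"cannot parse GFF3 {gff3_path!r}: {exc}") from exc

    lengths: dict[str, int] = dict(chrom_lengths or {})
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            if len(parts) >= 4:
                lengths.setdefault(parts[1], int(parts[3]))

    genes: list[GeneModel] = []
    for root_type in GENE_ROOT_TYPES:
        for feat in db.features_of_type(root_type):
            genes.append(_collapse_gene(db, feat))
    if not genes:
        raise AnnotationParseError(f"{gff3_path}: no gene features found")
    for g in genes:
        lengths.setdefault(g.chrom, 0)
        lengths[g.chrom] = max(lengths[g.chrom], g.tx_end)
    return ExtendedAnnotation(genes, lengths, extension_nt=extension_nt)


def _collapse_gene(db: gffutils.FeatureDB, feat) -> GeneModel:
    gene_id = feat.id
    if feat.end < feat.start:
        raise ValidationError(f"gene {gene_id}: end ({feat.end}) <= start ({feat.start})")
    isoforms: list[Isoform] = []
    tx_types: list[str] = []
    for tx in db.children(feat, level=1):
        exons = [(c.start - 1, c.end) for c in db.children(tx, featuretype="exon")]
        cds = [(c.start - 1, c.end) for c in db.children(tx, featuretype="CDS")]
        isoforms.append(
            Isoform(
                tx_id=tx.id,
                start=tx.start - 1,
                end=tx.end,
                exons=_merge_intervals(exons) or [(tx.start - 1, tx.end)],
                cds=_merge_intervals(cds),
            )
        )
        tx_types.append(tx.featuretype)
    if not isoforms:
        isoforms = [
            Isoform(gene_id + ".0", feat.start - 1, feat.end, [(feat.start - 1, feat.end)])
        ]
        tx_types = [feat.featuretype]

    biotype = None
    for key in ("biotype", "gene_biotype", "locus_type"):
        if key in feat.attributes:
            biotype = feat.attributes[key][0]
            break
    if biotype is None:
        if feat.featuretype == "pseudogene":
            biotype = "pseudogene"
        elif feat.featuretype == "transposable_element_gene":
            biotype = "transposable_element"
        elif any(t == "mRNA" for t in tx_types) or any(iso.cds for iso in isoforms):
            biotype = "protein_coding"
        else:
            biotype = _TX_TYPE_TO_BIOTYPE.get(tx_types[0], "other")

    tx_start = min(iso.start for iso in isoforms)
    tx_end = max(iso.end for iso in isoforms)
    all_exons = [iv for iso in isoforms for iv in iso.exons]
    all_cds = [iv for iso in isoforms for iv in iso.cds]
    return GeneModel(
        gene_id=gene_id,
        chrom=feat.seqid,
        strand=feat.strand if feat.strand in "+-" else "+",
        tx_start=tx_start,
        tx_end=tx_end,
        exons=all_exons,
        cds=all_cds,
        biotype=biotype,
        isoforms=isoforms,
    )
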