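"""Synthetic annotated genomes with poly(A) tags planted in known classes.

Gene and intergenic lengths follow geometric-like discrete distributions
with configurable means; background sequence is i.i.d. uniform over ACGT.
Sites are planted with rejection sampling against explicit geometric
constraints (distances to gene boundaries computed directly from the
annotation), so every truth row is correct by construction.  Poly(A)-signal
hexamers are embedded at a fixed offset upstream of planted sites and
internal-priming artifacts get an A-rich downstream tract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError, PlacementError
from .genome_model import ExtendedAnnotation, GeneModel
from .pat_processing import CleavageSite
from .signal_analysis import CANONICAL_PAS, enumerate_variants

PLANT_CLASSES = ("UTR3", "SE", "A", "SO", "sense_promoter", "antisense_proximal")
HEXAMER_CLASSES = ("AATAAA", "VARIANT_1NT", "NOPAS")

# balanced downstream 20-mer written after genuine antisense-class sites so
# the priming filter never trips on them (A 25 %, A+G 50 %)
_SAFE_DOWNSTREAM = "ACGTACGTACGTACGTACGT"
_ARTIFACT_DOWNSTREAM = "AAAAAAAAAAAAAAACGTCG"  # 75 % A
_HEXAMER_OFFSET = -30  # upstream junction offset of the planted signal


@dataclass
class SimulationConfig:
    n_chroms: int = 2
    n_genes: int = 100
    mean_gene_len: int = 2343
    mean_intergenic_len: int = 5086
    n_sites: int = 120
    class_mix: dict = field(
        default_factory=lambda: {
            "UTR3": 0.15,
            "SE": 0.35,
            "A": 0.15,
            "SO": 0.15,
            "sense_promoter": 0.10,
            "antisense_proximal": 0.10,
        }
    )
    hexamer_mix: dict = field(
        default_factory=lambda: {"AATAAA": 0.5, "VARIANT_1NT": 0.3, "NOPAS": 0.2}
    )
    tags_per_site_min: int = 3
    tags_per_site_mean: float = 6.0
    ip_artifact_rate: float = 0.0
    microhet_jitter_nt: int = 10
    extension_nt: int = 50
    se_cutoff_nt: int = 700
    seed: int = 0

    def validate(self) -> None:
        if self.mean_gene_len <= 0 or self.mean_intergenic_len <= 0:
            raise ParameterError("mean lengths must be positive (sizing error)")
        if self.n_chroms < 1 or self.n_genes < 1:
            raise ParameterError("need at least one chromosome and one gene")
        if not (0 <= self.ip_artifact_rate < 1):
            raise ParameterError("ip_artifact_rate must be in [0, 1)")
        if not (0 <= self.microhet_jitter_nt <= 24):
            raise ParameterError("microhet_jitter_nt must be in [0, 24]")
        if self.tags_per_site_min < 1:
            raise ParameterError("tags_per_site_min must be >= 1")
        for mix, keys in ((self.class_mix, PLANT_CLASSES), (self.hexamer_mix, HEXAMER_CLASSES)):
            if any(k not in keys for k in mix) or any(v < 0 for v in mix.values()):
                raise ParameterError(f"bad mixture {mix}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ParameterError("mixture proportions must sum to 1")


# ---------------------------------------------------------------------------
# Genome simulation


def _draw_len(rng: np.random.Generator, mean: int, minimum: int) -> int:
    return max(int(rng.geometric(1.0 / mean)), minimum)


def simulate_genome(
    cfg: SimulationConfig,
) -> tuple[ExtendedAnnotation, dict[str, np.ndarray]]:
    """Build an annotated genome; returns (annotation, mutable sequences).

    Sequences are per-chrom numpy ``U1`` arrays so tag planting can edit
    them in place; ``sequences_as_strings`` converts for downstream use.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    seqs: dict[str, np.ndarray] = {}
    per_chrom = [
        cfg.n_genes // cfg.n_chroms + (1 if i < cfg.n_genes % cfg.n_chroms else 0)
        for i in range(cfg.n_chroms)
    ]
    gi = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = _draw_len(rng, cfg.mean_intergenic_len, 300)
        for _ in range(per_chrom[ci]):
            glen = _draw_len(rng, cfg.mean_gene_len, 500)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_make_gene(f"G{gi + 1:05d}", chrom, strand, pos, glen))
            gi += 1
            pos += glen + _draw_len(rng, cfg.mean_intergenic_len, 300)
        clen = pos + 500
        chrom_lengths[chrom] = clen
        seqs[chrom] = rng.choice(np.array(list("ACGT")), size=clen)
    ann = ExtendedAnnotation(genes, chrom_lengths, extension_nt=cfg.extension_nt)
    return ann, seqs


def _make_gene(gene_id: str, chrom: str, strand: str, start: int, length: int) -> GeneModel:
    """One gene: 100 nt 5'-UTR, CDS (split by a 150 nt intron when long
    enough), 150 nt 3'-UTR.  Coordinates are genomic; structure mirrors for
    the minus strand."""
    end = start + length
    utr5, utr3 = 100, 150
    if strand == "+":
        cds_lo, cds_hi = start + utr5, end - utr3
    else:
        cds_lo, cds_hi = start + utr3, end - utr5
    if length >= 1200:
        mid = (cds_lo + cds_hi) // 2
        exons = [(start, mid - 75), (mid + 75, end)]
        cds = [(cds_lo, mid - 75), (mid + 75, cds_hi)]
    else:
        exons = [(start, end)]
        cds = [(cds_lo, cds_hi)]
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=end,
        exons=exons,
        cds=cds,
        biotype="protein_coding",
    )


def sequences_as_strings(seqs: dict[str, np.ndarray]) -> dict[str, str]:
    """Plain chrom -> str mapping, usable wherever a genome handle is needed."""
    return {c: "".join(a) for c, a in seqs.items()}


# ---------------------------------------------------------------------------
# Site geometry (computed straight from the annotation, by construction)


@dataclass
class _Geometry:
    intergenic: bool
    d5s_stop: Optional[int]
    d3s: Optional[int]
    d5a: Optional[int]
    d3a: Optional[int]
    antisense_overlap: bool


def _site_geometry(ann: ExtendedAnnotation, chrom: str, strand: str, p: int) -> _Geometry:
    sign = 1 if strand == "+" else -1
    gap = ann.containing_intergenic_interval(chrom, strand, p)
    a_ok = gap is not None and gap[0] < p < gap[1]
    up = ann.nearest_gene_upstream(chrom, strand, p)
    d5s = None
    if up is not None:
        anchor = up.stop_codon_cut if up.stop_codon_cut is not None else up.cut3_extended
        d5s = sign * (p - anchor)
    down = ann.nearest_gene_downstream(chrom, strand, p)
    d3s = sign * (down.cut5 - p) if down is not None else None
    opp = "-" if strand == "+" else "+"
    up_a = ann.nearest_gene_upstream(chrom, strand, p, gene_strand=opp)
    d5a = None
    if up_a is not None:
        d5a = sign * (p - (up_a.ext_end if strand == "+" else up_a.ext_start))
    down_a = ann.nearest_gene_downstream(chrom, strand, p, gene_strand=opp)
    d3a = None
    if down_a is not None:
        d3a = sign * ((down_a.ext_start if strand == "+" else down_a.ext_end) - p)
    as_base = p if strand == "+" else p - 1
    overlap = bool(ann.genes_overlapping_base(chrom, opp, as_base, extended=False))
    return _Geometry(a_ok, d5s, d3s, d5a, d3a, overlap)


# ---------------------------------------------------------------------------
# Tag simulation


@dataclass
class _Planted:
    site_id: str
    chrom: str
    pos: int
    strand: str
    planted_class: str
    hexamer_class: str
    is_artifact: bool
    n_tags: int = 0


def _allocate(n: int, mix: dict, keys, rng: np.random.Generator) -> dict[str, int]:
    """Largest-remainder allocation of n items over mixture proportions."""
    props = [mix.get(k, 0.0) for k in keys]
    raw = [n * p for p in props]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
    for i in range(rem):
        counts[order[i % len(keys)]] += 1
    return {k: c for k, c in zip(keys, counts) if c > 0}


def simulate_tags(
    ann: ExtendedAnnotation,
    seqs: dict[str, np.ndarray],
    cfg: SimulationConfig,
) -> tuple[list[CleavageSite], pd.DataFrame]:
    """Plant labeled sites, emit jittered tags, edit signal sequence in place.

    Returns (cleavage sites, truth table).  The truth table has one row per
    planted site: site_id, chrom, pos, strand, planted_class, hexamer_class,
    is_internal_priming_artifact, n_tags.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11]))
    margin = cfg.microhet_jitter_nt + 26  # keep planted geometry safe under jitter
    counts = _allocate(cfg.n_sites, cfg.class_mix, PLANT_CLASSES, rng)
    n_artifacts = int(round(cfg.ip_artifact_rate * cfg.n_sites))

    occupied: dict[tuple[str, str], list[int]] = {}
    planted: list[_Planted] = []

    def too_close(chrom: str, strand: str, p: int) -> bool:
        return any(abs(p - q) < 150 for q in occupied.get((chrom, strand), []))

    def place(cls: str, n: int, artifact: bool) -> None:
        genes = list(ann.genes.values())
        made = 0
        attempts = 0
        max_attempts = 4000 * max(n, 1)
        while made < n:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    f"could not place {cls!r} site {made + 1}/{n}: no eligible locus"
                )
            cand = _propose(cls, genes, ann, cfg, rng, margin)
            if cand is None:
                continue
            chrom, strand, p = cand
            if too_close(chrom, strand, p):
                continue
            if not _check(cls, ann, chrom, strand, p, cfg, margin):
                continue
            hex_cls = (
                str(rng.choice(HEXAMER_CLASSES, p=[cfg.hexamer_mix.get(k, 0.0) for k in HEXAMER_CLASSES]))
            )
            occupied.setdefault((chrom, strand), []).append(p)
            planted.append(
                _Planted(
                    f"S{len(planted) + 1:05d}", chrom, p, strand, cls, hex_cls, artifact
                )
            )
            made += 1

    for cls, n in counts.items():
        place(cls, n, artifact=False)
    if n_artifacts:
        place("A", n_artifacts, artifact=True)

    # sequence edits + tag emission
    sites: list[CleavageSite] = []
    for pl in planted:
        _write_signals(seqs, pl, cfg, rng)
        sites.extend(_emit_tags(pl, cfg, rng, ann.chrom_lengths[pl.chrom]))

    truth = pd.DataFrame(
        {
            "site_id": [p.site_id for p in planted],
            "chrom": [p.chrom for p in planted],
            "pos": [p.pos for p in planted],
            "strand": [p.strand for p in planted],
            "planted_class": [p.planted_class for p in planted],
            "hexamer_class": [p.hexamer_class for p in planted],
            "is_internal_priming_artifact": [p.is_artifact for p in planted],
            "n_tags": [p.n_tags for p in planted],
        }
    )
    return sites, truth


def _propose(
    cls: str,
    genes: list[GeneModel],
    ann: ExtendedAnnotation,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    margin: int,
):
    """One candidate (chrom, strand, junction) for the class, or None."""
    se_hi = cfg.se_cutoff_nt - 1 - margin
    if cls in ("UTR3", "SE", "sense_promoter"):
        g = genes[rng.integers(len(genes))]
        sign = 1 if g.strand == "+" else -1
        stop = g.stop_codon_cut
        if cls == "UTR3":
            ext_off = abs(g.cut3_extended - stop)
            delta = int(rng.integers(1, ext_off))
            return g.chrom, g.strand, stop + sign * delta
        if cls == "SE":
            ext_off = abs(g.cut3_extended - stop)
            if ext_off + margin >= se_hi:
                return None
            delta = int(rng.integers(ext_off + margin, se_hi))
            return g.chrom, g.strand, stop + sign * delta
        # sense_promoter: just upstream of this gene's transcript start
        delta = int(rng.integers(1 + margin, cfg.se_cutoff_nt - margin))
        return g.chrom, g.strand, g.cut5 - sign * delta
    if cls == "A":
        g = genes[rng.integers(len(genes))]
        if not g.cds:
            return None
        lo, hi = g.cds[0][0], g.cds[-1][1]
        if hi - lo < 2 * margin + 2:
            return None
        p = int(rng.integers(lo + margin, hi - margin))
        strand = "-" if g.strand == "+" else "+"
        return g.chrom, strand, p
    if cls == "antisense_proximal":
        g = genes[rng.integers(len(genes))]
        strand = "-" if g.strand == "+" else "+"
        side = rng.random() < 0.5
        lo, hi = margin, max(200 - margin, margin + 1)
        delta = int(rng.integers(lo, hi))
        p = g.ext_start - delta if side else g.ext_end + delta
        return g.chrom, strand, p
    if cls == "SO":
        key = list(ann.chrom_lengths)[rng.integers(len(ann.chrom_lengths))]
        strand = "+" if rng.random() < 0.5 else "-"
        gaps = [
            (s, e)
            for s, e in ann.intergenic_intervals(key, strand)
            if e - s > 2 * (2000 + margin) + 2
        ]
        if not gaps:
            return None
        s, e = gaps[rng.integers(len(gaps))]
        p = int(rng.integers(s + 2000 + margin, e - 2000 - margin))
        return key, strand, p
    raise ParameterError(f"unknown class {cls!r}")


def _check(
    cls: str,
    ann: ExtendedAnnotation,
    chrom: str,
    strand: str,
    p: int,
    cfg: SimulationConfig,
    margin: int,
) -> bool:
    """Constraints each planted class must satisfy, by direct geometry."""
    clen = ann.chrom_lengths[chrom]
    if not (400 < p < clen - 400):
        return False
    geo = _site_geometry(ann, chrom, strand, p)
    cut = cfg.se_cutoff_nt
    prox = 200
    if cls == "UTR3":
        # proposal already sits between the host's stop and its extended end
        return not geo.intergenic
    if not geo.intergenic:
        return False
    if cls == "SE":
        return geo.d5s_stop is not None and margin <= geo.d5s_stop < cut - margin
    far_sense = geo.d5s_stop is None or geo.d5s_stop >= cut + margin
    no_as = not geo.antisense_overlap
    far_as = all(
        d is None or d >= prox + margin for d in (geo.d5a, geo.d3a)
    )
    far_down = geo.d3s is None or geo.d3s >= cut + margin
    if cls == "A":
        return far_sense and geo.antisense_overlap
    if cls == "antisense_proximal":
        near_as = any(
            d is not None and margin <= d < prox - margin for d in (geo.d5a, geo.d3a)
        )
        return far_sense and no_as and near_as
    if cls == "sense_promoter":
        return (
            far_sense
            and no_as
            and far_as
            and geo.d3s is not None
            and margin <= geo.d3s < cut - margin
        )
    if cls == "SO":
        # far from every gene on either strand
        return no_as and all(
            d is None or d >= 2000 + margin
            for d in (geo.d5s_stop, geo.d3s, geo.d5a, geo.d3a)
        )
    raise ParameterError(f"unknown class {cls!r}")


def _write_signals(
    seqs: dict[str, np.ndarray],
    pl: _Planted,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    arr = seqs[pl.chrom]
    hexamer = None
    if pl.hexamer_class == "AATAAA":
        hexamer = CANONICAL_PAS
    elif pl.hexamer_class == "VARIANT_1NT":
        variants = enumerate_variants()
        hexamer = variants[rng.integers(len(variants))]
    _scrub_pas_window(arr, pl.pos, pl.strand)
    if hexamer is not None:
        _write_oriented(arr, pl.pos, pl.strand, _HEXAMER_OFFSET, hexamer)
    downstream = _ARTIFACT_DOWNSTREAM if pl.is_artifact else None
    if downstream is None and pl.planted_class == "A":
        downstream = _SAFE_DOWNSTREAM
    if downstream is not None:
        _write_oriented(arr, pl.pos, pl.strand, 0, downstream)


_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _write_oriented(arr: np.ndarray, pos: int, strand: str, offset: int, seq: str) -> None:
    """Write *seq* so it reads 5'->3' on the site's strand starting at the
    transcription-relative *offset* from the junction."""
    n = len(seq)
    if strand == "+":
        s = pos + offset
        if 0 <= s and s + n <= arr.size:
            arr[s : s + n] = list(seq)
    else:
        e = pos - offset  # offset<0 -> region [e, e+n) on genomic axis
        if 0 <= e - n and e <= arr.size:
            arr[e - n : e] = [_RC[c] for c in reversed(seq)]


def _scrub_pas_window(arr: np.ndarray, pos: int, strand: str) -> None:
    """Remove chance AATAAA/variant matches from the upstream 50 nt."""
    bad = {CANONICAL_PAS, *enumerate_variants()}
    for _ in range(10):
        if strand == "+":
            lo, hi = max(pos - 50, 0), pos
            window = "".join(arr[lo:hi])
        else:
            lo, hi = pos, min(pos + 50, arr.size)
            window = "".join(_RC[c] for c in arr[lo:hi][::-1])
        hit = next(
            (i for i in range(len(window) - 5) if window[i : i + 6] in bad), None
        )
        if hit is None:
            return
        # flip the middle base of the offending hexamer to C
        if strand == "+":
            arr[lo + hit + 3] = "C"
        else:
            arr[hi - 1 - (hit + 3)] = "G"


def _emit_tags(
    pl: _Planted, cfg: SimulationConfig, rng: np.random.Generator, clen: int
) -> list[CleavageSite]:
    extra_mean = max(cfg.tags_per_site_mean - cfg.tags_per_site_min, 0.0)
    n_total = cfg.tags_per_site_min + int(rng.poisson(extra_mean))
    n_jitter = min(2, n_total - cfg.tags_per_site_min, cfg.microhet_jitter_nt)
    n_jitter = max(n_jitter, 0)
    sites = []
    used = {pl.pos}
    for _ in range(n_jitter):
        off = int(rng.integers(1, cfg.microhet_jitter_nt + 1))
        q = pl.pos + (off if rng.random() < 0.5 else -off)
        if q in used or not (0 <= q <= clen):
            continue
        used.add(q)
        sites.append(CleavageSite(pl.chrom, q, pl.strand, 1))
    sites.append(CleavageSite(pl.chrom, pl.pos, pl.strand, n_total - len(sites)))
    pl.n_tags = n_total
    return sites


# ---------------------------------------------------------------------------
# File output


def write_fasta(seqs: dict[str, np.ndarray], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            s = "".join(seqs[chrom])
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_truth_tsv(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def simulate(cfg: SimulationConfig, outdir: str) -> dict[str, str]:
    """Run the full simulation and write GFF3 + FASTA + tag BED + truth TSV."""
    import os

    from .pat_processing import write_sites_bed

    os.makedirs(outdir, exist_ok=True)
    ann, seqs = simulate_genome(cfg)
    sites, truth = simulate_tags(ann, seqs, cfg)
    paths = {
        "gff3": os.path.join(outdir, "genome.gff3"),
        "fasta": os.path.join(outdir, "genome.fa"),
        "tags": os.path.join(outdir, "tags.bed"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "chrom_sizes": os.path.join(outdir, "chrom.sizes"),
    }
    ann.to_gff3(paths["gff3"])
    write_fasta(seqs, paths["fasta"])
    write_sites_bed(sites, paths["tags"])
    write_truth_tsv(truth, paths["truth"])
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, ln in sorted(ann.chrom_lengths.items()):
            fh.write(f"{chrom}\t{ln}\n")
    return paths
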