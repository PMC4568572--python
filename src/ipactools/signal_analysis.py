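"""Base-composition profiles around cleavage sites and poly(A)-signal classes.

Profiles cover transcription-relative positions -up..+down-1 around each
junction (default -300..+99, i.e. 300 nt upstream and 100 nt downstream).
Poly(A) signals are classed as the canonical AATAAA hexamer, its 18
single-substitution variants, or no signal, scanning a fixed upstream
window.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError

CANONICAL_PAS = "AATAAA"
DEFAULT_UP = 300
DEFAULT_DOWN = 100
DEFAULT_PAS_WINDOW = (-50, -1)

_BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class CompositionProfile:
    positions: np.ndarray  # transcription-relative offsets
    freq: np.ndarray  # (n_positions, 4) fractions of A,C,G,T; NaN where no data
    n_obs: np.ndarray  # observations per position
    n_excluded: int  # site/position pairs lost to chromosome edges

    def base_freq(self, base: str) -> np.ndarray:
        return self.freq[:, _BASES.index(base.upper())]


def _oriented_window(genome, chrom: str, strand: str, pos: int, up: int, down: int) -> str:
    """Sequence at transcription-relative offsets [-up, down) around junction
    *pos*, padded with N where it runs off the chromosome."""
    rec = genome[chrom]
    clen = len(rec)
    if strand == "+":
        s, e = pos - up, pos + down
        seq = str(rec[max(s, 0) : min(e, clen)]).upper()
        return "N" * max(-s, 0) + seq + "N" * max(e - clen, 0)
    s, e = pos - down, pos + up
    seq = str(rec[max(s, 0) : min(e, clen)]).upper()
    seq = "N" * max(-s, 0) + seq + "N" * max(e - clen, 0)
    return _revcomp(seq)


def composition_profile(
    sites: Sequence[tuple[str, int, str]],
    genome,
    up: int = DEFAULT_UP,
    down: int = DEFAULT_DOWN,
) -> CompositionProfile:
    """Per-position base fractions over all sites, strand-oriented.

    *sites* is a sequence of (chrom, junction_pos, strand).  Positions with
    no observations (all sites off the chromosome there) carry NaN, not 0.
    """
    if up < 0 or down < 0:
        raise ParameterError("window sizes must be >= 0")
    n_pos = up + down
    counts = np.zeros((n_pos, 4), dtype=np.int64)
    excluded = 0
    for chrom, pos, strand in sites:
        window = _oriented_window(genome, chrom, strand, pos, up, down)
        for i, ch in enumerate(window):
            j = _BASES.find(ch)
            if j >= 0:
                counts[i, j] += 1
            else:
                excluded += 1
    n_obs = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / n_obs[:, None]
    freq[n_obs == 0] = np.nan
    return CompositionProfile(np.arange(-up, down), freq, n_obs, excluded)


class PASClassLabel(str, Enum):
    AATAAA = "AATAAA"
    VARIANT_1NT = "VARIANT_1NT"
    NOPAS = "NOPAS"


@dataclass
class PASClass:
    label: PASClassLabel
    hexamer: Optional[str] = None
    offset: Optional[int] = None  # transcription-relative start of the match


def enumerate_variants() -> list[str]:
    """The 18 hexamers at Hamming distance exactly 1 from AATAAA."""
    out = []
    for i in range(6):
        for b in _BASES:
            if b != CANONICAL_PAS[i]:
                out.append(CANONICAL_PAS[:i] + b + CANONICAL_PAS[i + 1 :])
    return out


def classify_pas(
    site: tuple[str, int, str],
    genome,
    search_window: tuple[int, int] = DEFAULT_PAS_WINDOW,
) -> PASClass:
    """Scan the upstream window for AATAAA, then 1-nt variants, else NOPAS.

    ``search_window`` is (lo, hi) of transcription-relative hexamer start
    offsets, e.g. (-50, -1) searches hexamers starting at -50..-6 so the
    match lies fully within -50..-1.  The canonical hexamer wins over any
    variant regardless of position; within a class the leftmost match wins.
    """
    lo, hi = search_window
    if lo > hi:
        raise ParameterError("search window inverted")
    chrom, pos, strand = site
    up = -lo
    seq = _oriented_window(genome, chrom, strand, pos, up, 0)
    region = seq[: hi - lo + 1]  # offsets lo..hi inclusive
    idx = region.find(CANONICAL_PAS)
    if idx >= 0:
        return PASClass(PASClassLabel.AATAAA, CANONICAL_PAS, lo + idx)
    variants = set(enumerate_variants())
    for i in range(len(region) - 5):
        hexamer = region[i : i + 6]
        if hexamer in variants:
            return PASClass(PASClassLabel.VARIANT_1NT, hexamer, lo + i)
    return PASClass(PASClassLabel.NOPAS)


def pas_class_counts(
    sites: Sequence[tuple[str, int, str]],
    genome,
    search_window: tuple[int, int] = DEFAULT_PAS_WINDOW,
) -> dict[str, int]:
    counts = {c.value: 0 for c in PASClassLabel}
    for s in sites:
        counts[classify_pas(s, genome, search_window).label.value] += 1
    return counts


def write_profile_tsv(profile: CompositionProfile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("position\tfA\tfC\tfG\tfT\tn_obs\n")
        for i, pos in enumerate(profile.positions):
            vals = "\t".join(
                "nan" if np.isnan(v) else f"{v:.6f}" for v in profile.freq[i]
            )
            fh.write(f"{pos}\t{vals}\t{int(profile.n_obs[i])}\n")
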