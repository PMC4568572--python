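"""Random intergenic background positions and the empirical distance FDR.

The FDR at distance d is the fraction of randomly sampled intergenic
positions lying within d of the anchor, evaluated on a 20-nt grid up to
2000 nt.  The denominator defaults to the total number of sampled positions
(the variant that is arithmetically consistent with the ratio the procedure
is calibrated against); restricting it to positions within the maximum
distance is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, SamplingError
from .genome_model import ExtendedAnnotation

DEFAULT_STEP = 20
DEFAULT_MAX_DISTANCE = 2000


@dataclass(frozen=True)
class BackgroundPosition:
    chrom: str
    pos: int
    strand: str


def sample_background(
    ann: ExtendedAnnotation, n: int, seed: int
) -> list[BackgroundPosition]:
    """Sample *n* positions uniformly over the union of intergenic intervals.

    Intervals are length-weighted; each position gets a uniformly random
    strand (the strand's own intergenic space is used for that strand).
    Deterministic under *seed*.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    intervals = list(ann.all_intergenic_intervals())
    lengths = np.array([e - s for _, _, s, e in intervals], dtype=float)
    if not intervals or lengths.sum() <= 0:
        raise SamplingError("annotation has no intergenic space")
    if n == 0:
        return []
    idx = rng.choice(len(intervals), size=n, p=lengths / lengths.sum())
    out = []
    for i in idx:
        chrom, strand, s, e = intervals[i]
        out.append(BackgroundPosition(chrom, int(rng.integers(s, e)), strand))
    return out


@dataclass
class FDRCurve:
    bin_edges: np.ndarray  # grid distances 0, step, ..., max_d
    bg_cum: np.ndarray  # background positions at distance <= d
    ipac_cum: np.ndarray
    n_bg_total: int
    fdr: np.ndarray

    def fdr_at(self, d: int) -> float:
        """FDR at the grid point covering distance d (exact grid hit expected)."""
        i = int(np.searchsorted(self.bin_edges, d, side="right")) - 1
        return float(self.fdr[max(i, 0)])


def fdr_curve(
    ipac_d,
    bg_d,
    step: int = DEFAULT_STEP,
    max_d: int = DEFAULT_MAX_DISTANCE,
    denominator: str = "all",
) -> FDRCurve:
    """Binned cumulative distance counts and the empirical FDR.

    ``denominator`` is ``all`` (total sampled background positions) or
    ``within_max`` (background positions within ``max_d``).
    """
    bg = np.asarray(list(bg_d), dtype=float)
    ip = np.asarray(list(ipac_d), dtype=float)
    if bg.size == 0:
        raise ParameterError("empty background: FDR curve undefined")
    if np.any(bg < 0) or (ip.size and np.any(ip < 0)):
        raise ParameterError("distances must be >= 0")
    grid = np.arange(0, max_d + step, step)
    bg_cum = np.array([(bg <= d).sum() for d in grid])
    ipac_cum = np.array([(ip <= d).sum() for d in grid])
    if denominator == "all":
        denom = bg.size
    elif denominator == "within_max":
        denom = int((bg <= max_d).sum())
        if denom == 0:
            raise ParameterError("no background positions within max_d")
    else:
        raise ParameterError(f"unknown denominator {denominator!r}")
    return FDRCurve(grid, bg_cum, ipac_cum, int(bg.size), bg_cum / denom)


def select_cutoff(curve: FDRCurve, alpha: float = 0.1) -> int:
    """Largest grid distance with FDR strictly below *alpha* (0 if none)."""
    if not (0 < alpha <= 1):
        raise ParameterError("alpha must be in (0, 1]")
    ok = np.nonzero(curve.fdr < alpha)[0]
    return int(curve.bin_edges[ok[-1]]) if ok.size else 0


def write_curve_tsv(curve: FDRCurve, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("distance\tbg_cum\tipac_cum\tfdr\n")
        for d, b, i, f in zip(curve.bin_edges, curve.bg_cum, curve.ipac_cum, curve.fdr):
            fh.write(f"{int(d)}\t{int(b)}\t{int(i)}\t{f:.6f}\n")


def write_background_bed(positions, path: str) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(positions):
            fh.write(f"{p.chrom}\t{p.pos}\t{p.pos + 1}\tbg_{i}\t0\t{p.strand}\n")
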