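"""Genome layout: the shared coordinate frame of binned copy-number profiles.

All profiles, segments and recurrent regions in this package live on a
:class:`GenomeLayout` — an ordered set of chromosomes partitioned into
fixed-width bins (default 100 kb), each chromosome split into a p and a q arm
at a per-chromosome arm boundary. Bin indices are 0-based and half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeLayout", "make_genome_layout", "scaled_human_layout"]

# hg19 autosome lengths and approximate centromere midpoints, in Mb.  Used
# only to build a realistically proportioned default layout.
_HG19_AUTOSOME_MB = {
    "1": 249.25, "2": 243.20, "3": 198.02, "4": 191.15, "5": 180.92,
    "6": 171.12, "7": 159.14, "8": 146.36, "9": 141.21, "10": 135.53,
    "11": 135.01, "12": 133.85, "13": 115.17, "14": 107.35, "15": 102.53,
    "16": 90.35, "17": 81.20, "18": 78.08, "19": 59.13, "20": 63.03,
    "21": 48.13, "22": 51.30,
}
_HG19_CENTROMERE_MB = {
    "1": 125.0, "2": 93.3, "3": 91.0, "4": 50.4, "5": 48.4, "6": 61.0,
    "7": 59.9, "8": 45.6, "9": 49.0, "10": 40.2, "11": 53.7, "12": 35.8,
    "13": 17.9, "14": 17.6, "15": 19.0, "16": 36.6, "17": 24.0, "18": 17.2,
    "19": 26.5, "20": 27.5, "21": 13.2, "22": 14.7,
}


class LayoutError(ValueError):
    """Raised for invalid genome-layout parameters."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes partitioned into fixed-width bins.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, n_bins)`` pairs.
    arm_boundary:
        Per-chromosome bin index (chromosome-local) of the first q-arm bin;
        strictly inside ``(0, n_bins)``.
    bin_width:
        Bases per bin.
    """

    chromosomes: tuple[tuple[str, int], ...]
    arm_boundary: dict[str, int]
    bin_width: int = 100_000

    # derived, filled in __post_init__
    _offsets: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise LayoutError("layout needs at least one chromosome")
        if self.bin_width <= 0:
            raise LayoutError("bin_width must be positive")
        off = 0
        offsets = {}
        for name, n in self.chromosomes:
            if n < 2:
                raise LayoutError(f"chromosome {name}: need at least 2 bins, got {n}")
            b = self.arm_boundary.get(name)
            if b is None or not (0 < b < n):
                raise LayoutError(f"chromosome {name}: arm boundary {b} not inside (0, {n})")
            offsets[name] = off
            off += n
        object.__setattr__(self, "_offsets", offsets)

    @property
    def n_bins(self) -> int:
        return sum(n for _, n in self.chromosomes)

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def n_bins_of(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def offset(self, chrom: str) -> int:
        """Global bin index of the chromosome's first bin."""
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        o = self.offset(chrom)
        return slice(o, o + self.n_bins_of(chrom))

    def arm_bins(self, chrom: str, arm: str) -> tuple[int, int]:
        """Chromosome-local half-open bin range of an arm ('p' or 'q')."""
        n = self.n_bins_of(chrom)
        b = self.arm_boundary[chrom]
        if arm == "p":
            return 0, b
        if arm == "q":
            return b, n
        raise LayoutError(f"unknown arm {arm!r}")

    @property
    def arm_names(self) -> list[str]:
        return [f"{c}{a}" for c in self.chrom_names for a in ("p", "q")]

    def bin_table(self) -> pd.DataFrame:
        """One row per bin: chrom, start, end (bp, half-open) in layout order."""
        rows = []
        for name, n in self.chromosomes:
            idx = np.arange(n)
            rows.append(pd.DataFrame({
                "chrom": name,
                "start": idx * self.bin_width,
                "end": (idx + 1) * self.bin_width,
            }))
        return pd.concat(rows, ignore_index=True)

    def chrom_of_bins(self) -> np.ndarray:
        """Per global bin: integer chromosome index (layout order)."""
        return np.repeat(np.arange(len(self.chromosomes)),
                         [n for _, n in self.chromosomes])


def make_genome_layout(
    n_chromosomes: int | None = None,
    bins_per_chromosome: int | list[int] = 140,
    bin_width: int = 100_000,
    arm_boundaries: dict[str, int] | None = None,
    names: list[str] | None = None,
) -> GenomeLayout:
    """Build a layout of contiguous 0-based half-open bins.

    ``bins_per_chromosome`` may be a single count applied to every chromosome
    or a per-chromosome list (in which case ``n_chromosomes`` is optional).
    Arm boundaries default to the chromosome midpoint.
    """
    if isinstance(bins_per_chromosome, int):
        if n_chromosomes is None or n_chromosomes < 1:
            raise LayoutError("n_chromosomes must be >= 1")
        bins = [bins_per_chromosome] * n_chromosomes
    else:
        bins = list(bins_per_chromosome)
        if n_chromosomes is not None and n_chromosomes != len(bins):
            raise LayoutError("n_chromosomes disagrees with bins_per_chromosome")
    if any(b < 2 for b in bins):
        raise LayoutError("every chromosome needs at least 2 bins")
    if names is None:
        names = [str(i + 1) for i in range(len(bins))]
    chroms = tuple(zip(names, bins))
    if arm_boundaries is None:
        arm_boundaries = {name: max(1, n // 2) for name, n in chroms}
    return GenomeLayout(chromosomes=chroms, arm_boundary=dict(arm_boundaries),
                        bin_width=bin_width)


def scaled_human_layout(scale: float = 0.1, bin_width: int = 100_000) -> GenomeLayout:
    """22-autosome layout proportioned like hg19, linearly scaled.

    At the default ``scale=0.1`` with 100 kb bins the genome has ~2,900 bins
    (about one tenth of the human autosomes at 100 kb resolution), which keeps
    whole-cohort simulations fast while preserving relative chromosome and
    arm sizes.
    """
    if scale <= 0:
        raise LayoutError("scale must be positive")
    names, bins, arm = [], [], {}
    for name, mb in _HG19_AUTOSOME_MB.items():
        n = max(2, round(mb * 1e6 * scale / bin_width))
        b = round(_HG19_CENTROMERE_MB[name] * 1e6 * scale / bin_width)
        names.append(name)
        bins.append(n)
        arm[name] = min(max(1, b), n - 1)
    return GenomeLayout(chromosomes=tuple(zip(names, bins)),
                        arm_boundary=arm, bin_width=bin_width)
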