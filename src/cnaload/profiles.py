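"""Binned read counts -> logR profiles -> QC -> segments -> copy-number load.

The shallow-sequencing signal model: reads are counted in fixed-width genomic
bins; each bin's count is divided by the profile median and log2-transformed
into a logR value (0 = diploid).  Profiles are screened by two QC rules
(mapped reads > 1e6 and MAPD < 0.4), segmented per chromosome into
piecewise-constant segments by penalized binary segmentation, and each
segment mean is discretized into one of five copy-number calls::

    t < -1.3          homozygous_deletion   (code -2)
    -1.3 <= t < -0.1  loss                  (code -1)
    -0.1 <= t <= 0.1  diploid               (code  0)
    0.1 <  t <= 0.9   gain                  (code +1)
    t > 0.9           amplification         (code +2)

Copy-number load per sample is summarized as the fraction of bins in
non-neutral segments (|mean logR| > 0.1) and the number of internal
segment boundaries (breakpoints).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeLayout

__all__ = [
    "LogRProfile", "Segment", "SegmentedProfile", "LoadSummary",
    "counts_to_logr", "qc_sample", "segment_profile", "call_segments",
    "summarize_load", "call_label", "call_code", "CALL_LABELS",
]

NEUTRAL_BAND = 0.1
AMP_HIGH = 0.9
DEL_LOW = -1.3
MIN_MAPPED_READS = 1_000_000
MAPD_MAX = 0.4

CALL_LABELS = {
    -2: "homozygous_deletion",
    -1: "loss",
    0: "diploid",
    1: "gain",
    2: "amplification",
}


class ProfileError(ValueError):
    pass


@dataclass
class LogRProfile:
    """Per-bin log2 ratio values for one sample on a layout."""

    sample_id: str
    layout: GenomeLayout
    logr: np.ndarray            # imputed, finite, length = layout.n_bins
    n_mapped_reads: int
    missing: np.ndarray = None  # bool mask of zero-count bins
    mapd: float = field(default=None)

    def __post_init__(self):
        self.logr = np.asarray(self.logr, dtype=float)
        if self.logr.shape != (self.layout.n_bins,):
            raise ProfileError("logr length does not match layout")
        if self.missing is None:
            self.missing = np.zeros(self.layout.n_bins, dtype=bool)
        if self.mapd is None:
            self.mapd = compute_mapd(self.logr, self.layout, self.missing)


@dataclass
class Segment:
    chrom: str
    start_bin: int   # chromosome-local, half-open
    end_bin: int
    mean_logr: float
    call: str | None = None

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


@dataclass
class SegmentedProfile:
    sample_id: str
    layout: GenomeLayout
    segments: list[Segment]

    def bin_means(self) -> np.ndarray:
        """Per-bin segment-mean logR over the whole genome (global bins)."""
        out = np.empty(self.layout.n_bins)
        for seg in self.segments:
            off = self.layout.offset(seg.chrom)
            out[off + seg.start_bin: off + seg.end_bin] = seg.mean_logr
        return out

    def n_segments_of(self, chrom: str) -> int:
        return sum(1 for s in self.segments if s.chrom == chrom)


@dataclass(frozen=True)
class LoadSummary:
    n_breakpoints: int
    altered_fraction: float


def counts_to_logr(binned_counts, layout: GenomeLayout, sample_id: str = "sample",
                   n_mapped_reads: int | None = None) -> LogRProfile:
    """Median-normalize binned read counts into a logR profile.

    ``logr_i = log2(count_i / median positive count)``.  Zero-count bins are
    flagged missing and imputed with the median logR of the informative bins
    so segmentation sees a finite vector; they are excluded from MAPD.
    """
    counts = np.asarray(binned_counts, dtype=float)
    if counts.shape != (layout.n_bins,):
        raise ProfileError("counts length does not match layout")
    if np.any(counts < 0):
        raise ProfileError("counts must be non-negative")
    positive = counts > 0
    if not positive.any():
        raise ProfileError("no signal: all bins have zero reads")
    med = np.median(counts[positive])
    logr = np.full(layout.n_bins, np.nan)
    logr[positive] = np.log2(counts[positive] / med)
    missing = ~positive
    if missing.any():
        logr[missing] = np.median(logr[positive])
    if n_mapped_reads is None:
        n_mapped_reads = int(counts.sum())
    return LogRProfile(sample_id=sample_id, layout=layout, logr=logr,
                       n_mapped_reads=n_mapped_reads, missing=missing)


def compute_mapd(logr: np.ndarray, layout: GenomeLayout,
                 missing: np.ndarray | None = None, stat: str = "mean") -> float:
    """Noise metric: absolute deviation between adjacent within-chromosome bins.

    ``stat='mean'`` (default) averages |logR_{i+1} - logR_i|; ``stat='median'``
    gives the classic median-based variant.  Pairs touching a missing bin are
    dropped.  Returns NaN when no valid pair exists.
    """
    diffs = []
    for chrom, n in layout.chromosomes:
        sl = layout.chrom_slice(chrom)
        x = logr[sl]
        d = np.abs(np.diff(x))
        if missing is not None:
            m = missing[sl]
            keep = ~(m[:-1] | m[1:])
            d = d[keep]
        diffs.append(d)
    d = np.concatenate(diffs) if diffs else np.array([])
    if d.size == 0:
        return float("nan")
    return float(np.mean(d) if stat == "mean" else np.median(d))


def qc_sample(profile: LogRProfile) -> dict:
    """Apply the two shallow-seq QC rules.

    Pass requires more than one million mapped reads AND MAPD below 0.4.
    Returns ``{'pass': bool, 'reasons': [...], 'mapd': float,
    'n_mapped_reads': int}``.
    """
    reasons = []
    if not profile.n_mapped_reads > MIN_MAPPED_READS:
        reasons.append(f"mapped reads {profile.n_mapped_reads} <= {MIN_MAPPED_READS}")
    mapd = profile.mapd
    if np.isnan(mapd):
        reasons.append("MAPD undefined (no adjacent bin pairs)")
    elif not mapd < MAPD_MAX:
        reasons.append(f"MAPD {mapd:.3f} >= {MAPD_MAX}")
    return {"pass": not reasons, "reasons": reasons, "mapd": mapd,
            "n_mapped_reads": profile.n_mapped_reads}


# ---------------------------------------------------------------------------
# segmentation

def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Best single changepoint of x by residual-sum-of-squares reduction.

    Returns (split index m in 1..n-1, RSS gain).  The gain of splitting at m
    is n1*n2/n * (mean_left - mean_right)^2, computed for all m at once.
    """
    n = x.size
    cs = np.cumsum(x)
    n1 = np.arange(1, n)
    n2 = n - n1
    mean1 = cs[:-1] / n1
    mean2 = (cs[-1] - cs[:-1]) / n2
    gain = n1 * n2 / n * (mean1 - mean2) ** 2
    m = int(np.argmax(gain))
    return m + 1, float(gain[m])


def _binary_segment(x: np.ndarray, threshold: float) -> list[int]:
    """Recursive binary segmentation; returns sorted internal breakpoints.

    A split is accepted while its RSS gain strictly exceeds ``threshold``.
    """
    breaks: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 2:
            return
        m, gain = _best_split(x[lo:hi])
        if gain > threshold:
            breaks.append(lo + m)
            recurse(lo, lo + m)
            recurse(lo + m, hi)

    recurse(0, x.size)
    return sorted(breaks)


def _exhaustive_segment(x: np.ndarray, threshold: float, max_breaks: int = 2) -> list[int]:
    """Oracle: global minimizer of RSS + threshold * n_breaks over all
    partitions with at most ``max_breaks`` breakpoints (ties -> fewer breaks).

    Brute force; intended for small vectors in tests.
    """
    from itertools import combinations

    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def rss(lo, hi):
        s = cs[hi] - cs[lo]
        s2 = cs2[hi] - cs2[lo]
        return s2 - s * s / (hi - lo)

    best_cost, best = rss(0, n), []
    for k in range(1, max_breaks + 1):
        for combo in combinations(range(1, n), k):
            bounds = [0, *combo, n]
            cost = sum(rss(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
            cost += threshold * k
            if cost < best_cost - 1e-12:
                best_cost, best = cost, list(combo)
    return best


def _noise_sigma(logr: np.ndarray, layout: GenomeLayout,
                 missing: np.ndarray | None = None) -> float:
    """Robust per-profile noise SD from adjacent within-chromosome differences.

    For i.i.d. Gaussian noise the differences are N(0, 2 sigma^2), so
    sigma = median|d| / (0.6745 * sqrt(2)).  Robust to a minority of true
    breakpoints among the differences.
    """
    med = compute_mapd(logr, layout, missing, stat="median")
    if np.isnan(med):
        return 0.0
    return med / (0.6745 * np.sqrt(2.0))


def segment_profile(profile: LogRProfile, penalty: float = 2.0) -> SegmentedProfile:
    """Segment a logR profile per chromosome into piecewise-constant segments.

    Recursive binary segmentation with a BIC-like acceptance threshold
    ``penalty * log(n_bins_chrom) * sigma_hat^2`` per breakpoint, where
    sigma_hat is the robust profile noise SD.  Noiseless profiles therefore
    split exactly at their true changepoints and constant profiles stay as
    one segment per chromosome.
    """
    sigma2 = _noise_sigma(profile.logr, profile.layout, profile.missing) ** 2
    segments: list[Segment] = []
    for chrom, n in profile.layout.chromosomes:
        if n == 0:
            warnings.warn(f"chromosome {chrom} is empty; skipped")
            continue
        x = profile.logr[profile.layout.chrom_slice(chrom)]
        threshold = penalty * np.log(n) * sigma2
        breaks = _binary_segment(x, threshold)
        bounds = [0, *breaks, n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            segments.append(Segment(chrom, a, b, float(np.mean(x[a:b]))))
    return SegmentedProfile(profile.sample_id, profile.layout, segments)


# ---------------------------------------------------------------------------
# five-level discretization and load summary

def call_code(t: float) -> int:
    """Five-level integer code of a segment-mean logR value ``t``.

    Boundary convention exactly as the threshold table: -0.1 and 0.1 belong
    to diploid; -1.3 belongs to loss; 0.9 belongs to gain.
    """
    if t < DEL_LOW:
        return -2
    if t < -NEUTRAL_BAND:
        return -1
    if t <= NEUTRAL_BAND:
        return 0
    if t <= AMP_HIGH:
        return 1
    return 2


def call_label(t: float) -> str:
    return CALL_LABELS[call_code(t)]


def call_segments(segmented: SegmentedProfile,
                  neutral_band: float = NEUTRAL_BAND,
                  amp_high: float = AMP_HIGH,
                  del_low: float = DEL_LOW) -> SegmentedProfile:
    """Assign one of the five copy-number labels to each segment (in place)."""
    for seg in segmented.segments:
        t = seg.mean_logr
        if not np.isfinite(t):
            raise ProfileError("segment mean is not finite")
        if t < del_low:
            seg.call = "homozygous_deletion"
        elif t < -neutral_band:
            seg.call = "loss"
        elif t <= neutral_band:
            seg.call = "diploid"
        elif t <= amp_high:
            seg.call = "gain"
        else:
            seg.call = "amplification"
    return segmented


def summarize_load(segmented: SegmentedProfile,
                   neutral_band: float = NEUTRAL_BAND) -> LoadSummary:
    """Fraction of bins in non-neutral segments and number of breakpoints.

    A bin is altered when its segment mean is outside the +/-``neutral_band``
    logR band.  Breakpoints are internal segment boundaries, i.e.
    (number of segments) - (number of chromosomes) for a tiling segmentation.
    """
    total = segmented.layout.n_bins
    altered = sum(s.n_bins for s in segmented.segments
                  if abs(s.mean_logr) > neutral_band)
    n_chroms = len({s.chrom for s in segmented.segments})
    n_breaks = len(segmented.segments) - n_chroms
    return LoadSummary(n_breakpoints=n_breaks, altered_fraction=altered / total)


def write_seg(profiles: list[SegmentedProfile], path) -> None:
    """Write segments of one or more samples in IGV SEG format (TSV)."""
    import pandas as pd
    rows = []
    for sp in profiles:
        bw = sp.layout.bin_width
        for s in sp.segments:
            rows.append((sp.sample_id, s.chrom, s.start_bin * bw, s.end_bin * bw,
                         s.n_bins, s.mean_logr))
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                "n_bins", "mean_logr"]).to_csv(
        path, sep="\t", index=False)
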