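"""Recurrent copy-number alterations across a cohort.

The recurrence score of a bin in a given direction is the canonical
frequency-times-amplitude sum

    G_amp(bin) = sum_samples max(0, mean_logr - 0.1)
    G_del(bin) = sum_samples max(0, -mean_logr - 0.1)

i.e. each sample contributes the amplitude by which its segment mean exceeds
the neutral +/-0.1 band.  Significance is assessed against a permutation null
in which every sample's called-segment track is circularly shifted within
each chromosome by an independent uniform offset, preserving the per-sample
number and length of events.  Per-bin empirical p-values (observed G against
the per-chromosome null maximum) are Benjamini-Hochberg adjusted; significant
bins are merged into maximal runs and trimmed to their peak core.  Regions
are classified focal vs whole-arm by the >70%-of-arm rule.

Arm-level recurrent aberrations are additionally emitted as one feature per
chromosome arm whose median call is non-diploid in at least 25% of samples,
mirroring the two feature families (focal and whole-arm) used for clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from .profiles import NEUTRAL_BAND, SegmentedProfile, call_code

__all__ = [
    "RecurrentRegion", "CallMatrix", "CohortSegments", "stack_segment_means",
    "per_bin_scores", "permutation_null", "detect_recurrent_regions",
    "classify_span", "arm_level_features", "build_call_matrix",
]


class RecurrenceError(ValueError):
    pass


@dataclass
class RecurrentRegion:
    """A recurrently altered genomic interval (chromosome-local bins)."""

    region_id: str
    chrom: str
    start_bin: int
    end_bin: int
    direction: str               # 'amp' or 'del'
    frequency: float
    g_score: float
    q_value: float
    span_class: str | None = None  # 'focal' or 'whole_arm'

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


@dataclass
class CohortSegments:
    """Stacked per-bin segment means for a segmented cohort."""

    layout: GenomeLayout
    sample_ids: list[str]
    bin_means: np.ndarray  # (n_samples, n_bins)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def stack_segment_means(profiles: list[SegmentedProfile]) -> CohortSegments:
    if not profiles:
        raise RecurrenceError("empty cohort")
    layout = profiles[0].layout
    B = np.vstack([p.bin_means() for p in profiles])
    return CohortSegments(layout=layout, sample_ids=[p.sample_id for p in profiles],
                          bin_means=B)


def _amplitudes(B: np.ndarray, band: float = NEUTRAL_BAND):
    amp = np.maximum(0.0, B - band)
    dele = np.maximum(0.0, -B - band)
    return amp, dele


def per_bin_scores(cohort: CohortSegments, band: float = NEUTRAL_BAND) -> pd.DataFrame:
    """Per-bin amplification and deletion G-scores over the cohort."""
    if cohort.n_samples == 0:
        raise RecurrenceError("empty cohort")
    amp, dele = _amplitudes(cohort.bin_means, band)
    return pd.DataFrame({"g_amp": amp.sum(axis=0), "g_del": dele.sum(axis=0)})


def permutation_null(cohort: CohortSegments, n_perm: int = 200,
                     seed: int | None = None,
                     band: float = NEUTRAL_BAND) -> dict:
    """Null distribution of the per-chromosome maximum G-score.

    Each permutation circularly shifts every sample's per-bin amplitude track
    (both directions together) by an independent uniform offset within each
    chromosome, then records the maximum summed G per chromosome and
    direction.  Returns ``{'amp': (n_perm, n_chroms), 'del': ...,
    'chroms': [...]}``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation q-values will be unstable")
    rng = np.random.default_rng(seed)
    amp, dele = _amplitudes(cohort.bin_means, band)
    n_samples = cohort.n_samples
    chroms = cohort.layout.chrom_names
    out_amp = np.zeros((n_perm, len(chroms)))
    out_del = np.zeros((n_perm, len(chroms)))
    for ci, chrom in enumerate(chroms):
        sl = cohort.layout.chrom_slice(chrom)
        a = amp[:, sl]
        d = dele[:, sl]
        nb = a.shape[1]
        base = np.arange(nb)[None, :]
        for p in range(n_perm):
            offsets = rng.integers(0, nb, size=n_samples)[:, None]
            idx = (base + offsets) % nb
            ga = np.take_along_axis(a, idx, axis=1).sum(axis=0)
            gd = np.take_along_axis(d, idx, axis=1).sum(axis=0)
            out_amp[p, ci] = ga.max()
            out_del[p, ci] = gd.max()
    return {"amp": out_amp, "del": out_del, "chroms": chroms}


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (monotone)."""
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def detect_recurrent_regions(scores: pd.DataFrame, null: dict,
                             cohort: CohortSegments,
                             q_cutoff: float = 0.25,
                             peak_fraction: float = 0.95,
                             band: float = NEUTRAL_BAND) -> list[RecurrentRegion]:
    """Call recurrently amplified/deleted regions at a q-value cutoff.

    Per-bin empirical p = (1 + #{null chrom-max >= observed G}) / (1 + n_perm)
    against the null of the bin's own chromosome; p-values of both directions
    are pooled for Benjamini-Hochberg adjustment.  Significant bins are merged
    into maximal same-direction runs per chromosome, and each run is trimmed
    to the contiguous core around its peak whose G stays within
    ``peak_fraction`` of the run maximum.
    """
    layout = cohort.layout
    chrom_idx = layout.chrom_of_bins()
    n_perm = null["amp"].shape[0]
    pvals = {}
    for direction, col in (("amp", "g_amp"), ("del", "g_del")):
        g = scores[col].to_numpy()
        nullmax = null[direction][:, chrom_idx]            # (n_perm, n_bins)
        exceed = (nullmax >= g[None, :]).sum(axis=0)
        pvals[direction] = (1.0 + exceed) / (1.0 + n_perm)
    pooled = np.concatenate([pvals["amp"], pvals["del"]])
    q_pooled = _bh_adjust(pooled)
    nb = layout.n_bins
    qvals = {"amp": q_pooled[:nb], "del": q_pooled[nb:]}

    B = cohort.bin_means
    freq = {"amp": (B > band).mean(axis=0), "del": (B < -band).mean(axis=0)}

    regions: list[RecurrentRegion] = []
    for direction in ("amp", "del"):
        g = scores["g_amp" if direction == "amp" else "g_del"].to_numpy()
        sig = (qvals[direction] < q_cutoff) & (g > 0)
        for chrom in layout.chrom_names:
            sl = layout.chrom_slice(chrom)
            s = sig[sl]
            if not s.any():
                continue
            gs = g[sl]
            qs = qvals[direction][sl]
            fs = freq[direction][sl]
            # maximal runs of significant bins
            edges = np.flatnonzero(np.diff(np.concatenate([[0], s.view(np.int8), [0]])))
            for a, b in zip(edges[::2], edges[1::2]):
                # trim to contiguous peak core within peak_fraction of run max
                peak = a + int(np.argmax(gs[a:b]))
                level = peak_fraction * gs[peak]
                lo = peak
                while lo > a and gs[lo - 1] >= level:
                    lo -= 1
                hi = peak + 1
                while hi < b and gs[hi] >= level:
                    hi += 1
                rid = f"{direction}_{chrom}:{lo}-{hi}"
                regions.append(RecurrentRegion(
                    region_id=rid, chrom=chrom, start_bin=int(lo), end_bin=int(hi),
                    direction=direction,
                    frequency=float(fs[lo:hi].mean()),
                    g_score=float(gs[lo:hi].max()),
                    q_value=float(qs[lo:hi].min()),
                ))
    for r in regions:
        r.span_class = classify_span(r, layout)
    return regions


def classify_span(region: RecurrentRegion, layout: GenomeLayout,
                  arm_fraction: float = 0.70) -> str:
    """'whole_arm' iff the region covers strictly more than ``arm_fraction``
    of either arm of its chromosome, else 'focal'."""
    if region.chrom not in dict(layout.chromosomes):
        raise RecurrenceError(f"region chromosome {region.chrom} not in layout")
    n = layout.n_bins_of(region.chrom)
    if not (0 <= region.start_bin < region.end_bin <= n):
        raise RecurrenceError("region outside chromosome bounds")
    for arm in ("p", "q"):
        a, b = layout.arm_bins(region.chrom, arm)
        overlap = max(0, min(region.end_bin, b) - max(region.start_bin, a))
        if overlap / (b - a) > arm_fraction:
            return "whole_arm"
    return "focal"


def arm_level_features(cohort: CohortSegments, min_freq: float = 0.25,
                       band: float = NEUTRAL_BAND) -> list[RecurrentRegion]:
    """Whole-arm feature family: one feature per chromosome arm whose median
    per-bin call is non-diploid in at least ``min_freq`` of samples.

    Direction is the majority direction among altered samples.
    """
    layout = cohort.layout
    B = cohort.bin_means
    feats = []
    for chrom in layout.chrom_names:
        off = layout.offset(chrom)
        for arm in ("p", "q"):
            a, b = layout.arm_bins(chrom, arm)
            med = np.median(B[:, off + a: off + b], axis=1)
            n_amp = int((med > band).sum())
            n_del = int((med < -band).sum())
            freq = (n_amp + n_del) / cohort.n_samples
            if freq >= min_freq:
                direction = "amp" if n_amp >= n_del else "del"
                feats.append(RecurrentRegion(
                    region_id=f"arm_{chrom}{arm}_{direction}",
                    chrom=chrom, start_bin=a, end_bin=b, direction=direction,
                    frequency=freq, g_score=float("nan"), q_value=float("nan"),
                    span_class="whole_arm"))
    return feats


@dataclass
class CallMatrix:
    """Samples x recurrent-region matrix of five-level copy-number codes.

    Codes are integers in {-2, -1, 0, 1, 2}; the binary view marks any
    non-diploid code as altered.
    """

    codes: pd.DataFrame  # index = sample ids, columns = region ids

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def region_ids(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def binary(self) -> pd.DataFrame:
        return self.codes != 0

    def altered_fraction(self) -> pd.Series:
        """Per-sample fraction of regions altered (the CIN numerator)."""
        return self.binary.mean(axis=1)


def build_call_matrix(cohort: CohortSegments,
                      regions: list[RecurrentRegion]) -> CallMatrix:
    """Discretize each (sample, region) pair into a five-level code.

    The region-level signal per sample is the length-weighted mean of segment
    logR over the region's bins (with a tiling segmentation this is the mean
    of per-bin segment means), discretized by the five-level threshold table.
    """
    if not regions:
        raise RecurrenceError("no regions to build a call matrix from")
    layout = cohort.layout
    B = cohort.bin_means
    cols = {}
    for r in regions:
        off = layout.offset(r.chrom)
        m = B[:, off + r.start_bin: off + r.end_bin].mean(axis=1)
        cols[r.region_id] = np.array([call_code(t) for t in m], dtype=int)
    codes = pd.DataFrame(cols, index=cohort.sample_ids)
    return CallMatrix(codes=codes)


def regions_to_bed(regions: list[RecurrentRegion], layout: GenomeLayout, path) -> None:
    """Write regions as BED (bp coordinates) with score/direction/q columns."""
    bw = layout.bin_width
    rows = [(r.chrom, r.start_bin * bw, r.end_bin * bw, r.region_id,
             r.g_score, r.direction, r.q_value, r.frequency, r.span_class)
            for r in regions]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "g_score",
                                "direction", "q_value", "frequency",
                                "span_class"]).to_csv(path, sep="\t", index=False)
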