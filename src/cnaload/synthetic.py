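"""Synthetic cohort generator for the copy-number-load analysis.

Emulates the statistical structure the downstream pipeline assumes, so every
stage is testable without patient data:

* three CNA archetypes of strictly increasing genome-altered fraction
  (cluster 1 nearly copy-number quiet, cluster 2 intermediate, cluster 3
  high), each defined by a catalog of recurrently altered chromosome arms and
  focal regions with per-cluster alteration probabilities;
* cluster-specific mutation/MSI enrichment: the low-instability archetype is
  enriched for MSI, POLE/POLD1, BRAF and PIK3CA and depleted for TP53, the
  unstable archetypes the reverse;
* proportional-hazards survival (exponential by default, Weibull shape
  configurable) with clinical covariates, a chemotherapy-backbone term, a
  bevacizumab (BVZ) main effect and BVZ x cluster interaction terms, with
  administrative censoring at 60 months;
* xenograft tumor-volume series on a twice-weekly measurement grid.

Read counts per bin follow the purity mixture model: a bin with tumor copy
number c in a sample of purity rho has expected count
``depth * (rho * c + (1 - rho) * 2) / 2``, Poisson-sampled after
multiplicative log-normal noise on the logR scale.

Determinism: one global seed; per-sample substreams are derived from
(seed, sample index), so identical (config, seed) reproduce the cohort
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeLayout, scaled_human_layout

__all__ = [
    "CatalogRegion", "ClusterArchetype", "HazardModel", "CohortConfig",
    "SyntheticCohort", "default_archetypes", "default_hazard_model",
    "simulate_sample", "simulate_cohort", "simulate_xenograft_series",
    "simulate_exponential_survival",
]

DAYS_PER_MONTH = 30.4375


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CatalogRegion:
    """A recurrently altered interval of an archetype's event catalog."""

    region_id: str
    chrom: str
    start_bin: int          # chromosome-local, half-open
    end_bin: int
    direction: int          # +1 gain, -1 loss
    prob: float             # per-sample alteration probability
    copy_number: int        # tumor copies painted when the event fires


@dataclass
class ClusterArchetype:
    """One CNA cluster archetype: event catalog plus mutation profile."""

    label: int
    expected_altered_fraction: tuple[float, float]
    shared_region_catalog: list[CatalogRegion]
    n_events_range: tuple[int, int]          # random focal passengers
    event_length_range: tuple[int, int]      # passenger length in bins
    mutation_rates: dict[str, float]


# Direction of arm-level events.  The classic colorectal gains (1q, 7p, 8q,
# 13q, 20q) and losses (8p, 17p, 18q, 14q/15q/21q/22q) anchor the table; the
# remaining assignments balance gains against losses within each archetype so
# that even a heavily altered genome keeps diploid as its median state and
# median normalization of read counts stays valid.
_GAIN_ARMS = {"1q", "7p", "8q", "13q", "20q", "5p", "6p", "12p",
              "2p", "3q", "4p", "9q", "10p", "11q", "16p", "19p",
              "17q", "7q", "14p", "15p", "18p", "20p", "21p", "22p"}

# Arm sets recurrently altered in the intermediate- and high-instability
# archetypes.  Each set is direction-balanced, and high-probability
# same-direction events never sit on both arms of one chromosome — this
# keeps the within-chromosome circular-shift permutation null informative.
_CORE_ARMS = ["1q", "7p", "8q", "13q", "20q", "5p", "6p", "12p",
              "3p", "8p", "14q", "15q", "17p", "18q", "21q", "22q"]
_EXTENDED_ARMS = ["2p", "3q", "4p", "9q", "10p", "11q", "16p", "19p",
                  "1p", "2q", "4q", "5q", "6q", "10q", "11p", "12q"]
# Arms preferentially altered in the intermediate archetype only, so that
# cluster membership is not a pure function of copy-number load.
_CLUSTER2_ARMS = ["16q", "17q", "19q"]


def _arm_region(layout: GenomeLayout, arm_name: str, prob: float,
                rid_prefix: str) -> CatalogRegion:
    chrom, arm = arm_name[:-1], arm_name[-1]
    a, b = layout.arm_bins(chrom, arm)
    direction = 1 if arm_name in _GAIN_ARMS else -1
    copy = 3 if direction > 0 else 1
    return CatalogRegion(region_id=f"{rid_prefix}_{arm_name}",
                         chrom=chrom, start_bin=a, end_bin=b,
                         direction=direction, prob=prob, copy_number=copy)


def _focal_catalog(layout: GenomeLayout) -> list[dict]:
    """Focal event templates: (chrom, relative position, length, direction,
    copies, per-cluster probabilities).  A couple of regions are more frequent
    in the lower-instability archetypes so that cluster membership is not a
    pure function of load."""
    return [
        # driver-like focal events enriched in clusters 2+3, placed on arms
        # outside the recurrent arm sets so focal peaks and whole-arm events
        # stay resolvable as separate recurrent regions
        dict(chrom="7", at=0.75, length=6, direction=1, copy=6,
             probs={1: 0.02, 2: 0.40, 3: 0.50}),   # 7q focal amplicon
        dict(chrom="9", at=0.10, length=8, direction=-1, copy=0,
             probs={1: 0.02, 2: 0.45, 3: 0.55}),   # 9p homozygous deletion
        dict(chrom="13", at=0.05, length=5, direction=-1, copy=1,
             probs={1: 0.03, 2: 0.40, 3: 0.50}),
        dict(chrom="20", at=0.15, length=5, direction=1, copy=6,
             probs={1: 0.02, 2: 0.30, 3: 0.45}),   # 20p focal amplicon
        # cluster-2-leaning focal events
        dict(chrom="14", at=0.03, length=5, direction=1, copy=3,
             probs={1: 0.03, 2: 0.45, 3: 0.15}),
        dict(chrom="9", at=0.30, length=6, direction=-1, copy=1,
             probs={1: 0.03, 2: 0.40, 3: 0.12}),
        # cluster-3-leaning focal events
        dict(chrom="15", at=0.06, length=6, direction=1, copy=3,
             probs={1: 0.02, 2: 0.10, 3: 0.40}),
        dict(chrom="22", at=0.10, length=6, direction=1, copy=3,
             probs={1: 0.02, 2: 0.10, 3: 0.40}),
        # more frequent in cluster 1/2 than 3
        dict(chrom="21", at=0.15, length=4, direction=1, copy=3,
             probs={1: 0.25, 2: 0.12, 3: 0.05}),
        dict(chrom="18", at=0.05, length=5, direction=1, copy=3,
             probs={1: 0.20, 2: 0.10, 3: 0.05}),
    ]


# Per-archetype arm alteration probabilities.
_ARM_PROBS = {
    1: {"core": 0.02, "extended": 0.02, "cluster2": 0.02, "other": 0.02},
    2: {"core": 0.70, "extended": 0.08, "cluster2": 0.50, "other": 0.04},
    3: {"core": 0.80, "extended": 0.75, "cluster2": 0.08, "other": 0.15},
}

# Mutation / MSI enrichment pattern: the low-instability archetype carries
# the hypermutated phenotypes, the unstable archetypes carry TP53.
_MUTATION_RATES = {
    1: {"tp53": 0.25, "kras": 0.35, "braf": 0.30, "pik3ca": 0.35,
        "apc": 0.55, "pole_pold1": 0.15, "msi": 0.45, "hypermutator": 0.50},
    2: {"tp53": 0.65, "kras": 0.38, "braf": 0.07, "pik3ca": 0.18,
        "apc": 0.60, "pole_pold1": 0.01, "msi": 0.04, "hypermutator": 0.05},
    3: {"tp53": 0.72, "kras": 0.40, "braf": 0.05, "pik3ca": 0.15,
        "apc": 0.62, "pole_pold1": 0.01, "msi": 0.02, "hypermutator": 0.03},
}

_EXPECTED_ALTERED = {1: (0.01, 0.06), 2: (0.25, 0.45), 3: (0.45, 0.75)}
_PASSENGERS = {1: (0, 3), 2: (2, 6), 3: (3, 8)}


def default_archetypes(layout: GenomeLayout | None = None) -> dict[int, ClusterArchetype]:
    """The three default archetypes on a layout (default: scaled human)."""
    if layout is None:
        layout = scaled_human_layout()
    focal_templates = _focal_catalog(layout)
    archetypes = {}
    for label in (1, 2, 3):
        catalog: list[CatalogRegion] = []
        probs = _ARM_PROBS[label]
        for arm_name in layout.arm_names:
            if arm_name in _CORE_ARMS:
                p = probs["core"]
            elif arm_name in _EXTENDED_ARMS:
                p = probs["extended"]
            elif arm_name in _CLUSTER2_ARMS:
                p = probs["cluster2"]
            else:
                p = probs["other"]
            catalog.append(_arm_region(layout, arm_name, p, "arm"))
        for tmpl in focal_templates:
            n = layout.n_bins_of(tmpl["chrom"])
            start = int(tmpl["at"] * n)
            end = min(n, start + tmpl["length"])
            catalog.append(CatalogRegion(
                region_id=f"focal_{tmpl['chrom']}:{start}",
                chrom=tmpl["chrom"], start_bin=start, end_bin=end,
                direction=tmpl["direction"], prob=tmpl["probs"][label],
                copy_number=tmpl["copy"]))
        archetypes[label] = ClusterArchetype(
            label=label,
            expected_altered_fraction=_EXPECTED_ALTERED[label],
            shared_region_catalog=catalog,
            n_events_range=_PASSENGERS[label],
            event_length_range=(2, 10),
            mutation_rates=dict(_MUTATION_RATES[label]))
    _validate_archetypes(archetypes)
    return archetypes


def _validate_archetypes(archetypes: dict[int, ClusterArchetype]) -> None:
    fr = [np.mean(a.expected_altered_fraction) for a in
          (archetypes[1], archetypes[2], archetypes[3])]
    if not (fr[0] < fr[1] < fr[2]):
        raise SimulationError("altered fractions must strictly increase with label")
    m1, m2, m3 = (archetypes[k].mutation_rates for k in (1, 2, 3))
    for flag in ("msi", "pole_pold1", "braf", "pik3ca"):
        if not (m1[flag] > m2[flag] and m1[flag] > m3[flag]):
            raise SimulationError(f"archetype 1 must be enriched for {flag}")
    if not (m1["tp53"] < m2["tp53"] and m1["tp53"] < m3["tp53"]):
        raise SimulationError("archetype 1 must be depleted for tp53")


@dataclass
class HazardModel:
    """Proportional-hazards survival model for cohort simulation.

    Rates are per month.  Defaults reproduce the treatment-effect structure
    used throughout the analysis: moderate cluster prognostic effects, a BVZ
    effect confined to the unstable clusters (within-cluster BVZ hazard
    ratios of about 1.15, 0.58 and 0.69), and 60-month administrative
    censoring.  With all coefficients zero, survival is exchangeable across
    arms and clusters.
    """

    baseline_hazard: float = np.log(2) / 9.0        # cluster-1 reference PFS
    covariate_log_hazards: dict = field(default_factory=lambda: {
        "age": 0.010,        # per year over 63
        "t_stage": 0.08,
        "n_stage": 0.12,
        "m_stage": 0.25,
        "male": 0.0,
        "doublet": float(np.log(0.79)),
    })
    cluster_log_hazards: tuple = (0.0, float(np.log(0.48)), float(np.log(0.57)))
    treatment_log_hazard: float = float(np.log(1.15))
    interaction_log_hazards: tuple = (0.0,
                                      float(np.log(0.58) - np.log(1.15)),
                                      float(np.log(0.69) - np.log(1.15)))
    censoring_months: float = 60.0
    weibull_shape: float = 1.0
    os_baseline_hazard: float = np.log(2) / 22.0
    os_attenuation: float = 0.8

    def __post_init__(self):
        if self.baseline_hazard <= 0 or self.os_baseline_hazard <= 0:
            raise SimulationError("baseline hazards must be positive")
        if self.censoring_months <= 0:
            raise SimulationError("censoring cap must be positive")

    def null(self) -> "HazardModel":
        """Copy with all coefficients zero (exchangeable arms/clusters)."""
        return HazardModel(
            baseline_hazard=self.baseline_hazard,
            covariate_log_hazards={k: 0.0 for k in self.covariate_log_hazards},
            cluster_log_hazards=(0.0, 0.0, 0.0),
            treatment_log_hazard=0.0,
            interaction_log_hazards=(0.0, 0.0, 0.0),
            censoring_months=self.censoring_months,
            weibull_shape=self.weibull_shape,
            os_baseline_hazard=self.os_baseline_hazard,
            os_attenuation=self.os_attenuation)


def default_hazard_model() -> HazardModel:
    return HazardModel()


def simulate_exponential_survival(log_hazard, baseline_rate: float,
                                  censor_months: float | None, rng,
                                  shape: float = 1.0):
    """Draw survival times under a proportional-hazards model.

    ``T = (E / (baseline * exp(lp)))^(1/shape)`` with E ~ Exp(1); shape 1
    gives exponential times.  Returns (time_months, event) with
    administrative censoring at ``censor_months`` (None = no censoring).
    """
    lp = np.asarray(log_hazard, dtype=float)
    e = rng.exponential(1.0, size=lp.shape)
    t = (e / (baseline_rate * np.exp(lp))) ** (1.0 / shape)
    if censor_months is None:
        return t, np.ones(lp.shape, dtype=int)
    event = (t < censor_months).astype(int)
    return np.minimum(t, censor_months), event


# ---------------------------------------------------------------------------
# per-sample profile simulation

def simulate_sample(layout: GenomeLayout, archetype: ClusterArchetype,
                    purity: float = 0.8, depth: float = 400.0,
                    noise_sd: float = 0.12, seed=None):
    """Simulate one sample's binned read counts.

    Returns ``(counts, true_segments, flags)`` where ``true_segments`` is the
    run-length encoding of the noiseless tumor copy-number state (a list of
    ``(chrom, start_bin, end_bin, copy_number)`` tuples tiling the genome)
    and ``flags`` the mutation/MSI booleans plus the mutation rate per Mb.
    """
    if not (0 < purity <= 1):
        raise SimulationError(f"purity must be in (0, 1], got {purity}")
    if depth <= 0:
        raise SimulationError("depth must be positive")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    copy = np.full(layout.n_bins, 2, dtype=int)
    for region in archetype.shared_region_catalog:
        if rng.random() < region.prob:
            off = layout.offset(region.chrom)
            copy[off + region.start_bin: off + region.end_bin] = region.copy_number
    lo, hi = archetype.n_events_range
    n_passengers = int(rng.integers(lo, hi + 1))
    lmin, lmax = archetype.event_length_range
    for _ in range(n_passengers):
        ci = int(rng.integers(0, len(layout.chromosomes)))
        chrom, n = layout.chromosomes[ci]
        length = int(rng.integers(lmin, lmax + 1))
        start = int(rng.integers(0, max(1, n - length)))
        off = layout.offset(chrom)
        copy[off + start: off + start + length] = 3 if rng.random() < 0.5 else 1

    ratio = (purity * copy + (1 - purity) * 2) / 2.0
    lam = depth * ratio
    if noise_sd > 0:
        lam = lam * np.exp2(rng.normal(0.0, noise_sd, size=lam.shape))
    counts = rng.poisson(lam)

    true_segments = []
    for chrom, n in layout.chromosomes:
        sl = layout.chrom_slice(chrom)
        c = copy[sl]
        breaks = np.flatnonzero(np.diff(c)) + 1
        bounds = [0, *breaks.tolist(), n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            true_segments.append((chrom, int(a), int(b), int(c[a])))

    flags = {name: bool(rng.random() < p)
             for name, p in archetype.mutation_rates.items()}
    flags["mut_per_mb"] = float(rng.uniform(12, 60) if flags["hypermutator"]
                                else rng.uniform(0.5, 9))
    return counts, true_segments, flags


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass
class CohortConfig:
    n_samples: int = 908
    mixture_proportions: tuple = (0.187, 0.368, 0.445)
    seed: int = 0
    layout: GenomeLayout | None = None
    archetypes: dict[int, ClusterArchetype] | None = None
    hazard_model: HazardModel | None = None
    depth: float = 400.0
    noise_sd: float = 0.12
    purity_range: tuple = (0.4, 0.95)
    bvz_fraction: float = 185 / 409          # treatment arm assignment
    doublet_fraction: float = 0.93
    metastatic_probs: tuple = (0.25, 0.45, 0.52)  # stage-enrichment by cluster
    treatment_by_cluster: tuple | None = None     # confounding switch
    with_profiles: bool = True


@dataclass
class SyntheticCohort:
    layout: GenomeLayout
    clinical: pd.DataFrame             # one row per sample
    counts: np.ndarray | None          # (n_samples, n_bins) or None
    true_segments: list | None
    config: CohortConfig
    seed: int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical["sample_id"])

    def write(self, outdir) -> None:
        """Write bins.tsv (bins x samples counts), clinical.tsv, truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.counts is not None:
            bins = self.layout.bin_table()
            mat = pd.DataFrame(self.counts.T, columns=self.sample_ids)
            pd.concat([bins, mat], axis=1).to_csv(outdir / "bins.tsv",
                                                  sep="\t", index=False)
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
        truth = {
            "seed": self.seed,
            "n_samples": int(len(self.clinical)),
            "mixture_proportions": list(self.config.mixture_proportions),
            "true_cluster": {r.sample_id: int(r.true_cluster)
                             for r in self.clinical.itertuples()},
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


_T_STAGE_PROBS = {1: (0.05, 0.25, 0.55, 0.15),
                  2: (0.02, 0.18, 0.58, 0.22),
                  3: (0.02, 0.16, 0.58, 0.24)}
_N_STAGE_PROBS = {1: (0.40, 0.35, 0.25),
                  2: (0.28, 0.37, 0.35),
                  3: (0.25, 0.37, 0.38)}


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate a full cohort: profiles, flags, clinical covariates, survival.

    Cluster labels are drawn from the mixture; PFS and OS are drawn from the
    hazard model (exponential by default) with administrative censoring;
    the treatment arm is assigned independently of cluster unless
    ``treatment_by_cluster`` enables confounding.
    """
    mix = np.asarray(config.mixture_proportions, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9:
        raise SimulationError(f"mixture proportions sum to {mix.sum()}, not 1")
    k = mix.size
    if config.n_samples < k:
        raise SimulationError("need at least one sample per mixture component")
    layout = config.layout or scaled_human_layout()
    archetypes = config.archetypes or default_archetypes(layout)
    hazard = config.hazard_model or default_hazard_model()
    seed = config.seed
    top = np.random.default_rng([seed, 0])
    clusters = top.choice(np.arange(1, k + 1), size=config.n_samples, p=mix)

    rows = []
    counts = (np.empty((config.n_samples, layout.n_bins), dtype=np.int64)
              if config.with_profiles else None)
    true_segments = [] if config.with_profiles else None
    beta = hazard.covariate_log_hazards
    for i in range(config.n_samples):
        rng = np.random.default_rng([seed, i + 1])
        cl = int(clusters[i])
        arch = archetypes[cl]
        purity = float(rng.uniform(*config.purity_range))
        if config.with_profiles:
            c, segs, flags = simulate_sample(layout, arch, purity=purity,
                                             depth=config.depth,
                                             noise_sd=config.noise_sd, seed=rng)
            counts[i] = c
            true_segments.append(segs)
        else:
            flags = {name: bool(rng.random() < p)
                     for name, p in arch.mutation_rates.items()}
            flags["mut_per_mb"] = float(rng.uniform(12, 60) if flags["hypermutator"]
                                        else rng.uniform(0.5, 9))
        age = float(np.clip(rng.normal(63, 10), 30, 88))
        male = int(rng.random() < 0.61)
        t_stage = int(rng.choice([1, 2, 3, 4], p=_T_STAGE_PROBS[cl]))
        n_stage = int(rng.choice([0, 1, 2], p=_N_STAGE_PROBS[cl]))
        m_stage = int(rng.random() < config.metastatic_probs[cl - 1])
        doublet = int(rng.random() < config.doublet_fraction)
        bvz_p = (config.bvz_fraction if config.treatment_by_cluster is None
                 else config.treatment_by_cluster[cl - 1])
        bvz = int(rng.random() < bvz_p)

        lp = (hazard.cluster_log_hazards[cl - 1]
              + bvz * (hazard.treatment_log_hazard
                       + hazard.interaction_log_hazards[cl - 1])
              + beta["age"] * (age - 63)
              + beta["t_stage"] * (t_stage - 3)
              + beta["n_stage"] * (n_stage - 1)
              + beta["m_stage"] * m_stage
              + beta["male"] * male
              + beta["doublet"] * doublet)
        pfs_m, pfs_e = simulate_exponential_survival(
            lp, hazard.baseline_hazard, hazard.censoring_months, rng,
            shape=hazard.weibull_shape)
        os_m, os_e = simulate_exponential_survival(
            hazard.os_attenuation * lp, hazard.os_baseline_hazard,
            hazard.censoring_months, rng, shape=hazard.weibull_shape)
        rows.append({
            "sample_id": f"S{i:04d}", "true_cluster": cl, "purity": purity,
            "age": age, "male": male, "t_stage": t_stage, "n_stage": n_stage,
            "m_stage": m_stage, "metastatic": m_stage, "doublet": doublet,
            "bvz": bvz,
            "pfs_days": float(pfs_m * DAYS_PER_MONTH), "pfs_event": int(pfs_e),
            "os_days": float(os_m * DAYS_PER_MONTH), "os_event": int(os_e),
            **{f: flags[f] for f in arch.mutation_rates},
            "mut_per_mb": flags["mut_per_mb"],
        })
    clinical = pd.DataFrame(rows)
    return SyntheticCohort(layout=layout, clinical=clinical, counts=counts,
                           true_segments=true_segments, config=config, seed=seed)


# ---------------------------------------------------------------------------
# xenograft growth series

def simulate_xenograft_series(n_per_arm: int = 6,
                              growth_rate: float = 0.07,
                              rate_sd: float = 0.01,
                              effect_multipliers: dict | None = None,
                              measurement_sd: float = 0.08,
                              seed: int | None = None,
                              baseline_volume: float = 250.0,
                              weeks: int = 4,
                              model: str = "exponential",
                              carrying_capacity: float = 4000.0) -> dict:
    """Tumor-volume time series per animal per arm, measured twice weekly.

    Each animal grows exponentially (or logistically) at a per-animal rate
    ``r ~ N(growth_rate, rate_sd)`` scaled by its arm's effect multiplier;
    negative effective rates model shrinkage.  Measurement noise is
    multiplicative log-normal, keeping volumes positive.  Returns
    ``{arm: DataFrame(animal, day, volume)}``.
    """
    if n_per_arm < 1:
        raise SimulationError("n_per_arm must be >= 1")
    if baseline_volume <= 0:
        raise SimulationError("baseline volume must be positive")
    if effect_multipliers is None:
        effect_multipliers = {"control": 1.0, "treated": 1.0}
    rng = np.random.default_rng(seed)
    days = np.array(sorted({0, *range(3, 7 * weeks + 1, 7),
                            *range(7, 7 * weeks + 1, 7)}), dtype=float)
    out = {}
    for arm, mult in effect_multipliers.items():
        rows = []
        for a in range(n_per_arm):
            r = rng.normal(growth_rate, rate_sd) * mult
            if model == "exponential":
                v = baseline_volume * np.exp(r * days)
            elif model == "logistic":
                kcap = carrying_capacity
                v = kcap / (1 + (kcap / baseline_volume - 1) * np.exp(-r * days))
            else:
                raise SimulationError(f"unknown growth model {model!r}")
            if measurement_sd > 0:
                v = v * np.exp(rng.normal(0.0, measurement_sd, size=v.shape))
            rows.append(pd.DataFrame({"animal": f"{arm}_{a}", "day": days,
                                      "volume": v}))
        out[arm] = pd.concat(rows, ignore_index=True)
    return out
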