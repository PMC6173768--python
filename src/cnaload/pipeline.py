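"""End-to-end convenience pipeline: counts -> logR -> QC -> segments ->
recurrent regions -> call matrix -> consensus clusters -> CIN scores."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cin import cin_scores
from .consensus import ConsensusResult, canonicalize_labels, consensus_cluster
from .profiles import (LoadSummary, SegmentedProfile, call_segments,
                       counts_to_logr, qc_sample, segment_profile,
                       summarize_load)
from .recurrence import (CallMatrix, CohortSegments, RecurrentRegion,
                         arm_level_features, build_call_matrix,
                         detect_recurrent_regions, per_bin_scores,
                         permutation_null, stack_segment_means)
from .synthetic import SyntheticCohort

__all__ = ["PipelineResult", "run_pipeline", "segment_cohort"]


@dataclass
class PipelineResult:
    profiles: list
    qc: pd.DataFrame
    segmented: list[SegmentedProfile]
    loads: pd.DataFrame
    cohort_segments: CohortSegments
    regions: list[RecurrentRegion]
    features: list[RecurrentRegion]
    call_matrix: CallMatrix
    consensus: ConsensusResult
    labels: pd.Series            # canonical 1..k (1 = most stable)
    cin: pd.DataFrame


def segment_cohort(cohort: SyntheticCohort, penalty: float = 2.0,
                   enforce_qc: bool = True):
    """Per-sample logR transform, QC and segmentation for a whole cohort."""
    profiles, qc_rows, segmented, load_rows = [], [], [], []
    for i, sid in enumerate(cohort.sample_ids):
        prof = counts_to_logr(cohort.counts[i], cohort.layout, sample_id=sid)
        q = qc_sample(prof)
        qc_rows.append({"sample_id": sid, **{k: q[k] for k in
                                             ("pass", "mapd", "n_mapped_reads")},
                        "reasons": "; ".join(q["reasons"])})
        if enforce_qc and not q["pass"]:
            continue
        seg = call_segments(segment_profile(prof, penalty=penalty))
        load = summarize_load(seg)
        profiles.append(prof)
        segmented.append(seg)
        load_rows.append({"sample_id": sid,
                          "altered_fraction": load.altered_fraction,
                          "n_breakpoints": load.n_breakpoints})
    qc = pd.DataFrame(qc_rows).set_index("sample_id")
    loads = pd.DataFrame(load_rows).set_index("sample_id")
    return profiles, qc, segmented, loads


def run_pipeline(cohort: SyntheticCohort, penalty: float = 2.0,
                 n_perm: int = 200, q_cutoff: float = 0.25, k: int = 3,
                 frac: float = 0.8, reps: int = 200,
                 seed: int | None = None,
                 cin_threshold: float = 0.25) -> PipelineResult:
    """Run the full discovery analysis on a simulated (or loaded) cohort.

    The clustering feature space combines the focal recurrent regions
    detected at ``q < q_cutoff`` with the arm-level feature family; consensus
    labels are canonicalized so cluster 1 is the most copy-number stable.
    """
    profiles, qc, segmented, loads = segment_cohort(cohort, penalty=penalty)
    cs = stack_segment_means(segmented)
    scores = per_bin_scores(cs)
    null = permutation_null(cs, n_perm=n_perm, seed=seed)
    regions = detect_recurrent_regions(scores, null, cs, q_cutoff=q_cutoff)
    arms = arm_level_features(cs)
    features = [r for r in regions if r.span_class == "focal"] + arms
    if not features:
        features = regions + arms
    cm = build_call_matrix(cs, features)
    cons = consensus_cluster(cm, k=k, frac=frac, reps=reps, seed=seed)
    labels = canonicalize_labels(cons.labels, loads)
    cin = cin_scores(cm, threshold=cin_threshold)
    return PipelineResult(profiles=profiles, qc=qc, segmented=segmented,
                          loads=loads, cohort_segments=cs, regions=regions,
                          features=features, call_matrix=cm, consensus=cons,
                          labels=labels, cin=cin)
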