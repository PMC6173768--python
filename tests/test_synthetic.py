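import numpy as np
import pandas as pd
import pytest

from cnaload.genome import make_genome_layout
from cnaload.profiles import counts_to_logr
from cnaload.survival import cox_fit, km_estimate
from cnaload.synthetic import (ClusterArchetype, CatalogRegion, CohortConfig,
                               HazardModel, SimulationError,
                               default_archetypes, default_hazard_model,
                               simulate_cohort, simulate_exponential_survival,
                               simulate_sample, simulate_xenograft_series)

LAYOUT = make_genome_layout(bins_per_chromosome=[40, 40])


def _quiet_archetype(catalog=None, label=1):
    return ClusterArchetype(
        label=label, expected_altered_fraction=(0.0, 0.1),
        shared_region_catalog=catalog or [],
        n_events_range=(0, 0), event_length_range=(2, 5),
        mutation_rates={"tp53": 0.5, "msi": 0.1, "hypermutator": 0.1})


def test_neutral_genome_gives_flat_depth_and_zero_logr():
    counts, segs, _ = simulate_sample(LAYOUT, _quiet_archetype(), purity=1.0,
                                      depth=500, noise_sd=0.0, seed=1)
    # Poisson mean is exactly the depth in every bin
    assert abs(counts.mean() - 500) < 5
    prof = counts_to_logr(counts, LAYOUT)
    assert np.abs(np.median(prof.logr)) < 0.01
    assert segs == [("1", 0, 40, 2), ("2", 0, 40, 2)]


def test_whole_arm_loss_signal_follows_purity_mixture():
    arm = CatalogRegion("arm_1p_del", "1", 0, 20, -1, 1.0, 1)
    for purity, expected_ratio in [(1.0, 0.5), (0.5, 0.75)]:
        counts, _, _ = simulate_sample(LAYOUT, _quiet_archetype([arm]),
                                       purity=purity, depth=20000,
                                       noise_sd=0.0, seed=2)
        ratio = counts[:20].mean() / counts[40:].mean()
        assert ratio == pytest.approx(expected_ratio, rel=0.01)
    # at purity 0.5 the downstream logR is log2(0.75) ~ -0.415
    assert np.log2(0.75) == pytest.approx(-0.415, abs=1e-3)


@pytest.mark.parametrize("kwargs", [
    dict(purity=0.0), dict(purity=1.5), dict(depth=-1), dict(noise_sd=-0.1)])
def test_invalid_sample_parameters_raise(kwargs):
    with pytest.raises(SimulationError):
        simulate_sample(LAYOUT, _quiet_archetype(), **kwargs)


def test_true_segments_tile_the_genome(cohort300):
    for segs in cohort300.true_segments[:50]:
        by_chrom = {}
        for chrom, a, b, _ in segs:
            by_chrom.setdefault(chrom, []).append((a, b))
        for chrom, n in cohort300.layout.chromosomes:
            spans = sorted(by_chrom[chrom])
            assert spans[0][0] == 0 and spans[-1][1] == n
            assert all(x[1] == y[0] for x, y in zip(spans, spans[1:]))


# ---------------------------------------------------------------------------
# cohort-level behaviour

def test_same_seed_reproduces_cohort_exactly():
    cfg = CohortConfig(n_samples=25, seed=5)
    a = simulate_cohort(cfg)
    b = simulate_cohort(CohortConfig(n_samples=25, seed=5))
    assert np.array_equal(a.counts, b.counts)
    pd.testing.assert_frame_equal(a.clinical, b.clinical)


def test_bad_mixture_raises():
    with pytest.raises(SimulationError):
        simulate_cohort(CohortConfig(n_samples=10,
                                     mixture_proportions=(0.5, 0.4, 0.2)))


def test_degenerate_mixture_is_all_cluster_one():
    coh = simulate_cohort(CohortConfig(n_samples=10,
                                       mixture_proportions=(1.0, 0.0, 0.0),
                                       seed=2, with_profiles=False))
    assert (coh.clinical["true_cluster"] == 1).all()


def test_mixture_proportions_recovered_at_large_n():
    coh = simulate_cohort(CohortConfig(n_samples=10_000, seed=3,
                                       with_profiles=False))
    shares = coh.clinical["true_cluster"].value_counts(normalize=True)
    for k, p in zip((1, 2, 3), (0.187, 0.368, 0.445)):
        assert abs(shares[k] - p) < 0.015


def test_printed_cohort_mixture_at_study_size():
    """At n = 908 the cluster sizes land near 170/334/404."""
    coh = simulate_cohort(CohortConfig(n_samples=908, seed=17,
                                       with_profiles=False))
    counts = coh.clinical["true_cluster"].value_counts()
    for k, expected in zip((1, 2, 3), (170, 334, 404)):
        sd = np.sqrt(908 * (expected / 908) * (1 - expected / 908))
        assert abs(counts[k] - expected) < 3 * sd


def test_mutation_flags_match_archetype_rates(cohort300):
    arch = default_archetypes(cohort300.layout)
    clin = cohort300.clinical
    for cl in (1, 2, 3):
        sub = clin[clin["true_cluster"] == cl]
        for flag, rate in arch[cl].mutation_rates.items():
            freq = sub[flag].mean()
            tol = 4 * np.sqrt(rate * (1 - rate) / len(sub)) + 0.01
            assert abs(freq - rate) < tol, (cl, flag, freq, rate)


def test_hypermutator_flag_consistent_with_rate(cohort300):
    clin = cohort300.clinical
    assert ((clin["mut_per_mb"] > 10) == clin["hypermutator"]).all()


def test_null_hazard_model_is_exchangeable_across_arms(rng):
    cfg = CohortConfig(n_samples=4000, seed=9, with_profiles=False,
                       hazard_model=default_hazard_model().null())
    coh = simulate_cohort(cfg)
    km = km_estimate(coh.clinical, group_col="bvz",
                     duration_col="pfs_days", event_col="pfs_event")
    m0, m1 = km[0]["median"], km[1]["median"]
    assert abs(m1 - m0) / m0 < 0.10


def test_cox_recovers_generative_log_hazard(rng):
    """Large-sample calibration: a single binary log-hazard of ln 0.5 is
    recovered within +/-0.05 by a Cox fit at n = 5000, no censoring."""
    x = rng.integers(0, 2, 5000)
    t, e = simulate_exponential_survival(x * np.log(0.5), 0.08, None, rng)
    df = pd.DataFrame({"time": t, "event": e, "x": x})
    est = cox_fit(df, covariates=["x"])[0]
    assert np.log(est.hazard_ratio) == pytest.approx(np.log(0.5), abs=0.05)


def test_censoring_cap_is_respected(cohort300):
    days = cohort300.clinical["pfs_days"]
    events = cohort300.clinical["pfs_event"]
    cap = 60 * 30.4375
    assert (days <= cap + 1e-9).all()
    assert (events[days >= cap - 1e-9] == 0).all()


def test_archetype_load_ordering(pipeline300, truth300):
    med = pipeline300.loads.join(truth300).groupby("true_cluster")[
        "altered_fraction"].median()
    assert med[1] < med[2] < med[3]
    lo1, hi1 = (0.0, 0.10)
    assert lo1 <= med[1] <= hi1
    assert 0.25 <= med[2] <= 0.45
    assert 0.45 <= med[3] <= 0.75


def test_cohort_write_round_trip(tmp_path):
    coh = simulate_cohort(CohortConfig(n_samples=6, seed=4))
    coh.write(tmp_path)
    bins = pd.read_csv(tmp_path / "bins.tsv", sep="\t")
    assert bins.shape == (coh.layout.n_bins, 3 + 6)
    clin = pd.read_csv(tmp_path / "clinical.tsv", sep="\t")
    assert len(clin) == 6
    import json
    truth = json.loads((tmp_path / "truth.json").read_text())
    assert truth["seed"] == 4 and len(truth["true_cluster"]) == 6


# ---------------------------------------------------------------------------
# hazard model validation

def test_invalid_hazard_models_raise():
    with pytest.raises(SimulationError):
        HazardModel(baseline_hazard=0.0)
    with pytest.raises(SimulationError):
        HazardModel(censoring_months=-1)


# ---------------------------------------------------------------------------
# xenografts

def test_noiseless_series_is_exactly_exponential():
    out = simulate_xenograft_series(n_per_arm=2, growth_rate=0.05, rate_sd=0.0,
                                    measurement_sd=0.0, seed=0)
    df = out["control"]
    for _, g in df.groupby("animal"):
        v = g.sort_values("day")
        assert np.allclose(v["volume"], 250 * np.exp(0.05 * v["day"]))


def test_twice_weekly_grid_over_four_weeks():
    out = simulate_xenograft_series(n_per_arm=1, seed=1)
    days = np.sort(out["control"]["day"].unique())
    assert days[0] == 0 and days[-1] == 28
    assert len(days) == 9  # two measurements per week plus baseline


def test_equal_multipliers_give_equal_expected_trajectories():
    out = simulate_xenograft_series(n_per_arm=40, rate_sd=0.0,
                                    measurement_sd=0.05, seed=2,
                                    effect_multipliers={"a": 1.0, "b": 1.0})
    end_a = out["a"].query("day == 28")["volume"].mean()
    end_b = out["b"].query("day == 28")["volume"].mean()
    assert abs(np.log(end_a / end_b)) < 0.05


def test_volumes_are_positive_even_with_shrinkage():
    out = simulate_xenograft_series(
        n_per_arm=4, effect_multipliers={"c": 1.0, "t": -2.0},
        measurement_sd=0.2, seed=5)
    assert (out["t"]["volume"] > 0).all()


def test_bad_xenograft_parameters_raise():
    with pytest.raises(SimulationError):
        simulate_xenograft_series(n_per_arm=0)
    with pytest.raises(SimulationError):
        simulate_xenograft_series(baseline_volume=-5)
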