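"""Survival estimation, treatment-effect inference and preclinical response.

Covers the outcome side of the analysis: Kaplan-Meier curves with median
survival, multivariate Cox proportional-hazards fits (Efron tie handling,
Wald confidence intervals, complete-case per model), treatment x biomarker
interaction models, per-stratum treatment effects, two-arm power (analytic
Schoenfeld formula or log-rank simulation), cluster enrichment tests (Fisher
exact for mutation/MSI/hypermutator flags, chi-square for clinical
variables), and mRECIST response calls with a log-rank arm comparison for
xenograft growth series.

Cox fitting is delegated to lifelines; this module owns the modelling
conventions (reference levels, dummy coding, interaction construction) and
the domain rules (hypermutator > 10 mut/Mb; mRECIST regression at -50%,
progression at +35% of baseline volume).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "EffectEstimate", "MrecistCall", "km_estimate", "cox_fit",
    "interaction_analysis", "stratified_effect", "power_twoarm",
    "enrichment_tests", "mrecist_and_logrank", "is_hypermutator",
    "simulate_twoarm_times",
]

MRECIST_REGRESSION = 0.50   # volume <= 50% of baseline
MRECIST_PROGRESSION = 1.35  # volume >= 135% of baseline
HYPERMUTATOR_RATE = 10.0    # mutations per megabase, strict


class SurvivalError(ValueError):
    pass


@dataclass(frozen=True)
class EffectEstimate:
    term: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class MrecistCall:
    animal_id: str
    best_response: str                  # 'regression' | 'stable' | 'progression'
    time_to_progression: float          # progression day, or last day if censored
    progressed: bool


def is_hypermutator(mutations_per_mb: float) -> bool:
    """More than 10 somatic mutations per megabase (strict inequality)."""
    return mutations_per_mb > HYPERMUTATOR_RATE


# ---------------------------------------------------------------------------
# Kaplan-Meier

def km_estimate(records: pd.DataFrame, group_col: str | None = None,
                duration_col: str = "time", event_col: str = "event") -> dict:
    """Product-limit survival curves and median survival per group.

    The median is the first time at which S(t) <= 0.5; with everything
    censored it is reported as ``inf`` (not reached).
    """
    if records[event_col].sum() < 1 and group_col is None:
        warnings.warn("no events: survival is identically 1")
    groups = ([(None, records)] if group_col is None
              else list(records.groupby(group_col)))
    out = {}
    for name, sub in groups:
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col])
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        out[name] = {"curve": curve,
                     "median": float(kmf.median_survival_time_)}
    return out


# ---------------------------------------------------------------------------
# Cox models

def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str,
             covariates: list[str]) -> CoxPHFitter:
    cols = [duration_col, event_col, *covariates]
    data = df[cols].dropna()
    n_events = int(data[event_col].sum())
    if n_events < 2:
        raise SurvivalError(f"insufficient events ({n_events}) for a Cox fit")
    for c in covariates:
        if data[c].nunique() < 2:
            raise SurvivalError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except Exception as exc:
        raise SurvivalError(f"Cox fit failed to converge: {exc}") from exc
    return cph


def cox_fit(records: pd.DataFrame, duration_col: str = "time",
            event_col: str = "event",
            covariates: list[str] | None = None) -> list[EffectEstimate]:
    """Multivariate Cox proportional-hazards fit.

    ``covariates`` are numeric columns of ``records`` (categorical variables
    are expected pre-encoded as dummies against their reference level:
    cluster 1, CIN-low and the no-treatment arm are references throughout the
    package).  Efron tie handling and Wald confidence intervals, as provided
    by lifelines.  Complete cases only; requires at least 10 events.
    """
    if covariates is None:
        covariates = [c for c in records.columns if c not in (duration_col, event_col)]
    data = records[[duration_col, event_col, *covariates]].dropna()
    if int(data[event_col].sum()) < 10:
        raise SurvivalError("fewer than 10 events")
    cph = _fit_cox(data, duration_col, event_col, covariates)
    out = []
    s = cph.summary
    for term in s.index:
        out.append(EffectEstimate(
            term=str(term),
            hazard_ratio=float(s.loc[term, "exp(coef)"]),
            ci_low=float(s.loc[term, "exp(coef) lower 95%"]),
            ci_high=float(s.loc[term, "exp(coef) upper 95%"]),
            p_value=float(s.loc[term, "p"]),
        ))
    return out


def encode_cluster_dummies(records: pd.DataFrame,
                           cluster_col: str = "cluster") -> pd.DataFrame:
    """Add cluster_2..cluster_k dummy columns with cluster 1 as reference."""
    out = records.copy()
    for lab in sorted(records[cluster_col].unique()):
        if lab == 1:
            continue
        out[f"cluster_{lab}"] = (records[cluster_col] == lab).astype(int)
    return out


def interaction_analysis(records: pd.DataFrame, duration_col: str = "time",
                         event_col: str = "event", arm_col: str = "bvz",
                         stratum_col: str = "cluster",
                         covariates: list[str] | None = None) -> list[EffectEstimate]:
    """Cox model with biomarker and treatment main effects plus interaction.

    ``stratum_col`` may be the cluster label (reference cluster 1) or a
    binary CIN-high indicator; interaction terms are products of the arm
    indicator with the non-reference stratum dummies.  Returns the
    interaction estimates only.
    """
    strata = sorted(records[stratum_col].unique())
    ref = strata[0]
    for s in strata:
        for a in sorted(records[arm_col].unique()):
            if ((records[stratum_col] == s) & (records[arm_col] == a)).sum() == 0:
                raise SurvivalError(f"empty cell: {stratum_col}={s}, {arm_col}={a}")
    df = records.copy()
    terms = [arm_col]
    inter_terms = []
    for s in strata:
        if s == ref:
            continue
        main = f"{stratum_col}_{s}"
        inter = f"{arm_col}_x_{stratum_col}_{s}"
        df[main] = (df[stratum_col] == s).astype(int)
        df[inter] = df[main] * df[arm_col]
        terms += [main, inter]
        inter_terms.append(inter)
    if covariates:
        terms += list(covariates)
    ests = cox_fit(df, duration_col, event_col, covariates=terms)
    return [e for e in ests if e.term in inter_terms]


def stratified_effect(records: pd.DataFrame, stratum_col: str,
                      duration_col: str = "time", event_col: str = "event",
                      arm_col: str = "bvz",
                      covariates: list[str] | None = None,
                      min_events: int = 10) -> dict:
    """Treatment effect within each stratum of ``stratum_col``.

    Strata missing an arm or with fewer than ``min_events`` events are
    skipped with a warning.  Returns ``{stratum: EffectEstimate}`` for the
    treatment term.
    """
    out = {}
    for name, sub in records.groupby(stratum_col):
        if sub[arm_col].nunique() < 2:
            warnings.warn(f"stratum {name}: only one treatment arm; skipped")
            continue
        if int(sub[event_col].sum()) < min_events:
            warnings.warn(f"stratum {name}: fewer than {min_events} events; skipped")
            continue
        ests = cox_fit(sub, duration_col, event_col,
                       covariates=[arm_col, *(covariates or [])])
        out[name] = next(e for e in ests if e.term == arm_col)
    return out


# ---------------------------------------------------------------------------
# power

def simulate_twoarm_times(n1: int, n2: int, hr: float, rng,
                          event_fraction: float = 1.0,
                          baseline_rate: float = 1.0):
    """Exponential two-arm survival data; arm 1 has hazard ``hr`` times arm 2.

    With ``event_fraction < 1`` an independent exponential censoring process
    is added at the rate giving that expected event fraction.
    """
    t1 = rng.exponential(1.0 / (baseline_rate * hr), size=n1)
    t2 = rng.exponential(1.0 / baseline_rate, size=n2)
    times = np.concatenate([t1, t2])
    arm = np.concatenate([np.ones(n1, dtype=int), np.zeros(n2, dtype=int)])
    event = np.ones(times.size, dtype=int)
    if event_fraction < 1.0:
        rates = np.where(arm == 1, baseline_rate * hr, baseline_rate)
        c_rates = rates * (1.0 - event_fraction) / event_fraction
        cens = rng.exponential(1.0 / c_rates)
        event = (times <= cens).astype(int)
        times = np.minimum(times, cens)
    return times, event, arm


def power_twoarm(n1: int, n2: int, hr: float, alpha: float = 0.05,
                 mode: str = "schoenfeld", event_fraction: float = 1.0,
                 seed: int | None = None, n_reps: int = 2000) -> float:
    """Power of a two-sided log-rank test for a hazard ratio ``hr``.

    ``mode='schoenfeld'`` evaluates the analytic approximation
    ``Phi(delta - z) + Phi(-delta - z)`` with
    ``delta = sqrt(d p (1-p)) |ln hr|``, ``d`` the expected event count and
    ``p`` the allocation fraction; at hr = 1 this returns exactly alpha.
    ``mode='simulate'`` is the rejection fraction of a two-sided log-rank test
    over ``n_reps`` replicates of exponential two-arm data.
    """
    if n1 < 2 or n2 < 2:
        raise SurvivalError("need at least 2 per arm")
    if hr <= 0 or not (0 < alpha < 1):
        raise SurvivalError("invalid hr or alpha")
    if mode == "schoenfeld":
        d = (n1 + n2) * event_fraction
        p = n1 / (n1 + n2)
        z = stats.norm.ppf(1 - alpha / 2)
        delta = np.sqrt(d * p * (1 - p)) * abs(np.log(hr))
        return float(stats.norm.cdf(delta - z) + stats.norm.cdf(-delta - z))
    if mode == "simulate":
        rng = np.random.default_rng(seed)
        rejections = 0
        for _ in range(n_reps):
            times, event, arm = simulate_twoarm_times(n1, n2, hr, rng,
                                                      event_fraction)
            res = logrank_test(times[arm == 1], times[arm == 0],
                               event_observed_A=event[arm == 1],
                               event_observed_B=event[arm == 0])
            rejections += res.p_value < alpha
        return rejections / n_reps
    raise SurvivalError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# enrichment

def enrichment_tests(labels: pd.Series, flags: pd.DataFrame | None = None,
                     clinical: pd.DataFrame | None = None) -> dict:
    """Cluster enrichment tests, reported as raw (uncorrected) p-values.

    For each boolean flag (mutation, MSI, hypermutator): a two-sided Fisher
    exact test per cluster on the one-vs-rest 2x2 table.  For each clinical
    variable: a chi-square test on the full clusters x categories table.
    Features with an empty table margin are skipped with a warning.
    """
    out = {"fisher": None, "chisq": None}
    if flags is not None:
        rows = []
        for feat in flags.columns:
            f = flags[feat].loc[labels.index].astype(bool)
            if f.all() or (~f).all():
                warnings.warn(f"flag {feat!r}: empty margin; skipped")
                continue
            for lab in sorted(labels.unique()):
                inc = labels == lab
                table = [[int((inc & f).sum()), int((inc & ~f).sum())],
                         [int((~inc & f).sum()), int((~inc & ~f).sum())]]
                odds, p = stats.fisher_exact(table, alternative="two-sided")
                rows.append({"feature": feat, "cluster": lab,
                             "odds_ratio": odds, "p_value": p})
        out["fisher"] = pd.DataFrame(rows)
    if clinical is not None:
        rows = []
        for var in clinical.columns:
            tab = pd.crosstab(labels, clinical[var].loc[labels.index])
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                warnings.warn(f"variable {var!r}: degenerate table; skipped")
                continue
            chi2, p, dof, _ = stats.chi2_contingency(tab)
            rows.append({"variable": var, "chi2": chi2, "dof": dof, "p_value": p})
        out["chisq"] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# xenograft mRECIST

def mrecist_call(days, volumes, animal_id: str = "animal") -> MrecistCall:
    """Classify one volume series by modified RECIST rules.

    Baseline is the first measurement.  Progression is the first time the
    volume reaches 135% of baseline; regression requires any measurement at
    or below 50% of baseline before progression.  Animals reaching study end
    without progression are censored at the last measurement day.
    """
    days = np.asarray(days, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size == 0 or volumes[0] <= 0:
        raise SurvivalError("series needs a positive baseline volume")
    if volumes.size < 2:
        warnings.warn(f"{animal_id}: single-timepoint series; stable/censored")
        return MrecistCall(animal_id, "stable", float(days[-1]), False)
    base = volumes[0]
    prog_idx = np.flatnonzero(volumes >= MRECIST_PROGRESSION * base)
    prog_i = int(prog_idx[0]) if prog_idx.size else None
    upto = volumes[:prog_i] if prog_i is not None else volumes
    regressed = bool((upto <= MRECIST_REGRESSION * base).any())
    if prog_i is not None:
        best = "regression" if regressed else "progression"
        return MrecistCall(animal_id, best, float(days[prog_i]), True)
    best = "regression" if regressed else "stable"
    return MrecistCall(animal_id, best, float(days[-1]), False)


def mrecist_and_logrank(series_by_arm: dict) -> dict:
    """mRECIST calls per animal plus a two-sided log-rank arm comparison.

    ``series_by_arm`` maps arm name -> list of ``(animal_id, days, volumes)``
    tuples (or a tidy DataFrame with columns animal, day, volume).  Exactly
    two arms are compared by log-rank on time to progression.
    """
    calls: dict[str, list[MrecistCall]] = {}
    for arm, series in series_by_arm.items():
        if isinstance(series, pd.DataFrame):
            series = [(str(a), g["day"].to_numpy(), g["volume"].to_numpy())
                      for a, g in series.groupby("animal")]
        calls[arm] = [mrecist_call(days, vols, animal_id=str(aid))
                      for aid, days, vols in series]
    result = {"calls": calls, "logrank_p": None, "logrank_statistic": None}
    if len(calls) == 2:
        (arm_a, ca), (arm_b, cb) = calls.items()
        ta = [c.time_to_progression for c in ca]
        tb = [c.time_to_progression for c in cb]
        ea = [c.progressed for c in ca]
        eb = [c.progressed for c in cb]
        res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        result["logrank_p"] = float(res.p_value)
        result["logrank_statistic"] = float(res.test_statistic)
    return result
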