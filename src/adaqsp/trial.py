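"""Virtual clinical trial engine.

For every virtual subject a full (immune-coupled) simulation and a paired
PK-only simulation are run on the same parameter set.  Subjects are ADA
positive when total ADA strictly exceeds the assay threshold (default
100 ng/mL) at one or more scheduled ADA sampling times.  The impact of ADA
on exposure is assessed by a two-sided Wilcoxon rank-sum test comparing
free plasma drug at the final sampling time between ADA-positive and
ADA-negative subjects.  The [ADA]:[Drug] molar ratio — maximum sampled
total ADA over the full run divided by the PK-only free plasma drug at the
final ADA sampling time — summarises, per subject, whether ADA levels are
high enough relative to exposure to matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import (
    DrugParameters,
    ImmuneRates,
    MtxParameters,
    Regimen,
    SamplingSchedule,
    SolverSettings,
    TrialConfig,
)
from .immune import simulate_subject
from .pbpk import SolverFailure, SubjectTrajectory
from .population import VirtualSubject
from .units import IGG_MW_G_PER_MOL, nM_to_ng_per_ml


@dataclass
class TrialResult:
    """Per-subject metrics plus the group-level exposure verdict."""

    subjects: pd.DataFrame
    incidence_pct: float
    wilcoxon_p: Optional[float]
    verdict: str  # "impact" | "no_impact" | "not_assessable"
    n_failed: int
    seed: int
    metadata: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_subjects": int(len(self.subjects)),
            "incidence_pct": self.incidence_pct,
            "wilcoxon_p": self.wilcoxon_p,
            "verdict": self.verdict,
            "n_failed": self.n_failed,
            "seed": self.seed,
            **self.metadata,
        }


def classify_ada(
    trajectory: SubjectTrajectory,
    ada_times: Sequence[float],
    threshold_ng_per_ml: float = 100.0,
    ada_mw: float = IGG_MW_G_PER_MOL,
) -> bool:
    """ADA positive iff sampled total ADA strictly exceeds the threshold.

    Only the scheduled sampling times count; excursions between samples are
    invisible to the assay.
    """
    if threshold_ng_per_ml <= 0:
        raise ValueError("ADA threshold must be positive")
    sampled = trajectory.ada_total_at(ada_times)
    return bool(np.any(nM_to_ng_per_ml(sampled, ada_mw) > threshold_ng_per_ml))


def _rank_sum_exact_p(ranks_x_sum: float, n1: int, n: int) -> float:
    """Two-sided exact p for untied ranks 1..n via subset-sum counting."""
    # counts[s] = number of n1-subsets of {1..n} with rank sum s
    max_sum = n * (n + 1) // 2
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    counts[0, 0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            counts[k, r:] += counts[k - 1, : max_sum + 1 - r]
    dist = counts[n1]
    total = dist.sum()
    w = int(round(ranks_x_sum))
    p_low = dist[: w + 1].sum() / total
    p_high = dist[w:].sum() / total
    return min(1.0, 2.0 * min(p_low, p_high))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact subset enumeration when the pooled sample has at most 12
    observations and no ties; otherwise a normal approximation with
    tie-corrected variance and continuity correction.  Returns p in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    n1, n2 = x.size, y.size
    n = n1 + n2
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    # midranks for ties
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    has_ties = len(np.unique(pooled)) < n
    w = ranks[:n1].sum()
    if n <= 12 and not has_ties:
        return _rank_sum_exact_p(w, n1, n)
    mu = n1 * (n + 1) / 2.0
    _vals, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = max(0.0, abs(w - mu) - 0.5) / math.sqrt(var)
    return min(1.0, 2.0 * float(norm.sf(z)))


def wilcoxon_rank_sum_permutation(x, y) -> float:
    """Brute-force permutation oracle (small samples only, test use)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n = x.size, x.size + y.size
    ranks = pd.Series(pooled).rank().to_numpy()
    w_obs = ranks[:n1].sum()
    sums = np.array(
        [ranks[list(idx)].sum() for idx in combinations(range(n), n1)]
    )
    p_low = np.mean(sums <= w_obs + 1e-12)
    p_high = np.mean(sums >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_low, p_high))


def ada_drug_ratio(
    full: SubjectTrajectory,
    pk_only: SubjectTrajectory,
    schedule: SamplingSchedule,
) -> tuple[float, bool]:
    """[ADA]:[Drug] molar ratio and an infinity flag.

    Maximum sampled total ADA (nM, full run) over the PK-only free plasma
    drug (nM) at the final ADA sampling time; 0 when ADA never forms, +inf
    (flagged) when the PK-only drug concentration at the final time is zero.
    """
    max_ada = float(np.max(full.ada_total_at(schedule.ada_times_h)))
    if max_ada == 0.0:
        return 0.0, False
    denom = pk_only.free_plasma_at(schedule.final_time_h)
    if denom == 0.0:
        return float("inf"), True
    return max_ada / denom, False


def compare_pk(
    subjects: pd.DataFrame,
    alpha: float = 0.05,
    min_positive_group: int = 2,
) -> tuple[str, Optional[float]]:
    """Exposure-impact verdict from the per-subject table.

    ``impact`` requires both p < alpha and a lower ADA-positive median of
    free drug at the final time; fewer than ``min_positive_group`` positives
    (or no negatives) is not assessable.  Accepts a ``TrialResult`` or its
    per-subject frame.
    """
    if hasattr(subjects, "subjects"):
        subjects = subjects.subjects
    ok = subjects[~subjects["solver_failed"]]
    pos = ok.loc[ok["ada_positive"], "free_drug_final_full"].to_numpy()
    neg = ok.loc[~ok["ada_positive"], "free_drug_final_full"].to_numpy()
    if pos.size < min_positive_group or neg.size < 1:
        return "not_assessable", None
    p = wilcoxon_rank_sum(pos, neg)
    if p < alpha and np.median(pos) < np.median(neg):
        return "impact", p
    return "no_impact", p


def _trial_grid(
    drug: DrugParameters, regimen: Regimen, schedule: SamplingSchedule
) -> np.ndarray:
    pts = {0.0, schedule.final_time_h}
    pts.update(schedule.ada_times_h)
    pts.update(schedule.pk_times_h)
    for t, _mg in regimen.doses():
        if t <= schedule.final_time_h:
            pts.add(t)
    return np.array(sorted(pts))


def run_trial(
    population: Sequence[VirtualSubject],
    drug: DrugParameters,
    regimen: Regimen,
    schedule: SamplingSchedule,
    trial_config: Optional[TrialConfig] = None,
    rates: Optional[ImmuneRates] = None,
    mtx_params: Optional[MtxParameters] = None,
    immune_enabled: bool = True,
    solver: Optional[SolverSettings] = None,
    seed: int = 0,
    keep_trajectories: bool = False,
) -> TrialResult:
    """Paired full / PK-only virtual trial over a population.

    Deterministic given the population and configs; the ``seed`` is recorded
    as run metadata.  A subject whose solver fails is flagged, excluded from
    the statistics, and counted.
    """
    cfg = trial_config or TrialConfig()
    rates = rates or ImmuneRates()
    grid = _trial_grid(drug, regimen, schedule)
    rows = []
    trajectories = {} if keep_trajectories else None
    n_failed = 0
    for subj in population:
        alleles = subj.genotype.allele_set()
        row = {
            "id": subj.id,
            "ada_positive": False,
            "max_ada_nM": np.nan,
            "max_ada_ng_ml": np.nan,
            "free_drug_final_full": np.nan,
            "free_drug_final_pkonly": np.nan,
            "ratio": np.nan,
            "ratio_inf": False,
            "solver_failed": False,
        }
        try:
            full = simulate_subject(
                drug,
                subj.physiology,
                regimen,
                grid,
                rates=rates,
                alleles=alleles,
                clearance_L_per_h=subj.clearance_L_per_h,
                immune_enabled=immune_enabled,
                mtx_params=mtx_params,
                solver=solver,
                subject_id=subj.id,
            )
            pk = simulate_subject(
                drug,
                subj.physiology,
                regimen,
                grid,
                rates=rates,
                alleles=alleles,
                clearance_L_per_h=subj.clearance_L_per_h,
                immune_enabled=False,
                solver=solver,
                subject_id=subj.id,
            )
        except SolverFailure:
            n_failed += 1
            row["solver_failed"] = True
            rows.append(row)
            continue
        max_ada = float(np.max(full.ada_total_at(schedule.ada_times_h)))
        ratio, inf_flag = ada_drug_ratio(full, pk, schedule)
        row.update(
            ada_positive=classify_ada(
                full,
                schedule.ada_times_h,
                cfg.ada_threshold_ng_per_ml,
                cfg.ada_mw_g_per_mol,
            ),
            max_ada_nM=max_ada,
            max_ada_ng_ml=nM_to_ng_per_ml(max_ada, cfg.ada_mw_g_per_mol),
            free_drug_final_full=full.free_plasma_at(schedule.final_time_h),
            free_drug_final_pkonly=pk.free_plasma_at(schedule.final_time_h),
            ratio=ratio,
            ratio_inf=inf_flag,
        )
        rows.append(row)
        if keep_trajectories:
            trajectories[subj.id] = (full, pk)
    subjects = pd.DataFrame(rows)
    ok = subjects[~subjects["solver_failed"]]
    incidence = 100.0 * float(ok["ada_positive"].mean()) if len(ok) else float("nan")
    verdict, p = compare_pk(subjects, cfg.alpha, cfg.min_positive_group)
    result = TrialResult(
        subjects=subjects,
        incidence_pct=incidence,
        wilcoxon_p=p,
        verdict=verdict,
        n_failed=n_failed,
        seed=seed,
        metadata={"drug": drug.name, "n_doses": len(regimen.doses())},
    )
    if keep_trajectories:
        result.metadata["trajectories"] = trajectories
    return result


SCAN_LABELS = ("Study Dose", "2xDose", "2xFreq")


def dose_adjustment_scan(
    population: Sequence[VirtualSubject],
    drug: DrugParameters,
    base_regimen: Regimen,
    schedule: SamplingSchedule,
    trial_config: Optional[TrialConfig] = None,
    rates: Optional[ImmuneRates] = None,
    mtx_params: Optional[MtxParameters] = None,
    solver: Optional[SolverSettings] = None,
    seed: int = 0,
) -> dict[str, dict]:
    """Fraction of subjects with [ADA]:[Drug] > 1 under dose adjustments.

    Runs the study regimen, doubled dose amount, and halved dosing interval
    (doubled frequency, same span) on the *same* population, reporting for
    each the fraction of subjects whose ratio exceeds 1.
    """
    if base_regimen.dose_times_h is not None:
        raise ValueError(
            "dose adjustment scan requires an interval-pattern regimen"
        )
    double_dose = base_regimen.model_copy(
        update={"dose_mg": base_regimen.dose_mg * 2}
    )
    double_freq = base_regimen.model_copy(
        update={
            "interval_h": base_regimen.interval_h / 2,
            "n_doses": base_regimen.n_doses * 2,
        }
    )
    out = {}
    for label, regimen in zip(SCAN_LABELS, (base_regimen, double_dose, double_freq)):
        res = run_trial(
            population, drug, regimen, schedule,
            trial_config=trial_config, rates=rates, mtx_params=mtx_params,
            solver=solver, seed=seed,
        )
        ok = res.subjects[~res.subjects["solver_failed"]]
        frac = float((ok["ratio"] > 1.0).mean()) if len(ok) else float("nan")
        out[label] = {
            "fraction_ratio_gt_1": frac,
            "incidence_pct": res.incidence_pct,
            "verdict": res.verdict,
        }
    return out
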