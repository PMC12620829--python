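"""Mechanistic humoral immune-response model coupled to the PBPK module.

The lymph-node immune block tracks immature/mature dendritic cells, naive,
activated and memory drug-specific CD4+ T cells, the corresponding B-cell
lineage, short- and long-lived plasma cells, secreted ADA and the 1:1
ADA-drug immune complex.  T-cell activation is driven per epitope by the
elution-rank activation signal

    D = [ID_m / (ID_m + Ttot)] * S / (S + K_Ag_N),
    S = DC_Uptake * AgVS * sum_alleles (100 / EL_rank - 1)^2

where AgVS is the drug concentration in the tissue vascular space and the
sum runs over the class-II specificities expressed by the subject (the
allele *set*: homozygous loci contribute once; epitope-allele pairs absent
from the rank table contribute nothing).  D is a dimensionless fraction in
[0, 1] per epitope, non-decreasing in AgVS and DC uptake and non-increasing
in every elution rank.  Methotrexate co-medication inhibits the T-cell
proliferation rate through an inhibitory Emax model (IC50 283 nM).

ADA is a lumped IgG pool secreted into plasma that binds free drug 1:1;
the complex is cleared at a first-order rate, and drug bound in complexes
is removed from the free-drug mass balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .config import (
    DrugParameters,
    ImmuneRates,
    MtxParameters,
    PhysiologyParameters,
    Regimen,
    SolverSettings,
)
from .epitope import Epitope
from .pbpk import (
    DRUG_COMPARTMENTS,
    IMMUNE_STATES,
    MtxConcentration,
    SubjectTrajectory,
    build_dose_events,
    integrate_with_events,
    pk_rhs_factory,
    simulate_pk_only,
)


@dataclass(frozen=True)
class ActivationInputs:
    """Inputs to the per-epitope T-cell activation signal."""

    id_m: float  # mature dendritic cells
    t_tot: float  # total drug-specific T cells (naive + activated + memory)
    dc_uptake: float
    ag_vs_nM: float  # drug concentration in the tissue vascular space
    elution_ranks: Sequence[float]  # per expressed allele, in (0, 100]
    k_ag_n: float


def _rank_weight(ranks: Iterable[float]) -> float:
    w = 0.0
    for r in ranks:
        if not (0.0 < r <= 100.0):
            raise ValueError(f"elution rank must be in (0, 100], got {r}")
        term = 100.0 / r - 1.0
        w += term * term
    return w


def epitope_activation_signal(inputs: ActivationInputs) -> float:
    """Dimensionless activation fraction in [0, 1] for one epitope."""
    if inputs.k_ag_n <= 0:
        raise ValueError("k_ag_n must be positive")
    if inputs.dc_uptake < 0:
        raise ValueError("dc_uptake must be >= 0")
    if inputs.ag_vs_nM < 0:
        raise ValueError("antigen concentration must be >= 0")
    denom_cells = inputs.id_m + inputs.t_tot
    if denom_cells <= 0:
        return 0.0
    s = inputs.dc_uptake * inputs.ag_vs_nM * _rank_weight(inputs.elution_ranks)
    if s == 0.0:
        return 0.0
    return (inputs.id_m / denom_cells) * s / (s + inputs.k_ag_n)


def mtx_proliferation_factor(c_mtx_nM: float, params: MtxParameters) -> float:
    """Multiplicative inhibition of the T-cell proliferation rate, (1-imax, 1]."""
    if c_mtx_nM < 0:
        raise ValueError("methotrexate concentration must be >= 0")
    return 1.0 - params.imax * c_mtx_nM / (params.ic50_nM + c_mtx_nM)


def genotype_allele_set(genotype) -> tuple[str, ...]:
    """Unique class-II specificities expressed by a subject (allele set,
    not allele count: homozygous loci contribute once)."""
    alleles: list[str] = []
    for pair in genotype.values() if isinstance(genotype, dict) else genotype.alleles.values():
        for a in pair:
            if a not in alleles:
                alleles.append(a)
    return tuple(alleles)


def epitope_weights(epitopes: Sequence[Epitope], alleles: Sequence[str]) -> np.ndarray:
    """Per-epitope presentation weight sum_alleles (100/EL_rank - 1)^2."""
    return np.array(
        [_rank_weight(ep.rank_for(a) for a in alleles) for ep in epitopes]
    )


# ---------------------------------------------------------------------------
# coupled PBPK + immune system

def build_coupled_system(
    drug: DrugParameters,
    physiology: PhysiologyParameters,
    rates: ImmuneRates,
    clearance_L_per_h: float,
    weights: Sequence[float],
    mtx_conc: Optional[Callable[[float], float]] = None,
) -> tuple[Callable, np.ndarray]:
    """Right-hand side and initial state of the joint 18-state ODE.

    State layout: 6 drug amounts (nmol) in the PBPK order, then ID_i, ID_m,
    NT, AT, MT, NB, AB, MB, SP, LP (cells), ADA and Complex amounts (nmol,
    plasma).  ``weights`` are the per-epitope presentation weights for this
    subject; with no epitopes the immune block is inert.
    """
    pk_rhs = pk_rhs_factory(drug, physiology, clearance_L_per_h)
    r = rates
    v_pl = physiology.v_plasma_L
    v_v = physiology.v_tissue_vascular_L
    u_dc = drug.dc_uptake
    k = r.k_ag_n
    w_list = [float(w) for w in weights if w > 0]
    nt0 = drug.naive_t_fraction * r.t_repertoire
    kon, koff, k_ic = r.kon_per_nM_per_h, r.koff_per_h, r.k_ic
    have_mtx = mtx_conc is not None

    def rhs(t, y, u_inf=0.0):
        d_pk = pk_rhs(t, y, u_inf)
        (id_i, id_m, nt, at, mt, nb, ab, mb, sp, lp, a_ada, a_cx) = y[6:]
        ag_vs = max(y[3], 0.0) / v_v
        t_tot = nt + at + mt
        denom_cells = id_m + t_tot
        d_total = 0.0
        if denom_cells > 0.0 and ag_vs > 0.0 and u_dc > 0.0:
            base = u_dc * ag_vs
            frac = id_m / denom_cells
            for w in w_list:
                s = base * w
                d_total += s / (s + k)
            d_total *= frac
        f_ag = ag_vs / (ag_vs + r.k_dc_nM)
        mtx_f = (
            mtx_proliferation_factor(float(mtx_conc(t)), mtx_params_ref)
            if have_mtx
            else 1.0
        )
        # dendritic cells
        d_id_i = r.k_id_in - r.k_id_death * id_i - r.k_mat * f_ag * id_i
        d_id_m = r.k_mat * f_ag * id_i - r.k_idm_death * id_m
        # T lineage
        act_t = r.k_act_t * d_total
        d_nt = -act_t * nt
        d_at = (
            act_t * nt
            + r.k_react_t * d_total * mt
            + r.rho_at * mtx_f * d_total * at
            - (r.k_at_death + r.k_mem_t) * at
        )
        d_mt = r.k_mem_t * at - r.k_react_t * d_total * mt - r.k_mt_death * mt
        # B lineage: antigen gate x T-cell help
        g_b = ag_vs / (ag_vs + r.k_bcell_ag_nM)
        # Hill-2 T-help: a threshold in activated-T numbers separates weak
        # (influx-limited) from strong (proliferation-driven) B responses
        h_t = at * at / (at * at + r.k_help_cells * r.k_help_cells)
        drive = g_b * h_t
        d_nb = -r.k_act_b * drive * nb
        d_ab = (
            r.k_act_b * drive * nb
            + r.k_react_b * drive * mb
            + r.rho_ab * drive * ab * max(0.0, 1.0 - ab / r.b_cap_cells)
            - (r.k_ab_death + r.k_diff) * ab
        )
        d_mb = r.f_mb * r.k_diff * ab - r.k_react_b * drive * mb - r.k_mb_death * mb
        d_sp = r.f_sp * r.k_diff * ab - r.k_sp_death * sp
        d_lp = r.f_lp * r.k_diff * ab - r.k_lp_death * lp
        # ADA secretion into plasma, 1:1 binding to free plasma drug
        c_pl = max(y[1], 0.0) / v_pl
        c_ada = max(a_ada, 0.0) / v_pl
        c_cx = max(a_cx, 0.0) / v_pl
        bind_net = (kon * c_ada * c_pl - koff * c_cx) * v_pl  # nmol/h
        secretion = r.k_sec_sp_nmol_per_h * sp + r.k_sec_lp_nmol_per_h * lp
        d_ada = secretion - r.k_ada_elim * a_ada - bind_net
        d_cx = bind_net - k_ic * a_cx
        d_pk[1] -= bind_net  # free-drug loss to complex
        return d_pk + [
            d_id_i, d_id_m, d_nt, d_at, d_mt, d_nb, d_ab, d_mb, d_sp, d_lp,
            d_ada, d_cx,
        ]

    mtx_params_ref = getattr(mtx_conc, "pd_params", None)
    if have_mtx and mtx_params_ref is None:
        raise ValueError("mtx_conc must carry pd_params (MtxParameters)")

    y0 = np.zeros(18)
    y0[6] = r.id_i0
    y0[8] = nt0
    y0[11] = r.nb0
    return rhs, y0


def _immune_inert(drug: DrugParameters, weights: np.ndarray) -> bool:
    return drug.dc_uptake == 0 or weights.size == 0 or not np.any(weights > 0)


def simulate_subject(
    drug: DrugParameters,
    physiology: PhysiologyParameters,
    regimen: Regimen,
    time_grid,
    rates: Optional[ImmuneRates] = None,
    alleles: Sequence[str] = (),
    clearance_L_per_h: Optional[float] = None,
    immune_enabled: bool = True,
    mtx_params: Optional[MtxParameters] = None,
    solver: Optional[SolverSettings] = None,
    subject_id: Optional[str] = None,
) -> SubjectTrajectory:
    """Full (immune-coupled) or PK-only simulation of one subject.

    With the immune module disabled the call is delegated verbatim to
    :func:`adaqsp.pbpk.simulate_pk_only`, so the two are bit-identical.
    With no epitopes (or zero DC uptake) the immune block is provably inert:
    only the PBPK states are integrated and the immune states are reported
    frozen at their initial conditions, which keeps the drug trajectory
    exactly equal to the PK-only run.
    """
    rates = rates or ImmuneRates()
    solver = solver or SolverSettings()
    cl = (
        clearance_L_per_h
        if clearance_L_per_h is not None
        else drug.clearance_mean_L_per_h * physiology.clearance_multiplier
    )
    if not immune_enabled:
        return simulate_pk_only(
            drug, physiology, regimen, time_grid,
            clearance_L_per_h=cl, solver=solver, subject_id=subject_id,
        )
    weights = epitope_weights(drug.epitopes, tuple(alleles))
    t_grid = np.asarray(time_grid, dtype=float)
    if _immune_inert(drug, weights):
        traj = simulate_pk_only(
            drug, physiology, regimen, t_grid,
            clearance_L_per_h=cl, solver=solver, subject_id=subject_id,
        )
        traj.mode = "full"
        # immune states stay at their initial conditions
        n = len(t_grid)
        traj.cells["ID_i"] = np.full(n, rates.id_i0)
        traj.cells["NT"] = np.full(n, drug.naive_t_fraction * rates.t_repertoire)
        traj.cells["NB"] = np.full(n, rates.nb0)
        return traj

    mtx_conc = None
    if mtx_params is not None and regimen.mtx is not None:
        mtx_conc = MtxConcentration(mtx_params, regimen.mtx)
        mtx_conc.pd_params = mtx_params
    rhs, y0 = build_coupled_system(
        drug, physiology, rates, cl, weights, mtx_conc=mtx_conc
    )
    events = build_dose_events(drug, physiology, regimen)
    Y = integrate_with_events(rhs, y0, events, t_grid, solver, subject_id)
    vols = np.array(
        [
            1.0,
            physiology.v_plasma_L,
            physiology.v_lymph_node_L,
            physiology.v_tissue_vascular_L,
            physiology.v_tissue_endosomal_L,
            physiology.v_tissue_interstitial_L,
        ]
    )
    conc = Y[:, :6] / vols
    cells = {name: Y[:, 6 + i] for i, name in enumerate(IMMUNE_STATES[:-2])}
    ada_free = Y[:, 16] / physiology.v_plasma_L
    cx = Y[:, 17] / physiology.v_plasma_L
    return SubjectTrajectory(
        times=t_grid,
        drug_nM={name: conc[:, i] for i, name in enumerate(DRUG_COMPARTMENTS)},
        ada_free_nM=ada_free,
        ada_total_nM=ada_free + cx,
        complex_nM=cx,
        cells=cells,
        mode="full",
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# calibration of the half-maximal activation constant

@dataclass
class CalibrationResult:
    k_ag_n: float
    rmse: float
    insensitive: bool
    evaluations: list[tuple[float, float]]  # (k, rmse) over the search grid


def calibrate_k_ag_n(
    targets: Sequence[tuple[object, float]],
    simulate_incidence: Callable[[object, float], float],
    bounds: tuple[float, float],
    n_grid: int = 13,
    refine_xatol_log: float = 0.02,
) -> CalibrationResult:
    """Bound-constrained scalar fit of ``k_ag_n`` to observed incidences.

    ``targets`` pairs an opaque drug configuration with its observed
    incidence (%); ``simulate_incidence(config, k)`` must return the
    simulated incidence (%) at a fixed seed so the objective is
    deterministic.  The RMSE objective is evaluated on a log-spaced grid
    over ``bounds`` and refined by golden-section search around the best
    grid point.  If every configuration's incidence is identical across the
    whole grid the result is flagged insensitive.
    """
    if not targets:
        raise ValueError("at least one calibration target is required")
    lo, hi = bounds
    if lo <= 0 or hi <= lo:
        raise ValueError("bounds must satisfy 0 < lower < upper")

    cache: dict[float, float] = {}

    def rmse(k: float) -> float:
        if k not in cache:
            errs = [
                simulate_incidence(cfg, k) - obs for cfg, obs in targets
            ]
            cache[k] = math.sqrt(sum(e * e for e in errs) / len(errs))
        return cache[k]

    grid = np.geomspace(lo, hi, n_grid)
    grid_inc = [
        tuple(simulate_incidence(cfg, k) for cfg, _obs in targets) for k in grid
    ]
    insensitive = len(set(grid_inc)) == 1
    grid_rmse = np.array([rmse(float(k)) for k in grid])
    best = int(np.argmin(grid_rmse))
    k_best, r_best = float(grid[best]), float(grid_rmse[best])

    if not insensitive:
        b_lo = float(grid[max(best - 1, 0)])
        b_hi = float(grid[min(best + 1, n_grid - 1)])
        if b_hi > b_lo:
            res = minimize_scalar(
                lambda lk: rmse(float(np.exp(lk))),
                bounds=(math.log(b_lo), math.log(b_hi)),
                method="bounded",
                options={"xatol": refine_xatol_log},
            )
            k_ref = float(np.exp(res.x))
            if rmse(k_ref) < r_best:
                k_best, r_best = k_ref, rmse(k_ref)

    evals = sorted((float(k), float(v)) for k, v in cache.items())
    return CalibrationResult(
        k_ag_n=k_best, rmse=r_best, insensitive=insensitive, evaluations=evals
    )
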