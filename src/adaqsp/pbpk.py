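"""Minimal PBPK model of a protein therapeutic and oral methotrexate PK.

The therapeutic distributes over plasma, lymph node, and a lumped tissue
split into vascular, endosomal and interstitial sub-compartments.  Transport
is blood flow between plasma and the tissue vascular space, convective
transcapillary filtration limited by a vascular reflection coefficient,
lymph drainage from interstitium through the lymph node back to plasma, and
a small passive vascular<->endosomal exchange.  Elimination is a single
linear clearance from plasma (subject mean x multiplier); FcRn recycling is
not modelled mechanistically.  Subcutaneous doses enter a first-order depot
with bioavailability applied to the depot amount; infusions are zero-order
inputs into plasma.

State variables are amounts in nmol; reported trajectories are
concentrations in nM.  Time is in hours.  Doses are handled by integrating
between dose events and applying state jumps, with outputs at event times
taken pre-dose (trough convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .config import (
    DrugParameters,
    MtxParameters,
    MtxRegimen,
    PhysiologyParameters,
    Regimen,
    SolverSettings,
)
from .units import mg_to_nmol

DRUG_COMPARTMENTS = (
    "depot",
    "plasma",
    "lymph_node",
    "tissue_vascular",
    "tissue_endosomal",
    "tissue_interstitial",
)

IMMUNE_STATES = (
    "ID_i", "ID_m", "NT", "AT", "MT", "NB", "AB", "MB", "SP", "LP",
    "ADA", "Complex",
)


class SolverFailure(RuntimeError):
    """ODE solver did not converge for one subject."""

    def __init__(self, message: str, subject_id: Optional[str] = None):
        super().__init__(message)
        self.subject_id = subject_id


@dataclass
class SubjectTrajectory:
    """Simulated time course for one virtual subject.

    ``drug_nM`` maps compartment name to free-drug concentration (the depot
    entry is an amount in nmol, flagged by its name); ``ada_total_nM`` is the
    assay-visible total ADA (free + complexed), the quantity used for
    positivity classification and the [ADA]:[Drug] ratio.
    """

    times: np.ndarray
    drug_nM: dict[str, np.ndarray]
    ada_free_nM: np.ndarray
    ada_total_nM: np.ndarray
    complex_nM: np.ndarray
    cells: dict[str, np.ndarray]
    mode: str  # "full" or "pk_only"
    subject_id: Optional[str] = None

    def at(self, series: np.ndarray, t: float) -> float:
        idx = np.flatnonzero(np.isclose(self.times, t, rtol=0, atol=1e-9))
        if idx.size == 0:
            raise ValueError(f"time {t} h is not on the trajectory grid")
        return float(series[idx[0]])

    def free_plasma_at(self, t: float) -> float:
        return self.at(self.drug_nM["plasma"], t)

    def ada_total_at(self, times) -> np.ndarray:
        return np.array([self.at(self.ada_total_nM, t) for t in np.atleast_1d(times)])

    def total_drug_nmol(self, physiology: PhysiologyParameters) -> np.ndarray:
        """Free drug over all compartments plus drug held in complexes."""
        vols = {
            "plasma": physiology.v_plasma_L,
            "lymph_node": physiology.v_lymph_node_L,
            "tissue_vascular": physiology.v_tissue_vascular_L,
            "tissue_endosomal": physiology.v_tissue_endosomal_L,
            "tissue_interstitial": physiology.v_tissue_interstitial_L,
        }
        total = self.drug_nM["depot"].copy()  # depot stored as nmol
        for name, v in vols.items():
            total = total + self.drug_nM[name] * v
        total = total + self.complex_nM * physiology.v_plasma_L
        return total


# ---------------------------------------------------------------------------
# dose events

@dataclass
class DoseEvents:
    """Bolus state jumps and zero-order infusion windows."""

    boluses: list[tuple[float, int, float]] = field(default_factory=list)
    # (t_h, state_index, amount_nmol)
    infusions: list[tuple[float, float, float]] = field(default_factory=list)
    # (t0_h, t1_h, rate_nmol_per_h) into plasma

    def breakpoints(self) -> list[float]:
        pts = {t for t, _i, _a in self.boluses}
        for t0, t1, _r in self.infusions:
            pts.update((t0, t1))
        return sorted(pts)

    def infusion_rate(self, t: float) -> float:
        return sum(r for t0, t1, r in self.infusions if t0 <= t < t1)


def build_dose_events(
    drug: DrugParameters, physiology: PhysiologyParameters, regimen: Regimen
) -> DoseEvents:
    events = DoseEvents()
    for t, dose_mg in regimen.doses():
        if dose_mg <= 0:
            raise ValueError(f"non-positive dose {dose_mg} mg at t={t} h")
        amount_mg = dose_mg * physiology.body_weight_kg if regimen.per_kg else dose_mg
        nmol = mg_to_nmol(amount_mg, drug.molecular_weight_g_per_mol)
        if drug.route == "SC":
            events.boluses.append((t, 0, drug.bioavailability * nmol))
        elif drug.route == "IV_bolus":
            events.boluses.append((t, 1, nmol))
        else:  # IV_infusion
            dur = drug.infusion_duration_h
            events.infusions.append((t, t + dur, nmol / dur))
    return events


# ---------------------------------------------------------------------------
# PBPK right-hand side (scalar arithmetic: called thousands of times per run)

def pk_rhs_factory(
    drug: DrugParameters,
    physiology: PhysiologyParameters,
    clearance_L_per_h: float,
) -> Callable:
    """RHS over the 6 drug states; returns f(t, y, infusion_rate) -> list."""
    p = physiology
    ka = drug.ka_per_h if drug.route == "SC" else 0.0
    v_pl, v_ln = p.v_plasma_L, p.v_lymph_node_L
    v_v, v_e, v_i = (
        p.v_tissue_vascular_L,
        p.v_tissue_endosomal_L,
        p.v_tissue_interstitial_L,
    )
    qb, ql, qe = p.q_blood_L_per_h, p.q_lymph_L_per_h, p.q_endosomal_L_per_h
    refl = 1.0 - p.sigma_vascular
    cl = clearance_L_per_h

    def rhs(t, y, u_inf=0.0):
        a_dep, a_pl, a_ln, a_v, a_e, a_i = y[:6]
        c_pl = a_pl / v_pl
        c_ln = a_ln / v_ln
        c_v = a_v / v_v
        c_e = a_e / v_e
        c_i = a_i / v_i
        absorption = ka * a_dep
        j_endo = qe * (c_v - c_e)
        d_dep = -absorption
        d_pl = (
            absorption + u_inf + ql * c_ln - qb * c_pl
            + (qb - ql) * c_v - cl * c_pl
        )
        d_v = qb * c_pl - (qb - ql) * c_v - ql * refl * c_v - j_endo
        d_e = j_endo
        d_i = ql * refl * c_v - ql * c_i
        d_ln = ql * c_i - ql * c_ln
        return [d_dep, d_pl, d_ln, d_v, d_e, d_i]

    return rhs


# ---------------------------------------------------------------------------
# event-aware integrator

def integrate_with_events(
    rhs: Callable,
    y0: np.ndarray,
    events: DoseEvents,
    t_grid: np.ndarray,
    solver: SolverSettings,
    subject_id: Optional[str] = None,
) -> np.ndarray:
    """Integrate y' = rhs(t, y, infusion_rate) across dose events.

    Outputs are returned at ``t_grid``; a grid point coinciding with a bolus
    time reports the pre-dose state.  Deterministic for fixed inputs.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("time grid must be 1-D and strictly increasing")
    t_end = t_grid[-1]
    breaks = [b for b in events.breakpoints() if b <= t_end]
    # segment edges only at event times; grid points are handled via t_eval
    edges = sorted({0.0, t_end, *breaks})

    y = np.array(y0, dtype=float)
    out = np.empty((len(t_grid), len(y)))
    filled = np.zeros(len(t_grid), dtype=bool)

    if np.isclose(t_grid[0], 0.0):
        out[0] = y
        filled[0] = True

    bolus_by_time: dict[float, list[tuple[int, float]]] = {}
    for t, idx, amt in events.boluses:
        if t <= t_end:
            bolus_by_time.setdefault(t, []).append((idx, amt))

    for t0, t1 in zip(edges[:-1], edges[1:]):
        for idx, amt in bolus_by_time.get(t0, []):
            y[idx] += amt
        u = events.infusion_rate(0.5 * (t0 + t1))
        mask = (~filled) & (t_grid > t0 + 1e-12) & (t_grid <= t1 + 1e-12)
        t_eval = t_grid[mask]
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method=solver.method,
            t_eval=t_eval if t_eval.size else None,
            rtol=solver.rtol,
            atol=solver.atol_nmol,
            args=(u,),
            dense_output=False,
        )
        if not sol.success:
            raise SolverFailure(
                f"ODE solver failed in segment [{t0}, {t1}] h: {sol.message}",
                subject_id=subject_id,
            )
        if t_eval.size:
            out[mask] = sol.y.T
            filled[mask] = True
        y = sol.y[:, -1] if sol.y.shape[1] else y
        # continue from the true segment endpoint
        if sol.t.size == 0 or not np.isclose(sol.t[-1], t1):
            sol2 = solve_ivp(
                rhs,
                (sol.t[-1] if sol.t.size else t0, t1),
                y,
                method=solver.method,
                rtol=solver.rtol,
                atol=solver.atol_nmol,
                args=(u,),
            )
            if not sol2.success:
                raise SolverFailure(
                    f"ODE solver failed in segment [{t0}, {t1}] h: {sol2.message}",
                    subject_id=subject_id,
                )
            y = sol2.y[:, -1]

    if not filled.all():
        raise SolverFailure("internal error: unfilled grid points", subject_id)
    # solver undershoot can leave magnitudes ~atol below zero; report 0 instead
    return np.clip(out, 0.0, None)


def _empty_trajectory_parts(n: int):
    zeros = np.zeros(n)
    cells = {name: zeros.copy() for name in IMMUNE_STATES[:-2]}
    return zeros, cells


def simulate_pk_only(
    drug: DrugParameters,
    physiology: PhysiologyParameters,
    regimen: Regimen,
    time_grid,
    clearance_L_per_h: Optional[float] = None,
    solver: Optional[SolverSettings] = None,
    subject_id: Optional[str] = None,
) -> SubjectTrajectory:
    """Drug disposition with the immune-response model deactivated.

    ``clearance_L_per_h`` defaults to the drug's population mean times the
    subject's clearance multiplier.
    """
    solver = solver or SolverSettings()
    cl = (
        clearance_L_per_h
        if clearance_L_per_h is not None
        else drug.clearance_mean_L_per_h * physiology.clearance_multiplier
    )
    if cl < 0:
        raise ValueError("clearance must be >= 0")
    t_grid = np.asarray(time_grid, dtype=float)
    events = build_dose_events(drug, physiology, regimen)
    rhs = pk_rhs_factory(drug, physiology, cl)
    y0 = np.zeros(6)
    Y = integrate_with_events(rhs, y0, events, t_grid, solver, subject_id)
    vols = np.array(
        [
            1.0,  # depot reported as an amount
            physiology.v_plasma_L,
            physiology.v_lymph_node_L,
            physiology.v_tissue_vascular_L,
            physiology.v_tissue_endosomal_L,
            physiology.v_tissue_interstitial_L,
        ]
    )
    conc = Y / vols
    zeros, cells = _empty_trajectory_parts(len(t_grid))
    return SubjectTrajectory(
        times=t_grid,
        drug_nM={name: conc[:, i] for i, name in enumerate(DRUG_COMPARTMENTS)},
        ada_free_nM=zeros.copy(),
        ada_total_nM=zeros.copy(),
        complex_nM=zeros.copy(),
        cells=cells,
        mode="pk_only",
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# methotrexate: two-compartment oral PK, solved analytically

def mtx_system_matrix(p: MtxParameters) -> np.ndarray:
    """Linear system over amounts (gut, central, peripheral)."""
    k10 = p.cl_mtx_L_per_h / p.v1_mtx_L
    k12 = p.q_mtx_L_per_h / p.v1_mtx_L
    k21 = p.q_mtx_L_per_h / p.v2_mtx_L
    ka = p.ka_mtx_per_h
    return np.array(
        [
            [-ka, 0.0, 0.0],
            [ka, -(k10 + k12), k21],
            [0.0, k12, -k21],
        ]
    )


class MtxConcentration:
    """Analytic central methotrexate concentration (nM) under repeat dosing.

    The three-state linear system is eigendecomposed once; each dose
    contributes a tri-exponential term by superposition (the model is linear
    in dose).
    """

    def __init__(self, params: MtxParameters, regimen: MtxRegimen):
        self.params = params
        self.regimen = regimen
        A = mtx_system_matrix(params)
        lam, V = np.linalg.eig(A)
        dose_nmol = (
            params.f_mtx
            * mg_to_nmol(regimen.dose_mg, params.molecular_weight_g_per_mol)
        )
        # response of the central amount to a unit gut bolus
        w = V @ np.diag(np.linalg.solve(V, np.array([1.0, 0.0, 0.0])))
        self._lam = np.real_if_close(lam)
        self._coef = np.real_if_close(w[1, :]) * dose_nmol / params.v1_mtx_L
        self._dose_times = np.array(regimen.dose_times())

    def __call__(self, t) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time must be >= 0")
        dt = t_arr[..., None] - self._dose_times  # (..., n_doses)
        active = dt >= 0
        terms = np.where(
            active[..., None],
            self._coef * np.exp(np.where(active[..., None], dt[..., None], 0.0) * self._lam),
            0.0,
        )
        c = terms.sum(axis=(-1, -2))
        c = np.clip(np.real(c), 0.0, None)
        return float(c) if np.isscalar(t) or t_arr.ndim == 0 else c


def mtx_concentration(params: MtxParameters, mtx_regimen: MtxRegimen, t):
    """Central methotrexate concentration (nM) at time(s) ``t`` hours."""
    return MtxConcentration(params, mtx_regimen)(t)
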