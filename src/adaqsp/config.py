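"""Validated parameter containers and structured-text (YAML) configuration.

Every container is a pydantic model with ``extra="forbid"`` so that unknown
keys in a config file are rejected by name.  Field names carry their units
(``clearance_mean_L_per_h``).  Defaults encode the package's reference
study conditions: 250 virtual subjects, a 100 ng/mL ADA positivity threshold
(the FDA minimum recommended assay sensitivity), up to five selected
epitopes, and a methotrexate IC50 of 283 nM.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .epitope import Epitope
from .units import IGG_MW_G_PER_MOL


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)


class DrugParameters(_Model):
    """Compound-specific PK and immunogenicity inputs for the therapeutic."""

    name: str = "drug"
    molecular_weight_g_per_mol: float = Field(gt=0)
    clearance_mean_L_per_h: float = Field(gt=0)
    clearance_cv: float = Field(default=0.0, ge=0)
    route: Literal["IV_bolus", "IV_infusion", "SC"] = "IV_bolus"
    bioavailability: Optional[float] = None  # SC only, (0, 1]
    ka_per_h: Optional[float] = None  # SC first-order absorption
    infusion_duration_h: Optional[float] = None  # IV_infusion only
    dc_uptake: float = Field(default=1.0, ge=0)
    naive_t_fraction: float = Field(default=1e-4, gt=0, le=1)
    epitopes: list[Epitope] = Field(default_factory=list)

    @field_validator("epitopes", mode="before")
    @classmethod
    def _coerce_epitopes(cls, v):
        if v is None:
            return []
        return [Epitope(**e) if isinstance(e, dict) else e for e in v]

    @model_validator(mode="after")
    def _route_consistency(self):
        if self.route == "SC":
            if self.bioavailability is None or not (0 < self.bioavailability <= 1):
                raise ValueError("SC route requires bioavailability in (0, 1]")
            if self.ka_per_h is None or self.ka_per_h <= 0:
                raise ValueError("SC route requires ka_per_h > 0")
        if self.route == "IV_infusion":
            if self.infusion_duration_h is None or self.infusion_duration_h <= 0:
                raise ValueError("IV_infusion route requires infusion_duration_h > 0")
        return self


class PhysiologyParameters(_Model):
    """One subject's minimal-PBPK physiology.

    Plasma, lymph node, and a lumped tissue split into vascular, endosomal
    and interstitial sub-compartments.  ``sigma_vascular`` is the vascular
    reflection coefficient limiting convective transcapillary transport;
    ``q_endosomal_L_per_h`` is a passive vascular<->endosomal exchange flow
    (the endosomal space is structural — elimination is linear from plasma).
    """

    body_weight_kg: float = Field(default=70.0, gt=0)
    v_plasma_L: float = Field(default=3.0, gt=0)
    v_lymph_node_L: float = Field(default=0.3, gt=0)
    v_tissue_vascular_L: float = Field(default=1.5, gt=0)
    v_tissue_endosomal_L: float = Field(default=0.5, gt=0)
    v_tissue_interstitial_L: float = Field(default=8.0, gt=0)
    q_blood_L_per_h: float = Field(default=60.0, gt=0)
    q_lymph_L_per_h: float = Field(default=0.12, gt=0)
    q_endosomal_L_per_h: float = Field(default=0.05, gt=0)
    sigma_vascular: float = Field(default=0.95, ge=0, le=1)
    clearance_multiplier: float = Field(default=1.0, gt=0)

    @model_validator(mode="after")
    def _flow_order(self):
        if not self.q_lymph_L_per_h < self.q_blood_L_per_h:
            raise ValueError("lymph flow must be smaller than blood flow")
        return self


class MtxParameters(_Model):
    """Oral methotrexate: two-compartment PK with first-order absorption,
    plus an inhibitory Emax effect on the T-cell proliferation rate."""

    ka_mtx_per_h: float = Field(default=0.7, gt=0)
    cl_mtx_L_per_h: float = Field(default=7.0, gt=0)
    q_mtx_L_per_h: float = Field(default=0.3, gt=0)
    v1_mtx_L: float = Field(default=10.0, gt=0)
    v2_mtx_L: float = Field(default=4.0, gt=0)
    f_mtx: float = Field(default=0.7, gt=0, le=1)
    imax: float = Field(default=1.0, gt=0, le=1)
    ic50_nM: float = Field(default=283.0, gt=0)
    molecular_weight_g_per_mol: float = Field(default=454.44, gt=0)


class ImmuneRates(_Model):
    """Rate constants for the humoral-response lineages.

    These lineage constants are assumed structural stand-ins, not
    values from a published fit: they are tuned so that a strong-epitope
    compound seroconverts within about four weeks of repeat dosing while a
    weak-epitope compound does not.  Units are 1/h unless stated.
    ``k_ag_n`` is the half-maximal activation constant of the presented
    antigen signal (dimensionless), the one constant intended for
    calibration against observed incidences.
    """

    k_ag_n: float = Field(default=5e3, gt=0)
    t_repertoire: float = Field(default=1e6, gt=0)  # naive CD4 pool scaling

    # dendritic cells
    id_i0: float = Field(default=100.0, ge=0)  # initial immature DC count
    k_id_in: float = Field(default=10.0, ge=0)  # immature DC supply, cells/h
    k_id_death: float = Field(default=0.01, ge=0)
    k_mat: float = Field(default=0.1, ge=0)  # antigen-driven maturation
    k_dc_nM: float = Field(default=1.0, gt=0)  # half-max antigen for maturation
    k_idm_death: float = Field(default=0.02, ge=0)

    # drug-specific CD4+ T lineage
    k_act_t: float = Field(default=0.1, ge=0)
    rho_at: float = Field(default=0.1, ge=0)  # proliferation, MTX-inhibited
    k_at_death: float = Field(default=0.01, ge=0)
    k_mem_t: float = Field(default=0.005, ge=0)
    k_mt_death: float = Field(default=1e-4, ge=0)
    k_react_t: float = Field(default=0.01, ge=0)

    # drug-specific B lineage
    nb0: float = Field(default=100.0, ge=0)  # initial naive B count
    k_act_b: float = Field(default=0.05, ge=0)
    rho_ab: float = Field(default=0.1, ge=0)
    b_cap_cells: float = Field(default=5e3, gt=0)  # B-cell carrying capacity
    k_ab_death: float = Field(default=0.01, ge=0)
    k_diff: float = Field(default=0.02, ge=0)  # plasma-cell differentiation
    f_sp: float = Field(default=0.8, ge=0)
    f_lp: float = Field(default=0.05, ge=0)
    f_mb: float = Field(default=0.15, ge=0)
    k_help_cells: float = Field(default=4000.0, gt=0)  # half-max T help (Hill 2)
    k_bcell_ag_nM: float = Field(default=1.0, gt=0)  # half-max antigen gate
    k_sp_death: float = Field(default=0.02, ge=0)
    k_lp_death: float = Field(default=0.001, ge=0)
    k_mb_death: float = Field(default=5e-4, ge=0)
    k_react_b: float = Field(default=0.01, ge=0)

    # ADA secretion, elimination and drug binding
    k_sec_sp_nmol_per_h: float = Field(default=1.5e-3, ge=0)  # per cell
    k_sec_lp_nmol_per_h: float = Field(default=3e-3, ge=0)
    k_ada_elim: float = Field(default=0.0014, ge=0)  # IgG turnover, t1/2 ~21 d
    kon_per_nM_per_h: float = Field(default=0.36, gt=0)
    koff_per_h: float = Field(default=0.36, gt=0)
    k_ic: float = Field(default=0.005, ge=0)  # immune-complex clearance


class MtxRegimen(_Model):
    """Oral methotrexate co-medication schedule (dose 0 = no exposure)."""

    dose_mg: float = Field(ge=0)
    interval_h: float = Field(default=168.0, gt=0)
    n_doses: int = Field(default=1, ge=1)
    start_h: float = Field(default=0.0, ge=0)

    def dose_times(self) -> list[float]:
        return [self.start_h + i * self.interval_h for i in range(self.n_doses)]


class Regimen(_Model):
    """Therapeutic dosing schedule.

    ``dose_times_h``, when given, overrides the (interval, n_doses) pattern
    and may carry per-dose amounts for loading regimens.
    """

    dose_mg: float = Field(gt=0)
    per_kg: bool = False
    interval_h: float = Field(default=336.0, gt=0)
    n_doses: int = Field(default=1, ge=1)
    dose_times_h: Optional[list[float]] = None
    dose_amounts_mg: Optional[list[float]] = None  # paired with dose_times_h
    mtx: Optional[MtxRegimen] = None

    @model_validator(mode="after")
    def _explicit_schedule(self):
        if self.dose_times_h is not None:
            if sorted(self.dose_times_h) != list(self.dose_times_h):
                raise ValueError("dose_times_h must be non-decreasing")
            if any(t < 0 for t in self.dose_times_h):
                raise ValueError("dose times must be >= 0")
            if self.dose_amounts_mg is not None:
                if len(self.dose_amounts_mg) != len(self.dose_times_h):
                    raise ValueError(
                        "dose_amounts_mg must match dose_times_h in length"
                    )
                if any(a <= 0 for a in self.dose_amounts_mg):
                    raise ValueError("dose amounts must be positive")
        elif self.dose_amounts_mg is not None:
            raise ValueError("dose_amounts_mg requires dose_times_h")
        return self

    def doses(self) -> list[tuple[float, float]]:
        """(time h, amount mg) pairs."""
        if self.dose_times_h is not None:
            amounts = self.dose_amounts_mg or [self.dose_mg] * len(self.dose_times_h)
            return list(zip(self.dose_times_h, amounts))
        return [(i * self.interval_h, self.dose_mg) for i in range(self.n_doses)]


class SamplingSchedule(_Model):
    """ADA and PK assessment times; the final time must appear in both."""

    ada_times_h: list[float]
    pk_times_h: list[float]
    final_time_h: float = Field(gt=0)

    @model_validator(mode="after")
    def _times_consistent(self):
        for name, times in (("ada", self.ada_times_h), ("pk", self.pk_times_h)):
            if not times:
                raise ValueError(f"{name}_times_h must be non-empty")
            if any(t < 0 or t > self.final_time_h for t in times):
                raise ValueError(
                    f"{name} sampling times must lie within [0, final_time_h]"
                )
            if self.final_time_h not in times:
                raise ValueError(
                    f"final_time_h must be present in {name}_times_h"
                )
        return self


class TrialConfig(_Model):
    """Trial-level analysis settings."""

    ada_threshold_ng_per_ml: float = Field(default=100.0, gt=0)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    ada_mw_g_per_mol: float = Field(default=IGG_MW_G_PER_MOL, gt=0)
    min_positive_group: int = Field(default=2, ge=1)


class LognormalSpec(_Model):
    mean: float = Field(gt=0)
    cv: float = Field(default=0.0, ge=0)


class PopulationConfig(_Model):
    """Virtual-population size and physiological variability.

    Each physiological parameter is sampled from an independent lognormal
    distribution parameterised by its arithmetic mean and CV; CV = 0 gives
    the mean deterministically.
    """

    n: int = Field(default=250, ge=1)
    body_weight_kg: LognormalSpec = LognormalSpec(mean=70.0, cv=0.15)
    v_plasma_L: LognormalSpec = LognormalSpec(mean=3.0, cv=0.2)
    v_lymph_node_L: LognormalSpec = LognormalSpec(mean=0.3, cv=0.2)
    v_tissue_vascular_L: LognormalSpec = LognormalSpec(mean=1.5, cv=0.2)
    v_tissue_endosomal_L: LognormalSpec = LognormalSpec(mean=0.5, cv=0.2)
    v_tissue_interstitial_L: LognormalSpec = LognormalSpec(mean=8.0, cv=0.2)
    q_blood_L_per_h: LognormalSpec = LognormalSpec(mean=60.0, cv=0.3)
    q_lymph_L_per_h: LognormalSpec = LognormalSpec(mean=0.12, cv=0.3)
    q_endosomal_L_per_h: LognormalSpec = LognormalSpec(mean=0.05, cv=0.3)
    sigma_vascular: float = Field(default=0.95, ge=0, le=1)


class SolverSettings(_Model):
    """Deterministic stiff-capable ODE solver settings (LSODA)."""

    rtol: float = Field(default=1e-8, gt=0)
    atol_nmol: float = Field(default=1e-10, gt=0)
    method: str = "LSODA"


class SimulationConfig(_Model):
    """Top-level config: one document per virtual study."""

    drug: DrugParameters
    regimen: Regimen
    schedule: SamplingSchedule
    trial: TrialConfig = TrialConfig()
    population: PopulationConfig = PopulationConfig()
    immune: ImmuneRates = ImmuneRates()
    immune_enabled: bool = True
    mtx: Optional[MtxParameters] = None
    solver: SolverSettings = SolverSettings()


class ConfigError(ValueError):
    """Raised for unreadable or invalid configuration files."""


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML study configuration."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not valid YAML: {exc}")
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    try:
        return SimulationConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries field names
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc
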