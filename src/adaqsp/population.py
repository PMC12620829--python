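"""Virtual-population generation: physiology and HLA class II genetics.

Subjects carry lognormally sampled physiological parameters and clearance
(arithmetic-mean / CV parameterisation) and an HLA genotype of two alleles
or haplotypes at each of the DRB1, DQ and DP loci, drawn independently with
replacement according to population frequencies (so homozygosity is
allowed).  Frequency tables aggregated over several studies weight each
study by its sample size before per-locus renormalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DrugParameters, LognormalSpec, PhysiologyParameters, PopulationConfig

LOCI = ("DRB1", "DQ", "DP")


@dataclass
class FrequencyTable:
    """Per-locus allele/haplotype frequencies (normalised to sum to 1)."""

    loci: dict[str, list[tuple[str, float]]]
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def normalised(self) -> "FrequencyTable":
        out = {}
        for locus, entries in self.loci.items():
            total = sum(f for _a, f in entries)
            if total <= 0:
                raise ValueError(f"locus {locus} has no positive frequencies")
            out[locus] = [(a, f / total) for a, f in entries]
        return FrequencyTable(loci=out, provenance=list(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": locus, "allele": a, "frequency": f}
            for locus, entries in self.loci.items()
            for a, f in entries
        ]
        return pd.DataFrame(rows, columns=["locus", "allele", "frequency"])


@dataclass(frozen=True)
class HLAGenotype:
    """Unordered pair of alleles/haplotypes per locus."""

    alleles: Mapping[str, tuple[str, str]]

    def allele_set(self) -> tuple[str, ...]:
        seen: list[str] = []
        for pair in self.alleles.values():
            for a in pair:
                if a not in seen:
                    seen.append(a)
        return tuple(seen)


@dataclass
class VirtualSubject:
    id: str
    physiology: PhysiologyParameters
    genotype: HLAGenotype
    clearance_L_per_h: float
    rng_seed: int


def aggregate_allele_frequencies(
    studies: Sequence[tuple[int, Mapping[str, Mapping[str, float]]]],
    provenance: Optional[Sequence[tuple[str, int]]] = None,
) -> FrequencyTable:
    """Weighted average of per-study frequencies, weights = sample sizes.

    Each study is ``(sample_size, {locus: {allele: frequency}})``.  An allele
    missing from a study counts as frequency 0 there (with a warning), and
    each locus is renormalised so the listed alleles sum to 1.
    """
    if not studies:
        raise ValueError("at least one study is required")
    total_n = 0
    for n, freqs in studies:
        if n <= 0:
            raise ValueError("study sample sizes must be positive")
        for locus, table in freqs.items():
            for a, f in table.items():
                if not (0 <= f <= 1):
                    raise ValueError(
                        f"frequency {f} for {locus}/{a} outside [0, 1]"
                    )
        total_n += n
    loci: dict[str, dict[str, float]] = {}
    all_alleles: dict[str, set[str]] = {}
    for _n, freqs in studies:
        for locus, table in freqs.items():
            all_alleles.setdefault(locus, set()).update(table)
    for locus, alleles in all_alleles.items():
        acc = {a: 0.0 for a in alleles}
        for n, freqs in studies:
            table = freqs.get(locus, {})
            for a in alleles:
                if a not in table and len(studies) > 1:
                    warnings.warn(
                        f"allele {a} absent from one study at locus {locus}; "
                        "treated as frequency 0",
                        stacklevel=2,
                    )
                acc[a] += n * table.get(a, 0.0)
        loci[locus] = {a: v / total_n for a, v in acc.items()}
    table = FrequencyTable(
        loci={
            locus: sorted(entries.items()) for locus, entries in loci.items()
        },
        provenance=list(provenance or []),
    )
    return table.normalised()


def read_frequency_table(path) -> FrequencyTable:
    """Read a locus/allele/study_id/sample_size/frequency TSV and aggregate."""
    df = pd.read_csv(path, sep="\t")
    required = {"locus", "allele", "study_id", "sample_size", "frequency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"frequency table missing column(s): {sorted(missing)}")
    studies = []
    provenance = []
    for study_id, sub in df.groupby("study_id", sort=True):
        n = int(sub["sample_size"].iloc[0])
        freqs: dict[str, dict[str, float]] = {}
        for _, row in sub.iterrows():
            freqs.setdefault(str(row["locus"]), {})[str(row["allele"])] = float(
                row["frequency"]
            )
        studies.append((n, freqs))
        provenance.append((str(study_id), n))
    return aggregate_allele_frequencies(studies, provenance=provenance)


def sample_genotypes(
    table: FrequencyTable, n: int, seed: int
) -> list[HLAGenotype]:
    """Two independent draws per locus per subject, with replacement."""
    if n < 1:
        raise ValueError("n must be >= 1")
    norm = table.normalised()
    rng = np.random.default_rng(seed)
    names: dict[str, list[str]] = {}
    probs: dict[str, np.ndarray] = {}
    for locus, entries in norm.loci.items():
        if not entries:
            raise ValueError(f"locus {locus} has no alleles")
        names[locus] = [a for a, _f in entries]
        probs[locus] = np.array([f for _a, f in entries])
    draws = {
        locus: rng.choice(len(names[locus]), size=(n, 2), p=probs[locus])
        for locus in norm.loci
    }
    return [
        HLAGenotype(
            alleles={
                locus: (
                    names[locus][draws[locus][i, 0]],
                    names[locus][draws[locus][i, 1]],
                )
                for locus in norm.loci
            }
        )
        for i in range(n)
    ]


def lognormal_draws(spec: LognormalSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal with arithmetic mean ``spec.mean`` and CV ``spec.cv``."""
    if spec.cv < 0:
        raise ValueError("CV must be >= 0")
    if spec.cv == 0:
        return np.full(n, spec.mean)
    sigma2 = np.log1p(spec.cv**2)
    mu = np.log(spec.mean) - 0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


_PHYS_FIELDS = (
    "body_weight_kg",
    "v_plasma_L",
    "v_lymph_node_L",
    "v_tissue_vascular_L",
    "v_tissue_endosomal_L",
    "v_tissue_interstitial_L",
    "q_blood_L_per_h",
    "q_lymph_L_per_h",
    "q_endosomal_L_per_h",
)


def sample_physiology(
    config: PopulationConfig,
    clearance: LognormalSpec,
    n: int,
    seed: int,
) -> tuple[list[PhysiologyParameters], np.ndarray]:
    """Independent lognormal draws per physiological parameter + clearance.

    The rare draw violating Q_lymph < Q_blood is redrawn from the same
    stream (bounded retries) so every returned parameter set is valid.
    """
    rng = np.random.default_rng(seed)
    draws = {name: lognormal_draws(getattr(config, name), n, rng) for name in _PHYS_FIELDS}
    cl_mult = lognormal_draws(LognormalSpec(mean=1.0, cv=clearance.cv), n, rng)
    cl = clearance.mean * cl_mult
    out = []
    for i in range(n):
        values = {name: float(draws[name][i]) for name in _PHYS_FIELDS}
        for _attempt in range(100):
            if values["q_lymph_L_per_h"] < values["q_blood_L_per_h"]:
                break
            values["q_lymph_L_per_h"] = float(
                lognormal_draws(config.q_lymph_L_per_h, 1, rng)[0]
            )
        out.append(
            PhysiologyParameters(
                sigma_vascular=config.sigma_vascular,
                clearance_multiplier=float(cl_mult[i]),
                **values,
            )
        )
    return out, cl


def generate_population(
    table: FrequencyTable,
    config: Optional[PopulationConfig] = None,
    drug: Optional[DrugParameters] = None,
    clearance: Optional[LognormalSpec] = None,
    n: Optional[int] = None,
    seed: int = 0,
) -> list[VirtualSubject]:
    """Sample ``n`` virtual subjects (default 250) with paired per-subject seeds.

    Clearance variability comes from ``clearance`` or, when a drug is given,
    from its (mean, CV); derived per-subject seeds feed any downstream
    stochastic step reproducibly.
    """
    config = config or PopulationConfig()
    n = int(n if n is not None else config.n)
    if n < 1:
        raise ValueError("population size must be >= 1")
    if clearance is None:
        if drug is None:
            raise ValueError("either drug or clearance spec must be given")
        clearance = LognormalSpec(
            mean=drug.clearance_mean_L_per_h, cv=drug.clearance_cv
        )
    rng = np.random.default_rng(seed)
    phys_seed, geno_seed = rng.integers(0, 2**31 - 1, size=2)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n)
    physiology, cl = sample_physiology(config, clearance, n, int(phys_seed))
    genotypes = sample_genotypes(table, n, int(geno_seed))
    return [
        VirtualSubject(
            id=f"S{i + 1:04d}",
            physiology=physiology[i],
            genotype=genotypes[i],
            clearance_L_per_h=float(cl[i]),
            rng_seed=int(subject_seeds[i]),
        )
        for i in range(n)
    ]


def population_frame(subjects: Sequence[VirtualSubject]) -> pd.DataFrame:
    """One row per subject: physiology, clearance, and six allele columns."""
    rows = []
    for s in subjects:
        row = {"id": s.id, "clearance_L_per_h": s.clearance_L_per_h}
        row.update({f: getattr(s.physiology, f) for f in _PHYS_FIELDS})
        for locus in s.genotype.alleles:
            a1, a2 = s.genotype.alleles[locus]
            row[f"{locus}_1"] = a1
            row[f"{locus}_2"] = a2
        row["rng_seed"] = s.rng_seed
        rows.append(row)
    return pd.DataFrame(rows)
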