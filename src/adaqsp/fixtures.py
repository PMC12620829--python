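"""Seeded synthetic inputs: toy proteomes, rank tables, HLA tables, scenarios.

Real studies feed this simulator NetMHCIIpan elution ranks, Allele Frequency
Net tables and UniProt proteomes.  None of those are shipped; instead this
module generates structurally faithful synthetic stand-ins so that every
pipeline stage runs end-to-end without downloads.  The three named drug
scenarios define the package's reference study conditions:

``high_risk_drug``   five strong epitopes (elution ranks <= 2 across the
                     reference set) — seroconverts broadly under repeat
                     dosing, with ADA high enough to impact exposure.
``low_risk_drug``    epitopes with ranks >= 20 — occasional weak ADA
                     responses that never reach exposure-relevant levels.
``no_epitope_drug``  empty epitope list — the immune block is inert.

Allele names follow real nomenclature shape (locus*NN:NN); the frequencies
are seeded placeholders, not population estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    DrugParameters,
    ImmuneRates,
    Regimen,
    SamplingSchedule,
    TrialConfig,
)
from .epitope import PEPTIDE_LENGTH, Epitope
from .population import FrequencyTable, generate_population
from .trial import TrialResult, run_trial

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SCENARIO_NAMES = ("high_risk_drug", "low_risk_drug", "no_epitope_drug")
SCENARIO_SEED = 20250  # fixed: scenario tables are study inputs, not run randomness

DRB1_ALLELES = (
    "DRB1*01:01", "DRB1*03:01", "DRB1*04:01", "DRB1*04:05", "DRB1*07:01",
    "DRB1*08:02", "DRB1*09:01", "DRB1*11:01", "DRB1*12:01", "DRB1*13:02",
    "DRB1*15:01",
)
DQ_HAPLOTYPES = (
    "DQA1*05:01-DQB1*02:01", "DQA1*05:01-DQB1*03:01", "DQA1*03:01-DQB1*03:02",
    "DQA1*04:01-DQB1*04:02", "DQA1*01:01-DQB1*05:01", "DQA1*01:02-DQB1*06:02",
)
DP_HAPLOTYPES = (
    "DPA1*02:01-DPB1*01:01", "DPA1*01:03-DPB1*02:01", "DPA1*01:03-DPB1*04:01",
    "DPA1*03:01-DPB1*04:02", "DPA1*02:01-DPB1*05:01", "DPA1*02:01-DPB1*14:01",
)
REFERENCE_ALLELES = DRB1_ALLELES + DQ_HAPLOTYPES + DP_HAPLOTYPES


def make_toy_proteome(
    n_records: int,
    record_length: int = 120,
    seed: int = 0,
    spike: str | None = None,
    spike_record: int = 0,
) -> list[tuple[str, str]]:
    """Random amino-acid FASTA records, optionally spiking a 15-mer.

    The spiked peptide is inserted whole into ``spike_record`` so it is
    recoverable by substring search (used by self-filter tests).
    """
    if n_records < 0:
        raise ValueError("n_records must be >= 0")
    if spike is not None and record_length < PEPTIDE_LENGTH:
        raise ValueError(
            f"record_length must be >= {PEPTIDE_LENGTH} to spike a peptide"
        )
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_records):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=record_length))
        if spike is not None and i == spike_record:
            pos = int(rng.integers(0, record_length - len(spike) + 1))
            seq = seq[:pos] + spike + seq[pos + len(spike):]
        records.append((f"toyprot{i + 1:03d}", seq))
    return records


def make_antigen_sequence(length: int = 75, seed: int = SCENARIO_SEED) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def make_rank_table(
    peptides,
    alleles,
    scenario: str,
    seed: int = SCENARIO_SEED,
) -> pd.DataFrame:
    """Complete (peptide x allele) elution-rank table for a risk scenario.

    ``high_risk`` draws ranks uniformly from (0.1, 2]; ``low_risk`` from
    [20, 100] — the ranges that make best-rank invariants of the shipped
    scenarios hold by construction.
    """
    if not len(peptides) or not len(alleles):
        raise ValueError("peptides and alleles must be non-empty")
    rng = np.random.default_rng(seed)
    key = scenario.removesuffix("_drug")
    if key == "high_risk":
        lo, hi = 0.1, 2.0
    elif key == "low_risk":
        lo, hi = 20.0, 100.0
    else:
        raise ValueError(f"unknown rank-table scenario: {scenario!r}")
    rows = []
    for pep in peptides:
        for allele in alleles:
            rows.append(
                {
                    "peptide": pep,
                    "allele": allele,
                    "el_rank": round(float(rng.uniform(lo, hi)), 4),
                }
            )
    return pd.DataFrame(rows, columns=["peptide", "allele", "el_rank"])


def make_default_hla_table(seed: int = SCENARIO_SEED) -> FrequencyTable:
    """Placeholder frequency table: 11 DRB1 alleles, 6 DQ and 6 DP haplotypes.

    Mirrors the IEDB class-II reference-set structure; frequencies are
    seeded Dirichlet draws summing to 1 per locus.
    """
    rng = np.random.default_rng(seed)
    loci = {}
    for locus, names in (
        ("DRB1", DRB1_ALLELES),
        ("DQ", DQ_HAPLOTYPES),
        ("DP", DP_HAPLOTYPES),
    ):
        freqs = rng.dirichlet(np.full(len(names), 3.0))
        loci[locus] = list(zip(names, freqs.tolist()))
    return FrequencyTable(loci=loci, provenance=[("synthetic", 1000)])


@dataclass
class Scenario:
    """A named, fully specified virtual study."""

    name: str
    drug: DrugParameters
    regimen: Regimen
    schedule: SamplingSchedule
    trial: TrialConfig
    rates: ImmuneRates
    hla_table: FrequencyTable
    rank_table: pd.DataFrame
    antigen_sequence: str


def _scenario_epitopes(rank_df: pd.DataFrame, antigen: str) -> list[Epitope]:
    epitopes = []
    for i, pep in enumerate(rank_df["peptide"].unique()):
        sub = rank_df[rank_df["peptide"] == pep]
        ranks = dict(zip(sub["allele"], sub["el_rank"].astype(float)))
        epitopes.append(
            Epitope(
                peptide=pep,
                start=antigen.index(pep) + 1,
                ranks=ranks,
                best_rank=min(ranks.values()),
            )
        )
    return epitopes


def get_scenario(name: str, seed: int = SCENARIO_SEED) -> Scenario:
    """Build one of the shipped scenarios (deterministic for a fixed seed)."""
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}"
        )
    antigen = make_antigen_sequence(seed=seed)
    # five non-overlapping 15-mers tiled across the synthetic antigen
    peptides = [
        antigen[i : i + PEPTIDE_LENGTH]
        for i in range(0, 5 * PEPTIDE_LENGTH, PEPTIDE_LENGTH)
    ]
    if name == "no_epitope_drug":
        rank_df = pd.DataFrame(columns=["peptide", "allele", "el_rank"])
        epitopes = []
    else:
        rank_df = make_rank_table(peptides, REFERENCE_ALLELES, name, seed=seed)
        epitopes = _scenario_epitopes(rank_df, antigen)
    drug = DrugParameters(
        name=name,
        molecular_weight_g_per_mol=150_000.0,
        clearance_mean_L_per_h=0.01,
        clearance_cv=0.3,
        route="SC",
        bioavailability=0.7,
        ka_per_h=0.01,
        dc_uptake=1.0,
        naive_t_fraction=1e-4,
        epitopes=epitopes,
    )
    regimen = Regimen(dose_mg=100.0, interval_h=336.0, n_doses=6)
    troughs = [336.0 * k for k in range(1, 7)]
    schedule = SamplingSchedule(
        ada_times_h=troughs, pk_times_h=troughs, final_time_h=2016.0
    )
    return Scenario(
        name=name,
        drug=drug,
        regimen=regimen,
        schedule=schedule,
        trial=TrialConfig(),
        rates=ImmuneRates(),
        hla_table=make_default_hla_table(seed=seed),
        rank_table=rank_df,
        antigen_sequence=antigen,
    )


def run_scenario(
    name: str,
    n: int = 250,
    seed: int = 0,
    scenario: Scenario | None = None,
    **trial_kwargs,
) -> TrialResult:
    """Generate a population for a scenario and run its virtual trial."""
    sc = scenario or get_scenario(name)
    population = generate_population(sc.hla_table, drug=sc.drug, n=n, seed=seed)
    return run_trial(
        population,
        sc.drug,
        sc.regimen,
        sc.schedule,
        trial_config=sc.trial,
        rates=sc.rates,
        seed=seed,
        **trial_kwargs,
    )


def write_scenario(scenario: Scenario, out_dir) -> None:
    """Write a ready-to-run scenario directory (FASTA + TSVs)."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_fasta(
        out / "antigen.fasta", [(scenario.name + "_antigen", scenario.antigen_sequence)]
    )
    _io.write_fasta(
        out / "proteome.fasta", make_toy_proteome(5, 120, seed=SCENARIO_SEED)
    )
    scenario.rank_table.to_csv(out / "ranks.tsv", sep="\t", index=False)
    hla = scenario.hla_table.to_frame()
    hla.insert(2, "study_id", "synthetic")
    hla.insert(3, "sample_size", 1000)
    hla = hla[["locus", "allele", "study_id", "sample_size", "frequency"]]
    hla.to_csv(out / "hla.tsv", sep="\t", index=False, float_format="%.10g")
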