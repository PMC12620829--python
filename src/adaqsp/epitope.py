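"""T-cell epitope selection from MHC-II elution ranks.

Pipeline: enumerate all 15-mer windows of a protein sequence (or an eluted
peptide list), discard any 15-mer that occurs verbatim in a self-proteome
(immune tolerance to self peptides), attach per-allele elution-rank
percentiles (NetMHCIIpan-style, lower = stronger presentation), and greedily
pick up to five non-overlapping peptides with the lowest best rank across the
HLA reference set as the highest-risk potential T-cell epitopes.

Exact substring matching against the proteome stands in for a BLAST screen;
pre-filtered candidate lists from a real alignment run can be supplied
directly to :func:`select_epitopes`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

PEPTIDE_LENGTH = 15
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Epitope:
    """A candidate T-cell epitope.

    peptide    15-residue amino-acid string
    start      1-based inclusive position in the parent sequence
               (0 when the parent is an eluted-peptide list with no
               coordinates; such candidates are treated as non-overlapping)
    ranks      allele name -> elution rank percentile in (0, 100]
    best_rank  minimum rank over the HLA reference set
    """

    peptide: str
    start: int
    ranks: Mapping[str, float] = field(default_factory=dict)
    best_rank: float = 100.0

    def __post_init__(self):
        if len(self.peptide) != PEPTIDE_LENGTH:
            raise ValueError(
                f"epitope peptide must be {PEPTIDE_LENGTH} residues, "
                f"got {len(self.peptide)}"
            )
        for allele, r in self.ranks.items():
            if not (0.0 < r <= 100.0):
                raise ValueError(
                    f"elution rank for {allele!r} must be in (0, 100], got {r}"
                )

    def overlaps(self, other: "Epitope") -> bool:
        """Shared parent-sequence position; positionless candidates never overlap."""
        if self.start == 0 or other.start == 0:
            return False
        a0, a1 = self.start, self.start + PEPTIDE_LENGTH - 1
        b0, b1 = other.start, other.start + PEPTIDE_LENGTH - 1
        return a0 <= b1 and b0 <= a1

    def rank_for(self, allele: str) -> float:
        """Rank for one allele; missing pairs contribute nothing (rank 100)."""
        return float(self.ranks.get(allele, 100.0))


def _check_sequence(seq: str, label: str = "sequence") -> str:
    seq = seq.strip().upper()
    for i, ch in enumerate(seq):
        if ch not in VALID_RESIDUES:
            raise ValueError(
                f"invalid residue {ch!r} at position {i + 1} in {label}"
            )
    return seq


def enumerate_candidates(
    source: str | Sequence[str],
) -> list[tuple[str, int]]:
    """All 15-mer windows of a protein sequence or an eluted-peptide list.

    A single string is treated as a primary protein sequence and yields
    ``max(0, L - 14)`` windows with 1-based start positions.  A list of
    strings is treated as eluted peptides: each peptide is windowed
    independently and candidates carry ``start = 0`` (no parent coordinates);
    peptides shorter than 15 residues are skipped with a warning.
    """
    if isinstance(source, str):
        seq = _check_sequence(source)
        return [
            (seq[i : i + PEPTIDE_LENGTH], i + 1)
            for i in range(len(seq) - PEPTIDE_LENGTH + 1)
        ]
    out: list[tuple[str, int]] = []
    seen: set[str] = set()
    for j, pep in enumerate(source):
        seq = _check_sequence(pep, label=f"eluted peptide {j + 1}")
        if len(seq) < PEPTIDE_LENGTH:
            warnings.warn(
                f"eluted peptide {j + 1} is shorter than {PEPTIDE_LENGTH} "
                "residues and was skipped",
                stacklevel=2,
            )
            continue
        for i in range(len(seq) - PEPTIDE_LENGTH + 1):
            mer = seq[i : i + PEPTIDE_LENGTH]
            if mer not in seen:
                seen.add(mer)
                out.append((mer, 0))
    return out


def filter_self(
    candidates: Iterable[tuple[str, int]],
    proteome: Iterable[tuple[str, str]],
) -> list[tuple[str, int]]:
    """Drop candidates found verbatim inside any single self-proteome record.

    Matching is case-insensitive and strictly per record — a 15-mer spanning
    the junction of two records is not a match.  Order is preserved and the
    operation is idempotent.
    """
    records = [seq.upper() for _hdr, seq in proteome]
    kept = []
    for pep, start in candidates:
        mer = pep.upper()
        if not any(mer in rec for rec in records):
            kept.append((pep, start))
    return kept


def select_epitopes(candidates: Sequence[Epitope], max_n: int = 5) -> list[Epitope]:
    """Greedy non-overlapping selection by ascending best rank.

    Candidates are visited in order of (best_rank, start, peptide); one is
    skipped if its 15-residue interval shares any parent position with an
    already selected epitope.  Selection stops at ``max_n`` or exhaustion.
    The result is independent of the input order (deterministic tie-breaks)
    but greedy, not a guaranteed optimum over all non-overlapping subsets.
    """
    if max_n < 1:
        raise ValueError(f"max_n must be >= 1, got {max_n}")
    ordered = sorted(candidates, key=lambda e: (e.best_rank, e.start, e.peptide))
    chosen: list[Epitope] = []
    for cand in ordered:
        if len(chosen) >= max_n:
            break
        if any(cand.overlaps(sel) for sel in chosen):
            continue
        chosen.append(cand)
    return chosen


def read_elution_ranks(path) -> dict[tuple[str, str], float]:
    """Read a tab-separated (peptide, allele, el_rank) table.

    Requires a header row with columns ``peptide``, ``allele``, ``el_rank``.
    Duplicate (peptide, allele) rows keep the minimum rank with a warning;
    ranks outside (0, 100] are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"peptide", "allele", "el_rank"} - set(df.columns)
    if missing:
        raise ValueError(
            f"elution-rank table {path} is missing column(s): {sorted(missing)}"
        )
    bad = df[(df["el_rank"] <= 0) | (df["el_rank"] > 100)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"elution rank {row['el_rank']} for ({row['peptide']}, "
            f"{row['allele']}) is outside (0, 100]"
        )
    out: dict[tuple[str, str], float] = {}
    for pep, allele, rank in zip(df["peptide"], df["allele"], df["el_rank"]):
        key = (str(pep), str(allele))
        if key in out:
            warnings.warn(
                f"duplicate elution-rank rows for {key}; keeping the minimum",
                stacklevel=2,
            )
            out[key] = min(out[key], float(rank))
        else:
            out[key] = float(rank)
    return out


def build_epitopes(
    candidates: Sequence[tuple[str, int]],
    ranks: Mapping[tuple[str, str], float],
    reference_alleles: Sequence[str],
    max_n: int = 5,
) -> list[Epitope]:
    """Attach ranks to filtered candidates and run the greedy selection.

    ``best_rank`` is the minimum elution rank over ``reference_alleles``
    (the strongest presentation signal across the HLA reference set);
    a candidate with no rank for any reference allele is an error.
    """
    pool: list[Epitope] = []
    for pep, start in candidates:
        pep_ranks = {
            allele: ranks[(pep, allele)]
            for allele in reference_alleles
            if (pep, allele) in ranks
        }
        if not pep_ranks:
            raise ValueError(
                f"candidate {pep!r} has no elution rank for any reference allele"
            )
        pool.append(
            Epitope(
                peptide=pep,
                start=start,
                ranks=pep_ranks,
                best_rank=min(pep_ranks.values()),
            )
        )
    return select_epitopes(pool, max_n=max_n)
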