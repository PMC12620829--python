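"""Readers/writers for external formats and the run manifest.

CSV for tabular outputs, JSON for summaries, FASTA/TSV for biological
inputs; no binary formats.  All writers are deterministic: stable column
order and floats formatted to 10 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

FLOAT_FORMAT = "%.10g"


class FastaParseError(ValueError):
    pass


def read_fasta(path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) pairs; wrapped lines joined, case preserved."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before any FASTA header"
                )
            break
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return records


def write_fasta(path, records: Sequence[tuple[str, str]], width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def write_table(path, df: pd.DataFrame, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def config_hash(obj) -> str:
    """Stable sha256 over a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written once per output directory."""

    seed: int
    config_hashes: dict = dataclass_field(default_factory=dict)
    effective_settings: dict = dataclass_field(default_factory=dict)
    stage_wall_clock_s: dict = dataclass_field(default_factory=dict)
    warnings: list = dataclass_field(default_factory=list)
    package_version: str = __version__

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.stage_wall_clock_s[name] = round(
                    time.perf_counter() - self.t0, 3
                )
                return False

        return _Timer()

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(
            out / "manifest.json",
            {
                "package_version": self.package_version,
                "seed": self.seed,
                "config_hashes": self.config_hashes,
                "effective_settings": self.effective_settings,
                "stage_wall_clock_s": self.stage_wall_clock_s,
                "warnings": self.warnings,
            },
        )
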