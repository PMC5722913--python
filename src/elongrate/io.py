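"""Readers, writers and run configuration.

All genomic coordinates in exchanged files are 1-based and inclusive (GFF
convention); bedGraph export converts to its native 0-based half-open
intervals at the boundary. Half-life tables must carry an explicit unit
column — seconds are never guessed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .genome import GeneRecord, SyntheticGenome

SPEED_TABLE_COLUMNS = [
    "gene", "length", "n_r", "d_p", "half_life_s", "a", "n_p",
    "v_raw", "v", "rnap_signal", "delay_s", "passes_filter",
]


# ---------------------------------------------------------------------------
# annotation

def write_genome_gff3(genome: SyntheticGenome, path) -> None:
    lines = ["##gff-version 3", f"##sequence-region chr 1 {genome.genome_length}"]
    for g in genome.genes:
        attrs = f"ID={g.gene_id};operon_id={g.operon_id};operon_position={g.operon_position}"
        lines.append(
            "\t".join(
                ["chr", "elongrate", "gene", str(g.start), str(g.end), ".", g.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_genome_gff3(path) -> SyntheticGenome:
    genes: list[GeneRecord] = []
    genome_length = 0
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("##sequence-region"):
            genome_length = int(line.split()[-1])
            continue
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise DataError(f"{path}:{i}: expected 9 GFF columns, got {len(parts)}")
        _, _, ftype, start, end, _, strand, _, attrs = parts
        if ftype != "gene":
            continue
        if strand not in ("+", "-"):
            raise DataError(f"{path}:{i}: invalid strand {strand!r}")
        a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        genes.append(
            GeneRecord(
                gene_id=a["ID"],
                start=int(start),
                end=int(end),
                strand=strand,
                operon_id=a.get("operon_id", a["ID"]),
                operon_position=int(a.get("operon_position", 0)),
            )
        )
    if genome_length == 0:
        genome_length = max(g.end for g in genes)
    return SyntheticGenome(genes=genes, genome_length=genome_length)


# ---------------------------------------------------------------------------
# tabular data

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_probe_track(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"coordinate", "strand", "replicate", "intensity"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: probe track missing columns {sorted(missing)}")
    bad = ~df["strand"].isin(["+", "-", "both"])
    if bad.any():
        row = int(df.index[bad][0]) + 2  # header + 1-based
        raise DataError(f"{path}: invalid strand value at row {row}")
    return df.sort_values("coordinate", kind="mergesort", ignore_index=True)


def read_gene_values(path, value_column: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or value_column not in df.columns:
        raise DataError(f"{path}: need columns 'gene' and {value_column!r}")
    return df[["gene", value_column]]


def read_half_life_table(path) -> pd.DataFrame:
    """Read per-gene mRNA half-lives; returns columns gene, half_life_s.

    The file must have columns ``gene``, ``half_life`` and ``unit``
    (either ``s`` or ``min`` per row); refusing to guess the unit is a
    hard contract because a 60-fold error silently rescales every speed.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "half_life", "unit"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: half-life table missing columns {sorted(missing)}")
    bad = ~df["unit"].isin(["s", "min"])
    if bad.any():
        raise DataError(f"{path}: half-life unit must be 's' or 'min'")
    factor = df["unit"].map({"s": 1.0, "min": 60.0})
    out = pd.DataFrame({"gene": df["gene"], "half_life_s": df["half_life"] * factor})
    if (out["half_life_s"] <= 0).any():
        raise DataError(f"{path}: half-lives must be positive")
    return out


def read_speed_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SPEED_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: speed table missing columns {sorted(missing)}")
    return df


def write_bedgraph(track: pd.DataFrame, path, span: int = 1) -> None:
    """Export a probe track as bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="elongrate"\n')
        for _, row in track.iterrows():
            start0 = int(row["coordinate"]) - 1
            fh.write(f"chr\t{start0}\t{start0 + span}\t{row['intensity']:.6g}\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_anticodon_table(path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    if "anticodon" not in df.columns:
        raise DataError(f"{path}: need column 'anticodon'")
    return list(df["anticodon"].astype(str))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Declarative run configuration; CLI flags override file values."""

    footprint_nt: float = 40.0
    reference_gene: str = "infB"
    reference_speed: float = 49.5
    norm_window_nt: int = 30_000
    norm_quantile: float = 0.10
    aggregate_statistic: str = "mean"
    replicate_whitelist: list[str] | None = None
    random_probe_offset: float = 0.0
    min_rnap_signal: float = 0.5
    total_rnap: float | None = 1300.0
    total_mrna: float | None = None
    grid_min: float = 1.0
    grid_max: float = 90.0
    grid_step: float = 1.0
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("footprint_nt", "reference_speed", "norm_window_nt", "grid_step"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0 < self.norm_quantile < 1):
            raise ConfigurationError("norm_quantile must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
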