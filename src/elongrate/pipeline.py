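"""End-to-end composition of the pipeline stages.

normalize -> aggregate -> speeds -> scale -> delays -> filter, with every
stage logging row counts so gene tallies stay auditable. Inputs can be
probe-level tracks (normalized here) or already-aggregated per-gene
tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import array_norm, io, speed
from .errors import DataError
from .genome import SyntheticGenome

log = logging.getLogger(__name__)


def normalize_expression_tracks(
    fwd_reps: list[pd.DataFrame],
    rev_reps: list[pd.DataFrame],
    random_probe_offset: float = 0.0,
) -> pd.DataFrame:
    """Transcriptome-array chain: quantile normalize, offset, strand max.

    Each replicate array carries both strands, so normalization treats the
    concatenated fwd+rev probe set of a replicate as one array and
    equalizes distributions across replicates (never across strands —
    strand asymmetry is real signal). An optional constant (the mean
    signal of non-genomic control probes, if the platform has them) is
    subtracted, replicates are averaged per strand, and the larger strand
    value is taken per coordinate.
    """
    if len(fwd_reps) != len(rev_reps):
        raise DataError("need matching forward/reverse replicate tracks")
    joint = [
        pd.concat([f, r], ignore_index=True) for f, r in zip(fwd_reps, rev_reps)
    ]
    if len(joint) > 1:
        joint = array_norm.quantile_normalize(joint)
    n = len(fwd_reps[0])
    normed_fwd, normed_rev = [], []
    for f, r, j in zip(fwd_reps, rev_reps, joint):
        x = j["intensity"].to_numpy()
        if random_probe_offset:
            x = np.maximum(x - random_probe_offset, 0.0)
        nf, nr = f.copy(), r.copy()
        nf["intensity"], nr["intensity"] = x[:n], x[n:]
        normed_fwd.append(nf)
        normed_rev.append(nr)
    fwd = array_norm.average_replicates(normed_fwd)
    rev = array_norm.average_replicates(normed_rev)
    return array_norm.strand_max(fwd, rev)


def normalize_rnap_tracks(
    reps: list[pd.DataFrame],
    window: int = 30_000,
    q: float = 0.10,
    replicate_whitelist: list[str] | None = None,
) -> pd.DataFrame:
    """ChIP-array chain: median-scale, quantile normalize, average, de-background.

    Replicate exclusion is an explicit whitelist (never automatic): a
    replicate pair with strong selective differences biases the density
    and is dropped by name.
    """
    if replicate_whitelist is not None:
        reps = [t for t in reps if t["replicate"].iloc[0] in replicate_whitelist]
        if not reps:
            raise DataError("replicate whitelist excluded every track")
    scaled = [array_norm.scale_median(t, 1.0) for t in reps]
    if len(scaled) > 1:
        scaled = array_norm.quantile_normalize(scaled)
    averaged = array_norm.average_replicates(scaled)
    return array_norm.running_quantile_background(averaged, window=window, q=q)


def speeds_from_gene_tables(
    genome: SyntheticGenome,
    expression: pd.DataFrame,
    rnap: pd.DataFrame,
    half_lives: pd.DataFrame,
    config: io.RunConfig,
) -> pd.DataFrame:
    """Join per-gene tables, run the model, scale, compute delays, filter."""
    m = expression.rename(columns={"value": "n_r"})[["gene", "n_r"]].merge(
        rnap.rename(columns={"value": "d_p"})[["gene", "d_p"]], on="gene", how="inner"
    )
    n0 = len(m)
    m = m.merge(half_lives[["gene", "half_life_s"]], on="gene", how="inner")
    log.info(
        "join report: %d expression+RNAP genes, %d after half-life join", n0, len(m)
    )
    table = speed.build_speed_table(m, genome=genome, footprint=config.footprint_nt)
    if config.reference_gene in set(table["gene"]):
        table = speed.scale_speeds(table, config.reference_gene, config.reference_speed)
    else:
        log.warning(
            "reference gene %r absent; speeds left on the raw scale", config.reference_gene
        )
    table = speed.regulation_delay(genome, table)
    table = speed.filter_genes(table, min_rnap_signal=config.min_rnap_signal)
    log.info("%d/%d genes pass the analysis filter", int(table["passes_filter"].sum()), len(table))
    return table


def run_pipeline(config: io.RunConfig, out_dir=None) -> pd.DataFrame:
    """Run the full pipeline from the files named in ``config.paths``.

    Required paths: ``annotation`` (GFF3) and ``half_life`` (TSV with a
    unit column), plus either probe-level tracks (``expression_fwd``,
    ``expression_rev``, ``rnap_tracks``: lists of TSVs) or per-gene tables
    (``expression``, ``rnap``). Writes speed_table.tsv under ``out_dir``
    when given; returns the speed table.
    """
    paths = config.paths
    for key in ("annotation", "half_life"):
        if key not in paths:
            raise DataError(f"config.paths missing {key!r}")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(paths[key])
    genome = io.read_genome_gff3(paths["annotation"])
    half = io.read_half_life_table(paths["half_life"])

    if "expression_fwd" in paths:
        fwd = [io.read_probe_track(p) for p in paths["expression_fwd"]]
        rev = [io.read_probe_track(p) for p in paths["expression_rev"]]
        rnap_reps = [io.read_probe_track(p) for p in paths["rnap_tracks"]]
        expr_track = normalize_expression_tracks(fwd, rev, config.random_probe_offset)
        rnap_track = normalize_rnap_tracks(
            rnap_reps,
            window=config.norm_window_nt,
            q=config.norm_quantile,
            replicate_whitelist=config.replicate_whitelist,
        )
        expression = array_norm.aggregate_probes_to_genes(
            expr_track, genome, statistic=config.aggregate_statistic
        )
        rnap = array_norm.aggregate_probes_to_genes(
            rnap_track, genome, statistic=config.aggregate_statistic
        )
    else:
        expression = io.read_gene_values(paths["expression"], "value")
        rnap = io.read_gene_values(paths["rnap"], "value")

    table = speeds_from_gene_tables(genome, expression, rnap, half, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_tsv(table, out_dir / "speed_table.tsv")
    return table
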