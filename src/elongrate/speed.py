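"""Steady-state model of transcription elongation speed.

At balanced growth the mRNA pool of a gene turns over so that synthesis
equals degradation. With mRNA level ``n_r`` (arbitrary units) and half-life
``lam`` (seconds), the share of the pool older than one second is
``0.5**(1/lam)``, so the promoter activity (initiations per second, summed
over all promoters feeding the gene) is

    a = n_r * (1 - 0.5**(1/lam)).

RNAP ChIP occupancy gives a density ``d_p`` — the fraction of a gene
coverable by 40-nt elongating-polymerase footprints that is actually
covered — so the polymerase count on a gene of length ``l`` is
``n_p = (l / footprint) * d_p`` and the mean elongation speed is

    v = a * l / n_p = a * footprint / d_p   [nt/s].

``v`` inherits the unknown linear units of ``n_r`` and ``d_p``; it is put
on an absolute scale by pinning a reference gene (default *infB* at
49.5 nt/s) and can be cross-checked by a molecule census against an
assumed total of transcribing RNAPs or cellular mRNAs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConfigurationError, DataError
from .genome import SyntheticGenome

log = logging.getLogger(__name__)

#: Footprint of an elongating RNA polymerase on DNA, in nt.
RNAP_FOOTPRINT_NT = 40.0

#: Reference elongation speed used for absolute scaling, nt/s (infB at
#: 60 min/doubling, interpolated from single-gene measurements).
REFERENCE_SPEED_NT_S = 49.5


def promoter_activity(n_r, half_life_s):
    """Promoter activity a = n_r * (1 - 0.5**(1/lam)) in initiations/s.

    Parameters
    ----------
    n_r : array_like
        mRNA level, arbitrary units, >= 0.
    half_life_s : array_like
        mRNA half-life in seconds, > 0.
    """
    n_r = np.asarray(n_r, dtype=float)
    lam = np.asarray(half_life_s, dtype=float)
    if np.any(lam <= 0):
        raise ArgumentError("half-life must be positive (seconds)")
    return n_r * (1.0 - 0.5 ** (1.0 / lam))


def rnap_count(length_nt, d_p, footprint: float = RNAP_FOOTPRINT_NT):
    """Number of polymerases on a gene: n_p = (l / footprint) * d_p."""
    length_nt = np.asarray(length_nt, dtype=float)
    if np.any(length_nt <= 0):
        raise ArgumentError("gene length must be positive")
    return length_nt / footprint * np.asarray(d_p, dtype=float)


def transcription_speed(n_r, half_life_s, d_p, footprint: float = RNAP_FOOTPRINT_NT):
    """Elongation speed v = a * footprint / d_p in nt/s.

    Genes with ``d_p == 0`` get ``v = NaN`` (undefined, excluded
    downstream); negative densities are a data error.
    """
    d_p = np.asarray(d_p, dtype=float)
    if np.any(d_p < 0):
        raise DataError("RNAP density must be >= 0 after background correction")
    a = promoter_activity(n_r, half_life_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(d_p > 0, a * footprint / d_p, np.nan)
    return v


def build_speed_table(
    measurements: pd.DataFrame,
    genome: SyntheticGenome | None = None,
    footprint: float = RNAP_FOOTPRINT_NT,
) -> pd.DataFrame:
    """Assemble the per-gene speed table from joined measurements.

    ``measurements`` needs columns ``gene``, ``n_r``, ``d_p``,
    ``half_life_s`` and ``length`` (nt); ``length`` may instead come from
    ``genome``. Returns a table with promoter activity ``a``, polymerase
    count ``n_p``, unscaled speed ``v_raw``, scaled speed ``v`` (equal to
    ``v_raw`` until :func:`scale_speeds`), the unscaled corrected RNAP
    signal used by the analysis filter, and a ``passes_filter`` flag.
    """
    m = measurements.copy()
    required = {"gene", "n_r", "d_p", "half_life_s"}
    missing = required - set(m.columns)
    if missing:
        raise DataError(f"measurements missing columns: {sorted(missing)}")
    if "length" not in m.columns:
        if genome is None:
            raise DataError("measurements lack 'length' and no annotation given")
        lengths = {g.gene_id: g.length for g in genome.genes}
        unknown = [g for g in m["gene"] if g not in lengths]
        if unknown:
            log.info("dropping %d genes absent from annotation", len(unknown))
            m = m[~m["gene"].isin(unknown)]
        m["length"] = m["gene"].map(lengths)

    a = promoter_activity(m["n_r"].to_numpy(), m["half_life_s"].to_numpy())
    n_p = rnap_count(m["length"].to_numpy(), m["d_p"].to_numpy(), footprint)
    v_raw = transcription_speed(
        m["n_r"].to_numpy(), m["half_life_s"].to_numpy(), m["d_p"].to_numpy(), footprint
    )
    table = pd.DataFrame(
        {
            "gene": m["gene"].to_numpy(),
            "length": m["length"].to_numpy(),
            "n_r": m["n_r"].to_numpy(),
            "d_p": m["d_p"].to_numpy(),
            "half_life_s": m["half_life_s"].to_numpy(),
            "a": a,
            "n_p": n_p,
            "v_raw": v_raw,
            "v": v_raw.copy(),
            "rnap_signal": m["d_p"].to_numpy(),
            "delay_s": np.nan,
            "passes_filter": False,
        }
    )
    return filter_genes(table)


def scale_speeds(
    table: pd.DataFrame,
    reference_gene: str,
    reference_speed: float = REFERENCE_SPEED_NT_S,
) -> pd.DataFrame:
    """Rescale all speeds so the reference gene hits ``reference_speed``.

    Array units are linear in both mRNA level and RNAP density, so speeds
    are determined up to one global factor; pinning a single
    independently-measured gene fixes it. Ranks are unchanged.
    """
    ref = table.loc[table["gene"] == reference_gene, "v_raw"]
    if ref.empty:
        raise ConfigurationError(f"reference gene {reference_gene!r} not in table")
    v_ref = float(ref.iloc[0])
    if not np.isfinite(v_ref) or v_ref <= 0:
        raise ConfigurationError(
            f"reference gene {reference_gene!r} has no positive unscaled speed"
        )
    out = table.copy()
    out["v"] = out["v_raw"] * (reference_speed / v_ref)
    return out


def regulation_delay(genome: SyntheticGenome, table: pd.DataFrame) -> pd.DataFrame:
    """Cumulative transcription delay of each gene within its operon.

    delay_k = sum_{i<=k} l_i / v_i over the operon in transcription order:
    the time from initiation at the operon promoter until a full-length
    transcript of gene k exists. Genes downstream of (or at) a gene with
    undefined or zero speed get NaN.
    """
    speeds = dict(zip(table["gene"], table["v"]))
    lengths = dict(zip(table["gene"], table["length"]))
    out = table.copy()
    delays: dict[str, float] = {}
    for op, gene_ids in genome.operons.items():
        cum = 0.0
        broken = False
        for gid in gene_ids:
            v = speeds.get(gid, np.nan)
            l = lengths.get(gid, np.nan)
            if broken or not np.isfinite(v) or v <= 0 or not np.isfinite(l):
                broken = True
                delays[gid] = np.nan
                continue
            cum += l / v
            delays[gid] = cum
    out["delay_s"] = out["gene"].map(delays)
    return out


def filter_genes(table: pd.DataFrame, min_rnap_signal: float = 0.5) -> pd.DataFrame:
    """Apply the analysis filter: v > 0 and unscaled RNAP signal > threshold.

    Both inequalities are strict; genes with undefined speed fail.
    """
    out = table.copy()
    v = out["v"].to_numpy(dtype=float)
    sig = out["rnap_signal"].to_numpy(dtype=float)
    out["passes_filter"] = np.isfinite(v) & (v > 0) & (sig > min_rnap_signal)
    return out


def molecule_census(
    table: pd.DataFrame,
    total_rnap: float | None = None,
    total_mrna: float | None = None,
    footprint: float = RNAP_FOOTPRINT_NT,
) -> dict:
    """Absolute molecule totals implied by the scaled speeds.

    Exactly one anchor is given. Anchoring on ``total_rnap`` fixes the
    RNAP-density unit via sum(n_p) = total_rnap; the absolute per-gene mRNA
    count then follows from the speed scale through
    n_r = v * n_p / (l * (1 - 0.5**(1/lam))), and its sum is the implied
    cellular mRNA total. Anchoring on ``total_mrna`` runs the same logic
    the other way. Only filter-passing genes are counted.
    """
    if (total_rnap is None) == (total_mrna is None):
        raise ArgumentError("give exactly one of total_rnap or total_mrna")
    t = table[table["passes_filter"]].copy()
    if t.empty:
        raise DataError("no filter-passing genes to census")
    decay = 1.0 - 0.5 ** (1.0 / t["half_life_s"].to_numpy(dtype=float))
    l = t["length"].to_numpy(dtype=float)
    v = t["v"].to_numpy(dtype=float)
    if total_rnap is not None:
        beta = total_rnap / float(t["n_p"].sum())
        n_p_abs = t["n_p"].to_numpy(dtype=float) * beta
        n_r_abs = v * n_p_abs / (l * decay)
        return {
            "anchor": "rnap",
            "rnap_unit_scale": beta,
            "total_rnap": float(n_p_abs.sum()),
            "total_mrna": float(n_r_abs.sum()),
            "per_gene": pd.DataFrame({"gene": t["gene"], "n_p_abs": n_p_abs, "n_r_abs": n_r_abs}),
        }
    alpha = total_mrna / float(t["n_r"].sum())
    n_r_abs = t["n_r"].to_numpy(dtype=float) * alpha
    a_abs = n_r_abs * decay
    n_p_abs = a_abs * l / v
    return {
        "anchor": "mrna",
        "mrna_unit_scale": alpha,
        "total_rnap": float(n_p_abs.sum()),
        "total_mrna": float(n_r_abs.sum()),
        "per_gene": pd.DataFrame({"gene": t["gene"], "n_p_abs": n_p_abs, "n_r_abs": n_r_abs}),
    }
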