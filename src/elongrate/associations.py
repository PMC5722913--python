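"""Sequence features and the genome-wide statistical battery.

Codon-level features (relative codon frequencies, positional GC content,
wobble-read codon shares) are computed from CDS sequences and a tRNA
anticodon inventory. Associations with transcription speed are Spearman
rank correlations with two-sided p-values; group comparisons use the
Mann-Whitney U test; families of p-values are Benjamini-Hochberg adjusted
and called significant at adjusted p <= 0.05.
"""

from __future__ import annotations

import logging
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ArgumentError, ConfigurationError, StatisticsError

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}  # bacterial code
SENSE_CODONS = sorted(
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)

_WC = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}


def _reads(anticodon: str, codon: str) -> str | None:
    """Whether a tRNA anticodon (5'->3') decodes a codon; returns pairing class.

    The anticodon pairs antiparallel: its positions 3,2 must be
    Watson-Crick to codon positions 1,2; its first base (position 34)
    pairs codon position 3 either Watson-Crick or by wobble (G:U, U:G,
    and inosine I reading U, C or A). Returns "wc", "wobble" or None.
    """
    ac = anticodon.upper().replace("U", "T")
    cd = codon.upper().replace("U", "T")
    if _WC[ac[2]] != cd[0] or _WC[ac[1]] != cd[1]:
        return None
    third, wob = cd[2], ac[0]
    if wob == "I":
        return "wobble" if third in ("T", "C", "A") else None
    if _WC.get(wob) == third:
        return "wc"
    if (wob, third) in (("G", "T"), ("T", "G")):
        return "wobble"
    return None


def classify_wobble_codons(anticodons) -> dict[str, str]:
    """Classify each sense codon by how the tRNA pool reads it.

    "strict": decoded only by wobble-pairing anticodons; "mixed": decoded
    by both wobble and Watson-Crick anticodons; "wc": Watson-Crick only;
    "unread": no anticodon in the inventory decodes it.
    """
    out = {}
    for codon in SENSE_CODONS:
        kinds = {k for ac in anticodons if (k := _reads(ac, codon)) is not None}
        if not kinds:
            out[codon] = "unread"
        elif kinds == {"wobble"}:
            out[codon] = "strict"
        elif kinds == {"wc"}:
            out[codon] = "wc"
        else:
            out[codon] = "mixed"
    return out


def codon_features(
    sequences: dict[str, str],
    anticodons=None,
) -> pd.DataFrame:
    """Per-gene codon composition features.

    ``sequences`` maps gene id -> CDS (5'->3', in-frame). Returns one row
    per gene: relative frequency of each of the 61 sense codons (summing
    to 1), GC fraction at each codon position (gc1/gc2/gc3), the summed
    frequency of strictly-wobble-read and mixed-read codons (if an
    anticodon inventory is given), and the CDS length in nt. Genes whose
    length is not a multiple of 3 are skipped and logged; a missing start
    codon only warns.
    """
    wob = classify_wobble_codons(anticodons) if anticodons is not None else None
    rows = []
    for gid, seq in sequences.items():
        s = str(seq).upper().replace("U", "T")
        if len(s) % 3 != 0:
            log.warning("gene %s: length %d not divisible by 3; skipped", gid, len(s))
            continue
        codons = [s[i : i + 3] for i in range(0, len(s), 3)]
        if codons and codons[0] not in ("ATG", "GTG", "TTG"):
            log.warning("gene %s does not start with a start codon", gid)
        sense = [c for c in codons if c in set(SENSE_CODONS)]
        if not sense:
            log.warning("gene %s: no sense codons; skipped", gid)
            continue
        n = len(sense)
        counts = {c: 0 for c in SENSE_CODONS}
        for c in sense:
            counts[c] += 1
        row = {"gene": gid, "length_nt": len(s)}
        for c in SENSE_CODONS:
            row[f"freq_{c}"] = counts[c] / n
        for pos in range(3):
            bases = [c[pos] for c in sense]
            row[f"gc{pos + 1}"] = sum(b in "GC" for b in bases) / n
        if wob is not None:
            row["wobble_strict_freq"] = sum(
                counts[c] for c in SENSE_CODONS if wob[c] == "strict"
            ) / n
            row["wobble_mixed_freq"] = sum(
                counts[c] for c in SENSE_CODONS if wob[c] == "mixed"
            ) / n
        rows.append(row)
    return pd.DataFrame(rows)


def spearman_assoc(x, y, name: str = "") -> dict:
    """Spearman rank correlation with a two-sided p-value.

    Pairs with a non-finite value on either side are dropped. A zero-rank
    -variance side yields rho = NaN (undefined, reported as NA).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise StatisticsError("need >= 3 paired finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"feature": name, "rho": np.nan, "p": np.nan, "n": len(x)}
    res = stats.spearmanr(x, y)
    return {"feature": name, "rho": float(res.statistic), "p": float(res.pvalue), "n": len(x)}


def group_test(values_a, values_b) -> dict:
    """Two-sided Mann-Whitney U comparison of two gene groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ArgumentError("both groups must be non-empty")
    if len(a) + len(b) < 3:
        raise ArgumentError("need >= 3 values in total")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": len(a),
        "n_b": len(b),
    }


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ArgumentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def association_battery(
    features: pd.DataFrame,
    speeds: pd.Series,
    feature_columns=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate every feature column with transcription speed.

    ``features`` is indexed by gene (or has a ``gene`` column); ``speeds``
    is a gene-indexed Series of scaled speeds. Returns one row per
    feature: rho, two-sided p, BH-adjusted p, n, and a significance flag
    at adjusted p <= ``alpha``.
    """
    feats = features.set_index("gene") if "gene" in features.columns else features
    common = feats.index.intersection(speeds.index)
    if len(common) < 3:
        raise StatisticsError("fewer than 3 genes shared between features and speeds")
    feats = feats.loc[common]
    v = speeds.loc[common].to_numpy(dtype=float)
    cols = feature_columns if feature_columns is not None else list(feats.columns)
    rows = [spearman_assoc(feats[c].to_numpy(dtype=float), v, name=c) for c in cols]
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    p_adj = np.full(len(out), np.nan)
    if valid.any():
        p_adj[valid.to_numpy()] = bh_adjust(out.loc[valid, "p"].to_numpy())
    out["p_adj"] = p_adj
    out["significant"] = out["p_adj"] <= alpha
    return out


def nascent_share_genes(
    census_table: pd.DataFrame,
    d_p_min_percent: float = 1.8,
    n_r_max_copies: float = 0.97,
) -> list[str]:
    """Genes whose mRNA pool is dominated by nascent transcripts.

    Requires census-scaled columns ``d_p_percent`` (RNAP coverage, %) and
    ``mrna_copies`` (absolute copies per cell); both thresholds are
    strict. High occupancy with sub-single-copy mRNA means most of the
    measured signal is still attached to polymerases.
    """
    for col in ("d_p_percent", "mrna_copies"):
        if col not in census_table.columns:
            raise ConfigurationError(
                f"column {col!r} missing: run the molecule census before this analysis"
            )
    m = (census_table["d_p_percent"] > d_p_min_percent) & (
        census_table["mrna_copies"] < n_r_max_copies
    )
    return list(census_table.loc[m, "gene"])


def delay_order_prediction(
    delays: pd.Series,
    observed: pd.Series,
    label_order: list,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predict regulation-interval labels from calculated delays.

    Operons are ranked by delay and assigned predicted labels preserving
    the observed class sizes (shortest delays get the earliest interval).
    Absolute interval boundaries are not recoverable from the delays alone
    — only the ordering is — hence the size-preserving assignment.
    Returns (per-operon table, confusion matrix observed x predicted).
    """
    if len(delays) < 2:
        raise ArgumentError("need >= 2 operons")
    bad = set(observed.unique()) - set(label_order)
    if bad:
        raise ConfigurationError(f"observed labels {sorted(bad)} not in label_order")
    common = delays.index.intersection(observed.index)
    d = delays.loc[common]
    obs = observed.loc[common]
    class_sizes = [int((obs == lab).sum()) for lab in label_order]
    ranked = d.sort_values(kind="mergesort").index
    predicted = pd.Series(index=common, dtype=object)
    pos = 0
    for lab, size in zip(label_order, class_sizes):
        predicted[ranked[pos : pos + size]] = lab
        pos += size
    result = pd.DataFrame(
        {"operon": common, "delay_s": d.to_numpy(), "observed": obs.to_numpy(),
         "predicted": predicted.loc[common].to_numpy()}
    )
    confusion = pd.DataFrame(0, index=label_order, columns=label_order, dtype=int)
    for o, p in zip(result["observed"], result["predicted"]):
        confusion.loc[o, p] += 1
    return result, confusion
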