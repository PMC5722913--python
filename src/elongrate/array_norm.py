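"""Tiling-array signal processing.

Probe tracks are pandas DataFrames with columns ``coordinate`` (1-based nt),
``strand`` ("+", "-" or "both"), ``replicate`` and ``intensity``, sorted by
coordinate. The processing chain mirrors standard two-channel tiling
practice: quantile normalization across arrays, strand-max selection for
expression, median scaling for ChIP arrays, replicate averaging, a running
low-quantile background subtraction, and probe-to-gene aggregation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ArgumentError, DataError
from .genome import SyntheticGenome

log = logging.getLogger(__name__)

TRACK_COLUMNS = ["coordinate", "strand", "replicate", "intensity"]


def make_track(coordinates, intensities, strand: str = "+", replicate: str = "r1") -> pd.DataFrame:
    """Build a probe track DataFrame, sorted by coordinate."""
    df = pd.DataFrame(
        {
            "coordinate": np.asarray(coordinates, dtype=int),
            "strand": strand,
            "replicate": replicate,
            "intensity": np.asarray(intensities, dtype=float),
        }
    )
    return df.sort_values("coordinate", kind="mergesort", ignore_index=True)


def _check_aligned(tracks: list[pd.DataFrame]) -> None:
    n = len(tracks[0])
    for t in tracks[1:]:
        if len(t) != n:
            raise DataError("tracks differ in length")
        if not np.array_equal(t["coordinate"].to_numpy(), tracks[0]["coordinate"].to_numpy()):
            raise DataError("tracks differ in probe coordinates")


def quantile_normalize(tracks: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Quantile-normalize aligned tracks to their common rank-mean profile.

    Every output track carries the identical sorted value multiset: the
    per-rank mean over input tracks. Ties within a track receive the mean
    of the rank means they span, so within-track order is preserved.
    """
    if len(tracks) < 2:
        raise ArgumentError("quantile normalization needs at least 2 tracks")
    _check_aligned(tracks)
    mat = np.column_stack([t["intensity"].to_numpy(dtype=float) for t in tracks])
    rank_means = np.sort(mat, axis=0).mean(axis=1)
    out = []
    for j, t in enumerate(tracks):
        x = mat[:, j]
        order = np.argsort(x, kind="mergesort")
        normalized_sorted = rank_means.copy()
        # average rank means over runs of tied input values
        xs = x[order]
        boundaries = np.flatnonzero(np.diff(xs) != 0) + 1
        for lo, hi in zip(np.r_[0, boundaries], np.r_[boundaries, len(xs)]):
            if hi - lo > 1:
                normalized_sorted[lo:hi] = rank_means[lo:hi].mean()
        y = np.empty_like(x)
        y[order] = normalized_sorted
        new = t.copy()
        new["intensity"] = y
        out.append(new)
    return out


def strand_max(fwd: pd.DataFrame, rev: pd.DataFrame) -> pd.DataFrame:
    """Per-coordinate maximum of forward and reverse strand signal.

    Expression arrays probe both strands; the transcribed strand carries
    the real signal, so the larger of the two is taken as the RNA
    expression strength at each probe.
    """
    _check_aligned([fwd, rev])
    out = fwd.copy()
    out["intensity"] = np.maximum(
        fwd["intensity"].to_numpy(dtype=float), rev["intensity"].to_numpy(dtype=float)
    )
    out["strand"] = "both"
    return out


def scale_median(track: pd.DataFrame, target: float = 1.0) -> pd.DataFrame:
    """Scale a track so its intensity median equals ``target``."""
    med = float(np.median(track["intensity"].to_numpy(dtype=float)))
    if med <= 0:
        raise DataError(f"cannot median-scale: median is {med}")
    out = track.copy()
    out["intensity"] = out["intensity"] * (target / med)
    return out


def average_replicates(tracks: list[pd.DataFrame]) -> pd.DataFrame:
    """Arithmetic mean of aligned replicate tracks at each coordinate."""
    if not tracks:
        raise ArgumentError("no tracks to average")
    if len(tracks) == 1:
        out = tracks[0].copy()
        out["replicate"] = "mean"
        return out
    _check_aligned(tracks)
    out = tracks[0].copy()
    out["intensity"] = np.mean(
        np.column_stack([t["intensity"].to_numpy(dtype=float) for t in tracks]), axis=1
    )
    out["replicate"] = "mean"
    return out


def running_quantile_background(
    track: pd.DataFrame, window: int = 30_000, q: float = 0.10
) -> pd.DataFrame:
    """Subtract a running low-quantile background, flooring at zero.

    For each probe the background is the ``q``-quantile of intensities at
    probes whose coordinate lies within a centered window of ``window`` nt
    (truncated at the track edges). The large default window keeps the
    correction from eating into long transcription units while still
    tracking slow spatial drift in the ChIP baseline.
    """
    if window <= 0:
        raise ArgumentError("window must be positive")
    if not (0 < q < 1):
        raise ArgumentError("quantile must be in (0, 1)")
    coords = track["coordinate"].to_numpy(dtype=float)
    x = track["intensity"].to_numpy(dtype=float)
    half = window / 2.0
    lo = np.searchsorted(coords, coords - half, side="left")
    hi = np.searchsorted(coords, coords + half, side="right")
    bg = np.empty_like(x)
    for i in range(len(x)):
        if hi[i] <= lo[i]:
            log.warning("empty background window at coordinate %d", int(coords[i]))
            bg[i] = 0.0
        else:
            bg[i] = np.quantile(x[lo[i] : hi[i]], q)
    out = track.copy()
    out["intensity"] = np.maximum(x - bg, 0.0)
    return out


def aggregate_probes_to_genes(
    track: pd.DataFrame,
    genome: SyntheticGenome,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Summarize probe intensities per gene.

    Returns a DataFrame with ``gene``, ``value`` (mean or median of probes
    with coordinate in [start, end]) and ``n_probes``. Genes covered by no
    probe are omitted and logged.
    """
    if statistic not in ("mean", "median"):
        raise ArgumentError("statistic must be 'mean' or 'median'")
    agg = np.mean if statistic == "mean" else np.median
    coords = track["coordinate"].to_numpy(dtype=int)
    x = track["intensity"].to_numpy(dtype=float)
    rows = []
    skipped = []
    for g in genome.genes:
        lo = np.searchsorted(coords, g.start, side="left")
        hi = np.searchsorted(coords, g.end, side="right")
        if hi <= lo:
            skipped.append(g.gene_id)
            continue
        rows.append({"gene": g.gene_id, "value": float(agg(x[lo:hi])), "n_probes": hi - lo})
    if skipped:
        log.info("omitted %d genes with no probes: %s ...", len(skipped), skipped[:5])
    return pd.DataFrame(rows, columns=["gene", "value", "n_probes"])
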