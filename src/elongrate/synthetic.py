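"""Synthetic data with known ground truth.

Everything downstream — normalization, the steady-state speed model, the
validation fits, the association battery and the random forest — is
exercised against data generated here, where the true per-gene elongation
speeds, promoter activities and half-lives are known. The generator
emulates the shape of the real inputs: genes organized in operons with
lengths of a few hundred to a few thousand nt, per-gene speeds spanning
roughly 1-90 nt/s, steady-state mRNA levels and RNAP densities consistent
with the speed model plus multiplicative log-normal noise, tiled
probe-level array signals with smooth background drift, promoter-reporter
(GFP/OD) time series at 14-min intervals, and mRNA decay series after a
transcription-initiation stop.

It does not simulate polymerase traffic, collisions, supercoiling or
ribosome coupling; observables are drawn directly from the steady-state
relations plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import speed as speed_mod
from .array_norm import make_track
from .errors import ArgumentError, DataError
from .genome import GeneRecord, SyntheticGenome


def _sample_dist(spec, rng: np.random.Generator) -> int:
    """Resolve a distribution spec: int constant, (lo, hi) uniform, or callable."""
    if callable(spec):
        return int(spec(rng))
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    if isinstance(spec, (tuple, list)) and len(spec) == 2:
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    raise ArgumentError(f"cannot interpret distribution spec {spec!r}")


@dataclass
class SyntheticTruth:
    """Hidden ground truth behind a synthetic data set."""

    true_speed: pd.Series  # nt/s per gene
    true_activity: pd.Series  # initiations/s per gene
    true_half_life: pd.Series  # s per gene
    noise_cv: float
    seed: int

    def __post_init__(self) -> None:
        if (self.true_speed <= 0).any():
            raise ArgumentError("true speeds must be positive")
        if (self.true_half_life <= 0).any():
            raise ArgumentError("true half-lives must be positive")


@dataclass
class ReporterSeries:
    """Promoter-fusion GFP reporter time courses.

    ``gfp`` has one row per promoter and one column per timepoint;
    ``od`` is the shared culture optical density. GFP is stable; its mRNA
    decays with half-life ``half_life_gfp_s``, so a fraction
    ``0.5**(dt/half_life_gfp_s)`` of each step's GFP production is driven
    by mRNA left over from the previous step.
    """

    times: np.ndarray  # (T,) seconds
    od: np.ndarray  # (T,)
    gfp: np.ndarray  # (P, T)
    half_life_gfp_s: float
    activities: np.ndarray | None = None  # (P, T) true activity profiles, if known

    def __post_init__(self) -> None:
        if np.any(self.od <= 0):
            raise DataError("OD must be positive")
        if self.gfp.shape[1] != len(self.times):
            raise DataError("gfp and times shapes disagree")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_promoters(self) -> int:
        return self.gfp.shape[0]


def generate_genome(
    n_genes: int,
    operon_size_dist=(1, 5),
    length_dist=(200, 6000),
    seed: int = 0,
    intergenic_gap: int = 50,
    operon_gap: int = 400,
) -> SyntheticGenome:
    """Lay out ``n_genes`` genes in operons along a linear genome.

    Operon sizes and gene lengths are drawn from the given specs
    (constant int, (lo, hi) uniform, or callable(rng) -> int). Each operon
    gets a random strand; genes within an operon are contiguous up to a
    fixed intergenic gap and numbered in transcription order.
    """
    if n_genes < 1:
        raise ArgumentError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    cursor = 1 + operon_gap
    op_idx = 0
    remaining = n_genes
    while remaining > 0:
        size = min(max(1, _sample_dist(operon_size_dist, rng)), remaining)
        strand = "+" if rng.random() < 0.5 else "-"
        op_id = f"op{op_idx:04d}"
        placed = []
        for j in range(size):
            length = max(30, _sample_dist(length_dist, rng))
            start = cursor
            end = start + length - 1
            placed.append((start, end))
            cursor = end + 1 + intergenic_gap
        for j, (start, end) in enumerate(placed):
            pos = j if strand == "+" else size - 1 - j
            genes.append(
                GeneRecord(
                    gene_id=f"g{len(genes):04d}",
                    start=start,
                    end=end,
                    strand=strand,
                    operon_id=op_id,
                    operon_position=pos,
                )
            )
        cursor += operon_gap
        op_idx += 1
        remaining -= size
    return SyntheticGenome(genes=genes, genome_length=cursor + operon_gap)


def generate_truth(
    genome: SyntheticGenome,
    speed_range: tuple[float, float] = (1.0, 90.0),
    half_life_range_s: tuple[float, float] = (90.0, 1200.0),
    activity_median: float = 0.02,
    activity_sigma: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw per-gene true speeds, activities and half-lives.

    Speeds are log-uniform over ``speed_range`` (the grid the clearance
    fitter searches); half-lives log-uniform over a few minutes to ~20 min,
    matching the span of measured bacterial mRNA half-lives; activities
    log-normal around ``activity_median`` initiations/s.
    """
    rng = np.random.default_rng(seed)
    ids = genome.gene_ids
    n = len(ids)
    speeds = np.exp(rng.uniform(np.log(speed_range[0]), np.log(speed_range[1]), n))
    half_lives = np.exp(
        rng.uniform(np.log(half_life_range_s[0]), np.log(half_life_range_s[1]), n)
    )
    activities = activity_median * np.exp(rng.normal(0.0, activity_sigma, n))
    return SyntheticTruth(
        true_speed=pd.Series(speeds, index=ids),
        true_activity=pd.Series(activities, index=ids),
        true_half_life=pd.Series(half_lives, index=ids),
        noise_cv=noise_cv,
        seed=seed,
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


def generate_observables(
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    seed: int = 0,
    probe_spacing: int = 25,
    n_replicates: int = 2,
    drift_amplitude: float = 0.0,
    background: float = 0.02,
    make_probe_tracks: bool = True,
    footprint: float = speed_mod.RNAP_FOOTPRINT_NT,
):
    """Emit steady-state observables consistent with the speed model.

    Per gene, the noise-free mRNA level and RNAP density are the unique
    values the model maps back to the true speed and activity:
    ``n_r = a / (1 - 0.5**(1/lam))`` and ``d_p = a * footprint / v``.
    Multiplicative log-normal noise with ``truth.noise_cv`` is applied to
    ``n_r`` and ``d_p`` independently; half-lives are reported noise-free.

    Returns ``(measurements, tracks)`` where measurements has columns
    gene, n_r, d_p, half_life_s, length, and tracks maps
    ``{"expression_fwd", "expression_rev", "rnap"}`` to lists of replicate
    probe tracks (empty dict when ``make_probe_tracks`` is false).
    """
    rng = np.random.default_rng(seed)
    missing = [g.gene_id for g in genome.genes if g.gene_id not in truth.true_speed.index]
    if missing:
        raise DataError(f"truth missing genes: {missing[:5]}")
    ids = genome.gene_ids
    a = truth.true_activity[ids].to_numpy()
    v = truth.true_speed[ids].to_numpy()
    lam = truth.true_half_life[ids].to_numpy()
    decay = 1.0 - 0.5 ** (1.0 / lam)
    n_r = a / decay * _lognormal_noise(rng, truth.noise_cv, len(ids))
    d_p = a * footprint / v * _lognormal_noise(rng, truth.noise_cv, len(ids))
    lengths = np.array([g.length for g in genome.genes], dtype=float)
    measurements = pd.DataFrame(
        {"gene": ids, "n_r": n_r, "d_p": d_p, "half_life_s": lam, "length": lengths}
    )

    tracks: dict[str, list[pd.DataFrame]] = {}
    if make_probe_tracks:
        coords = np.arange(1, genome.genome_length + 1, probe_spacing)
        per_gene = {"expression_fwd": {}, "expression_rev": {}, "rnap": {}}
        for g, nri, dpi in zip(genome.genes, n_r, d_p):
            key = "expression_fwd" if g.strand == "+" else "expression_rev"
            per_gene[key][g.gene_id] = nri
            per_gene["rnap"][g.gene_id] = dpi
        for name in ("expression_fwd", "expression_rev", "rnap"):
            base = np.full(len(coords), background)
            for g in genome.genes:
                val = per_gene[name].get(g.gene_id)
                if val is None:
                    continue
                inside = (coords >= g.start) & (coords <= g.end)
                base[inside] = val
            reps = []
            for r in range(n_replicates):
                drift = np.zeros(len(coords))
                if drift_amplitude > 0:
                    for _ in range(3):
                        period = rng.uniform(0.2, 1.0) * genome.genome_length
                        phase = rng.uniform(0, 2 * np.pi)
                        drift += (
                            drift_amplitude
                            * rng.uniform(0.3, 1.0)
                            * (1 + np.sin(2 * np.pi * coords / period + phase))
                            / 2
                        )
                noisy = base * _lognormal_noise(rng, truth.noise_cv, len(coords)) + drift
                strand = {"expression_fwd": "+", "expression_rev": "-", "rnap": "both"}[name]
                reps.append(make_track(coords, noisy, strand=strand, replicate=f"r{r + 1}"))
            tracks[name] = reps
    return measurements, tracks


def generate_reporter_series(
    n_promoters: int,
    activity_profiles=None,
    half_life_gfp_s: float = 360.0,
    dt_s: float = 840.0,
    n_timepoints: int = 54,
    noise_cv: float = 0.0,
    drift_sigma: float = 0.1,
    seed: int = 0,
    od0: float = 0.05,
    od_doubling_s: float = 3600.0,
) -> ReporterSeries:
    """Simulate promoter-fusion GFP/OD time courses.

    The gfp-mRNA pool of promoter p follows
    ``m_t = a_t + f * m_{t-1}`` with carryover ``f = 0.5**(dt/half_life)``
    (initialized at its steady state for a_0), and the GFP increment at
    step t is ``OD_t * m_t * dt`` times multiplicative noise. By default
    activities drift smoothly and log-normally around a per-promoter base
    level, with step-to-step log-SD ``drift_sigma``; pass
    ``activity_profiles`` as an (n_promoters, n_timepoints) array or a
    callable ``(rng, n_promoters, times) -> array`` to override.
    """
    if half_life_gfp_s <= 0:
        raise ArgumentError("reporter mRNA half-life must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(n_timepoints, dtype=float) * dt_s
    if callable(activity_profiles):
        acts = np.asarray(activity_profiles(rng, n_promoters, times), dtype=float)
    elif activity_profiles is not None:
        acts = np.asarray(activity_profiles, dtype=float)
    else:
        base = np.exp(rng.normal(0.0, 1.0, n_promoters))
        steps = rng.normal(0.0, drift_sigma, (n_promoters, n_timepoints))
        acts = base[:, None] * np.exp(np.cumsum(steps, axis=1))
    if acts.shape != (n_promoters, n_timepoints):
        raise ArgumentError(f"activity profiles must have shape {(n_promoters, n_timepoints)}")

    f = 0.5 ** (dt_s / half_life_gfp_s)
    m = acts[:, 0] / (1.0 - f)  # steady-state initialization
    od = od0 * 2.0 ** (times / od_doubling_s)
    gfp = np.zeros((n_promoters, n_timepoints))
    for t in range(1, n_timepoints):
        m = acts[:, t] + f * m
        inc = od[t] * m * dt_s * _lognormal_noise(rng, noise_cv, n_promoters)
        gfp[:, t] = gfp[:, t - 1] + inc
    return ReporterSeries(
        times=times, od=od, gfp=gfp, half_life_gfp_s=half_life_gfp_s, activities=acts
    )


def generate_decay_series(
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    timepoints,
    noise_cv: float = 0.0,
    seed: int = 0,
    distance_to: str = "3prime",
) -> pd.DataFrame:
    """mRNA abundance after a transcription-initiation stop.

    Polymerases already on the DNA keep elongating, so a gene's mRNA pool
    is replenished at the steady-state rate until the last polymerase
    clears it — a lag of (promoter-to-gene distance) / speed — after which
    the pool decays exponentially with the gene's half-life. Returns a
    long DataFrame: operon, gene, distance_nt, time_s, abundance.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if len(timepoints) < 4:
        raise ArgumentError("need at least 4 timepoints to fit a delayed decay")
    if np.any(np.diff(timepoints) <= 0):
        raise ArgumentError("timepoints must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for g in genome.genes:
        if g.gene_id not in truth.true_speed.index:
            raise DataError(f"truth missing gene {g.gene_id}")
        v = float(truth.true_speed[g.gene_id])
        lam = float(truth.true_half_life[g.gene_id])
        a = float(truth.true_activity[g.gene_id])
        dist = genome.promoter_distance(g.gene_id, to=distance_to)
        delay = dist / v
        plateau = a / (1.0 - 0.5 ** (1.0 / lam))
        abund = np.where(
            timepoints <= delay, plateau, plateau * 0.5 ** ((timepoints - delay) / lam)
        )
        abund = abund * _lognormal_noise(rng, noise_cv, len(timepoints))
        for t, y in zip(timepoints, abund):
            rows.append(
                {
                    "operon": g.operon_id,
                    "gene": g.gene_id,
                    "distance_nt": dist,
                    "time_s": t,
                    "abundance": y,
                }
            )
    return pd.DataFrame(rows)


def generate_operon_cohort(
    n_operons: int,
    genes_per_operon: int = 3,
    speed_range: tuple[float, float] = (5.0, 60.0),
    length_dist=(500, 2500),
    half_life_range_s: tuple[float, float] = (120.0, 600.0),
    seed: int = 0,
):
    """Cohort of equal-size operons sharing one true speed per operon.

    One speed per operon is the regime the clearance-lag fitter assumes
    (a single polymerase convoy clears the whole transcription unit).
    Returns ``(genome, truth, operon_speed)`` with operon_speed a dict.
    """
    rng = np.random.default_rng(seed)
    genome = generate_genome(
        n_operons * genes_per_operon,
        operon_size_dist=genes_per_operon,
        length_dist=length_dist,
        seed=seed + 1,
    )
    operon_speed = {op: float(rng.uniform(*speed_range)) for op in sorted(genome.operons)}
    ids = genome.gene_ids
    speeds = pd.Series([operon_speed[g.operon_id] for g in genome.genes], index=ids)
    truth = SyntheticTruth(
        true_speed=speeds,
        true_activity=pd.Series(0.02, index=ids),
        true_half_life=pd.Series(
            rng.uniform(half_life_range_s[0], half_life_range_s[1], len(ids)), index=ids
        ),
        noise_cv=0.0,
        seed=seed,
    )
    return genome, truth, operon_speed


def planted_feature_speeds(
    n_genes: int,
    rho_strength: float = 1.0,
    noise_sigma: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene set with a planted monotone feature -> speed dependence.

    ``feature`` is uniform on [0, 1]; log-speed increases with the feature
    (slope ``rho_strength``) plus Gaussian noise. Used to test that the
    association battery recovers a planted positive rank correlation.
    """
    rng = np.random.default_rng(seed)
    feature = rng.uniform(0, 1, n_genes)
    log_v = np.log(10.0) + rho_strength * feature + rng.normal(0, noise_sigma, n_genes)
    return pd.DataFrame(
        {"gene": [f"g{i:04d}" for i in range(n_genes)], "feature": feature, "v": np.exp(log_v)}
    )
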