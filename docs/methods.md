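# Methods

## The steady-state speed model

The model treats each gene at balanced growth as a stationary system:
the mRNA pool is constant, so synthesis equals degradation, and the
polymerases on the gene form a steady stream. Under these assumptions
the promoter activity is *a* = *n_r*·(1 − 0.5^(1/λ)) initiations/s
(*n_r* mRNA level in arbitrary linear units, λ half-life in seconds),
the polymerase count is *n_p* = (*l*/footprint)·*d_p*, and the speed is
*v* = *a*·footprint/*d_p* nt/s. The two algebraic routes to *v*
(length-based *a·l/n_p* and density-based *a*·footprint/*d_p*) are
identical and are cross-checked numerically in the tests.

Assumptions that matter:

- **Stationarity.** Violations are bounded by the reporter-series check
  (below); the formula degrades gracefully because activity estimates
  enter only through a ratio.
- **Uniform footprint.** The elongating-polymerase footprint is a
  config constant (default 40 nt). Speeds are linear in it, so the
  choice only moves the absolute scale — which the reference-gene
  scaling then fixes — but it does affect the molecule census.
- **Linear array response.** Gene-level GC or platform bias that is
  linear cancels between *n_r* and *d_p* when both come from the same
  platform.

Genes with *d_p* = 0 get an undefined (NaN) speed, never 0; the
analysis filter (*v* > 0 and unscaled background-corrected RNAP signal
> 0.5, both strict) removes them downstream. Half-life inputs must
carry an explicit per-row unit (`s` or `min`); the reader refuses to
guess because a silent 60-fold error would rescale every speed.

## Parameters

| parameter | default | unit | why |
|---|---|---|---|
| footprint | 40 | nt | elongating RNAP footprint; linear scale factor |
| reference gene / speed | *infB* / 49.5 | nt/s | independently measured anchor at ~60 min/doubling |
| RNAP-signal filter | 0.5 | a.u. | noise floor of background-corrected ChIP signal |
| background window / quantile | 30 000 / 0.10 | nt / – | large window avoids eating long transcription units |
| census anchors | 1300 RNAP or 2400 mRNA | molecules | literature totals for exponential growth |
| clearance grid | 1–90 step 1 | nt/s | brackets reported bacterial elongation rates |
| reporter interval / points | 840 / 54 | s / – | the reporter experiment's sampling design |
| reporter mRNA half-life | 360 | s | published estimate for the gfp reporter mRNA |

## Array normalization

Expression arrays: each replicate array (both strands together) is
quantile-normalized against the other replicates — never across
strands, since strand asymmetry is signal — an optional constant
(control-probe mean, if the platform provides one) is subtracted,
replicates are averaged per coordinate, and the larger of the two
strand values is the expression strength. ChIP arrays: median-scaled to
1, quantile-normalized, averaged, then a running 10%-quantile
background (computed over the probes present in a centered 30-kb
window, truncated at edges) is subtracted with flooring at 0. Replicate
exclusion is an explicit whitelist, not an outlier detector.
Quantile-normalization ties take the mean of the tied ranks' means;
probe-to-gene aggregation is the arithmetic mean over in-gene probes
(median available), with zero-probe genes omitted and logged. The
aggregation statistic and the tie rule are conventions chosen here;
nothing downstream is sensitive to them beyond the probe-noise level.

## Validation procedures

**Stationarity robustness.** For promoter–GFP reporter series the
stationary activity is (ΔGFP/Δt/OD)·(1 − f) with carryover
f = 0.5^(Δt/λ_gfp) ≈ 0.198 for a 6-min reporter mRNA sampled every
14 min. The lag-corrected activity subtracts f times the rate of the
lag-th preceding interval: at lag 1 this inverts the generator's mRNA
recursion exactly; at larger lags it applies the same correction to an
increasingly stale measurement, emulating sparser sampling, so the
per-timepoint rank correlation with the stationary estimate declines
with lag. A decay-matched variant (subtracting f^lag with the matching
normalization, the correction appropriate if the series were genuinely
sampled every lag·Δt) is available via `decay_matched=True`; it
converges to the stationary estimate at large lag by construction.

**Clearance-lag fit.** After initiation stops, a gene's abundance stays
at its steady level until the last polymerase clears it (promoter-to-
gene distance over speed; distance is measured to the gene's 3' end by
default, configurable to 5') and then decays exponentially. For each
candidate speed on the grid the fitter computes per-gene delays and
fits the hinged model log n(t) = b0 + b1·max(0, t − delay) to **all**
timepoints of each gene, scoring the candidate by the unweighted mean
R² across the operon's genes (ties to the smaller speed; candidates
leaving any gene fewer than two post-delay points are excluded). The
pre-delay plateau constrains the intercept, which is what makes the
optimum unique: fitting only post-delay points would give a perfect
line for *every* candidate below the true speed, since those candidates
merely truncate the series deeper into the pure-exponential segment.
Best speeds at the first or last valid grid point carry a boundary
flag.

**Zero-intercept agreement.** slope = Σxy/Σx² with a t-based confidence
interval on n−1 degrees of freedom. On a noise-free 20-operon cohort the
slope against the clearance fits is 1.00 within one grid step and the
95% CI contains 1.

## Associations and the random forest

Codon features use the 61 sense codons of the bacterial code (stops
excluded); positional GC is computed over sense codons. Wobble classes
come from an explicit tRNA anticodon inventory: an anticodon decodes a
codon if positions 1–2 pair Watson–Crick and the wobble base pairs
either Watson–Crick or by wobble (G:U, U:G, inosine reading U/C/A); a
codon read only by wobble pairings is "strict", one read both ways is
"mixed". The inventory is an input because tRNA repertoires differ
between strains. All correlations are Spearman with two-sided p-values,
group comparisons are two-sided Mann–Whitney U, families of tests are
Benjamini–Hochberg adjusted with significance at adjusted p ≤ 0.05
(delegated to scipy/statsmodels; brute-force oracles in the tests).
Interval prediction from delays preserves the observed class sizes —
the delays fix only an ordering, not absolute interval boundaries.

The random forest uses the library's default hyperparameters (recorded
in the run log), features CAI, tAI, GC1, GC3, length, z-scored mRNA
level, RNAP density and mRNA/RNAP ratio (only the mRNA level is
z-scored, as specified for the feature set), 5-fold cross-validation
with folds from a seeded shuffle stratified on speed quartiles, mean
out-of-fold R², and pooled RRSE = sqrt(Σ(y−ŷ)²/Σ(y−ȳ)²).

## The synthetic-data generator

The generator emulates: operon-structured genomes (sizes 1–5, lengths
200–6000 nt), true speeds log-uniform over 1–90 nt/s, half-lives
log-uniform over 1.5–20 min, activities log-normal around 0.02/s,
steady-state observables inverted exactly from the model
(n_r = a/(1−0.5^(1/λ)), d_p = a·footprint/v) with independent mean-1
log-normal noise of configurable CV on level and density (half-lives
noise-free: treated as a stable mRNA property), probe tracks at 25-nt
spacing with low-frequency sinusoidal background drift, reporter series
from the mRNA-carryover recursion m_t = a_t + f·m_{t−1} with smoothly
drifting activities (log-random-walk, step SD 0.1 by default — the true
temporal autocorrelation of promoter activities is unknown, so
smoothness is a parameter, not a fixed constant), and plateau-then-
exponential decay series.

What it does **not** emulate: polymerase traffic and collisions,
supercoiling feedback, ribosome coupling, probe-level sequence bias,
cross-hybridization, or condition-dependent half-lives. Passing tests
therefore demonstrate that the inference chain is correct and
well-conditioned under its own assumptions — not that those assumptions
hold in any particular organism or experiment.

## Numerical choices and problem sizes

- Noise is multiplicative log-normal with E = 1
  (exp(N(−σ²/2, σ²)), σ² = ln(1+CV²)), keeping observables positive.
- The hinge fit uses least squares via `lstsq`; R² is floored at 0, and
  a zero-variance gene scores 1 only with zero residuals.
- Running-quantile windows are per-probe exact (O(n·w)); empty windows
  pass the value through with a logged warning.
- Analysis drivers use 1000 genes / 20% noise; the stationarity check
  uses the full 1920 × 54 reporter design; clearance cohorts use 20
  operons × 3 genes with decay sampled every 20 s to 2000 s. These
  sizes make every driver and the whole test suite run in seconds while
  keeping the statistics stable.
- All randomness flows through `numpy.random.default_rng` seeds;
  rerunning any stage with the same seed is bit-identical.

## Known limitations

- The molecule census interprets arbitrary-unit densities as a single
  global scale; heteroscedastic array response would bias it.
- The clearance fitter assumes one speed per operon and simultaneous
  initiation arrest; partial arrest or internal promoters violate it.
- Speeds for genes with very low RNAP density are noise-amplified (the
  density sits in the denominator); the 0.5-signal filter is a blunt
  but transparent guard.
- The random forest transfers poorly across growth conditions by
  design: it learns the condition-specific level/density/speed map.
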