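# Methods

## The problem

Soil respiration (Rs, µmol CO₂ m⁻² s⁻¹) follows a diel cycle, driven mainly
by soil temperature. Manual chamber surveys, however, are almost always made
at one convenient time of day — typically mid-day — so a monitoring series
carries a systematic bias relative to the daily mean flux, and any annual
budget upscaled from it inherits that bias. This package quantifies the bias
with temporal-stability statistics, identifies the most representative
sampling hours, and corrects non-optimally timed measurements.

## The temporal-stability statistics

For one 24-hr campaign with hourly fluxes x₁ … xₙ (n = 24 when complete) and
daily mean m = Σxᵢ/n, the relative difference at hour i is

    RD_i = (x_i − m) / m.

RD is dimensionless, sums to zero over a complete campaign, and is bounded
below by −1 when fluxes are non-negative. Across N campaigns the per-hour
mean relative difference and its sample standard deviation are

    MRD_i   = (1/N_i) Σ_campaigns RD_i
    SDMRD_i = sqrt( Σ (RD_i − MRD_i)² / (N_i − 1) ),

where N_i counts the campaigns that observed hour i. MRD_i is the
systematic bias of sampling at hour i; SDMRD_i is the precision of that
bias. One deliberate reading: the SDMRD denominator is the number of
*campaigns* contributing to the hour minus one, not the number of hourly
intervals per day — the latter appears in some presentations of the formula
but is dimensionally wrong for an across-campaign dispersion, and with it
SDMRD would not reduce to the ordinary sample SD.

Hours are ranked 1..H by ascending MRD (rank 1 = most negative); exact ties
go to the earlier hour so outputs are reproducible. Three selection rules
are reported side by side:

- **closest-to-zero**: the hour minimizing |MRD|, ties broken by lower
  SDMRD, then earlier hour;
- **middle rank**: the hour(s) holding ranks ⌈H/2⌉ and ⌈H/2⌉+1 (one rank
  when H is odd), i.e. ranks 12 and 13 for a full 24-hour profile;
- **longest run**: the longest circular run of hours with |MRD| at or below
  a threshold (default 0.05, i.e. 5% bias), ties to the earliest start.

Incomplete campaigns (n < 24) are retained and flagged rather than dropped:
RD is well defined for any n ≥ 2, and MRD simply averages the campaigns
that observed each hour. MRD is not clipped to [−1, 1]; values above 1
(flux more than twice the daily mean) are possible and only logged.

## The correction

A flux measured at hour i is mapped to its daily-mean equivalent by

    Rs_hat = Rs_i / (1 + MRD_i),        MRD_i > −1.

This is exact when the offset is the measurement's own RD (the identity the
tests verify) and unbiased to the extent the diel shape is stable across
days. Correction tables are keyed by (treatment, season, hour); for a
measurement window spanning several clock hours (e.g. a 12:00–14:00
survey) the offset is the mean of the per-hour MRD over the window. Hours
missing from a stability profile are filled by circular linear
interpolation on the 24-h clock and flagged — this keeps lookups total
without silently dropping records. Whether the original field analysis used
a single scalar offset per season or hour-resolved offsets is not
determinable from its description; the window rule covers both (a full-day
window reproduces a scalar seasonal offset).

Budgets are unweighted means and sample SDs of monitoring records per
season and per hydrological year (November–October by default), matching a
"mean of monthly measurements" budget rather than a time-integrated annual
sum; percent difference is 100·(corrected − uncorrected)/uncorrected, with
rounding applied only at display time (1 decimal for percents, 2 for
fluxes).

## Bayesian comparisons

Corrected-vs-uncorrected (and treatment-vs-treatment) series are compared
with a JZS Bayes-factor t-test: Cauchy(0, r) prior on the standardized
effect, r = √2/2 by default, point null at zero. BF10 is computed by
adaptive quadrature of the g-mixture representation (inverse-gamma(1/2,
r²/2) prior on g), with relative tolerance 1e-10. The package always
reports BF10 — evidence for the alternative — never its inverse. The test
suite checks this route against an independent formulation (non-central-t
marginal over the Cauchy prior) and against pingouin.

Flux–driver regressions (Rs against soil temperature or moisture) report
least-squares slopes with the central 95% posterior interval under a flat
reference prior, which coincides numerically with the classical t-based
interval; a g-prior variant is deliberately out of scope. Comparisons
between two fits report interval overlap, the slope ratio, and Δr².
Paired and independent t-test modes are both provided since either reading
of "annual series comparison" is defensible.

## The simulator

Ground truth is a Q10 response to a sinusoidal soil-temperature cycle with
an optional Michaelis-type moisture modifier:

    T(h)  = T_mean + A·cos(2π(h − h_peak)/24)
    Rs(h) = R_base · Q10^((T(h) − 10)/10) · θ/(θ + K_θ)

Defaults: T_mean = 15 °C, A = 5 °C (so T spans 10–20 °C), peak at 14:00
(typical soil thermal lag), Q10 = 2 (mid-range for Mediterranean shrubland
soils), R_base = 1 µmol m⁻² s⁻¹ at the 10 °C reference (any other reference
choice is absorbed by R_base), θ = 0.20 m³ m⁻³ constant with K_θ = 0.05 so
the moisture factor is a constant 0.8 and Q10 dominates the diel shape.
Noise is multiplicative lognormal with a mean-one correction
(σ² = ln(1 + CV²), mean shift −σ²/2), CV = 0.10 by default — chamber-flux
scatter scales with flux magnitude; additive Gaussian noise is available as
an option. The sampling schedule mirrors the field design the method was
built around: eight 24-hr campaigns (hourly, 9:00 → 8:00 next day) spread
over wet and dry seasons, three collars per treatment, and monthly mid-day
(12:00–14:00) monitoring over a November–October hydrological year.

What the simulator does *not* emulate: day-to-day weather, seasonal drift
of the diel amplitude, moisture pulses after rain, spatial heterogeneity
beyond i.i.d. collar noise, trenching-disturbance transients, and
non-sinusoidal diel shapes (the field data themselves were noted not to be
sinusoidal). Passing tests therefore demonstrate that the estimator and
correction recover a *stable* diel structure under realistic noise — not
that any particular field series satisfies the stability assumption; that
is an empirical question per site and season.

Under this forcing the relative profile crosses zero exactly twice per day,
so a sinusoidal cycle has two non-consecutive ideal sampling hours — the
property one test checks — and mid-day (12:00–14:00) sampling with a 14:00
peak overestimates the daily mean, which is the regime the end-to-end
bias-reduction test and acceptance script exercise.

## Numerical and design choices

- Hour binning floors timestamps to the local clock hour; no daylight-saving
  adjustment (field times are local; reproducibility beats tz-correctness
  here). Collars are averaged unweighted within treatment-hour.
- Default season map: dry = May–October, wet = November–April (Mediterranean
  climate); user-overridable, since any particular site's assignment is a
  judgment call.
- All tie-breaks (ranking, best hour, best run) resolve to the earlier hour.
- Quadrature failures in the Bayes factor raise a numerical error with the
  offending t, N, ν, r rather than returning a value.
- CLI outputs are written atomically (temp file + rename) and carry a
  `# tool=dielbias version=… seed=…` comment line; the readers skip `#`
  lines.
- Problem sizes in tests and the acceptance script: 20 replicate seeds for
  stochastic checks, campaign counts {2, 8, 32} for the convergence check,
  1000 random campaigns for the zero-sum identity — large enough for stable
  Monte-Carlo ordering, small enough to run in seconds.

## Known limitations

- The correction assumes the MRD profile estimated from campaign days
  transfers to monitoring days; regime change between them (e.g. a table
  built only on dry-season campaigns applied to wet-season surveys) breaks
  the guarantee, which is why tables are season-specific.
- Negative or zero daily-mean fluxes (possible with chamber artifacts or
  uptake) are rejected rather than handled: RD's sign semantics invert.
- Budgets are record means, not gap-weighted integrals; irregular sampling
  will weight dense periods more heavily.
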