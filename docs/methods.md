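# Methods

## Dose-response model and fitting

Growth (OD600 at the assay endpoint) is normalized to the mean of the
no-ion, no-phage control wells, so an uninhibited culture sits at ~1.
Each (ion, phage condition) series is fitted with the four-parameter
logistic on log10 concentration,

    y(x) = bottom + (top − bottom) / (1 + 10^{h(x − log10 c₅₀)}),  x = log10 c,

by bounded nonlinear least squares (trust-region reflective, analytic
Jacobian). Zero-concentration wells are excluded from the fit and used
only for normalization.

Numerical choices:

* **Initialization** — top/bottom at the response extremes; log10 c₅₀ at
  the midpoint-bracketing concentration of the per-concentration means
  (median log-concentration if no crossing); Hill slope 1.
* **Bounds** — h ∈ [0.2, 10]; log10 c₅₀ within [min conc/10, max conc×10];
  top/bottom within the response range padded by one range width.
* **Direction** — both orientations are started (top = max, bottom = min
  and the mirror); the lower-RSS solution wins, so rising (protective)
  responses are fitted without a separate code path. Parameters are stored
  with top ≥ bottom plus a direction flag.
* **No-inhibition sentinel** — a flat series, or a fitted dynamic range
  below 20% of the control level, is reported as `no_inhibition` with NaN
  half-max rather than an extrapolated threshold. The cutoff avoids
  assigning meaningless c₅₀ values beyond the tested range; it is the one
  deliberately sharp decision boundary in the fitter.

**Uncertainty** is a case-resampling bootstrap: wells are resampled with
replacement, refitted (warm-started from the full-data solution with a
relaxed 1e−9 tolerance, which keeps resampling stable and roughly an order
of magnitude faster), and the 95% percentile interval of the half-max is
reported. Resamples with fewer than 4 distinct concentrations, failed
optimizations, or sentinel refits count as failures; more than 50%
failures raises rather than returning a misleading interval. The default
is 1000 resamples with a caller-supplied seed.

**Classification.** A shift is significant when the two percentile
intervals are disjoint — a conservative convention chosen because the
source assays report "significant difference" without naming a test.
`enables_infection` when EC50 < IC50 with disjoint CIs, `protective` when
EC50 > IC50 with disjoint CIs, `toxic_only` otherwise, `no_inhibition`
when the phage-free curve never inhibits. A concentration exactly at a
threshold is treated as meeting it (the EC50 is half-maximal, not a hard
floor).

## Ionic strength

I = ½ Σ cᵢzᵢ² on a concentration basis, in mM. Activity coefficients are
not applied: thresholds and environmental profiles are compared on the
same concentration scale, and the comparisons span four orders of
magnitude where activity corrections are second-order. Dosed salts
default to chloride salts of the named cation (the two salts named in the
source assays are chlorides); the stoichiometry column can override this.
The ~30 mM Na⁺ assay-medium background is *not* added to converted
thresholds by default — it is reported separately, since published
threshold figures do not state whether it is included.

## Hot-spot models

**Lysis dilution** treats the lysed cell as a 1 µm sphere whose contents
mix evenly into a sphere of radius r: C(r) = C_cyto(r₀/r)³. This is the
even-mixing calculation, not a steady-state Fickian profile — it conserves
the released ion mass exactly and gives the closed-form crossing distance
r₀(C_cyto/threshold)^⅓. Cytoplasmic composition defaults to the standard
literature values (Na⁺ 212, K⁺ 38, Ca²⁺ 0.5, Mg²⁺ 1 mM).

**Evaporation** multiplies conservative ions (Na⁺, K⁺) by the
concentration factor and caps Ca²⁺/Mg²⁺ at configurable solubility
ceilings (defaults 0.5 and 1 mM). The ceilings are illustrative constants
standing for calcite/magnesium-silicate control, not a speciation
calculation: no equilibrium constants, pH evolution or activity
corrections are solved, which reproduces the qualitative capped-vs-linear
behavior without pretending to full geochemical modeling. Crossing
factors are exact closed forms (threshold/c₀ for conservative ions; `None`
when a ceiling sits below the threshold); the tests verify both solvers
against dense log-grid brute-force scans.

## Microbiome function

Each ±cocktail contrast is a per-carbon-source Welch two-sample t-test on
ammonium, unadjusted by default (one planned contrast per carbon source);
Benjamini–Hochberg adjustment is available via a flag. The dominant taxon
is the argmax of mean abundance in the phage-free condition, ties broken
lexicographically. DNRA genetic potential is the abundance-weighted sum
over taxa flagged capable of both reduction steps; capability flags are
inputs, not called from genomes. The nitrogen correction is
N = OD600 × 0.3 g dry weight/L per OD × 0.12 gN/g, also reported in mM via
14.007 g/mol.

## Synthetic data: what it emulates, and what it does not

The plate generator draws responses from a true 4PL per (ion, condition)
with Gaussian noise on the normalized scale (sd expressed as a fraction of
each curve's dynamic range), clipped at zero because optical densities
cannot be negative; serial dilution is 2-fold over 10 steps from a
configurable top concentration, with 2 replicates and zero-ion control
wells per condition — a realistic density for a 384-well ion array.
Phage presence is a binary condition label (the underlying assays run at
MOI ≈ 1; infection kinetics are not simulated). Not modeled: plate
position/edge effects, heteroscedastic or correlated well noise, growth
time courses. Passing recovery and coverage tests therefore validates the
estimators under clean 4PL truth with homoscedastic noise, not robustness
to systematic plate artifacts.

The microbiome generator fixes a base composition per carbon source,
multiplies phage-target taxa by a depletion factor in +cocktail samples,
computes ammonium from the depleted pre-renormalization biomass
(yield-weighted sum, additive noise, floored at 0), then renormalizes
abundances. The default community mirrors the studied enrichment: a
targeted DNRA *Escherichia* dominating on glucose, a nitrate→nitrite-only
*Klebsiella* on cellobiose, an untargeted DNRA *Sulfurospirillum* on
ethanol — and the targeted strain is absent on the carbon sources it
cannot use, so those contrasts are exact nulls. Four replicates per
(carbon source, condition) and 0.05 mM ammonium noise are the default
study conditions; compositional sampling noise is not simulated.

The environment profiles bundle the literature cytoplasm composition and
the ~0.1 mM global-mean freshwater Ca²⁺; the remaining freshwater, gut
and seawater entries are representative textbook compositions. The
springwater composition for evaporation scenarios is configurable, with
illustrative dilute-mountain-spring defaults (Na⁺ 0.134 mM) — published
descriptions of such waters do not fix a single composition, so these
defaults are labeled illustrative and every value can be overridden.

## Validation problem sizes

The statistical guarantees are checked by simulation at sizes chosen to
make the checks sharp but cheap: half-max recovery over a grid of true
EC50 ∈ {0.1, 1, 10, 100} mM × noise ∈ {0, 0.05, 0.1} (204 fits, median
relative bias < 10%); bootstrap coverage over 200 noisy series at 500
resamples (coverage within 90–100% at nominal 95% — percentile intervals
on 20-well nonlinear fits run a few points below nominal, which the band
anticipates); solver-vs-oracle agreement on 100 random scenarios with
10⁴-point grids; and 100 seeded microbiome runs each for effect detection
and null false-flag rates.

## Known limitations

* Thresholds are single-ion; mixture effects enter only through the
  optional ionic-strength mode, not through interaction terms.
* The bootstrap is percentile-based; BCa or profile-likelihood intervals
  would cover better at these sample sizes but cost considerably more
  refits.
* Evaporation chemistry is a cap, not an equilibrium model; pH and
  complexation are out of scope.
* The 4PL family is assumed; biphasic or hormetic responses will fit
  poorly and show up only through RSS.
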