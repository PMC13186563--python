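# Methods

This note documents the models, conventions and numerical choices behind
`combiplate`, in the order of the workflow.

## Encoding and layout

A consortium over an m-strain library is the bitmask c with bit k−1 set
iff strain k is present; `str(code)` renders x_m…x_1 with strain m
leftmost. Strain indices are 1-based. Merging is defined only for
disjoint consortia, where binary addition equals bitwise OR; overlapping
merges raise an error rather than silently carrying (01 + 01 = 10 would
encode the wrong community).

The canonical layout splits a code at `row_bits = min(m, log2(rows))`
(3 on 96-well, 4 on 384-well): the low bits give the row index i−1, the
high bits the *global* column index j−1, with columns continuing across
plates (columns 13–24 of a 96-well layout are plate 2, and so on). This
makes codes increase strictly top-to-bottom then left-to-right, places
strain k in alternating blocks of 2^(k−1) rows (k ≤ row_bits) or
2^(k−1−row_bits) global columns, and gives the identity
H(c) = H(B(i−1)) + H(B(j−1)). For m < row_bits everything sits in the
top 2^m wells of the first column. Wells are named letter + zero-padded
two-digit local column ("C02"); zero-padding is a convention of this
package. Plates whose row counts are not powers of two, and partial
factorial layouts, are out of scope.

## Assembly planning

`PlanConfig` holds the per-strain aliquot v₀ (µL), plate format, strategy,
homogenization mode, buffer label (no chemistry is modeled), and a well
capacity (default 300 µL, a typical 96-well working volume; 384-well users
should set it lower). Volumes are exact `fractions.Fraction` throughout
and rendered to 0.1 µL only in exports, so conservation and endpoint
checks are exact rather than float-tolerant.

Two strategies produce the same endpoint and are both checked by the
simulator:

* **direct_dispense** (default): the 2^row_bits starting mixes of the
  row-wise strains are prepared in tubes sized exactly for the run
  (v₀ × number of global columns per present strain). With full
  homogenization each tube also carries its buffer share
  ((row_bits − H)·v₀ per well-equivalent), so every dispense is a uniform
  row_bits·v₀ multichannel stroke per column and the row-wise buffer pass
  is bypassed. Column-wise strain additions (v₀ wherever the placement
  rule puts strain k) and a column-wise buffer pass
  (v₀·(m − row_bits − H(B(j−1)))) finish the run. For m = 8 this is a
  3-plate, 8-tube protocol, matching the materials of the reference bench
  run, in 162 steps versus the naive 1024.
* **block_duplication**: the literal column-doubling construction. The
  starting column is built at 2^(m−row_bits)·v₀ per strain; each round t
  copies every occupied column j onto column j + 2^(t−1) by withdrawing
  half of each well's contents (per-well single-channel transfers, since
  volumes vary with richness; the empty well is skipped) and adds the next
  strain at 2^(rounds−t)·v₀ to the new columns. Halving each round lands
  every present strain at exactly v₀. Homogenization is applied at the
  end as the positional column-wise + row-wise buffer passes. First-column
  volumes scale as 3·2^(m−3)·v₀, so at bench volumes (m = 8, v₀ = 25) the
  planner raises a capacity error naming the offending step — a real
  limitation of this strategy, reported rather than hidden.

The literal transfer schedule of the original bench protocol is not
encoded anywhere in this package; only the endpoint constraints are
treated as authoritative, and the simulator enforces them: every well must
end with exactly the strains of its layout code, each at v₀
monoculture-equivalent, with total volume m·v₀ (full homogenization),
H(c)·v₀ + column term (column_only), or H(c)·v₀ (off). The simulator
propagates proportional composition on every transfer, forbids drawing
from empty sources, and tracks the running maximum well volume against
capacity. Tip counts are an estimate (one tip set per step). Inoculation
is reported as bookkeeping (dilution factor, per-strain inoculum
volume = inoculum/m under uniform densities) rather than as pipetting
steps, since the growth plate lies outside the assembly plates the
simulator models.

## Spectral deviations

The additive expectation of a mixture is the pointwise sum of its
constituents' monoculture spectra; wavelength grids must match exactly (no
interpolation — a plate reader measures all samples on one grid). The
relative deviation δ = |measured − expected| / measured is computed only
where the *measured* spectrum exceeds a threshold (default 0.1 A.U.);
absolute deviations are kept everywhere. When replicates exist, δ is
computed on replicate means. Summaries pool all unmasked
(mixture, wavelength) points with equal weight — per-mixture pre-averaging
would be the alternative; pooled weighting is the package's documented
choice — and the headline summary is restricted to mixtures of ≥ 2
constituents. Spectra are assumed blank-corrected upstream. No spectral
unmixing, concentration inference or high-absorbance nonlinearity
correction is attempted.

## Landscape analytics

All interaction formulas operate on replicate means. If the empty
consortium was not measured its function is taken as 0 with a warning, and
that value is then used consistently. ε SDs are propagated from per-code
replicate SDs under an independence assumption and labeled approximate.
Ranking breaks ties by ascending code integer, purely for determinism.
Interactions above order 3 are not given pointwise estimators; they are
summarized through the variance decomposition.

## Variance by order

On a complete landscape the replicate-mean vector is expanded in the
orthogonal Walsh–Hadamard basis of ±1-coded presence variables; by
Parseval the variance over the hypercube splits exactly across non-empty
subsets, and order r's fraction is the squared-coefficient mass at weight
r divided by the total over orders ≥ 1. This is the standard orthogonal
variance partition on {0,1}^m landscapes; the alternative
(background-averaged Taylor coefficients) is deliberately isolated behind
`walsh_coefficients` so the basis could be swapped. The implementation
uses the Sylvester Hadamard matrix, whose character signs differ from the
±1 coding by a fixed per-coefficient sign — squared masses, orders and
round-trips are unaffected (the tests check this against explicit
character enumeration). Replicate means are used, so replicate noise is
included in the decomposed variance and, in expectation, adds mass at high
orders; a flat landscape returns all-zero fractions.

## Global epistasis

For strain k, ΔF_k(b) is regressed on F(b) by ordinary least squares over
all 2^(m−1) backgrounds excluding k (scipy's `linregress`, cross-checked
in tests against a normal-equations oracle at 1e−10). R² is defined as 0
when the response (or the regressor) is constant — nothing to explain,
nothing explained. The null model permutes the replicate-mean values
across consortia: it preserves the value distribution while destroying all
compositional structure. The permutation count B (default 1000) and seed
are recorded in the output; the p-value uses the add-one estimator
(1 + #{null ≥ observed}) / (B + 1). The exact randomization scheme is a
package choice and is flagged in the output metadata.

## Synthetic data

The spectra generator emulates a colorant-style validation: per-colorant
spectra are sums of 1–3 Gaussian peaks on a 380–780 nm grid, normalized to
comparable unit maxima (mirroring colorants diluted to comparable peak
absorbance), and each mixture constituent's aliquot is perturbed
multiplicatively by 1 + η, η ~ N(0, CV), independently per mixture. The
default CV of 0.0075 sits mid-way in the 0.5–1% error band typical of
handheld micropipettes; CV = 0 yields exactly additive mixtures. What it
does *not* emulate: instrument noise, baseline drift, chemical
interactions between colorants, or absorbance nonlinearity — so passing
tests bound pipetting-style error propagation only, not detector physics.

The landscape generator plants coefficients in either the subset-sum
("taylor") basis — which makes the background-referenced effect and
interaction estimators recover planted terms exactly at zero noise — or
the orthogonal "walsh" basis, which makes variance fractions exact.
Gaussian replicate noise is added per replicate. Multiplicative
landscapes F(c) = A·∏(1 + w_k) provide exact global epistasis
(ΔF_k(b) = w_k·F(b)). The generator targets the statistical structure the
analyses assume; it simulates no growth dynamics (no Lotka–Volterra or
consumer-resource mechanisms), so agreement on synthetic data validates
the estimators, not any ecological model.

Both generators are byte-deterministic under a fixed seed.

## Problem sizes in the test suite

Exhaustive checks run at the scales where enumeration is exact and cheap:
the layout bijection for m = 3..10 (every well), planner endpoints for
m ≤ 6 across all strategy × homogenization combinations plus the m = 8
reference configuration, interaction recovery at m = 6, Monte-Carlo
deviation comparison with 2000 oracle draws at m = 8, and a B = 200
permutation null at m = 5. These sizes match the experiments the package
is designed around (m ≤ 10 on 96-well plasticware).

## Known limitations

* No robot-vendor worklist dialects, evaporation/dead-volume modeling or
  scheduling optimization; the worklist CSV is generic.
* Tube capacities are not checked (bench tubes are far larger than any
  per-tube volume the planner produces at supported scales).
* Interaction terms are statistical deviations from an additive baseline,
  not mechanistic quantities.
* The Abs/biomass relation is nonlinear at high absorbance; the package
  treats the measured function as-is and makes no correction.
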