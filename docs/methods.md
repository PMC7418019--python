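# Methods

## Data model

A panel is a hospitals × quarters matrix of duplicative-prescription rates
in percent (the scale on which the insurer publishes them; no conversion to
proportions anywhere downstream), with hospital metadata: accreditation
type (medical center / regional / district), one of six regions (Taipei,
North, Central, South, Kao-Pin, East) and optional WGS84 coordinates.
Quarter labels use the `YYYYQn` dialect (`YYYY-Qn` accepted on input) and
must be strictly increasing. Missing quarters are explicit `NaN` cells —
never 0, because a 0% rate is legal data. Analysis requires complete
series: `filter_complete(panel, 25)` drops any hospital with a missing
cell in the last 25 quarters, mirroring the exclusion rule under which the
published panels were assembled. Hospitals without coordinates pass through
every statistic and are skipped (with a log message) only by map export.

## Scale quality

The quality question is whether a drug category's 25-quarter panel behaves
like a reliable, unidimensional scale, with quarters as items and hospitals
as cases — the only orientation under which "reliability of the 25-quarter
ratio data" is a single number per panel.

* **Cronbach α** = `k/(k−1)·(1 − Σ var_i / var(total))` with sample (n−1)
  variances; accepted when strictly greater than .70.
* **Dimension coefficient** = `Z/(1+Z)`, `Z = (a1/a2)/(a2/a3)`, where
  a1 ≥ a2 ≥ a3 are the three largest eigenvalues of the **correlation**
  matrix of items (correlation, not covariance, so the indicator is
  invariant to the scale differences between hospital types). Values above
  0.67 are read as unidimensional. Eigenvalues at or below the 1e−10 floor
  raise a degenerate-spectrum error rather than returning a misleading
  coefficient (this happens, e.g., for fewer than 4 cases, where the
  correlation matrix is rank-deficient).
* **Loadings** λ are item ↔ first-principal-component-score correlations,
  sign-flipped so Σλ ≥ 0. How the original analysis obtained λ is not
  documented; PCA loadings are the natural companion of the
  eigenvalue-based dimension coefficient, which is why they are used here.
* **AVE** = `Σλ² / (Σλ² + Σε)` and **CR** = `(Σλ)² / ((Σλ)² + Σε)` with
  `ε = 1 − λ²`, the standardized-item measurement error. For non-negative
  λ, AVE ≤ CR (checked as a property test).

## Growth/share statistics

Each hospital's recent series is reduced to *growth* — the Pearson
correlation of the values with the time index 1…T, with the convention
that a constant (zero-variance) series has growth 0 — and *share* — the
arithmetic mean. Growth is invariant under positive affine transforms of
the series and antisymmetric under time reversal; share is
affine-equivariant.

Two series modes exist. `raw` (default) uses the last `window_outputs`
(12) raw quarters; `moving_sd` first maps the last `2·window_outputs`
quarters to `window_outputs` moving sample SDs, where the i-th output is
the SD (ddof=1) of the window of length `N − window_outputs + 1` starting
at position i — the only window arrangement under which 24 points yield
12 SDs. `raw` is the default because the four published worked examples
(growth 0.48 for both `{−1×11, 1}` and `{2×11, 4}`; the quadrant datasets)
reproduce only on raw values; which mode produced the published dashboards
is not determinable, so both are provided behind a flag.

Quadrants: I if g>0 and s>0, II if g>0 and s≤0, III if g≤0 and s≤0, IV if
g≤0 and s>0. Boundary ties go to the non-red side because a zero trend is
not "increasing growth". Colors: I→red, II→yellow, III and IV→green —
lower duplication is better, so any non-positive trend is good
performance; the mapping is validated by the reproduction of all nine
published weighted scores. Mascots follow the classic BCG convention
(I star, II problem child, III dog, IV cash cow); the source names the
mascots but does not fix their quadrants.

The control region is the rectangle mean ± 2·SD (ddof=1) per axis over all
hospitals in a panel (the "95% CI" control area); a hospital is in control
when inside or on the boundary. The intersection of two ≈95.4% per-axis
bands covers ≈91% of independent bivariate-normal points, which the
acceptance suite checks empirically.

## Ranking

AHP weights: from ordinal category scores (green 3, yellow 2, red 1) build
the pairwise odds matrix `A_ij = s_i/s_j`, normalize each column by its
sum, average rows. For a consistent ratio matrix this reduces exactly to
`s_i/Σs = (1/2, 1/3, 1/6)`. The default `paper_rounded` mode rounds to one
decimal — (0.5, 0.3, 0.2) — and keeps the rounding only when the rounded
set still sums to 1.0, because every published score uses those rounded
weights; `exact` mode is available.

Weighted score of a hospital type = `red%·w_red + yellow%·w_yellow +
green%·w_green` on integer-rounded row percentages (matching the published
tables; a raw-count mode is behind a flag), reported to one decimal.
Shifting percentage mass from red to green strictly increases the score.

Contingency tables are tested with the textbook Pearson chi-square
(`Σ(O−E)²/E`, df=(r−1)(c−1), upper tail), dropping zero-margin rows or
columns with a warning and adjusting df. Note that the chi-square values
printed alongside the original 3×3 tables are not reproducible as Pearson
statistics of those printed counts; this package makes no attempt to match
them.

Ranks: 1 = highest weighted score; ties share the average rank. Kendall's
W over m drugs ranking n hospital types: `R_j` = rank row sums,
`S = Σ(R_j − m(n+1)/2)²`, `W = 12S/(m²(n³−n))`, `χ² = m(n−1)W`, df = n−1,
upper-tail p. Tied ranks are refused (tie-corrected W is out of scope);
the reported W is the computed value (12·14/216 = 0.7778 for the published
rank table, which rounds to 0.78). No multiple-testing correction is
applied, matching the original analysis.

## Dashboard export

GeoJSON output is RFC 7946: Point features in [lon, lat] order carrying
id, name, type, region, growth, share, quadrant, color, mascot and the
in-control flag. The HTML page is a single file with all data inline, a
coarse embedded Taiwan outline instead of any map-tile or commercial API
(keeping output fully offline and testable), and is byte-identical across
runs for identical input — no timestamps, sorted JSON keys. Bubble radius
is `bubble_scale·sqrt(|share|)` so bubble *area* is proportional to
momentum magnitude ("proportional" being ambiguous between radius and
area, area avoids visually exaggerating large values). Per-hospital charts:
the traditional chart shows the last 8 quarters (a 2-year trend) against
mean ± 2 SD limits from the full series; the moving chart shows the 12
moving SDs of the last 24 quarters with a least-squares trend line. Colors
default to #d7191c / #fdae61 / #1a9641 and are overridable.

## Synthetic generator

`generate_panel` emulates the published study conditions:
25 quarters from 2010Q3; type mix 20 medical centers / 77 regional / 305
district (the per-type counts of the antihypertension table, district-heavy
so contingency margins are realistic); regional mixes per type taken from
the same table's row percentages; base rates at the published management
thresholds (0.5805 / 0.4273 / 0.5934 percent); per-hospital trend profiles
`rate_t = max(0, base + slope·t + N(0, noise_sd))` with |slope| = 0.01
%/quarter and noise_sd = 0.05% by default — a trend of about a quarter of
a typical base rate over 25 quarters, large enough to be managerially
meaningful and small enough that recovery is non-trivial; default profile
mixes make higher-level hospitals improve more often (80/15/5,
70/20/10, 30/40/30 improving/stable/worsening), reflecting the better
published rankings of medical centers and regional hospitals;
quarter-level missingness 0 / 2% / 8% with district hospitals patchiest,
mirroring the incomplete district reporting the source discusses.
Coordinates are uniform draws in fixed per-region boxes inside Taiwan's
extent (lat 21.9–25.3, lon 120.0–122.0). All randomness flows through an
explicit `numpy.random.default_rng(seed)`; no global state.

What the generator does **not** emulate: the true distributional shape of
the real rates (Gaussian-around-threshold is a stated stand-in), seasonal
or policy-driven common shocks across hospitals, spatial clustering of
hospitals, or informative missingness (closures). Passing recovery tests
therefore show the pipeline's statistics are computed correctly and are
recoverable under realistic noise — not that the original panel values
would be reproduced.

`one_factor_panel` generates the standardized one-factor matrices
(`item = λ·factor + sqrt(1−λ²)·noise`, columns z-scored) used to verify
that α, the dimension coefficient and the loadings recover their
generating values.

## Numerical choices and degenerate inputs

* Sample (ddof=1) SDs and variances throughout.
* Eigenvalue floor 1e−10; threshold comparisons strict (>.70, >0.67) as
  printed.
* Constant series: growth 0; constant item: loadings error naming the item;
  zero total-score variance: α error.
* Rounding: weighted scores to one decimal, row percentages to integers
  (published-table convention), p-values to three decimals in JSON export.
* Control-region boundary inclusive with a 1e−12 slack against
  floating-point ties.

## Problem sizes

The test suite exercises the estimators at the sizes the recovery designs
call for — 200-hospital quadrant recovery, 50 × (1000 × 25) one-factor
replicates, 1000-point coverage checks — which keeps the full suite under
half a minute on one CPU.

## Known limitations

* Tie-corrected Kendall W and AHP consistency-ratio checks for
  inconsistent matrices are not implemented (the consistent 3-category
  matrix is the only use here).
* The published per-drug quality indicators and chi-squares cannot be
  reproduced without the original panels; they are covered by parameter
  recovery on synthetic data instead.
* The dashboard renders mascots as text labels; the original figures'
  visual encoding is not documented.
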