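# Methods

This note documents the models behind `acp`, the defaults and why they were
chosen, and what the synthetic data does and does not emulate.

## Gradient sedimentation model

A species of sedimentation coefficient *s* (Svedberg) is mapped to a
gradient position (fractions, 1-based from the top) by a straight line
`position = slope·s + intercept` fitted by least squares from sedimentation
standards. A linear map is adequate over the 2.8–8.9 S range spanned by the
four standards used for calibration (carbonic anhydrase 2.8 S, ovalbumin
3.6 S, BSA 4.2 S, β-amylase 8.9 S); no attempt is made to model the
sedimentation PDE or the glycerol viscosity profile. The default
calibration places the standards at fractions 3.8 / 4.6 / 5.2 / 9.9
(slope 1.0 fraction/S, intercept 1.0). These positions are a package
choice: they put a 6.5 S species at position 7.5 — an activity peak in
fractions 7–8, the regime the method targets — and the bulk of 40–80 kDa
monomeric protein in fractions 5–6.

Species without an explicit *s* get one from the globular scaling
`s = k·M^(2/3)` (M in Da), with `k = 2.8/29000^(2/3) ≈ 0.00297` anchored to
the 29 kDa / 2.8 S standard. This makes peak position monotone in mass, so
the average mass of proteins peaking in each fraction rises along the
gradient (monomers early, complexes late) — a qualitative feature of real
velocity gradients that the test suite asserts as monotonicity, not as
specific kDa values.

The band a species forms is Gaussian in fraction coordinate with
σ = 0.8 fractions by default (`band_sigma`). Real bands are shown but not
parameterized in gradient figures; 0.8 fractions makes a single species
span roughly 3–4 visible fractions of a 12-fraction gradient, which matches
the look of standard runs. Band mass in fraction *j* is the normal integral
over [j−½, j+½]; tails clipped at the gradient ends are folded back by
renormalization so each species' per-fraction amounts sum exactly to its
abundance. Renormalization (rather than reflection) was chosen because mass
conservation is the contract the rest of the pipeline relies on; a band
centred far past the last fraction degenerates to a point mass at the
nearest end (numerical guard).

Oligomeric pools: species sharing `pool_of` are summed under the parent id
when the observed matrix is built, because isobaric-label MS cannot
distinguish the monomeric and complexed forms of a protein.

## Measurement noise

TMT-style quantification noise is log-normal multiplicative per cell:
`observed = true · exp(ε)`, `ε ~ N(0, σ)`, `σ = sqrt(log(1+cv²))`, the
standard model for ratio-scale isobaric data. It is unbiased in the median
(mean bias `exp(σ²/2) ≈ 1.005` at cv = 0.1, negligible for correlation,
which is scale-invariant per protein). Default cv = 0.1 with two technical
replicates reflects a well-run TMT experiment. All randomness flows through
one integer seed per call; fraction-to-fraction and protein-to-protein
noise is independent — no co-isolation interference, ratio compression, or
abundance-dependent variance is modeled, which makes the simulated data
*kinder* than real TMT data (see Limitations).

Activity duplicates perturb the occupancy λ (log-normally, given cv) before
the end-point transform, so readouts stay within physical bounds
(50–100% capture); cv = 0 gives ideal duplicates.

## Reconstitution-assay model

Scramblase molecules reconstitute into an ensemble of identical vesicles
following Poisson statistics with mean occupancy λ. The reporter lipid is
split between leaflets with outer fraction `f_out` (default 0.5, symmetric
reconstitution). Scrambling is treated as infinitely fast relative to
lectin capture (pure end point, no kinetics), so a vesicle with ≥ 1
functional copy exposes its entire reporter pool:

    capture% = 100·[f_out + (1−f_out)·(1−e^(−λ))]        ∈ [100·f_out, 100]
    flipping% = 100·(1−e^(−λ))

From raw scintillation counts, `R = 100·P/(P+S)` per condition and
`flipping = 100·(R_ConA − R_buffer)/(R_ConA-TX − R_buffer)`; for ideal
symmetric vesicles the two parameterizations agree exactly (asserted to
1e-12 in the tests). Vesicle size dispersity (a λ distribution) is noted as
an extension but not modeled — the plain Poisson model is the assumption
the assay design rests on.

`occupancy_scale` is the single linear constant linking reconstituted
protein amount to copies per vesicle. It is a free calibration constant
(vesicle number and diameter are not modeled); simulations fix it with
`scale_for_peak_capture`, reproducing the experimental design rule of
reconstituting just enough material (half of each fraction) that the
richest fraction reports ~70% capture, i.e. 40% of vesicles occupied —
the steep part of the response where fraction-to-fraction differences
remain visible.

In-silico immunodepletion scales λ by the share of *active* abundance
surviving removal, at each protein-to-phospholipid ratio. Removing the sole
active species gives complete loss at every ratio; removing one of three
equal, redundant carriers lowers the flipping readout by one-third in the
small-λ (linear) regime. At saturation the model correctly predicts a
smaller drop — the assay's poor sensitivity to less-than-twofold changes,
asserted as such in the tests rather than hidden.

## Correlation and curation

Pearson R is computed per technical replicate between each protein's
profile and the activity profile over their common fractions — by default
the six TMT channels (fractions 5–10), even though activity is assayed over
5–11; the activity value at fraction 11 has no MS counterpart and is
ignored. Duplicate activity measurements are averaged per fraction first.
Zero-variance (flat) or partially missing profiles yield a *missing* R
(never 0), and missingness propagates to curation as "fails threshold".
Replicate Rs are aggregated as mean ± sample SD (ddof = 1; SD = 0 by
convention for a single defined replicate).

Curation intersects the R ≥ 0.9 set (inclusive comparison by default, a
`inclusive=False` flag gives strict >) with annotation-derived sets:
essential genes, membrane proteins with ≥ 3 predicted TM spans, and an
exact-match localization label (multi-localized proteins pass if any
semicolon-separated label matches; unknown localization counts as
non-matching). Unannotated proteins are excluded with an explicit
"unannotated" reason rather than silently dropped, and every exclusion
carries a machine-readable reason string. The three-way Venn region counts
are emitted for bookkeeping and satisfy inclusion–exclusion exactly. The
near-threshold report (default margin 0.02) lists proteins just missing
the cut, making the manual rescue of borderline candidates reproducible.

## The X + XY scenario

The failure mode that defeats activity correlation profiling: the activity
carrier X co-exists as an active monomer and an inactive complex XY
(mass `mass_x + mass_y`, 1:1 stoichiometry unless overridden) that
sediments deeper. Both pools report under X's id, so X's observed profile
is a two-band mixture — a discrete-pool realization of a "broadened"
profile — while the activity tracks only the monomer band. Defaults
(mass_x = 100 kDa, mass_y = 60 kDa) separate the bands by ~2.4 fractions.
R(X) falls monotonically as the complexed share grows; at 50% complexed,
R(X) ≈ 0.43 and X is discarded by curation despite carrying all the
activity. Setting `complex_active=True` restores R → 1 (control), and
flagging only the complex active expresses the inverse scenario (activity
due to a complex of individually inactive proteins).

One numerical subtlety: because the end-point readout is a concave
transform of scramblase amount, the noise-free correlation of the activity
carrier is ≈ 0.9986 rather than exactly 1 under the 70%-peak design rule.
The carrier still attains the maximum R among all species at zero noise.

## Recovery benchmark and the resolution limit

`recovery_benchmark` repeatedly simulates the full experiment (fresh
mixture, fresh noise, seeds derived from one master seed) and records the
rank of the true carrier by mean R plus whether it survives curation. With
3000 species, two replicates and cv = 0.1, the carrier's R is ~0.99 and it
passes curation in essentially every run — but it ranks strictly first
only rarely. This is a resolution limit of the method, not an
implementation artifact: the mixture contains hundreds of decoys per
fraction-width of gradient position, so tens of decoys sediment within
~0.05 fractions of the activity peak, their noise-free correlations within
~10⁻³ of the carrier's — inside the noise-induced spread of R. A six-point
profile cannot single out one protein from a continuum of co-sedimenting
species; it can only produce a candidate *set*, which is exactly why the
experimental method needs the downstream annotation filters and orthogonal
separations. The benchmark reports the rank distribution so this limit is
measurable rather than hidden.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| `n_fractions` | 12 | gradient fractions, 1 = top |
| `assayed_fractions` | 5–11 | activity-assayed window |
| `ms_fractions` | 5–10 | TMT channels (6-plex) |
| `band_sigma` | 0.8 fractions | Gaussian band spread |
| `k` | 0.00297 S/Da^(2/3) | globular mass→S scaling |
| calibration | slope 1.0, intercept 1.0 | fitted from 4 standards |
| `cv` (TMT) | 0.1 | per-cell multiplicative noise |
| `n_replicates` | 2 | technical replicates |
| `f_out` | 0.5 | outer-leaflet reporter share |
| `target_peak_capture` | 70% | reconstitution design rule |
| `reconstituted_share` | 0.5 | half of each fraction reconstituted |
| `r_threshold` | 0.9 (inclusive) | candidate cut |
| `min_tm` | 3 | TM-span filter |
| localization | "ER" | compartment filter |
| `n_decoys` | 2999 | mixture size (~3000 species) |
| decoy masses | log-uniform 20–300 kDa | mixture composition |
| decoy abundances | log-normal, sdlog 1.0 | dynamic range |

## Problem sizes used in the test suite

Unit tests run on pools of 2–500 species; the end-to-end and benchmark
checks use the full 3000-species mixture (100 seeded simulations for the
recovery benchmark, ~7 s total). The law-of-large-numbers check of the
noise model uses 10,000 replicates of a one-protein matrix.

## Limitations

* No raw-spectra level effects: peptide sampling, co-isolation
  interference, missing values by abundance, FDR — the simulator produces
  complete, well-behaved matrices, so passing tests demonstrate the
  statistical machinery, not robustness to MS pathologies.
* Bands are unimodal Gaussians per pool; real profiles show asymmetric
  tails and smearing from detergent micelles and aggregation.
* The linear S→position map is extrapolated beyond the standards' range
  for very large complexes; species past the last fraction pile up there.
* No thermodynamics of complex formation: X+XY pool shares are specified,
  not derived from a Kd.
* Annotation tables are inputs; the package neither predicts topology nor
  queries organism databases.
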