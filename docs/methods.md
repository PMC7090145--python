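# Methods

This note documents the models, conventions and numerical choices behind
`phenokit`, and what the synthetic-data generators do and do not emulate.

## Leaf-area measurement

Leaf area is the pure pixel ratio `green_px / reference_px` (cm²), with the
1 cm² black reference square assumed coplanar with the foliage; no
perspective or lens correction is applied, so the ratio is independent of
camera distance and resolution by construction.

A *green* pixel satisfies `G ≥ 60`, `G − R ≥ 20` and `G − B ≥ 20` on 8-bit
channels; a *black* pixel has all channels ≤ 40.  These defaults are robust
on the renderer's palette and fully overridable (`ColorRule`).  The
reference square is the largest black 4-connected component; 4-connectivity
is deliberately conservative against diagonal noise bridges.  A square-ness
guard (bounding-box fill ratio ≥ 0.85) rejects shadows and thin strokes; it
can be overridden with `force`, which downgrades the rejection to a
warning.  Note the guard is a fill-ratio test, not an aspect test: an
axis-aligned solid bar would pass it, a diagonal stroke or shadow will not.

Specular/glittery pixels on real ice-plant leaves (epidermal bladder cells)
may fail the green rule; the measured area is then a slight underestimate.
This limitation is accepted: validation here is against rendered scenes
whose palette the rule captures exactly.

## Growth model

Total leaf area follows an exponential-minus-one form clocked from
germination, `τ = 21` days before treatment start:

    A(D) = a₁·(r₁^(D+τ) − 1)                          D ≤ D₀
    A(D) = a₁·(r₁^(D+τ) − 1) − a₂·(r₂^(D+δ) − 1)      D > D₀

with breakpoint `D₀ = 0` (treatment day).  The control branch is zero at
`D = −τ` and negative before it, so the fitting domain defaults to
`D ∈ [−21, 14]`.

The salt-term clock `δ` (`salt_term_offset`) is the one genuinely open
design choice.  With `δ = τ` the second term is ≈ a₂·(r₂²¹ − 1) already at
`D → 0⁺` — for realistic parameter values a jump of over a thousand cm²
that drives the curve strongly negative within days, contradicting the
positive areas the model is meant to describe.  The default is therefore
`δ = 0` (salt effect clocked from the treatment day), which makes the curve
continuous at the breakpoint and positive over the observed window; the
`δ = τ` variant is preserved as an explicit option and raises a domain
error where it predicts negative area.  Continuity at the breakpoint holds
only for `δ = 0`.

Fitting is vertical least squares ("minimum distance" read as vertical,
not orthogonal — documented and swappable at the residual function).
Because the model is linear in its amplitude given the rate, the amplitude
is profiled out analytically and the search reduces to one dimension: a
200-point geometric scan of `r − 1` over [5·10⁻⁴, 1], bounded Brent
refinement of the best five grid cells, then a Nelder–Mead polish of
`(log a, log(r−1))` from each candidate (ftol 10⁻¹⁶, up to 10 restarts).
On noiseless model-generated data this recovers parameters to far better
than the 10⁻³ relative error the tests assert.  All-zero data yields
`a₁ = 0` with the rate flagged unidentifiable rather than an arbitrary
estimate.

Group divergence is an integer-day scan (matching the daily photography
cadence): the first `D > D₀` with `control(D) − salt(D) > 5% · control(D)`.

## Diel gas-exchange analysis

Days are indexed from lights-on; **a night belongs to the day it begins
in** ("day 8's night" is the dark period after day 8's light period).
Traces are validated against sampling gaps larger than twice the median
interval.

CAM onset is the first day whose nightly mean assimilation reaches
−0.1 μmol m⁻² s⁻¹.  The threshold operationalises "nocturnal exchange
rising to almost zero": tolerant of *almost*, while a C₃ night near
−1 μmol m⁻² s⁻¹ stays well clear of it.  Raising the threshold can only
delay the detected onset (tested as a monotonicity property).

Dawn/dusk anticipation is assessed over 15-min windows either side of the
light edges (30 samples at 30-s logging).  Window extremes are taken on a
2.5-min rolling mean: at a noise SD of 0.3 μmol m⁻² s⁻¹ a single 30-s
sample crosses the −2 line by chance in roughly 1% of windows, whereas the
smoothed statistic essentially never does, and a genuine transient (which
lasts minutes) survives smoothing.  The "CAM-like" flag requires the dawn
transient to span from below −2 to above +2 μmol m⁻² s⁻¹.

Stomata are classed open at aperture ≥ 1.4 μm — the midpoint between the
observed closed-state ceiling (1.1 μm) and open-state floor (1.7 μm); the
open proportion is the plain count division.  Standard errors throughout
are sample SD/√n.  Inversion is the first day with 4 am mean aperture
above the 4 pm mean.

## Physiological indices

RWC defaults to the protocol's printed formula `100·(FW−DW)/(TW−FW)`, which
differs from the conventional `100·(FW−DW)/(TW−DW)`; the conventional form
is an explicit `formula="standard"` option and the choice is carried in
output metadata.  `DW > FW` inputs return a flagged negative value with a
warning rather than an exception — the inconsistency should be visible, not
fatal.

MDA is computed in the assay's native unit (μmol L⁻¹ = 6.45·OD₅₃₂ −
0.56·OD₄₅₀; negative values warned, never clipped) and converted to
nmol g⁻¹ fresh weight with all volumes explicit:
`conc × assay_volume[L] × (extract/aliquot) / tissue_mass × 1000`, default
protocol numbers 3 mL extract on 0.2 g tissue, 2 mL aliquot assayed in
4 mL.  Under these defaults 1 μmol L⁻¹ ≙ 30 nmol g⁻¹, so the chain is
linear in OD₅₃₂ with slope 193.5 nmol g⁻¹ per absorbance unit.  The
parameterisation makes any other volume bookkeeping expressible.

Index aggregation is replicate-wise: each index is computed per replicate
and then averaged (mean of indices, not index of mean inputs).  Rows
missing an index's ingredients have that index omitted and logged, never
NaN-filled.

## Group statistics

Per-day two-sided Student's t-tests, pooled variance by default (the
classical test) with Welch by flag.  Zero-variance degeneracies are
resolved by convention before delegation to the generic routine: identical
constant groups give (t = 0, p = 1), fully separated constant groups
(t = ±∞, p = 0).  Stars follow the strict convention `**` for p < 0.01,
`*` for 0.01 ≤ p < 0.05.  No multiple-testing correction is applied — the
per-day tests mirror the figure-annotation practice of the field — and the
output metadata says so.

## Synthetic-data generators

The generators define the study conditions; their defaults are the
documented experiment, not tuning knobs.

**Scenes.**  Non-overlapping elliptical green blobs on white, palette
green (0, 180, 0) with channel jitter ≤ 20 and black ≤ 10, so the default
segmentation rule is correct by construction while the thresholds are still
exercised.  Each blob is rasterised as the exactly-`n` pixels closest to
its centre in the ellipse metric, and the last blob absorbs the rounding
residue, so the total green count equals `round(Σ areas · px_per_cm²)`
exactly and measured-vs-truth discrepancies isolate the measurement side.

**Growth.**  Daily model evaluations plus i.i.d. Gaussian noise, floored at
zero (areas are physical).  Zero noise reproduces the model bit-exactly.

**Diel traces.**  30-s sampling, 12/12 photoperiod, 14 days.  Control
daytime rides a half-sine between 6.5 and 10.5 μmol m⁻² s⁻¹ — the paper
constrains only the 6.0–12.0 range, and a smooth hump is the weakest shape
consistent with it; nights sit at −1.0.  Gaussian noise SD 0.3 keeps the
daytime maximum below the 12.0 ceiling with ≈ 5σ margin over a full trace.
No variance was reported for any measured series; all noise levels here are
stated choices.  The salt transition is parameterised by
`onset_ramp_start_day = 6`, `night_zero_day = 8`,
`inversion_spikes_from_day = 9`: nightly means ramp linearly from −1.0
(day 5) to −0.05 (day 8) and +0.3 after; daytime amplitude decays to 5% of
control over the same window; from day 9 dawn/dusk transients of amplitude
2.5 are injected as quartic ramps with a 5-sample full-amplitude plateau at
the edge (the quartic keeps the whole-night mean shift below ≈ 0.02
μmol m⁻² s⁻¹, the plateau keeps the ±2 excursion visible to the smoothed
edge detector).  The constructed margins make the detected onset day equal
`night_zero_day` for essentially every seed: the detector's per-night mean
has SE ≈ 0.008 against a 0.27 separation between the day-7 and day-8
targets.

**Stomata.**  Apertures are drawn uniformly within the printed open
(1.7–3.0 μm) and closed (0.7–1.1 μm) ranges — no distribution was stated,
and uniform adds no unsupported structure.  At an open-phase timepoint a
stoma is open with probability 0.8; at the opposite timepoint with the
complementary 0.2 (only the open-phase fraction is constrained by the
source; the complement is this package's symmetric choice).  That puts
open-phase means near 2.1 μm and closed-phase means near 1.2 μm — an
≈ 11 SE separation at n = 150, so the inversion day is detected exactly.

**Physiology.**  Daily tables for both groups, 4 replicates per cell.
Target trajectories follow the reported series: succulence 0.12 → 0.16
g cm⁻² over days 0–5 (both groups), continuing to 0.18 by day 11 for salt;
RWC 62.5 → 80% linearly with a +5-point salt offset on days 4–11; MDA 1.15
nmol g⁻¹ control, stepping to 1.75 for salt from day 7.  Raw columns are
backed out of the targets: FW = succulence × area, DW = 0.4·FW (fixed
dry-matter fraction), TW from inverting the printed RWC formula, OD₅₃₂
from inverting the MDA chain at OD₄₅₀ ≈ 0.04.  Multiplicative replicate
noise (4% succulence, 1.5% RWC, 8% MDA) is sized so four-replicate t-tests
behave like the reported figures — the salt MDA step is significant from
about day 7, earlier days mostly are not.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: instrument drift and IRGA matching artifacts,
weather/chamber fluctuations, leaf overlap and perspective in photographs,
specular bladder-cell pixels, between-plant variance structure (noise is
i.i.d. within cells), temperature effects, and any transpiration or
conductance channel.  Detector thresholds validated here transfer to real
traces only to the extent those traces match the assumed noise scale.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed through
`numpy.random.default_rng`; fixed seed means byte-identical CSV/JSON
output, which the pipeline test asserts file-by-file.  Default problem
sizes — 14-day traces at 2880 samples/day, 150 stomata per timepoint, 36
fitted days, 25-run detector sweeps — run the whole suite in well under a
minute; they were chosen as the study's own dimensions rather than scaled
surrogates.
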