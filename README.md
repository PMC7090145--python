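# phenokit

Quantitative phenotyping of the salt-induced C₃→CAM photosynthetic
transition in the common ice plant, *Mesembryanthemum crystallinum*.

The ice plant is a facultative CAM species: under salt stress it switches
from ordinary C₃ photosynthesis (stomata open by day, Rubisco fixing CO₂ in
the light) to crassulacean acid metabolism (stomata open at night, PEPC
fixing CO₂ into malate, decarboxylated behind closed stomata the next day).
`phenokit` implements the full measurement-and-analysis workflow that pins
down *when* that switch happens, for researchers doing gas-exchange or
image-based phenotyping of facultative CAM plants:

* **Leaf area from images** — whole-plant leaf area as the pixel ratio
  `A = green_px / reference_px × 1 cm²` against a 1 cm² black reference
  square lying in the same plane as the foliage.
* **Growth modelling** — the piecewise exponential leaf-area model
  `A(D) = a₁(r₁^(D+τ) − 1)` for `D ≤ 0` and
  `A(D) = a₁(r₁^(D+τ) − 1) − a₂(r₂^(D+δ) − 1)` for `D > 0`
  (D = days after treatment, τ = 21-day germination offset), fitted by
  nonlinear least squares, plus an integer-day scan for the first day the
  two groups diverge.
* **Diel gas-exchange analysis** — per-day day/night summaries of a 30-s
  net-assimilation trace, CAM-onset detection (first night whose mean
  assimilation reaches −0.1 μmol m⁻² s⁻¹), and detection of the dawn/dusk
  anticipation transients (spanning below −2 to above +2 μmol m⁻² s⁻¹)
  characteristic of mature CAM.
* **Stomatal analysis** — per-(day, timepoint) aperture means ± SE, the open
  proportion (open = aperture ≥ 1.4 μm), and inversion detection (first day
  the 4 am mean aperture beats the 4 pm mean).
* **Physiological indices** — relative water content
  `RWC = 100·(FW−DW)/(TW−FW)` %, leaf succulence `FW/area` (g cm⁻²), and
  MDA (lipid peroxidation) via `6.45·OD₅₃₂ − 0.56·OD₄₅₀` μmol L⁻¹ with an
  explicit volume-bookkeeping conversion to nmol g⁻¹ fresh weight.
* **Group statistics** — per-day two-sided Student's t-tests (pooled or
  Welch) with the `*` (p < 0.05) / `**` (p < 0.01) annotation convention.
* **Synthetic data with ground truth** — seeded generators for every input
  (toy leaf scenes, growth tables, diel traces, stomata tables, physiology
  tables), each emitting its latent truth so detectors and estimators can
  be scored.

## Worked example

Detect the CAM transition window on the default synthetic study
(`examples/06_full_study.py`, or `phenokit run --seed 42 --out study_out`):

```python
from phenokit import run_study
report = run_study({"seed": 42}, out_dir="study_out")
```

prints (via the example script):

```
CAM onset (gas exchange)     : day 8
stomatal inversion           : day 7
transition window            : days 7-8 (2 days)
growth divergence (>5%)      : day 4
leaf-area max relative error : 0.00%
```

Nightly mean assimilation drifts from ≈ −1 μmol m⁻² s⁻¹ (C₃ dark
respiration) to ≥ −0.1 on day 8 — net nocturnal CO₂ fixation switching on —
while stomata first open wider at 4 am than at 4 pm on day 7.  The two
independent detectors bracket the C₃→CAM switch in a window of at most
3 days.  Growth divergence and the MDA/succulence/RWC statistics corroborate
the same period.  Every number in the report is traceable to a CSV/JSON
artifact written under `study_out/`, and re-running with the same config
reproduces the artifacts byte-for-byte.

The other scripts in `examples/` demonstrate each capability on its own:
image-based area measurement, growth-curve fitting, gas-exchange onset
detection, stomatal inversion, and physiology indices with per-day stars.

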