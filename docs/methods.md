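# Methods

## Scope and model

`flashqa` reconstructs what a pencil-beam-scanning (PBS) proton delivery
actually did — in 2D, at the isocenter plane — from the machine's
time-resolved delivery log, and runs the quality-assurance checks a FLASH
(ultra-high dose rate, UHDR) trial needs around that reconstruction. The
physical model is deliberately the one used clinically for transmission
fields: a 250 MeV beam traverses the target, so depth dependence is ignored
and each spot is a 2D Gaussian in the lateral (U horizontal, T vertical)
plane with mean µ, widths (σU, σT) and an integral dose proportional to the
monitor units (MU) delivered while the beam dwelt there.

### Delivery log

A log covers one field at 1 kHz from field load to beam-off: two cumulative
dose-monitor channels (MU), two raw Hall-probe readings (one per scanning
magnet), and timestamps quantized to 0.1 ms. Channels are cumulative rather
than incremental so monotonicity is a checkable invariant and pause
detection reduces to finding flat runs. The file dialect is plain text (one
JSON header line plus CSV) so fixtures are diffable; write→read is
lossless.

### Spot segmentation

Beam-on samples are those whose monitor increment exceeds half the median
positive increment — a threshold that separates beam-on from quantization
noise without configuration, because increments are bimodal (≈0 during dead
times, ≈intensity·Δt during beam-on). Maximal beam-on runs are spots:

* **MU** is the cumulative-monitor difference between the beam-off gaps
  bracketing the run. The monitors are flat inside gaps, so partial
  increments at run edges are captured exactly; noise-free recovery is at
  the 1e-9 relative level.
* **µ** is the increment-weighted mean of the Hall-derived positions over
  the run, so intensity ramps at spot edges do not bias the position.
* **σ** comes from the commissioning table at the log's gantry angle
  (nearest entry within 5°), optionally modulated by a bounded (±10%)
  per-position variation field.

Consecutive runs whose positions agree within 1 mm on both axes are one
physical spot interrupted by a pause; they merge into a single record,
flagged `contains_pause` when the internal gap exceeds the longest regular
dead time (11 ms row change + 2 samples = 13 ms).

### Calibration chain

Hall reading → magnet current → lateral position are two separate
piecewise-linear, strictly monotone curves, composed on demand and never
extrapolated (out-of-domain readings are data errors). The dose calibration
carries Gy·mm² per MU so that a spot's point dose is
MU·dose_cal·N(x; µ, diag(σU², σT²)) with N the unit-integral bivariate
normal density; this makes both point doses and field-integral conservation
well defined. UHDR monitor readings are multiplied by a single daily
recombination factor (≥1, fitted against a recombination-free reference
detector; a factor above 1.25 is outside the empirically observed ~20%
regime and warns).

### Dose, cumulative dose, dose rate

The delivered dose map is the plain Gaussian sum over all reconstructed
spots with no tail cutoff. Cumulative dose per voxel is available in two
accrual modes: `spot-termination` (each spot lands as one step at its
termination time stamp — mirroring the log-reconstruction method) and
`sample-resolved` (accrual proportional to per-sample monitor increments).
Both end exactly at the static map.

The PBS-average dose rate of voxel v uses the 5%–95% window of its own
cumulative curve: DR_v = 0.9·D_v/(t95 − t05). Two threshold modes exist:

* `sample-crossing` (default) takes the first event/sample time at or past
  the threshold. This reproduces the characteristic sharp voxel-to-voxel
  variation at field edges: a threshold can land just before or after a
  beam-off plateau, moving the window edge by a whole dead time.
* `interpolated` linearly interpolates the crossing inside the rising
  segment and is the numerically stable alternative (exact for piecewise-
  linear cumulative curves).

Voxels below 1% of the map maximum, or whose window collapses to zero
width (single-step accrual), are flagged invalid instead of being given
meaningless or infinite rates.

### Planning-side (TPS) model

The simplified planning model places equally weighted spots on a
rectangular grid, uses one mean σ per gantry angle, constant intensity
(MU/s), constant dead times (4 ms per U step, 11 ms per T row change,
boustrophedon raster with U fast), and truncates each Gaussian at an
elliptical 4σ radius (integral deficit exp(−8) ≈ 0.034%). Its cumulative
dose is piecewise linear — dose accrues uniformly while a spot's beam is
on — which is why its dose-rate maps are smooth where the log-side
`sample-crossing` maps are jagged. The dose-averaged dose rate is
DADR_v = Σ_i d_iv²/τ_i / Σ_i d_iv with τ_i the spot's beam-on duration; it
depends only on beam-on durations, so pauses and dead times leave it
unchanged while the PBS-average rate drops — a useful definitional
contrast exercised in the tests.

### QA decision logic

PSQA checks a field against the plan: laser alignment (recorded, not
computed), a five-spot pattern (independent 2D Gaussian fits; ±2 mm
position, ±10% size; the suggested global correction is the negated mean
offset and is applied as a rigid translation when above 0.2 mm), central
dose (±5%, else the field is scaled by 1/ratio), then mean deviation in
the 90% isodose area (>3% triggers a boosting factor; the repeated,
boosted delivery is what the spatial comparison judges) and a global-
normalization gamma analysis at 3%/3 mm restricted to the 90% isodose
mask (search capped at 3×DTA, test map interpolated at 1/10 voxel). DQA is
the identical pipeline with the PSQA-day measurement as reference, plus
the daily UHDR recombination correction and a log scan whose interruptions
carry an exclusion recommendation (an interlock during a UHDR treatment
excludes the patient from that arm). UHDR fields must additionally keep
measured local dose rates strictly above 40 Gy/s.

Status aggregation: a failed laser, five-spot or dose-rate floor check is
`fail`; a gamma pass fraction ≤ 90% after corrections is
`clinical-review`; otherwise `pass-with-correction` if any correction was
applied, else `pass`.

### Blinding

Only the beam current differs between the CONV and UHDR arms, so the
delivery report omits — by construction, not by hiding — everything that
reveals dose rate, beam current or the arm label until unblinding: the
blinded report contains only part 1 (metadata, 2D dose metrics,
prescription check, sanitized QA outcomes); dose-rate maps, irradiation
times, point dose rates and raw QA live in parts 2–3 of the unblinded
report. A leak-scan test checks 50 randomized report pairs.

## Synthetic deliveries

The simulator realizes exactly the timing model above (constant intensity,
4/11 ms dead times, boustrophedon raster) plus optional per-sample Gaussian
noise on the Hall channels (sensor units) and on monitor increments
(truncated at zero so cumulative channels stay monotone), optional Hall
quantization, and pause injection that keeps total MU invariant. Monitor
counts are recorded as recombination-corrected MU; the arm label is
delivery metadata. During a dead time the magnets ramp linearly, starting
at the first sample tick at or after beam-off and settling exactly at the
next beam-on — so every sample that carries dose also carries the exact
spot position, which is what makes noise-free parameter recovery exact and
testable.

What it does **not** emulate: intensity fluctuation within a spot, magnet
hysteresis or overshoot, beam-size variation over time, monitor
nonlinearity, or any depth dimension. Passing tests therefore demonstrate
the correctness of the reconstruction and QA logic under the stated
delivery model, not robustness to machine pathologies outside it.

## Study conditions and problem sizes

The validation studies use UHDR-scale conditions: 100 MU per spot at
10⁴ MU/s (10 ms beam-on per spot), 2.5 mm spot spacing, σ = 3 mm, a linear
Hall chain spanning ±200 mm, dose calibration 0.7 Gy·mm²/MU (≈11 Gy per
fraction over a 2.5 mm grid), Hall noise of 0.2 mm-equivalent per sample
and monitor noise of 0.1% per spot. The accuracy study simulates 20 random
rectangular fields of 5–50 spots (case seeds 1–20 in the canonical run) and
measures, at the voxel nearest the spot-grid centroid, the reconstructed
vs true dose and the log-derived vs planning-model PBS-average dose rate.
The gamma study delivers a 20×20-spot field with in-tolerance residual
perturbations (1 mm offset, 2% dose scale, 8% σ drift) on a 1 mm grid.
Grids carry 12 mm (4σ) margins. These sizes keep the whole suite and the
acceptance script in the seconds-to-minutes range on one CPU.

A caveat the studies surface deliberately: for near-one-dimensional spot
strips the reference voxel's 95% threshold can sit at a row-change plateau,
where sensor noise can move the crossing by a full 11 ms dead time; the
PBS-average rate difference is then heavy-tailed across seeds even though
the noise-free agreement is exact.

## Numerical choices

* Crossing-time searches are vectorized per voxel chunk (2048 voxels) on
  the shared event-time grid; both threshold modes use the same machinery.
* Gamma offsets are visited in increasing distance with per-voxel early
  termination (a voxel is done once its current γ² is below the purely
  geometric term), which keeps the exhaustive search fast without
  approximation; a brute-force oracle in the tests checks equivalence.
* The 2D Gaussian spot fit is a bounded least-squares fit (amplitude,
  center, widths, constant background) initialized from image moments,
  capped at 200 function evaluations; flat images and border peaks are
  rejected before fitting.
* Degenerate dose-rate voxels are flagged with a reason
  (`dose-floor` / `degenerate`) rather than raising or returning infinities.
* Pause injection quantizes the pause to the 1 kHz grid so timestamps stay
  on-grid and totals stay exact.

## Known limitations

* 2D only: no CT-based recalculation, DVH/V95/D98 metrics, or 3D gamma.
* The dose-averaged rate uses per-spot beam-on duration as the
  instantaneous-rate denominator; other published variants differ.
* The five-spot nominal pattern (center + 4 points at ±40 mm) and the
  0.2 mm offset-application threshold are conventions of this toolkit.
* Whether the mean 90%-isodose deviation is compared signed or absolute
  against the 3% boosting threshold is configurable in principle; the
  implemented contract compares |signed mean|.
* The monitor-consistency check (|mon1 − mon2| > 1% warns) is a
  convention; the two channels are modeled as independent but identically
  calibrated.
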