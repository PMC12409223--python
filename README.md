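# flashqa

Quality-assurance and reporting toolkit for ultra-high dose rate (FLASH)
proton therapy delivered with pencil beam scanning (PBS).

FLASH trials deliver transmission proton fields at dose rates of tens of
Gy/s, where the delivered dose rate — not just the dose — is a clinical
quantity, yet it can only be known after the fact from the machine's own
delivery record. This package is for medical physicists who need to:

* **reconstruct** the delivered 2D dose and PBS-average dose-rate maps from
  time-resolved (1 kHz) machine delivery logs: cumulative dose-monitor
  counts, scanning-magnet Hall-probe readings, 0.1 ms timestamps;
* **check** each field with the trial's patient-specific and daily QA
  procedures: five-spot position/size fits (±2 mm / ±10%), central dose
  (±5%, else scaled), mean 90%-isodose deviation (>3% → boosting factor),
  3%/3 mm gamma analysis (pass: >90% of voxels in the 90% isodose at
  γ ≤ 1), and the UHDR local dose-rate floor (strictly above 40 Gy/s);
* **report** deliveries under a blinded design in which dose rate, beam
  current and the arm label may not be disclosed before unblinding;
* **simulate** PBS deliveries (constant intensity, 4 ms/11 ms spot-change
  dead times, sensor noise, beam pauses) so the entire chain is testable
  without machine data.

## The model in brief

Each spot is a 2D Gaussian at the isocenter plane; the delivered dose map is

D(x) = Σᵢ MUᵢ · c · N(x; µᵢ, diag(σ²_U,i, σ²_T,i)),

with MUᵢ the monitor units of spot i (from the cumulative monitor channel),
µᵢ from the Hall readings through the calibrated Hall→current→position
chain, σ from commissioning data, and c the dose-area calibration
(Gy·mm²/MU, times a daily recombination factor for UHDR fields). Tracking
each voxel's cumulative dose over time gives the PBS-average
(Folkerts-style) dose rate from the 5%–95% window,

DR_v = 0.9 · D_v / (t₉₅ − t₀₅),

computed either at sample/event resolution (reproducing the documented
sharp edge-voxel artifact) or with interpolated crossings. A simplified
planning-side model (rectangular equal-weight spot grid, one σ per gantry
angle, constant intensity, 4σ Gaussian cutoff, piecewise-linear cumulative
dose) provides the reference maps plus a dose-averaged dose-rate metric.
See `docs/methods.md` for the full account.

## Worked example

Simulate a 10×10-spot, 2.5 mm-spaced UHDR field (100 MU/spot at 10⁴ MU/s),
reconstruct it from its own log, and run QA against the plan:

```sh
$ flashqa simulate --plan plan.json --model model.json --seed 7 \
      --out log.csv
wrote log.csv (1470 samples, 10000.000 MU)

$ flashqa reconstruct --log log.csv --model model.json --out dose.csv
wrote dose.csv (max 11.1996 Gy, 100 spots)

$ flashqa tpsdose --plan plan.json --out tps.csv
wrote tps.csv (max 11.1968 Gy)

$ flashqa gamma --ref tps.csv --test dose.csv
gamma pass fraction: 100.00% (mean deviation +0.02%)

$ flashqa psqa --plan plan.json --log log.csv --model model.json \
      --out decision.json
PSQA status: pass
```

Reading the numbers: the 10 000 MU in the log are the plan's 100 spots ×
100 MU, conserved exactly by the simulator; the reconstructed and
planning-side maps peak near 11.2 Gy (the trial's 11 Gy fraction dose on
this grid); their gamma comparison passes everywhere and the mean dose
deviation in the 90% isodose area is +0.02%, so the PSQA decision is
`pass` with no corrections. `flashqa doserate` produces the PBS-average
dose-rate map of the same log (`--mode interpolated` for the stable
variant), and `flashqa report --blinded` emits the shareable part of the
delivery report with all dose-rate, current and arm information omitted by
construction. Plan and beam-model JSON files can be written with
`flashqa.write_plan` / `flashqa.write_beam_model`.

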