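# perwave

Analysis of PER2::LUC bioluminescence rhythms from suprachiasmatic nucleus
(SCN) explants under optogenetic stimulation — phase resetting, period
after-effects, waveform (rising/falling phase) metrics, entrainment to
T-cycles and skeleton photoperiods, and spatial phase/period/cluster mapping
of time-lapse imaging stacks.

## Who this is for

Chronobiologists recording luciferase reporter rhythms (e.g. with a
LumiCycle-style luminometer at 6-min sampling, or an imaging system at
10-min frames) who stimulate explants ex vivo and need the standard
quantifications:

* **Phase shift** `Δφ = t̂_peak − t_peak`: the difference between the first
  post-stimulus peak predicted by a linear regression of ≥ 3 pre-stimulus
  peak times and the observed one. Advance positive, delay negative.
* **Period** `τ` by regression of peak times on cycle index, regression of
  rising half-max times (when peaks are not obvious), or the Lomb–Scargle
  periodogram on a dense 16–32 h grid; **period change** `Δτ = τ_post −
  τ_pre` (lengthening positive).
* **Envelope normalization**: the damped rhythm is mapped into [0, 1]
  between geometric peak/trough envelopes extrapolated from the pre-stimulus
  cycles at the fitted damping rate `d` (peak_k ∝ d^k).
* **Normalized induction**: max − min of (normalized stimulated −
  normalized unstimulated) over the first post-stimulus cycle, in envelope
  amplitude units (AU) — the acute PER2 induction caused by the pulse.
* **Rising/falling durations** from the zero crossings of the smoothed
  first derivative, with the stimulated cycle expressed as a fold change
  (FC) over the mean pre-stimulus cycle.
* **Entrainment**: phase angle of entrainment (dusk pulse onset − rising
  half-max), its per-cycle drift, the entrained period, period
  after-effects, and classification of skeleton-photoperiod runs as
  entrained / phase-jumped / free-running.
* **Spatial maps**: grouped minimum-intensity denoising, 15 × 15-px ROI
  tiling, per-ROI phase/period/shift/period-change maps, circular variance
  (1 − mean resultant length), and the two-stage Ward clustering that
  delineates functional SCN subregions across slices.

Because raw recordings of this kind are rarely archived, the package ships
a ground-truthed synthetic generator (`perwave.synth`): damped sinusoidal
reporter rhythms built on a monotone phase function, so programmed phase
shifts, segment warps, period changes, induction transients and spatial
regional structure are *exact* and every pipeline stage can be verified
end to end.

## Worked example

```bash
perwave simulate --preset PS-CT14 --noise 0 --seed 1 --out sim/
perwave analyze pulse --trace sim/stimulated.csv \
    --reference sim/reference.csv --schedule sim/schedule.json --out res/
```

prints (abridged):

```json
{
  "shift_hr": -4.245185948688388,
  "predicted_peak_hr": 107.96844811033559,
  "observed_peak_hr": 112.21363405902397,
  "pre_period_hr": 23.99994902270597,
  "n_pre_peaks": 3,
  "damping_per_cycle": 0.957358197819071,
  "period_change_peak_regression_hr": 0.0011169633781484833,
  ...
}
```

The `PS-CT14` preset programs a 4.25 h phase delay from a pulse at CT14
(2 h after the PER2::LUC peak, which defines CT12). The estimator predicts
the next peak at ~108.0 h from the pre-stimulus regression, observes it at
~112.2 h, and reports `shift_hr ≈ −4.25` — a delay, recovered to within one
6-min sample. The unperturbed preset damps at 0.95/cycle and free-runs at
24.0 h, as the `pre_period_hr` and `damping_per_cycle` fields confirm.

Other presets cover the full design space: `WF-CT14`/`WF-CT21` (falling
1.31 FC / rising 0.72 FC waveform warps), `IND-CT14` (0.70 AU induction),
`AE-CT14-PR`/`AE-CT21-LS` (+0.91 / −1.98 h period after-effects),
`T22`/`T25` (one-pulse entrainment), `SK-8-16`/`SK-16-8`/`SK-16-8-JUMP`
(skeleton photoperiods, including a programmed phase jump), and
`SPATIAL-CT14` (a five-slice imaging cohort with three planted SCN
subregions). As a library:

```python
import perwave as pw
exp = pw.make_experiment("T22")
res = pw.analyze_entrainment(exp.stimulated, exp.schedule)
# res["entrained_period_hr"] -> 22.0, res["rising_fc_mean"] -> 0.79
```

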