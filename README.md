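# earval — validation toolkit for ear-level EEG sensors

Ear-EEG devices record brain activity from electrodes in and around the
ear canal and concha. Validating such a device means answering two
questions without ambiguity: *does the hardware chain work* (electrode
contact, noise floor, timing), and *does it pick up the neural responses
it should*? `earval` is an offline analysis engine plus synthetic-data
generator for exactly that workflow. It covers:

* **Nine EEG paradigm analyses** on recorded sessions with synchronized
  marker streams: resting state, alpha blocking, 40 Hz auditory
  steady-state response (ASSR), 10 Hz steady-state visual evoked
  potential (SSVEP), transient auditory/visual evoked potentials
  (AEP/VEP with P1/N1/P2 components), auditory and visual oddballs
  (mismatch negativity, P300) and electro-oculography (blinks,
  saccades).
* **Phantom bench metrics** for a conductive ear phantom: mixture
  recipes for the filling materials, conductivity from strip
  measurements, electrode-impedance QC classes, noise-floor RMS,
  SNR of a played-back signal and day-over-day integrity trends.
* **A trigger-latency estimator** that measures the delay and jitter
  between software markers and the physical stimulus on a bench trace.
* **A seeded session generator** that emulates the full test battery
  (500 Hz, 12-channel scalp + 2×8 in-ear montage, realistic trial
  counts and inter-stimulus intervals) with known ground truth, so the
  entire chain is testable without subjects or hardware.

## The statistics at the core

Steady-state responses are quantified as a narrowband SNR

    SNR(f0) = P(f0) / mean{ P(f) : f in band, |f − f0| > guard }

with `P` the Welch power spectral density (8 s Hann windows, 50%
overlap), `band` = 35–45 Hz for the 40 Hz ASSR and 5–15 Hz for the
10 Hz SSVEP, and a one-bin mainlobe guard around `f0`; significance is
a one-way ANOVA of per-segment power at the `f0` bin against the
neighbor-bin powers. Alpha blocking is the eyes-closed over eyes-open
power ratio in 8–12 Hz, `R_AM = P_closed / P_open`, in dB from a 2 s
STFT. Transient responses are band-limited (1–20 Hz), epoched with
latency correction, baseline-corrected on the 100 ms pre-stimulus
interval and averaged, with per-timepoint one-sample t-tests
(uncorrected) marking significant deflections; oddball difference
waves subtract the average of the standards that immediately precede a
deviant from the deviant average. Phantom mixture masses solve the
weight-fraction system (4% agar/0.5% salt: `A = 8w/191`, `s = w/191`;
15% gelatin/8% salt: `BG = 15w/77`, `s = 8w/77`; carbon fiber:
`CF = S·X/(100−X)`), and conductivity follows `σ = L/(R·A)`.

## Worked example

Generate a synthetic ASSR session and analyze it, referenced to Cz:

```
$ earval simulate --paradigm assr --seed 7 --out fixtures/
wrote fixtures/assr.xdf (250 s, 28 channels, 2 markers)

$ earval analyze assr fixtures/assr.xdf --reference Cz --channel P4 --channel ER8
paradigm channel reference metric     value            p
    assr      P4        Cz snr_db  4.980440 3.407155e-53
    assr     ER8        Cz snr_db -0.473224 4.177208e-01
```

The generator injected a 1 µV 40 Hz response with a centro-parietal
topography into 10 µVrms pink-noise EEG: at P4 the response stands
~5 dB above the neighboring 35–45 Hz bins and the ANOVA peak test is
decisive, while at the ear electrode ER8 (where the injected effect is
strongly attenuated) the SNR is indistinguishable from noise — the
pattern the toolkit is designed to expose when a given electrode or
reference cannot see a paradigm. Bench utilities print equally direct
numbers:

```
$ earval latency fixtures/latency.xdf
mean delay 21.02 ms, jitter 2.92 ms (1000 events, 0 missed)

$ earval phantom mixture agar 700
agar: 30 g
salt: 4 g

$ earval phantom conductivity 5000
conductivity 0.300 S/m (resistivity 3.333 Ohm m)
```

(The latency fixture injected Normal(21 ms, 2.8 ms) delays; the
estimator recovers them from the pulse trace alone. A 700 g water
phantom needs 30 g agar and 4 g salt for the 4%/0.5% weight
fractions.) `earval compare-refs` re-runs an analysis under several
re-referencing schemes and ranks them — the procedure for picking the
best in-ear reference electrode from phantom playback data.

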