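# wristrf

Radiofrequency wrist-transmission screening for osteopenia and osteoporosis.

A pair of patch antennas pressed against the wrist measures the complex
transmission coefficient S21(f) — magnitude and phase of the signal that
made it through skin, soft tissue and, crucially, bone — at 201 frequency
points from 300 kHz to 2 GHz. Bone loss changes the dielectric path, so the
spectrum carries diagnostic signal. `wristrf` implements the complete
analysis chain that turns such bilateral spectra into a screening decision:

1. **Cohort model** — typed records for subjects (age, BMI, wrist
   circumferences, group label) and their four spectra (S21/S11 × left/
   right), with lossless round-trip I/O as a packed CSV or a directory of
   Touchstone `.s2p` files.
2. **Feature assembly** — a spectrum becomes a feature vector via one of
   four encodings (magnitude, phase, magnitude+phase, real+imaginary); the
   two arms are averaged, concatenated, or kept separate; the wrist
   circumference(s) can be appended; and the complex spectrum can be
   normalized by the risk-factor ratio

   S21_N(f) = (Age / BMI) · S21(f).

   Vector lengths run from 201 (one magnitude spectrum) to 806 (both
   complex arm spectra plus both circumferences).
3. **Classifier** — a two-layer perceptron:
   input → dropout(0.5) → dense(N_in → N_hidden) → ReLU → dropout(0.5) →
   dense(N_hidden → 2) → softmax, with N_hidden = nint(N_in / 10),
   Glorot-uniform weights, zero biases, L2 penalty on weights only, trained
   full-batch for 1000 epochs.
4. **Evaluation** — stratified 7-subset cross-validation over *subjects*
   (both arms of a subject always share a fold). When arms are classified
   separately, the two predictions are fused into one diagnosis per
   subject: agreement wins; a conflict resolves to keep-left, keep-right,
   keep-osteo (flag as diseased) or keep-healthy. Reported metrics are
   fold means of sensitivity, specificity, accuracy and Youden's
   J = sensitivity + specificity − 1, with the diseased group as positive.

A synthetic-cohort generator reproduces the statistical structure of the
study data — 27 osteopenic/osteoporotic subjects (ages 55–90, mean 77.5)
vs. 40 healthy (ages 23–94, mean 60.2), bilateral multi-resonance spectra
with a controllable group effect — so the whole chain is testable without
any download.

## Worked example

```python
import wristrf as w

config = w.PipelineConfig(seed=1)  # simulate 27+40 subjects, complex/separate/+circumference
payload = w.run_pipeline(config, out_path="results.json")
for scheme, block in payload["results"]["schemes"].items():
    m = block["mean"]
    print(f"{scheme:12s} sens={m['sensitivity']:.3f} spec={m['specificity']:.3f} "
          f"acc={m['accuracy']:.3f} J={m['youden_j']:.3f}")
```

prints

```
separate     sens=0.982 spec=1.000 acc=0.993 J=0.982
keep_left    sens=0.964 spec=1.000 acc=0.986 J=0.964
keep_right   sens=1.000 spec=1.000 acc=1.000 J=1.000
keep_osteo   sens=1.000 spec=1.000 acc=1.000 J=1.000
keep_healthy sens=0.964 spec=1.000 acc=0.986 J=0.964
```

`separate` scores each of the 134 arms as its own pseudo-subject; the other
rows fuse the two per-arm predictions back into 67 subject-level diagnoses.
Here one diseased subject had one misclassified arm: resolving conflicts
toward the diseased class (`keep_osteo`) recovers it, while `keep_healthy`
keeps the miss — the expected sensitivity/specificity trade of the fusion
rule. At this default (moderate) synthetic effect size the task is nearly
saturated; lower `effect_amplitude` or raise `noise_sd` in
`SimulationParams` to make it harder.

The same pipeline is available from the shell:

```sh
wristrf simulate --seed 1 --out cohort.csv
wristrf run-cv --cohort cohort.csv --k 7 --seed 1 --out results.json
wristrf report --results results.json --plot metrics.svg
wristrf pipeline --seed 1 --out results.json
```

To analyse measured data instead of simulations, point `run-cv` (or
`cohort_path` in the pipeline YAML) at a packed CSV or a Touchstone
directory with demographic sidecars; see `wristrf.cohort` for both layouts.

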