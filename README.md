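# septfc

Time-frequency component analysis of somatosensory evoked potentials (SEPs)
for locating a compressive cervical spinal-cord injury.

An SEP is the stimulus-locked average of a few hundred cortical responses to
peripheral-nerve stimulation. Conventional monitoring reads only the latency
and amplitude of its main peak — enough to say *whether* the ascending
pathway is compromised, not *where*. This package implements an analysis
chain in which the smaller constituents of the waveform carry the location
information:

1. **Matching pursuit.** The averaged trace x(t) is greedily decomposed over
   a dictionary of unit-norm Gabor atoms
   g(t) = K·exp(−π((t−u)/s)²)·cos(2πf(t−u)+φ), each step selecting the atom
   with maximal projection energy onto the residual (phase optimal in closed
   form, parameters polished continuously within one grid cell). Every atom
   becomes a time-frequency component (TFC) with latency u (ms), frequency f
   (Hz), power a² (µV²) and relative energy a²/‖x‖².
2. **Categorization.** Per recording: the largest TFC is the *high-energy*
   component; remaining TFCs above 2% relative energy are *middle-energy*,
   the rest *low-energy*.
3. **Distribution regions.** Cohort TFC clouds are summarized by a
   product-Gaussian KDE over the time-frequency plane; local density peaks
   above 80% of the maximum mark the important regions, reported with their
   rectangle, peak, mean ± SD and per-subject occurrence rate.
4. **Cascade classification.** Three RBF-SVM stages: I — normal vs injured
   on the high component's (latency, frequency, power); II — C5 vs pooled
   C4/C6 by majority vote over middle-energy TFC points; III — C4 vs C6 by
   majority vote over low-energy TFC points. Hyperparameters come from an
   exhaustive log₂ grid search (C ∈ 2⁻²…2²⁰, γ ∈ 2⁻¹⁴…2¹⁰) inside each
   training fold; performance is 10 × 10-fold cross-validation over the
   72-recording study (36 normal, 12 per injury level).

No public SEP data set matches this design, so the package ships a calibrated
synthetic-SEP generator (`septfc.simulate`): per-condition Gabor components
with the reported cohort moments and occurrence rates, plus 200-sweep
averaged noise. Every stage of the chain is tested against it, and
`docs/methods.md` states precisely which reported quantities the synthetic
study reproduces and which it provably cannot.

## Worked example

```python
from septfc import StudyDesign, generate_study, mp_decompose, categorize

recordings = generate_study(StudyDesign(seed=42))
rec = next(r for r in recordings if r.subject_id == "C5-04")
pairs = mp_decompose(rec)
for atom, tfc in pairs:
    print(f"rank {tfc.rank}: t={tfc.time_ms:6.2f} ms  f={tfc.frequency_hz:6.2f} Hz "
          f"power={tfc.power:7.3f} µV²  rel={tfc.relative_energy:.4f}")
```

```
rank 1: t= 20.03 ms  f= 44.57 Hz power= 26.489 µV²  rel=0.9537
rank 2: t= 25.37 ms  f=106.77 Hz power=  1.252 µV²  rel=0.0451
```

The rank-1 component is the recording's high-energy TFC: a ~45 Hz wave at
20 ms latency carrying 95% of the signal energy — the main cortical response,
with the reduced frequency and power typical of the injured state. The rank-2
component (4.5% > 2% ⇒ middle-energy) sits near 25 ms / 107 Hz, inside the
C5 group's first middle-energy region — exactly the evidence stage II of the
cascade votes on:

```python
cat = categorize([t for _, t in pairs], subject_id=rec.subject_id,
                 condition=rec.condition)
print(len(cat.middle), len(cat.low))   # -> 1 0
```

The same chain is scriptable from the shell:

```bash
septfc generate --seed 42 --out study/       # 84 text recordings + manifest
septfc decompose study/ --out tfcs.csv
septfc categorize tfcs.csv --out cats.csv
septfc density cats.csv --category middle --conditions C4,C6 --out pdf.csv
septfc run --seed 42 --out results/          # full pipeline incl. 10x10 CV
```

`septfc run` prints the cross-validated accuracies of the full cascade and of
each stage, and writes per-recording predictions, the 4×4 confusion matrix,
region-summary tables and a JSON summary (all artifacts embed the
configuration hash).

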