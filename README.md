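# topomech

Single-molecule mechanics of type IIA topoisomerases: a worm-like-chain
(WLC) Monte Carlo simulator for DNA-looping probabilities, plus the
analysis pipelines for the three assays used to dissect how the poison
etoposide perturbs topoisomerase II — optical-trap DNA stretching,
mechanical DNA unzipping through a bound protein, and magnetic-tweezers
supercoil relaxation.  Seeded synthetic-trace generators emulate each
instrument's data, so every stage of the pipeline is testable end to end
without instrument files.

It is intended for single-molecule biophysicists who want to reanalyse
force spectroscopy traces of protein–DNA interactions with the exact
conventions of this assay family, or to predict loop-size distributions
from looping thermodynamics.

## The models at the core

**Looping J-factor.**  DNA is discretized as a chain of rigid segments
(5 bp each) with joint bending energy g(1 − cos θ), g = Lp/b in units of
kT (Lp = 45 nm).  A protein-imposed kink is a fixed tangent deflection α
at one vertex.  Pivot-move Metropolis Monte Carlo with a harmonic
umbrella bias U = ½k(r − r₀)² on the end-to-end distance r, combined
across windows with WHAM, yields the unbiased radial density P⁰(r); the
Jacobson–Stockmayer looping propensity at the 2 nm capture distance is

    J(r) = P⁰(r) / (4πr²),

converted to nanomolar with the Avogadro constant.  The bias stiffness
follows the schedule k(L, α) = (1.682/25)·exp(−0.008664 L)·(55 − 0.2 α)
pN·nm/bp².

**Trace reduction.**  Stretching traces are converted to contour length
through the modified Marko–Siggia relation F = (kT/Lp)[1/(4(1−l)²) − ¼ + l],
l = x/L₀ − F/K, with 0.338 nm/bp; unzipping traces to base pairs
unzipped through a two-arm dsDNA + extensible-FJC ssDNA model; twisting
traces to turns relaxed through a piecewise "hat-curve" calibration.
Rupture peaks are selected between 1 and 60 pN; pauses are found by
dwell-time analysis in 0.2-turn bins with a >2 s/bin criterion; tether
survival under constant force is fitted with a double exponential to get
the half-life t₁/₂.

## Worked example

Simulate a stretching trace in which a topoisomerase traps a 300 bp DNA
loop that ruptures at 28 pN, then recover both numbers from the trace
alone:

```python
from topomech import synthetic_data as sd, stretch_analysis as sa

scenario = sd.StretchScenario(loops=[(300.0, 28.0)], seed=3)
trace, truth = sd.gen_stretch_trace(scenario)

filt = sa.decimate_and_filter(trace)          # 1 kHz, 25 ms window
events = [sa.loop_size_of_event(filt, e) for e in sa.detect_ruptures(filt)]
for e in events:
    print(f"rupture at {e.peak_force:.1f} pN, loop {e.released_bp:.0f} bp")
```

prints

```
rupture at 27.8 pN, loop 299 bp
```

i.e. the detected force peak sits within the 25 ms filter's smearing of
the programmed 28 pN rupture, and the contour-length jump across the
peak recovers (to a base pair) the 300 bp of DNA released from the loop.

The looping simulator is driven the same way:

```python
from topomech import loop_mc as lm

settings = lm.McSettings(n_equil=20_000, n_prod=60_000, seed=42)
for p in lm.j_factor_curve([75.0, 150.0, 300.0], 150.0, settings):
    print(f"L = {p.loop_length_bp:4.0f} bp   J = {p.j_at_capture:10.0f} nM")
```

```
L =   75 bp   J =    1003111 nM
L =  150 bp   J =     209981 nM
L =  300 bp   J =      15700 nM
```

showing how strongly a sharp 150° bend concentrates one DNA end near
the other for short loops (an unbent 75 bp loop has J ≈ 0 at sampling
precision).

A command-line surface wraps the same stages:

```sh
topomech gen-stretch --seed 3 --out run/
topomech analyze-stretch --out run/results run/trace.tsv
topomech simulate-loop-j --lengths 50,100,200 --bend-angle 150 --seed 1 --out j.tsv
```

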