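# Methods

This note documents the models, numerical choices and known limits of
`topomech`.  The package couples a DNA-looping Monte Carlo simulator to
three trace-analysis pipelines (stretching, unzipping, twisting) and to
seeded generators that produce statistically realistic synthetic traces
for closed-loop testing.

## Polymer elasticity

dsDNA under tension follows the modified Marko–Siggia worm-like chain,

    F = (kT/Lp) [ 1/(4(1−l)²) − 1/4 + l ],   l = x/L₀ − F/K,

with persistence length Lp = 45 nm, helical rise 0.338 nm/bp, thermal
energy at 23 °C (kT ≈ 4.089 pN·nm) and enthalpic stretch modulus
K = 1,200 pN by default (typical of dsDNA in similar buffers; the assays
do not pin it down, and it is configurable).  Two published "modified"
variants exist that differ in where the enthalpic term enters; we use
the form in which l = x/L₀ − F/K appears throughout, which reduces to
the inextensible Marko–Siggia formula as K → ∞ (verified to <0.5% in the
tests).  Both the force solve F(x/L₀) and the inversions (contour length
from a force/extension point; bp unzipped from a force/extension point)
are bracketing root solves of the same relation, so forward and inverse
round-trip by construction.  Contour-length inversion below 0.25 pN is
flagged unreliable: dl/dF diverges at low force while the compaction
metric of interest is read at 0.5 pN, comfortably above.

ssDNA is an extensible freely-jointed chain with Kuhn length 1.5 nm,
contour 0.59 nm per nucleotide and stretch modulus 800 pN — standard
literature-scale values; the released-nucleotide free energy uses the
closed-form FJC integral plus an hF²/2K enthalpic term (the neglected
Langevin–enthalpic cross term is sub-percent below 25 pN).

The equilibrium unzipping baseline balances, at each fork position, the
nearest-neighbour opening free energy of that base pair against the work
of extending two released nucleotides at fixed force.  Nearest-neighbour
ΔH/ΔS values are the unified 1 M NaCl set with the per-stack entropy
salt correction 0.368·ln[Na⁺]eq cal/(mol·K), [Na⁺]eq = [monovalent] +
3.3·√[Mg²⁺]; the assay buffer (~100 mM monovalent, 3 mM Mg²⁺) gives a
mean baseline of ≈15.7 pN for a random 50% GC sequence, consistent with
the ~15 pN naked-DNA baseline the assays report.  Only the 10 distinct
stack energies occur, so the solver caches one root per distinct value.

## Looping Monte Carlo

The chain is discretized at 5 bp per rigid segment (b = 1.69 nm),
joint stiffness g = Lp/b in kT — fine enough to resolve ~100 bp loops
while keeping desk-scale runs cheap.  A protein-imposed bend is a rigid
tangent deflection of α degrees at the middle vertex; α = 150° means the
tangent deviates 150° from collinear (a near-hairpin kink).  The
opposite convention (included angle 150°, i.e. a 30° deflection) is
defensible from the phrase "a 150° bend" alone; we document the choice
prominently because the two give qualitatively different J(L) curves
(see Limitations).

Moves are pivot rotations of the tail subchain about a random axis
through a random internal non-bend vertex, with rotation angle uniform
in ±50°; the proposal is symmetric and preserves segment lengths and the
bend angle exactly.  Acceptance is Metropolis on bending energy plus the
umbrella bias ½k(r − r₀)².  The bias coordinate r is interpreted in
bp-equivalent units (r_nm/0.338), consistent with the stiffness
schedule's pN·nm/bp² units; a config switch selects the nm
interpretation instead.  Energy is tracked incrementally (only the pivot
joint's angle changes per move) and re-derived from scratch every 10⁴
steps; the maximum drift is reported and must stay below 10⁻⁶ kT.

Window schedule: because the printed stiffness schedule varies by orders
of magnitude across 50–600 bp, a fixed window count either gaps (stiff
bias) or wastes windows (soft bias).  We therefore run one unbiased
window first — it samples the natural part of P⁰(r), which is essential
for correct normalization of stiff chains whose probability mass sits
near full extension — and then place biased windows from the 2 nm
capture distance up to the natural median, spaced ~1.5σ of the bias
(σ = √(kT/k)), floored at the configured minimum (default 10) and capped
at 80.  WHAM iterates the self-consistent equations on a shared grid
(bin width min(0.5 nm, support/200)) to a 10⁻⁶ kT change in the window
offsets.  J is read in the bin containing r = 2 nm and divided by 4πr²
at the bin centre (capture is orientation-free).  Standard errors come
from splitting every window's production samples into 5 contiguous
blocks and repeating WHAM per block; block errors underestimate the
seed-to-seed scatter somewhat (MC samples are correlated on ~10³-step
scales), so the flexible-limit check also pools independent seeds.

Default schedule: 10⁵ equilibration steps discarded, 1.5×10⁶ production
steps per window; scaled-down runs (acceptance script, tests) use
5×10⁴/2×10⁵ and 2×10⁴/6×10⁴ respectively — chosen as the smallest runs
whose J(L) ordering is stable across seeds at the reported precision.

## Stretching analysis

Traces are block-averaged from the 10 kHz acquisition to 1 kHz and
smoothed with a 25 ms boxcar.  Rupture events are local force maxima
above 1 pN prominence and at most 60 pN (above which DNA overstretching
contaminates peak statistics), followed within 100 ms by a ≥1 pN drop
and a ≥10 nm extension gain — the latter two being the package's
concrete reading of the unstated peak-selection sensitivity.  Loop sizes
are the difference of median contour lengths over 50 ms windows on
either side of the peak, excluding 30 ms around the drop: the guard must
exceed the 12.5 ms half-width of the 25 ms filter or the smeared
transition biases sizes low.  The compaction metric interpolates the
extension at the first upward crossing of 0.5 pN of the 250 ms-smoothed
force — without that smoothing the first favourable noise excursion
systematically fires early.  Breakage force is the pre-collapse maximum
over the 50 ms before the force falls to the zero-tension baseline;
traces that reach the ~110 pN trap escape force, or end unbroken, are
censored lower bounds.

Tether survival pools lifetimes into a product-limit (Kaplan–Meier)
curve — censored tethers stay in the at-risk set — and fits
S(t) = a·e^(−t/τ₁) + (1−a)·e^(−t/τ₂) by least squares on that curve,
matching how the plotted remaining-tether fraction is fitted; t₁/₂
solves S = ½ numerically.  The least-squares covariance understates
uncertainty (survival-curve residuals are correlated), so the tests
check parameter recovery with bootstrap intervals, and the recovery
criterion is on the median t₁/₂ bias over replicate datasets.

## Unzipping analysis

Force/extension points are inverted pointwise to bp unzipped and the bp
series smoothed over 25 ms.  Alignment to a baseline maximizes the
normalized cross-correlation over protein-free regions at integer-bp
offsets within ±200 bp.  The interaction range sums consecutive runs
(≥5 bp, to suppress single-bin noise spikes) where the smoothed force
exceeds the baseline by ≥2 pN before the breakage position; the 2 pN
threshold is applied to smoothed force.  Breakage probability is the
binomial fraction of tethers breaking before 80% of full length with
sem √(p(1−p)/n).

## Twisting analysis

The hat curve (extension vs applied turns) is fitted with a continuous
piecewise model: linear plectonemic flanks joined by a quadratic cap
with matching slopes; the cap half-width, centre, plateau and the two
flank slopes are free.  Extension converts to turn state by inverting
the declared flank; extensions above the plateau are clipped and
flagged.  Turns-relaxed series are smoothed with a 2nd-order
Savitzky–Golay filter over 30 s (301 points at 10 Hz; the qualifier
"non-linear" in the source procedure is read as naming the polynomial
order), edges handled by the filter's polynomial extension.

Pause detection follows the dwell-time procedure exactly: 0.2-turn
binning, dwell per bin, clusters of adjacent bins with >2 s dwell each
collapse to one state, time-domain assignment within ±0.4 turns, and
refinement of level and duration by averaging the assigned samples.
Two additions are required by the heavy smoothing: dwell clusters whose
assignment windows overlap (levels ≤0.8 turns apart) merge into one
state, and states shorter than 12 s (~0.4× the filter window) are
dropped — the filter smears pause entry/exit into satellite dwell
features of exactly that scale, 0.5–1.3 turns off the true level, which
would otherwise contaminate level statistics.  Both knobs are exposed;
setting the resolution floor to zero recovers the bare 2 s criterion.
Analysis is restricted to the plectonemic window (turns relaxed below
the ~30-turn pre-buckling bound of the 12.7 kb tether at 0.22 pN):
beyond it extension no longer reads out turns, and the fully relaxed
end state would register as one giant pause.

The pause-free rate is the median over 0.5-turn progress bins of the
rolling 5 s linear-fit slope over the first burst (onset to first
detected pause), dropping the half-window adjacent to the pause where
the rolling fit already averages in the plateau.  Pause frequency fits
exp(−n/n₀) to the fraction of traces still pause-free after n turns,
with pause-free traces censored at 30 turns; the fit uses only the
region below the censor bound, where the empirical curve is exact, and
the frequency is 1/n₀.  The mean relaxation rate — a quantity whose
exact original definition is unstated — is defined here as total turns
relaxed divided by the time from onset to reaching the relaxed state
(pauses included), or to trace end with a flag if never reached.
Trapped-supercoil size converts the hat-plateau reduction to bp through
the WLC fractional extension at 0.22 pN (≈0.65, i.e. ≈0.22 nm/bp).

## Synthetic generators

The generators encode the study conditions as defaults: 12,688 bp
template stretched at 200 nm/s and sampled at 1 kHz with 0.3 pN force
noise; constant-force lifetimes drawn from a two-exponential mixture;
unzipping baselines from the nearest-neighbour model of seeded random
50% GC sequences with additive bound-protein force elevations;
magnetic-tweezers relaxation at 10 Hz with 30 nm extension noise, ±40
applied turns, 2-turn catalytic steps arriving as a Poisson process at
rate v/2 events/s (v = 1.2 turns/s pause-free), and pauses entered with
probability 0.1 per cycle.  Pause durations are exponential with mean
100 s — the poisoned enzyme's pauses are prolonged, of the order of the
trace length divided by a few bursts — so that most pauses are long
compared with the 30 s analysis filter, as in the real data.

Stretching is quasi-static with an explicit trap compliance
(0.3 pN/nm): the stage position s satisfies s = x(F) + F/k_trap, so a
loop release produces the instantaneous force drop and extension jump
that peak detection keys on.  Bead/trap dynamics, drift, anchor
chemistry and enzyme mechanism are not simulated; effect sizes (rupture
forces, pause probabilities) are inputs, not predictions.  Passing
closed-loop tests therefore demonstrates that the analysis recovers the
statistical structure it assumes, at instrument-realistic noise — not
that it is robust to every artifact of real instrument data.

## Known limitations

- The bent-chain J(L) with the deflection convention for α decreases
  monotonically from 50 bp on the 50–600 bp grid: a mid-loop 150° kink
  places the ends of very short loops naturally close together, so the
  smallest loops have the highest capture density.  An interior maximum
  near 100 bp, as the measured loop-size histogram shows, would require
  either the milder included-angle convention (which instead peaks near
  400 bp), a finite protein footprint, or end-orientation constraints —
  none of which the source procedure specifies.
- Twist (linking-number) elasticity, excluded volume and electrostatics
  are not modelled in the looping MC.
- WHAM block standard errors underestimate seed-to-seed scatter by
  roughly 2× for large flexible chains; pooling independent seeds is
  recommended for quantitative error bars.
- The survival fit minimizes squared error on the survival curve for
  fidelity to the source procedure; a censored-likelihood fit would be
  statistically preferable and the Kaplan–Meier machinery to build one
  is present.
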