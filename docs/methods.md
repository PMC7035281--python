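# Methods

This note documents the models implemented in leutkit, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## smFRET observation model and generator

A molecule's conformation follows a continuous-time Markov chain over
four states with FRET emission means 0, 0.47, 0.63 and 0.79 — a zero-FRET
photophysical state plus the inward-open (low), partially open
(intermediate) and occluded (high) conformations of the cytoplasmic gate.
The generator samples exact Gillespie paths and only then bins them into
camera frames of 25 ms (40 frames/s): a frame containing a state jump
records the duration-weighted mixture of the state means, which is what
produces unresolvable dwells when exchange approaches the frame rate.
Per-frame intensities are `I_D = T·(1−E)`, `I_A = T·E` with total
intensity `T = 1000` a.u.; the raw acceptor adds donor bleed-through
`I_A,raw = I_A + 0.165·I_D`; both channels then receive independent
Gaussian noise of SD `noise_sd · T` (default `noise_sd = 0.06`), which
yields FRET noise of about 0.7–1.0 × `noise_sd` depending on E.  The
intensity scale and noise SD are generator conventions chosen to give
realistic single-molecule signal-to-noise (SNR ≈ 12 against background);
they are not measured constants.

Photobleaching is a single exponential time (rate `bleach_rate`) after
which both channels drop to background; donor blinking is an alternating
telegraph process.  A frame is marked dark when more than half of its
integration time is dark.  Blinks zero the signal but frames remain
recorded, as in real camera streams.  No triplet photophysics or separate
acceptor bleaching channel is modeled, so selection-criterion tests
exercise the detection logic, not camera physics.

Ligand coupling modulates exactly one transition pair: the forward
low→intermediate rate is `k_on·[L]` and the reverse is `k_off`
(defaults `k_on = 4×10⁵ M⁻¹s⁻¹`, `k_off = 2.04 s⁻¹`, midpoint
`k_off/k_on = 5.1 µM`).  Concentrations are carried in molar everywhere.
The default base generator keeps the intermediate↔high exchange slow and
strongly favoring the intermediate (`k_ih = 0.05 s⁻¹`, `k_hi = 2.0 s⁻¹`,
equilibrium constant K = 0.025).  With this tree topology the stationary
occupancies are exactly Hill-shaped in `[L]` with a shared apparent
midpoint `EC50 = (k_off/k_on)/(1+K)`; K was fixed at 0.025 a priori so
that the titration is dominated by the low↔intermediate pair — the
regime the titration analysis is meant to probe — which keeps the
apparent EC50 within ~2.5% of the kinetic midpoint.  The generator is a
deliberate simplification: real titrations couple a chemical binding
step to several conformational rates, baseline occupancies at zero
ligand are not all-low, and bleaching truncates observation windows.
Passing recovery tests therefore demonstrates correctness of the
analysis chain under the stated kinetic scheme, not that real data obey
that scheme.

## Trace selection

Traces are kept only if all five criteria pass: (i) a single-step donor
photobleach, (ii) SNR_background ≥ 8, (iii) SNR_signal ≥ 5, (iv) fewer
than four donor blinking events, and (v) FRET efficiency above 0.15 for
at least 300 frames.  The SNR definitions are our own (the criteria are
conventional but the formulas are tool-internal elsewhere):
SNR_background = mean pre-bleach total intensity / SD of the post-bleach
background, and SNR_signal = bleach step amplitude / SD of the pre-bleach
total intensity.  Bleach detection anchors the background level at the
trace tail, thresholds at 30% of the signal amplitude above background
(one refinement pass), removes isolated single-frame flips, and rejects
multi-step traces when the best internal mean-shift of the pre-bleach
level exceeds max(4·σ̂, 0.3·step).  Bleaches within ~1 s of either trace
end are undetectable in principle.

## SKM idealization

Segmental K-means alternates Viterbi assignment (fixed Gaussian emission
means, shared per-trace noise SD) with re-estimation of the per-trace
transition matrix and noise SD from the assignment, until the assignment
is stable (max 100 iterations).  The emission means are never re-fitted:
they are part of the model, which keeps idealizations comparable across
conditions.  Numerical choices: noise SD floored at 1e-3 (so noiseless
traces are decoded exactly); transition pseudocount 1e-3 per pair;
uniform initial state distribution; exact likelihood ties resolve to the
lowest state index, making the algorithm fully deterministic.
Equal-length traces are decoded in one vectorized batch purely for
speed; results are identical to per-trace runs.

## Dwell kinetics

Rates use the dwell-time MLE `k_ij = N_ij / T_i` with
`SE = sqrt(N_ij)/T_i`.  Dwells in the zero-FRET state are photophysics,
not conformation: they are excluded from occupancy denominators and
dwell statistics, and transitions touching them are neither counted nor
bridged (configurable).  Every rate table carries a dead-time caveat:
dwells shorter than the 25 ms integration time are missed, biasing
`k_ij` low by roughly `λ_j · τ` (λ_j = destination exit rate, τ ≈ one
frame).  An optional first-order missed-event correction multiplies each
`k_ij` by `exp(λ_j·τ)` with λ solved self-consistently and τ = one frame
period (the instrument resolution, not a fitted value).  This is still a
dwell-based estimator, not an interval likelihood: it corrects the
leading-order undercount but ignores dwell merging across missed events
(quadratic in the missed fraction) and the routing of transitions
between non-adjacent emission levels through intervening states by
time-averaged jump frames.  Rates within reach of the frame rate
(≳ 4 s⁻¹) should be read as lower bounds even after correction.

The transition density plot bins each dwell-to-dwell transition by the
mean *observed* FRET of the preceding and following dwell (bin width
0.05); counts are conserved exactly, and the transitions-per-second
figure divides total transitions by total non-dark observation time.

## Dose-response fitting

Ensemble occupancies of the three non-zero states (mean ± SE over
molecules, dark frames excluded from denominators; an `exclude_states`
flag re-includes the zero state) are fitted jointly as
`occ_s(c) = base_s + amp_s · c/(c + EC50)` with one shared EC50 and the
Hill exponent fixed at 1.0 — a single binding event drives all occupancy
changes, so the curves must share their midpoint.  The fit is weighted
least squares on log10(EC50) (bounded well outside the tested range);
the EC50 SE is transformed back by the delta method.  A fit in which no
state has amplitude above 1e-3 raises an "unidentifiable" error, and an
EC50 outside the tested concentrations is flagged as extrapolated.

## Coordinate-frame geometry

Gate distances are minima over chemically relevant polar atom sets
(R5 {NE, NH1, NH2} × D369 {OD1, OD2}; Y268 {OH} × Q361 {OE1, NE2}),
robust to rotamer flips; the atom sets are configurable because no
standard fixes them.  χ1 is the signed N–CA–CB–CG dihedral in
(−180°, 180°], "out" when |χ1| ≥ 120° (configurable).  The substrate COM
is mass-weighted over all substrate atoms with standard atomic masses.

Water counting tests only the water oxygen and measures lipid proximity
against all lipid atoms.  "Backbone" means atoms named N, CA, C, O.  The
membrane-slab criterion is evaluated as the projection of the oxygen
onto the axis through the two bound atoms (Cβ F259 → Cα G13, ordered per
frame): in membrane-aligned frames whose bound atoms are separated
purely along z this is exactly the conventional z-coordinate window, and
the projection form makes every operator invariant under rigid motions
of the frame, which the test suite enforces to 1e-9.  Frames are assumed
wrapped; no periodic-boundary minimum-image correction is applied.
Thresholds ("within r" means distance ≤ r) all live in
`HydrationCriteria` and can be overridden individually, including from a
YAML file on the CLI.

Microstate maps histogram the (salt-bridge, H-bond) projection at 0.25 Å
bins; microstates are the most populated strict 8-neighborhood local
maxima, with exact count ties across a plateau resolved deterministically
to a single peak, labeled a, b, c… by decreasing population, each with
the nearest snapshot as its representative frame.  Ion coordination
collects polar (O/N) protein/substrate/water atoms within 3.0 Å and
labels shells by count (6 → octahedral-like, 5 →
trigonal-bipyramidal-like).

The planted-water fixture generator builds frames in which every water
either satisfies all membership criteria or violates exactly one, with
≥ 0.3 Å of slack against every threshold it must clear, plus optional
fully random waters; every water carries labels computed by an
independent plain-loop evaluation.  Lipids are single atoms and waters
rigid 3-atom molecules, sufficient because only the oxygen is tested.
These fixtures validate the counting logic exactly; they do not emulate
real solvation structure, so hydration statistics on real trajectories
additionally depend on simulation quality, wrapping and residue naming.

## Binding fits

The one-site model is fitted by nonlinear least squares with relative
(1/model) residual weighting by default, because counting-assay noise
scales with the signal (the generator uses lognormal noise of fixed CV);
relative weighting roughly halves the median Kd recovery error at 5% CV
and makes the covariance-based SEs agree with the empirical
seed-to-seed spread to a few percent, so first-order propagated SEs on
fold changes are trustworthy.  Uniform weighting is available.  The
nonspecific background is fitted jointly as `m·L` using the paired
nonspecific wells; a `subtract_paired` mode reproduces classic cold
ligand background subtraction.  Percent-of-max normalization divides by
the fitted Bmax, not the largest observed point, which is robust to
noise at the top concentration.  Kd is bounded in (0, 1e7] nM and a fit
touching its bounds is flagged rather than reported as converged.

## Problem sizes

Recovery studies run at desk scale: titrations use 150 molecules × 2000
frames (50 s) per concentration over 8 concentrations; rate recovery
uses 10⁴ s of simulated data; binding recovery uses 12-point triplicate
designs over 20 seeds; the hydration oracle comparison uses 1000 random
fixtures.  At these sizes the recovered EC50, Kd, fold change and
top-state emission mean sit well inside their stated tolerance bands,
and the full verification suite plus the acceptance script complete in
about a minute on one CPU.

## Known limitations

- The rate estimator is dwell-based; see the dead-time discussion above.
- Bleach detection assumes a single dominant on-level; slow drift or
  multi-level photophysics will be flagged as multi-step rather than
  modeled.
- The hydration criteria assume membrane-aligned, wrapped frames with
  the reference residue numbering present in the input file; no
  cross-homolog residue mapping is attempted.
- The titration generator couples ligand to a single transition pair;
  apparent EC50s from schemes with multiple coupled steps will differ
  from `k_off/k_on` in ways the shared-EC50 fit cannot resolve.
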