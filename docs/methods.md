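# Methods

## Motif grammar

CArG boxes are matched as degenerate consensus patterns — one allowed-base
set per position — not as weight matrices: the published site definitions
are exact/near-exact consensus classes, and no background model or p-value
is meaningful at that resolution. Four classes are built in:

| name         | positions                  | length |
|--------------|----------------------------|--------|
| canonical    | C (C/T) (A/T)×6 (A/G) G    | 10     |
| srf_like     | C C (A/T)×6 G G            | 10     |
| n10_like     | C T A (A/T)×4 T A G        | 10     |
| intermediate | C (A/T)×6 A G              | 9      |

The SRF class is sometimes abbreviated in the literature as the 8-mer
C(A/T)₆G; we implement the 10-mer CC(A/T)₆GG form, which is the form the
probe sequences actually instantiate. The intermediate class is kept as the
9-base form printed above.

An **atypical** site deviates from a class consensus at up to
`max_atypical` positions (default 2). The published atypical decamers from
the tomato *LeEXP1* and *LeACS4* promoters all sit at 1–2 deviations from
the canonical class, which is the minimal budget consistent with them; no
published rule defines the cutoff, so it is configurable. Classification of
a decamer returns the class with fewest deviations, ties resolved canonical
> srf_like > n10_like.

Scanning reports every matching window on both strands by default (CArG
boxes are quasi-palindromic, and which strand the original census scanned
is unknowable); a window whose minus-strand match reads identically to the
plus-strand match — an exact palindrome — is reported once, on "+".
Overlapping hits are all reported; no greedy masking. Coordinates are
0-based half-open.

## Circular permutation

A bent protein-DNA complex migrates slowest when the bend is mid-probe.
The relative mobility r = complex migration / free-probe migration (same
lane; whether the original gels normalised within-lane or to a reference
lane is not recorded, within-lane is assumed) is modelled as

    r(p) = a + b · cos(π (p − p0) / L),   b ≤ 0

with p the binding-site centre, L the probe length and p0 the bend centre:
one half-period across the probe, the standard circular-permutation
convention, with extremes at the bend centre and one probe-length away.
The bend angle comes from the *fitted* extremes, not the raw min/max lanes:

    μ_M = a + b,  μ_E = a − b,  α = 2·arccos(μ_M/μ_E).

**Fitting.** For fixed p0 the model is linear in (a, b), so the fit walks a
deterministic grid of 16 phase nodes over the 2L period, solves each linear
subproblem, keeps the best node with b ≤ 0, and polishes with
Levenberg-Marquardt (trf, b bounded above by 0). No random restarts, so the
fit is a pure function of the data. Fitted amplitudes below 1e-9
(relative-mobility units) are treated as a flat profile: α = 0 and the bend
centre is not meaningful. A fit with μ_M ≤ 0 is rejected as degenerate.
Standard errors come from the asymptotic covariance s²(JᵀJ)⁻¹; the angle's
standard error by the delta method. At least 4 lanes with distinct site
positions are required.

## Phasing

Bend-centre spacing follows from linker length by the construct geometry,
spacing = linker + 39 bp (12 bp → 51 bp, 20 bp → 59 bp). Mobility vs
spacing is modelled as

    r(s) = baseline − amplitude · cos(2π (s − s0) / T),   amplitude ≥ 0

with T the helical repeat, fixed at 10.5 bp/turn by default. The mobility
*minimum* (slowest complex, maximal cooperative bending) defines the
in-phase spacing s0 — chosen over integer-turn arithmetic because the
observed in-phase spacing of 55 bp is 5.24 turns, not integral. For fixed T
the model is linear in (offset, cos, sin) components and is solved
directly; a free T is profiled over a deterministic grid on [9, 12] bp/turn
and refined, and requires the sampled spacings to span at least T/2
(narrower designs, like the standard 51–59 bp ladder, can only be fit with
T fixed). s0 is reported shifted by whole repeats into the sampled spacing
window. Zero fitted amplitude flags the phase as indeterminate.

Phase classification uses the circular distance d (in turns) between a
spacing and s0 modulo T: d ≤ 0.125 → in phase, |d − 0.5| ≤ 0.125 → out of
phase, else intermediate. The ±0.125-turn tolerance splits the helix into
equal sectors; it is a package convention, not a measured quantity.

## Saturation binding

One-site isotherm bound(x) = B_MAX·x/(K_D + x), fitted by bounded
least squares initialised at B_MAX⁰ = max signal and K_D⁰ = the
interpolated probe amount at half-max — deterministic and scale-equivariant
(scaling x scales K_D, leaves B_MAX). Probe amounts carry no assumed
concentration unit; K_D is reported in the units the amounts were supplied
in. Data whose terminal slope still exceeds 90% of the initial slope are
flagged as non-saturating (K_D then poorly constrained from above); the fit
is still returned.

## Circularization kinetics

Minicircle formation is normalised so the no-protein control is 100%, then
summarised with first-order kinetics pct(t) = plateau·(1 − e^{−kt}). The
original readout is qualitative; the kinetic summary is imposed so the
in-phase vs out-of-phase comparison becomes a testable rate ratio. A
time course with zero spread returns (k = 0, plateau = observed level) by
contract; decreasing time courses are fitted but flagged non-monotone. The
comparison reports k_in/k_out and the verdict "in>out" when the ratio
exceeds 1 (an infinite-ratio flag covers k_out = 0).

## Synthetic data

Every generator is a deterministic function of (SimulationConfig,
arguments); the seed feeds per-assay `numpy` generator streams, so outputs
are byte-identical across runs and σ = 0 outputs lie exactly on the model
curves. Defaults encode the measured system and are fixed package
constants:

* permutation: 8 lanes spanning 10–90% of a 230 bp probe (the per-lane
  restriction-site positions of the original constructs are not published,
  so an even design is used), μ_E = 0.8, bend angle 93° (N10 class),
  bend centre mid-probe, free-probe migration 10.0 arbitrary units in every
  lane;
* phasing: linkers 12–20 bp in steps of 2 (spacings 51–59 bp), baseline
  0.6, amplitude 0.1, s0 = 55 bp, T = 10.5 bp/turn;
* binding: B_MAX = 1, K_D = 4.515, 8 probe amounts log-spaced 0.5–32;
* circularization: times 0–60 min by 10, k_in = 0.12/min > k_out =
  0.05/min with plateaus 75% and 55% — both below the 100% free-DNA
  control (bound protein inhibits ligation overall) with the in-phase
  probe faster, the qualitative ordering the assay establishes; the rate
  and plateau magnitudes themselves are package choices, as no quantitative
  rates were published;
* noise: Gaussian, σ = 0.005 relative-mobility units (plausible gel
  densitometry scale), 0.02·B_MAX for binding, 2 percentage points for
  minicircle fractions; the t = 0 minicircle point is pinned at 0 (ligation
  has not started).

Promoter simulation plants consensus-drawn (optionally deliberately
atypical) motifs at non-overlapping random positions in uniform ACGT
background and returns a truth table that also records accidental
exact-match windows found by a brute-force census.

**What passing tests show, and don't.** The generators emulate the *shape*
of each assay (cosine flexure, helical sinusoid, hyperbolic saturation,
first-order kinetics) with homoscedastic Gaussian noise. Real gels add
lane-to-lane distortions, densitometry nonlinearity, correlated errors and
partial occupancy; real promoters are not uniform-random sequence. Recovery
of truth parameters here validates the estimators and their
implementation, not the biological measurements themselves.

## Problem sizes

Recovery suites use 200 replicate mobility series per bend angle and 100
replicate binding curves per K_D — enough for the replicate means to
stabilise well inside the ±2° / ±5% recovery bands while the whole test
suite and the acceptance script each run in seconds.

## Known limitations

* The mapping from the phasing constructs' printed end distances to their
  total PCR-product lengths (230–238 bp) cannot be reconciled from the
  published numbers, so product-length accounting is excluded; only the
  linker → spacing map is modelled.
* K_D units are "as supplied"; cross-study comparison requires knowing the
  original concentration scale.
* The scanner is consensus-based by design; it will not rank near-miss
  sites beyond the integer mismatch count.
* Bend centres are only identifiable when the mobility minimum falls
  within the probe; flat or out-of-window profiles report α = 0 or an
  off-probe centre respectively.
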