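# Methods

## The lattice model

Genomic DNA is a 1D lattice of `N` base-pair units.  Each of `f` protein
species `g` — histone octamers, linker histones, transcription factors —
is characterized by a footprint `m(g)` (bp covered when bound), a
dimensionless activity `a(g) = K(g) · c0(g)` (sequence-average binding
constant times free concentration) and an optional per-position relative
affinity track `K(n, g)` indexed by the leftmost unit of the fully wrapped
binding frame.  A bound particle may unwrap `h1` and `h2` bp from its two
ends, up to `h1 + h2 ≤ h_max`, leaving the covered interval
`[n + h1, n + m − h2)`; the unwrapped frame portions remain accessible to
other particles.  Each unwrapped bp contributes a factor `eps_u` to the
statistical weight (default 1, i.e. unwrapped states are counted as pure
conformational multiplicity; `eps_u < 1` charges an energetic penalty per
broken histone-DNA contact).

A configuration is any set of particles whose *covered* intervals are
pairwise disjoint.  Its weight is

    ∏ particles a(g) · K(n, g) · eps_u^(h1+h2)  ×  ∏ neighbor pairs w(L, g1, g2)

where `L` is the uncovered distance between the covered edges of two
particles adjacent along the DNA, and `w` is a finite-range interaction:
`w(0) = ω` is McGhee–von Hippel contact cooperativity, `w(L < V) = 0` is
long-range anticooperativity (a minimal center-to-center spacing), and any
tabulated `w(L)` is accepted up to a range `R` beyond which `w ≡ 1`.

Measuring `L` between covered edges (not nominal frames) is a deliberate
choice: it keeps `L ≥ 0` under unwrapping, makes the unwrapping states that
share a covered interval exactly aggregable in the solver, and it is the
only convention under which an exclusion range `V` larger than the
measured internucleosome center spacing minus the footprint is satisfiable
— partially unwrapped nucleosomes can approach closer in frame terms than
`V` while their bound segments stay `V` apart, which is precisely the
regime needed to reproduce short-NRL yeast-like arrays together with a
30–40 bp exclusion.

Because the model is solved in the grand-canonical equilibrium ensemble,
"activity" subsumes remodeler-assisted equilibration: the ensemble is read
as a population of cells, not a single fiber's kinetics.

### Linker-histone rules

A `LinkerCapRule` designates one species as linker (H1-like) and one as
nucleosome.  A configuration is legal iff every linker can be assigned to
an adjacent nucleosome (only other linkers between the two, assignments
non-crossing) with at most `cap` linkers per nucleosome; when free binding
is disallowed, each linker must additionally *lie entirely within*
`vicinity` bp of its assigned nucleosome's covered edge — the vicinity is
a zone next to the nucleosome that the whole molecule must occupy.  With
`cap = 1` this is the chromatosome stoichiometry rule (no more than one
linker histone per nucleosome); with a cap set above what the vicinity can
geometrically hold, stoichiometry is limited by geometry alone.

The solver canonicalizes assignments greedily left-to-right (assign to the
last nucleosome whenever capacity, distance and no pending linkers allow;
otherwise the linker waits for the next nucleosome), which counts every
legal configuration exactly once; an exchange argument shows greedy
feasibility coincides with the existence of any non-crossing assignment.
The brute-force oracle instead searches assignments exhaustively, so the
two implementations validate each other's semantics, not just their
arithmetic.

## Exact solution

`solve` computes exact marginals — per-position frame-start probabilities,
per-species coverage `c(g, n)`, free-DNA probability and the log grand
partition function — by dynamic programming over particle covered-end
positions, with:

* exact aggregation of unwrapping states per covered interval (weights
  collected by convolution of the affinity track);
* neighbor sums split into an explicit near window (gap ≤ max(R, vicinity))
  and a cumulative far part where `w ≡ 1`;
* linker-cap bookkeeping as a small finite-state machine whose states
  (remaining capacity, distances to the last nucleosome and of pending
  linkers) are enumerated per model;
* forward and backward passes combined into per-placement marginals;
* per-position multiplicative rescaling (log offsets), so partition sums
  never overflow; forward and backward log-partition values are compared
  (tolerance 1e-8) as an internal consistency check every run.

Cyclic (ring) lattices are solved by conditioning on the anchor particle —
the one covering position 0, or the first one clockwise of it — which
reduces each case to a linear solve on the remaining arc with the anchor as
a boundary ghost on both sides.  The cost is O(anchors × N); rings are
meant for repeat-unit tori (hundreds of bp), not chromosomes.  Linker-cap
rules are not supported on rings.  A single particle on a ring is not its
own neighbor (no self-interaction across the wrap); two particles interact
through both of their gaps.

The brute-force enumerator (`brute_force_solve`) realizes the identical
contract by explicit enumeration (placements at individual unwrap-state
resolution, bitmask overlap checks, configurable configuration cap) and is
the test oracle throughout: randomized instances with N ≤ 12, one or two
species, unwrapping, cooperativity, exclusion, cap rules and both
boundaries agree with the DP to 1e-9.

The McGhee–von Hippel isotherm (`interior_density`, solved by bisection of
the log-activity, with the closed-form inverse `a(ν)` also exposed) is the
independent infinite-lattice reference: the interior of a 5 kb hard-wall
solve matches it to 1e-4 across footprints 2–147.

## NRL estimation

Occupancy oscillations next to a boundary are reduced to a peak list
(`scipy.signal.find_peaks`; default prominence 2% of the profile range,
minimum separation 100 bp, sub-bp refinement by a parabola through the
three samples around each maximum) and the peak positions are regressed on
their ordinal index; the OLS slope is the NRL.  Defaults: peaks within
1500 bp of the boundary; at least three peaks, else an explicit
insufficient-peaks signal.  Sub-bp refinement matters: with only 4–6
detectable peaks, integer peak coordinates alone quantize the slope by
±1–2 bp.

`scan_parameter` runs solve → peaks → fit over a parameter grid and flags
(rather than fails) grid points without three detectable peaks.  Flat or
weakly oscillating profiles (densities below ~0.7 of saturation within a
1.5 kb window) are genuinely outside the method's domain — statistical
positioning decays within a couple of periods there.

## Canonical study conditions (fixtures)

The fixture builders freeze the conditions used by the tests and the
acceptance script:

* `gen_boundary_model(density, ...)` — homogeneous hard-wall nucleosome
  (147 bp) lattice whose activity is the closed-form isotherm inverse of
  the target interior coverage; optional unwrapping, contact
  cooperativity ω, exclusion V.
* `gen_unwrap_model(h_max, activity=0.7)` — unwrapping scans are run at
  fixed activity (not re-matched density), so the density rise caused by
  opening unwrapped states is part of the measured effect.  At h_max = 40
  the repeat shrinks to ~125 bp; peak detection there needs
  `min_separation` below the default (the scans use 80 bp).
* `gen_linker_model(a_H1, footprint=15, vicinity=30)` — nucleosome
  (a = 0.7) plus a linker protein restricted to nucleosome vicinities,
  with the count cap set above what the 30-bp vicinity can hold.  The NRL
  rises with linker activity because gaps hosting linkers gain both
  excluded volume and positional entropy, and saturates as the vicinity
  zones fill.  The canonical titration grid is a_H1 = 0.005 · 2^k,
  k = 0..6, over which the bound linker-per-nucleosome stoichiometry rises
  from ~0.1 to ~1.5.  The "doubling" measurement is taken across the pair
  (0.08, 0.16), which brackets one bound linker per nucleosome — the
  upper, saturating range of the titration.
* `gen_capped_linker_model(a_H1)` — the refined chromatosome model:
  cap = 1, vicinity 30 bp, plus nucleosome-nucleosome contact
  cooperativity ω = 11.  NRL(a_H1) rises, is approximately linear in the
  bound linker-per-nucleosome ratio below ~0.65 (the knockout-series
  regime) and approaches a finite plateau, since each nucleosome can
  recruit at most one linker.
* Linker-size comparisons (footprints 5 / 15 / 30 bp — half, nominal and
  double the 15-bp linker — at equal per-particle activity 2.0, i.e.
  K = 2·10⁹ M⁻¹ at ~1 nM free linker) are made at *saturating nucleosome
  activity* (a_NCP = 20), where the repeat length is limited by the bound
  linkers rather than by nucleosome scarcity.  There, smaller linkers are
  the more potent NRL expanders: several of them stack into the same
  vicinity zone that one large linker fills, multiplying configurational
  entropy and resisting compression by the nucleosome gas.  At the
  dilute-nucleosome baseline (a_NCP = 0.7) the comparison is instead
  dominated by the larger linker's excluded volume depressing the
  nucleosome density itself, which trivially lengthens the repeat and
  inverts the ordering; and intermediate sizes (e.g. 10 bp) show ±5 bp
  commensuration wiggles of the stacked-linker extension against the
  30-bp zone, so the canonical comparison uses the half/nominal/double
  set, where the ordering is monotone with >10 bp margins.

A modeling finding worth recording: an equilibrium two-species model in
which the linker merely decorates nucleosome edges through contact
cooperativity does *not* produce a rising NRL — the decoration multiplies
the effective nucleosome fugacity, densifies the array and shortens the
measured repeat, regardless of whether activity, coverage or nucleosome
count is held fixed; and an unrestricted linker gas at activities above
~0.2 simply outcompetes nucleosomes (a 15-mer gas at a = 0.3 covers 57% of
the lattice by the isotherm).  The vicinity construction is therefore not
a convenience but the mechanism that makes linker-driven NRL growth
thermodynamically possible in 1D.

## Sequence tracks and periodicity

* `energy_to_affinity`: `K = exp(−β E)`, geometric-mean-normalized so only
  energy differences matter.
* `phasing_energy_track`: a deliberately minimal surrogate sequence model —
  the per-frame magnitude of the phasor sum of W/W (A/T) dinucleotide
  positions at the 10.4-bp helical period, negated and normalized.  It is
  *not* a calibrated nucleosome model; it only needs to rank frames within
  a repeat unit, which is all the tandem-repeat analyses require.  Any
  per-unit-periodic score yields the same downstream repeat length.
* `pwm_affinity`: log-odds scan of both strands (pseudocount 0.01, max over
  strands, N-windows at background), scaled so a consensus site scores the
  given site constant.
* `detrend_fourier_period`: subtract a degree-d polynomial (fit in a
  Legendre basis on x rescaled to [−1, 1]; raw high-degree monomials are
  numerically singular), Fourier-transform the residual, exclude
  frequencies below 4 cycles per window, and refine the maximal-power bin
  by parabolic interpolation of log power.  Numerical precondition: a
  degree-d polynomial can itself absorb oscillations of up to ~d/2 cycles,
  so the window must hold well over d/2 periods of the signal of interest
  (tests use ≥ 100 cycles).  Within that regime the recovered period is
  stable across degrees 50–120 and accurate to one interpolated FFT bin at
  SNR ≥ 2.

The satellite analyses tile the packaged 234-bp major satellite consensus
unit (`satellite_unit`) 50× with 49 nt of cyclic padding.  In the
sequence-dominant regime (low nucleosome activity, a = 0.05, surrogate
affinity at β = 6) the solved occupancy has exactly one peak per unit and
the fitted NRL equals the unit length.

## Aggregation and repeat fragments

Anchor-centered windows (default −1500..+1500 bp) are cut from per-bp
tracks, minus-strand windows optionally reversed (default on), each row
normalized to 1 at its leftmost position (rows with zero leftmost value
dropped and counted, as are anchors without coverage), and averaged
column-wise; heat-map rows can be stably sorted by descending mean over a
clipped region.  Missing values inside a window are treated as zero
coverage with a logged warning.

Fragment tables on the padded repeat reference are wrapped by reducing
left ends modulo the unit length (right ends carried, preserving length),
counted into per-position left/right end profiles with optional inclusive
size selection, and start-site (left-end) periodicity is measured by
circular autocorrelation of mean-subtracted counts.  The reported period
is the *smallest* lag reaching 80% of the in-range maximum — the
fundamental — since all multiples of a comb period carry comparable
autocorrelation.

## Problem sizes and determinism

All headline computations are deterministic (exact DP; no sampling); the
stochastic generators (fragment sampler, jittered anchor tracks) take
explicit integer seeds and no global RNG state is used.  Default problem
sizes — 3–6 kb lattices for scans, 11.7 kb for the 50-copy satellite
array, 5 kb for isotherm comparisons, N ≤ 12 for enumeration cross-checks
— were chosen so every analysis, including the full parameter-scan suite,
solves in seconds on one core while leaving at least 4–5 oscillation peaks
for regression.

## Known limitations

* Equilibrium only: remodeler kinetics enter solely as effective
  activities; no dynamics.
* The linker vicinity zone is a fixed window, orientation-agnostic, and
  linkers interrupt direct nucleosome-nucleosome contact cooperativity by
  construction (interactions are nearest-neighbor).
* Cyclic solves cost O(N²)-ish via anchor conditioning and exclude cap
  rules.
* The surrogate sequence model ranks frames by W/W phasing only; it is not
  a substitute for calibrated genome-wide nucleosome-preference models,
  whose outputs should be supplied as energy tracks instead.
* The synthetic fixtures emulate boundary-phased occupancy, periodic
  affinity landscapes and phased fragment start sites; they do not emulate
  MNase digestion bias, mappability artifacts or copy-number structure, so
  green tests certify the machinery and the model's internal physics, not
  concordance with any particular genomic dataset.
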