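# nuclattice

Exact 1D lattice models of competitive multi-protein binding to DNA, and
nucleosome repeat length (NRL) analysis — for chromatin biophysicists and
regulatory genomicists who want to ask *why* a genomic region has the
nucleosome spacing it has.

Genomic DNA is modeled as a lattice of `N` bp units bound competitively by
`f` protein species (histone octamers, linker histones H1, transcription
factors).  Species `g` covers `m(g)` bp, binds with dimensionless activity
`a(g) = K(g)·c0(g)` modulated by a per-position affinity `K(n, g)`, may
unwrap `h1 + h2 ≤ h_max` bp from its ends, and interacts with its
neighbors through a distance-dependent statistical weight `w(L, g1, g2)` —
contact cooperativity `ω = w(0)`, long-range anticooperativity
`w(L < V) = 0`, or any tabulated finite-range potential.  Linker-histone
stoichiometry rules (at most one H1 per nucleosome, binding only in a
nucleosome's vicinity) are supported as exact constraints.  The solver
computes exact equilibrium marginals — binding-start probabilities,
per-species coverage `c(g, n)`, free-DNA probability, and the log grand
partition function — by dynamic programming (no sampling), verified
against a brute-force enumeration oracle to 1e-9 and against the
McGhee–von Hippel isotherm

    ν / a = (1 − mν) · ((1 − mν) / (1 − (m−1)ν))^(m−1)

in the long-lattice interior.  On top of the solver sit the genomics
analyses: NRL extraction by regression of occupancy-peak positions on peak
index near a positioning boundary, parameter scans (density, unwrapping,
cooperativity, exclusion range, linker concentration and size), affinity
tracks from DNA sequence or imported energy tracks, periodicity detection
by high-degree polynomial detrending + Fourier transform, anchor-centered
aggregate profiles, and cyclic-coordinate fragment analyses on tandem
repeats such as the 234-bp mouse major satellite (end-frequency profiles,
size selection, 10-bp start-site periodicity by circular autocorrelation).

See `docs/methods.md` for the model, its assumptions, all numerical
choices and the canonical study conditions.

## Worked example

Statistical positioning next to a boundary, with a 30-bp exclusion zone
between nucleosomes:

```python
from nuclattice import LatticeModel, SpeciesSpec, InteractionRule, solve
from nuclattice.nrl import estimate_nrl_from_profile

model = LatticeModel(
    N=4000,
    species=[SpeciesSpec("NCP", 147, activity=0.7, is_nucleosome=True)],
    interactions=[InteractionRule.exclusion("NCP", "NCP", 30)],
)
sol = solve(model)
est = estimate_nrl_from_profile(sol.coverage["NCP"], window=1500)
print(f"mean occupancy  {sol.coverage['NCP'].mean():.3f}")
print(f"NRL             {est.nrl:.1f} bp  (r^2 = {est.r_squared:.4f}, {est.n_peaks} peaks)")
print(f"log Z           {sol.log_partition:.1f}")
```

prints

```
mean occupancy  0.648
NRL             205.6 bp  (r^2 = 0.9994, 6 peaks)
log Z           79.5
```

The hard wall at position 0 phases the nucleosomes; the fitted repeat
(205.6 bp) exceeds the 147-bp footprint by the typical linker, inflated
here by the 30-bp exclusion — remove the interaction rule and the same
script prints an NRL of ~169 bp.  The same pipeline is scriptable from the
shell (`nuclattice solve|nrl|scan|seq2aff|period|aggregate|repeats|simulate`),
e.g.:

```bash
nuclattice simulate --what boundary-profile --density 0.8 --length 4000 --out occ.bedgraph
nuclattice nrl --track occ.bedgraph
```

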