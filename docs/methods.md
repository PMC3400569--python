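# Methods

## The problem and the model system

Nucleotide release from a G-protein α-subunit is the rate-limiting step of
receptor-mediated activation, and the nucleotide sits buried between two
sub-domains, so *which way it leaves* is a real mechanistic question. The
computational strategy studied here answers it by (i) generating candidate
exit pathways with steered dynamics, (ii) converting each pathway into an
umbrella-sampling ladder and a WHAM free-energy profile, (iii) checking that
the pathways are energetically reproducible through per-residue interaction
profiles, and (iv) asking whether the collective motions excited during exit
correspond to intrinsic soft modes of the protein.

`exitpmf` implements that strategy as a reusable pipeline and validates it on
a synthetic system small enough that every stage has an analytic oracle: two
quasi-rigid lobes of 20 coarse residue sites each (one site ≈ one residue),
joined by soft hinge springs, with a single ligand bead bound in the
inter-lobe pocket. Two exit channels run along the ±y axis. The
ligand–environment potential contains, besides Lennard-Jones and Coulomb
terms, an *additive analytic channel term*

    U(r) = f(s) + ½·k_perp·ρ²,
    f(s) = −D·e^{−s²/2σ_w²} + A₊·e^{−(s−s_b)²/2σ_b²} + A₋·e^{−(s+s_b)²/2σ_b²}

with `s` the signed projection of the ligand's centre of mass on the channel
axis and `ρ` the off-axis distance. Because the transverse confinement is
independent of `s`, the exact potential of mean force along each channel
equals `f(s)` up to a constant. The ridge amplitudes `A₊, A₋` are calibrated
by a short fixed-point iteration so that the 1-D barrier (max − min of `f`
on each side) equals the configured channel heights exactly; the defaults
(5 kcal/mol for channel A, 12 for channel B) encode the "one easy, one hard
exit" structure whose recovery the pipeline is tested on. Channels are
explicit analytic terms rather than emergent packing precisely so that
ground truth exists.

Charges: the ligand carries −0.2 e, balanced by +0.025 e on each of the
eight pocket-lining sites (total charge zero). The magnitudes are kept small
so that the analytic channel term dominates the exit thermodynamics while
the per-residue interaction decomposition remains meaningful (pocket
contacts contribute ≈ −0.5 kcal/mol each in the bound state). Consequently
the *measured* pipeline barriers (≈ 7.5 and ≈ 14.5 kcal/mol at the defaults)
exceed the configured ridge heights by the electrostatic well depth plus the
entropic cost of localising the ligand near the pocket centre; the ordering,
which is what the study decides, is preserved.

## Units and constants

Å, kcal/mol, amu, ps, elementary charge throughout. R = k_B =
1.987×10⁻³ kcal·mol⁻¹·K⁻¹; Coulomb prefactor 332.0636 kcal·Å·mol⁻¹·e⁻²;
1 kcal/mol = 418.4 amu·Å²·ps⁻² converts forces to accelerations.

## Dynamics

BAOAB-discretised Langevin dynamics; default timestep 0.002 ps (the toy
force field is soft; the stiffest default oscillation is resolved by ~30
steps/period), friction 1 ps⁻¹, 298 K. With zero friction the scheme
reduces to velocity Verlet and conserves energy (regression-tested at
< 10⁻⁴ kcal/mol per 1000 steps at a 0.0002 ps step). One seed drives one
run; ladder runs derive per-window seeds as `seed + window_index`, and all
windows advance in one vectorised batch whose per-window noise streams come
from those seeds, so results are bitwise reproducible. A numba-compiled
kernel provides the default integration path; the generic numpy
implementation is kept as the reference and the two are asserted identical
(to ~1e-15 on the coordinates) in the tests.

The steering (TMD) bias is one-sided — zero when the observed RMSD is below
its target — and the RMSD is computed over the steered sites *without*
rotational/translational fitting: the protein frame is pinned instead by
weak positional anchors on all protein sites (the toy analog of membrane
anchoring) and by co-steering four pocket sites, mirroring the practice of
restraining four pocket Cα atoms. The exact prefactor convention is
`U = (k_per_atom·N/2)·ΔRMSD²`, i.e. 0.5 kcal·mol⁻¹·Å⁻² per steered atom by
default. If the restrained distance ever vanishes while `d_eq > 0`, the
umbrella force direction is taken along +x with a warning (a
probability-zero event; deterministic handling preferred over an error).

Desk-scale steering: the library default for the targeted-RMSD rate is the
protocol value 2.5×10⁻³ Å/ps (a 25 Å extraction then takes 10 ns), but the
study driver passes an explicit 60 ps pull, followed by a hold phase (20 %
of the duration at target RMSD 0) so the ligand relaxes onto the target.
The steering target is placed 20 Å out along the channel axis — beyond the
13 Å window region — because with the soft 0.5 kcal·mol⁻¹·Å⁻²·atom⁻¹ force
constant, the pulling force available at position `s` scales with the
remaining distance to the target and must exceed the ~6 kcal/mol/Å maximum
ridge slope of the hard channel. An extraction is flagged incomplete when
the final RMSD misses a tolerance (1 Å in the study driver ≈ 2 thermal
standard deviations of the soft one-sided bias) or the ligand ends below
95 % of the target's pocket distance.

## Window protocol

Greedy selection at a minimal 0.5 Å increment of the ligand:pocket-COM
distance (the bound start frame seeds the scan but is not a window — a
12.5 Å span then yields ~25 windows), force constant 10 kcal·mol⁻¹·Å⁻²;
gaps wider than 0.5 Å are filled with equally spaced windows seeded from
the nearer neighbour (ties toward the smaller distance) at
20 kcal·mol⁻¹·Å⁻². Window runs default to 5×10⁴ steps (100 ps) with the
first 10 % discarded as equilibration; the samples decorrelate in a few ps,
giving ≳10³ effective samples per window. The pocket COM is mass-weighted
over the protein sites within 4 Å of the ligand in the reference structure
(equal toy masses make this the geometric mean).

## WHAM

Standard self-consistent iteration of the two WHAM equations in log space
(logsumexp), bin width 0.1 Å anchored at multiples of the width, tolerance
10⁻⁶ kcal/mol on the window offsets, at most 10⁵ iterations; unvisited bins
are masked, never interpolated, and `barrier_height` refuses to bridge a
masked gap — silent interpolation would fabricate free energies. The profile
is anchored at min = 0. All windows share one temperature (298 K default).
No periodicity, no 2-D WHAM, no standard-state volume correction: the PMF
depth and the Kd-derived ΔG = −RT ln(Kd/1 M) (0.2 µM at 298 K ↦
9.13 kcal/mol, the "~10 kcal/mol" scale) are exposed side by side, not
conflated. "Ambient temperature" is taken as 298 K; using 300 K would shift
ΔG by ≈ 0.06 kcal/mol. Bootstrap errors are Bayesian (per-window Dirichlet
weights), with each replica re-solved from the converged offsets.

Validation fixtures: a harmonic landscape (κ = 2 kcal·mol⁻¹·Å⁻², 25 windows
at 0.5 Å, k = 10) must be recovered with RMS error < 0.3 kcal/mol, and a
quartic double well (barrier 4 kcal/mol, wells 2 Å either side of the top,
windows spanning the two wells) within 5 %. The double-well windows
deliberately stop at the wells: on the quartic outer walls the landscape
slope (≫ 10 kcal/mol/Å) exceeds what a k = 10 restraint can hold, the
sample clusters detach from their window centres, and the 0.1 Å binning
misrepresents the bias — a real protocol limitation worth knowing about.
The same fixture runs use 10⁵ steps/window so the barrier estimate's
stochastic error stays near 1–3 %. An independent cross-check solves the
unbinned MBAR equations (convex objective, L-BFGS) in the test suite and
agrees with the histogram WHAM to < 0.2 kcal/mol.

## Interaction energetics

Residue roster: union over all frames of all pathways of residues with any
site within 4 Å of any ligand site. Profiles: per frame, ligand:residue
LJ + Coulomb summed over site pairs; frames assigned to 0.02 Å bins of the
exit coordinate; bin value = unweighted mean over assigned frames (the
estimator is not dictated by the protocol; the mean is the obvious choice).
Qualitative colouring uses the sign of the bin mean with a ±0.5 kcal/mol
neutral dead-band. Cross-pathway comparison uses per-residue Pearson
correlation over jointly occupied bins on the shared anchored grid
(nearest-bin matching, never interpolation of energies), summarised over
residues with ≥ 10 joint bins. Two independent extractions of the same
channel correlate at ≈ 0.94 ± 0.05 on the defaults — the "conserved
interactions" signature.

## Modes and their comparison

Quasi-modes: frames are least-squares superposed (mass-weighted Kabsch,
two refinement passes of the mean) onto the mean structure, the
mass-weighted covariance (divided by F, so duplicating a trajectory leaves
it exactly unchanged) is diagonalised, and the top-variance components are
returned — "lowest frequency" in the quasi-harmonic sense means largest
variance. 50 modes by default, capped at 3M−6 with a warning. The
superposition-based rigid-body removal is a choice; an anchored frame would
also work, and the tests assert invariance under global translation.

Normal-mode reference: a uniform elastic network (springs between sites
within 8 Å, unit stiffness) on the reference structure, mass-weighted
Hessian, with exactly six near-zero rigid-body modes excluded from
matching. This stands in for an all-atom normal-mode set; its eigenvalues
are in network units and only the mode *shapes* are compared.

Comparison: each mode is rendered as the displacement matrix |Δd_ij|
between the reference and the structure displaced along the mode to a +1 Å
amplitude — normalised so the *maximum per-site* displacement is 1 Å (the
amplitude convention is ambiguous between per-site max and RMS; per-site
max is used and recorded here) — and matrix pairs are scored by the Mantel
statistic (Pearson r over upper triangles; permutation p from simultaneous
row/column relabelings, default 9999 when requested, two-sided). The
similarity criterion is a parameter with default 0.5; 0.6 is an equally
defensible stricter choice and both appear in the validation examples. The
planted-mode benchmark (thermally excite one network mode, recover it as
quasi-mode 1 with Mantel r > 0.5 and dot-product overlap > 0.9) passes for
each of the three softest non-rigid modes.

## What the synthetic system does and does not show

It emulates: a ligand bound between two elastically coupled lobes with
hinge-like soft modes; two geometrically distinct exit channels of known,
controllable barrier; per-site charges/LJ so interaction decomposition is
non-trivial; thermal sampling with realistic umbrella statistics. It does
not emulate: explicit solvent and its friction anisotropy, side-chain
rearrangements, rugged all-atom landscapes, force-field inaccuracies, or
the slow (hundreds of ns) conformational gating of a real heterotrimer.
Passing tests therefore certify the *estimators and the protocol logic* —
that WHAM, the window rules, the profiles and the mode comparison recover
known ground truth — not that any particular real system's numbers would be
reproduced at this scale.

## Numerical choices and degenerate inputs

- Window histograms share a global binning anchored at multiples of the bin
  width, so profiles from different runs are comparable bin by bin.
- The window selector tolerates float ties (an increment within 10⁻⁹ of the
  threshold counts), keeping the floor(span/increment) window count exact.
- Empty or constant extraction traces yield an empty ladder with a warning;
  a diverged window (energy beyond 10⁸ kcal/mol or non-finite) is flagged
  failed and excluded downstream; adjacent windows without a shared occupied
  bin trigger a warning, not a failure.
- Problem sizes in the default study (60 ps pulls, 5×10⁴-step windows,
  two replicas per channel) were chosen so the complete study runs in about
  twenty seconds and the ten-seed ordering screen in a few minutes while
  keeping every acceptance margin several standard errors wide.

## Known limitations

- The distance reaction coordinate folds the two channels onto one axis;
  windows stay in their channel only because the transverse confinement
  blocks channel-to-channel crossing at fixed distance. For emergent
  (non-analytic) channels a vector or path coordinate would be needed.
- Near d → 0 the distance coordinate acquires geometric (Jacobian)
  contributions; barriers are therefore measured from the bound-region
  minimum of the profile, not from the analytic well depth.
- The ENM reference uses uniform stiffness; heterogeneous contact maps
  would change mode ordering, though not the comparison machinery.
- The Mantel permutation p-value is exchangeability-based and is reported
  for information; mode matching itself uses the r threshold, as in the
  original protocol.
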