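# exitpmf

Ranking the exit pathways of a ligand buried between two quasi-rigid protein
lobes — the computational chain used to ask on which side a nucleotide such
as GDP leaves the G-protein α-subunit pocket: is the "phosphate-side" exit
thermodynamically easier than the "base-side" exit?

`exitpmf` implements that chain end to end and validates every stage against
analytic oracles on a synthetic two-lobe pocket system:

1. **Steered extraction (targeted MD).** A harmonic penalty on the RMSD of
   the ligand (plus four anchor sites) to a target structure,
   `U = (k/2·N)·(RMSD_obs − RMSD_targ(t))²` with a linearly decreasing
   `RMSD_targ(t)`, pulls the ligand along each candidate exit channel.
2. **Umbrella sampling.** Along each extraction, window seeds are selected
   at a minimal 0.5 Å increment of the distance *d* between the ligand
   reporter site and the mass-weighted pocket centre of mass; gaps wider
   than 0.5 Å are filled with extra windows at an escalated force constant
   (20 instead of 10 kcal·mol⁻¹·Å⁻²). Each window is sampled with
   `U = ½·k·(d − d_eq)²` under BAOAB Langevin dynamics.
3. **WHAM.** The standard self-consistent pair of equations combines the
   window histograms into a potential of mean force F(d); barriers are read
   off as `max F` along the path minus `min F` over the bound region, and
   the experimental scale is checked through `ΔG = −RT·ln(Kd/1 M)`.
4. **Interaction energetics.** For every residue within 4 Å of the ligand
   anywhere along the pathways, the ligand:residue Lennard-Jones + Coulomb
   energy is profiled against the exit coordinate every 0.02 Å, and profiles
   from independent extractions are compared by per-residue Pearson
   correlation.
5. **Essential dynamics vs normal modes.** Quasi-modes (principal components
   of the mass-weighted, superposed trajectory covariance) are compared to
   elastic-network normal modes by displacing the structure +1 Å along each
   mode, computing the pairwise inter-site displacement matrix |Δd_ij|, and
   scoring matrix similarity with the Mantel test (r > 0.5 marks closely
   related motions).

The synthetic system (2 lobes × 20 coarse residue sites + 1 ligand bead,
net charge zero) carries an *analytic* channel potential — a bound-state well
with Gaussian barrier ridges of configurable height on the +y and −y exit
axes — so the exact free-energy profile of each channel is known in closed
form and every estimator in the chain can be validated quantitatively.

## Worked example

```python
from exitpmf import RunConfig, run_full_study

report = run_full_study(RunConfig(master_seed=1))
v = report["verdict"]
print(v["preferred_channel"], round(v["barrier_A_kcal_mol"], 1),
      round(v["barrier_B_kcal_mol"], 1))
print(report["energetics"]["replica_correlation_A"])
print(report["modes"]["best_matches"])
```

prints

```
A 7.4 14.8
{'mean': 0.938, 'sd': 0.054}
{3: {'normal_mode': 4, 'mantel_r': 0.84}, 1: {'normal_mode': 3, 'mantel_r': 0.76}, ...}
```

meaning: channel A (built with the lower 5 kcal/mol channel ridge; the
measured barrier also contains the electrostatic well and the entropic cost
of leaving the pocket) is correctly ranked below channel B (12 kcal/mol
ridge); the two independent extractions of channel A share essentially the
same per-residue interaction sequence (mean r ≈ 0.94); and several
large-amplitude quasi-modes of the extraction trajectories match soft
elastic-network modes at Mantel r well above the 0.5 similarity criterion.

The same pipeline is available stage by stage from the shell:

```bash
exitpmf make-toy --seed 1 --out toy
exitpmf tmd --topology toy/topology.json --start toy/start.pdb --channel A --out tmdA
exitpmf windows --pathway tmdA --max-distance 13 --out ladder.json
exitpmf fill-gaps --ladder ladder.json --out ladder_filled.json
exitpmf run-ladder --topology toy/topology.json --ladder ladder_filled.json --out winA
exitpmf wham --metadata winA/metadata.dat --bootstrap 25 --out pmfA.tsv
```

The umbrella files are written in the classic whitespace-separated
metadata + time-series dialect, so they are interchangeable with other WHAM
implementations.

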