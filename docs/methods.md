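# Methods

This note records the models, conventions, numerical choices and known
limitations behind `abepitope`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate model and chain roles

Structures are parsed with gemmi (PDB fixed-column and mmCIF) into a small
chain/residue/atom hierarchy. Author residue numbering is the coordinate
convention throughout, because HLA epitope residues are cited by
mature-protein numbers (K146, R145, …) and because HLA-A/-B/-C allelomorphs
share that numbering, which is what makes cross-complex footprint
comparison by residue number meaningful. Policies:

- first model only for multi-model coordinate files (trajectories go
  through the `traj` module instead);
- alternate locations: highest occupancy wins, ties resolve to altloc 'A';
- waters excluded; other HETATM records retained with an `is_hetero` flag
  and excluded from protein-residue counts, interface analyses and SASA
  unless explicitly included;
- protein residues are the 20 standard amino acids.

Chain roles (mhc_heavy, beta2m, peptide, ab_heavy, ab_light, receptor) are
assigned by explicit hints or a length heuristic (peptide ≤ 15 residues,
β2m 95–105, MHC heavy chain the longest chain ≥ 250, then antibody
heavy/light by length). Any ambiguity is an error that names the candidate
chains rather than a guess. Three α2₁ helix definitions circulate in the
structural literature (141–155; an extended 131–155; a 127–158 fragment
used for dynamics), so all three are registered as named segments
(`alpha2_1`, `alpha2_1_ext`, `md_fragment`) and reports state which one was
used rather than guessing a single "true" range.

Van der Waals radii are Chothia-type single-element values (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80 Å); unknown elements fall back to 1.70 Å with a
warning (or an error in strict mode). Probe radius 1.4 Å (water).

## Superposition and correspondence

Kabsch superposition minimizes RMSD over proper rotations via SVD; the
determinant is forced to +1 always, even where a reflection would fit
better, because mirror images are not physical poses. Collinear or
fewer-than-three point sets are rejected. Cross-complex superposition uses
Cα atoms of the MHC heavy-chain α1–α2 platform (residues 1–180),
correspondence by author number, with global sequence alignment
(match +1, mismatch −1, gap open −2, extend −1; Biopython PairwiseAligner)
as the fallback when numbering disagrees. Receptor transplantation requires
at least 30 paired Cα atoms; fewer is an error, not a warning, since the
downstream clash verdict depends on the fit.

## SASA and buried surface area

Shrake–Rupley with a deterministic golden-spiral lattice (default 960
points per atom, minimum 92) on the expanded sphere r_vdw + 1.4 Å; heavy
atoms only. A surface point is accessible when outside every neighbor's
expanded sphere; per-atom SASA is the accessible fraction times the
expanded-sphere area. The two-sphere spherical-cap closed form (in
`synthetic`) is the independent oracle: at 960 points the implementation
agrees within 1 % on exposed atoms. Because the point lattice is fixed in
space, SASA is only approximately invariant under rigid motion of the input
(≲ 1–2 % at 960 points); tests and invariants use that tolerance rather
than pretending exact invariance.

Interface area is computed from three SASA evaluations (each side alone in
its bound conformation, then the complex): `BSA_total = SASA_A + SASA_B −
SASA_AB`. Both the total and the half (per-interface) conventions are
always computed and labeled, because "BSA" is used for either in the
interface literature; Fab/antigen interfaces of ~900 Å² are characteristic
of the half convention, which is therefore the default reported value,
with the other always printed beside it. Burial-based footprints use a
ΔSASA > 1.0 Å² threshold and are kept distinct from contact-based
footprints — the two definitions answer different questions and are never
merged.

## Contacts and footprints

A contact is any inter-group heavy-atom pair within 4.0 Å (Euclidean,
inclusive). The spatial-grid (k-d tree) search is required by tests to
match the all-pairs oracle exactly. No angular hydrogen-bond criteria are
applied: deposited models carry no hydrogens, so classification (hbond if
both atoms N/O at ≤ 3.5 Å; salt bridge for Asp/Glu carboxylate against
Lys/Arg/His basic nitrogen at ≤ 4.0 Å, taking precedence) is advisory
metadata and never affects contact existence. Closest-per-residue-pair
reduction breaks distance ties by atom-name pair, lexicographically, so
tables are deterministic.

Cross-complex footprint overlap maps each footprint onto the reference
ligand numbering (by number by default, logged alignment fallback),
intersects and unions the mapped residue sets, and reports the Jaccard
index plus any unmappable residues explicitly — residues are listed, never
silently dropped. The overlap is computed over the whole MHC heavy chain
with an optional α2₁-restricted view printed alongside, since the shared
residues of interest happen to lie on that helix.

## Clash analysis

A pair of atoms clashes when the center distance is below
r_i + r_j − 0.4 Å — the conventional "clash" overlap threshold; a stricter
1.5 Å threshold flags severe overlap. Clashes are binned by (receptor
domain segment × antibody domain segment); the dominant cell names the
blocking domains. KIR domain boundaries (D0/D1/D2) ship as best-effort
hint fixtures under `data/hints/` and are clearly marked approximate —
users analyzing deposited receptor complexes should verify them against
the file.

## SPR single-cycle kinetics

The 1:1 Langmuir surface model is solved in closed form per phase and
chained across the injection series without regeneration, so the trace is
continuous at every boundary. The default schedule is the standard
single-cycle series: five 2-fold steps, 31.25→500 nM, 120 s association +
120 s dissociation, 1 Hz sampling. No mass-transport limitation, baseline
drift, or bulk refractive-index jumps are modeled — the plain 1:1 model is
the fitting target.

Fitting optimizes (log ka, log kd, Rmax, R0) by trust-region least squares
(scipy), with log-parameterization keeping the rates positive without
constraints. Multistart (default 16 restarts) draws initial rates
log-uniformly from ka ∈ [1e3, 1e7] 1/(M·s), kd ∈ [1e-5, 1e-1] 1/s, seeded;
the best restart wins, with early exit on an essentially perfect fit.
Identifiability guards reject single-concentration schedules (ka and kd
are not separable from one phase) and flat traces. Standard errors come
from the Gauss–Newton covariance at the optimum with the delta method for
the log-rates. K_D is computed as kd/ka, exactly, never stored separately.
A table of published equilibrium constants for this antibody/HLA system
(wild type 0.02 µM, position-8 peptide variants ~8–90 nM, HLA-A*02:01
epitope mutants down to 0.007 µM, KIR/HLA 9.5–17 µM) ships as an
annotation fixture with source notes; it is reference metadata, never a
fitting result.

## Trajectory statistics

Trajectories are text-format frame stacks (multi-model PDB, or a plain
XYZ-per-frame dialect: whitespace `x y z` lines, frames separated by blank
or `FRAME` lines). Statistics: per-frame RMSD over a backbone selection
after Kabsch alignment; a density-normalized histogram P(d) whose mean and
SD are the population (ddof = 0) moments of the raw series, never of the
histogram; per-residue RMSF about the mean structure using a two-pass
protocol (align to frame 1 → compute mean → re-align to the mean), with
mean-square fluctuations averaged over each residue's selected atoms before
the square root. The reference choice for RMSF alignment is declared in
output metadata rather than assumed. For isotropic Gaussian jitter of
per-coordinate SD σ the expected RMSF is σ·√3, which the jitter generator
exposes as an exact ground truth; recovery within 5 % at 2000 frames and
amplitude-profile rank correlation > 0.95 over 30 residues are the working
accuracy targets at that problem size. Binary MD formats (DCD/XTC) and any
simulation machinery are out of scope.

## Synthetic generators

The generators emulate exactly the structure the analyses assume: ideal
α-helices (rise 1.5 Å, twist 100°, Cα radius 2.3 Å — consecutive Cα–Cα
≈ 3.8 Å by the chord formula), optionally numbered 141–155 to mimic the
α2₁ helix; toy complexes whose probe residues sit at exact designed
distances from named target atoms, making the expected contact table
derivable from the placement parameters; and Gaussian-jitter trajectories with known
per-residue amplitudes, optionally wrapped in a random global rigid motion
per frame to exercise alignment. Jitter and rigid-motion draws use
independent child RNG streams of one seed, so the underlying fluctuations
are identical with and without the rigid-motion flag. What these fixtures
do **not** emulate: real side-chain rotamers, Ramachandran-valid backbones,
correlated (non-isotropic) fluctuations, mass-transport artifacts in
sensorgrams. Passing tests therefore demonstrate correctness of the
computations, not robustness to every pathology of experimental data.

## Problem sizes and determinism

The test suite and acceptance script run entirely on synthetic inputs at
desk scale: 960–1920 sphere points, ≤ 2000-frame trajectories of ≤ 30
residues, 100-seed kinetic recovery at 1 Hz sampling, chosen so the full
suite completes in well under a minute while keeping Monte-Carlo errors far
below the asserted tolerances. All randomness is seeded (hypothesis runs
derandomized); two runs with the same seed are bit-identical.

Analyses of the deposited antibody/HLA and KIR/HLA structures (residue
counts, interface areas, footprint overlap, transplant clashes) are
implemented and wired into the regression test, but require the coordinate
files to be fetched explicitly (`scripts/fetch_structures.py`); nothing in
the package downloads data implicitly.

## Known limitations

- SASA is lattice-discretized: per-atom values carry ~1 % error at 960
  points and are only approximately rotation-invariant.
- Contact classification is distance-only; PDBsum/HBPLUS-style angular
  criteria are deliberately not reproduced.
- The 1:1 kinetic model cannot represent heterogeneous ligand or bivalent
  analyte binding; fitting such data will produce biased rates.
- Chain-role heuristics assume a classical MHC-I complex composition;
  receptor complexes generally need explicit hints (the MHC heavy chain is
  not reliably the longest chain when a three-domain KIR is present).
- The packaged KIR domain ranges are approximate fixtures, not derived
  from the deposited entries.
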