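# Methods

This note records the models, parameter choices and numerical decisions
behind `tmdock`, and what the synthetic test conditions do and do not
demonstrate about real membrane-protein docking.

## Coordinate conventions and preorientation

All coordinates are Å in a right-handed laboratory frame with the membrane
normal along +z and the bilayer parallel to the x–y plane. Input partners
are expected to be preoriented (OPM-style): the transmembrane-region center
of mass at z = 0. `check_preorientation` reports the mass-weighted z offset
of the TM selection and warns beyond 3 Å rather than failing — a badly
placed structure is still dockable, but the bilayer constraints then act
about the wrong plane, which is the user's call. Mass weighting is the
default because "center of mass" is the conventional reading; a geometric
(unweighted) center is available via `mass_weighted=False`. When no
explicit TM residue range is supplied, the TM region defaults to all
residues whose Cα lies in the slab |z| ≤ 15 Å, a typical bilayer
half-thickness; the range is user-overridable and the default is only a
convenience for well-oriented inputs. Unknown element symbols take
carbon's mass with a warning, so sloppy PDB element columns degrade
gracefully instead of crashing centroid computations.

## Density model

The docking representation is a frame-averaged, weighted Gaussian kernel
density on a regular grid:

ρ(x) = (1/F) Σ_f Σ_a w_a · N(x − r_fa; σ²I),

max-normalized so the isovalue is a fraction of the peak. Defaults:
grid spacing 1.0 Å, kernel σ = 1.8 Å (heavy-atom vdW scale), uniform atom
weights, 8 Å bounding-box padding, isovalue 0.5. Kernels are truncated at
4σ (truncated mass < 1e-4) and accumulated separably per axis, so map
construction is linear in atoms × frames. Before normalization each atom
contributes exactly its weight to the map integral; the test suite checks
Riemann-sum conservation to 2% for σ ≥ 1.5 × spacing.

This is deliberately a *stand-in* field: the published influence-density
maps this engine is designed around also encode electrostatics and
residue-level dynamics, and derive their ideal isovalue from a calibration
against solvent-accessible surface area that is not reproduced here. The
pipeline's downstream contracts depend only on a smooth, ensemble-derived,
normalized scalar field, so the density model is isolated behind
`DensityParams` and a faithful implementation can replace
`build_density_map` without touching anything else. The 0.5-of-max default
isovalue places the surface near the ensemble envelope on these normalized
maps; it is a configuration choice, not a calibrated constant.

Grids are axis-aligned and never rotated — the membrane frame is fixed by
preorientation, and rotating the *ligand pose* (not the map) keeps map
interpolation out of the scoring inner loop entirely: surfaces are
extracted once and their vertices/normals rigidly transformed per pose.

## Surface extraction and scoring

Isosurfaces come from marching cubes on the voxel grid, mapped to
laboratory coordinates. Per-vertex normals are computed from the
central-difference gradient of the map, trilinearly interpolated at each
vertex and oriented down-gradient (outward); gradient normals are more
stable on coarse grids than face-averaged ones. Marching-cubes vertices
lie on grid edges where trilinear interpolation is exactly linear, so the
level-set residual |ρ(v) − iso| is at floating-point scale; the invariant
enforced in tests allows 5% of the isovalue.

The complementarity score of a posed ligand surface against the receptor
surface is

score = Σ_{v : d(v) ≤ d_c} max(0, −n_v · n_r(v)) − λ · #{v inside},

where d(v) is the distance from ligand vertex v to the nearest receptor
vertex, n_r(v) that vertex's outward normal, "inside" means
(v − nearest) · n_r(v) < −clash_depth, d_c = 1.4 Å (half a water
diameter: closer than one water layer counts as contact), clash_depth = 0
and λ = 2. The published score lives in the original method's SI and is
not reproducible from the engine's own sources; this form realizes the
same contract — reward apposed anti-parallel patches, punish overlap, score
exactly zero when separated — with the fewest free parameters, all exposed
in `ScoreParams`. Nearest-vertex queries use a KD-tree built once per
receptor surface; the public single-point query resolves distance ties to
the lowest vertex index so rankings are reproducible, and an O(n) scan
oracle pins this in the tests.

## Search

Pose space is a 7D parameterization: translation
(t_x, t_y, t_z) plus axis–angle rotation about the ligand's TM center of
mass (the origin, by preorientation). Bilayer constraints: t_z ∈ [−5, 5] Å;
the rotation axis precesses at most 0.157 rad from +z; θ ∈ [0, 2π)
periodic. In-plane translation bounds derive from the receptor: ±(E/2 + 5 Å)
with E the larger x/y extent, so the ligand can reach any receptor face
without leaving contact range. Internally the swarm moves in a 6D box —
translations, axis precession, axis azimuth, spin — which makes the
precession cap a plain box bound; poses are exposed in axis-vector form.
Random poses are cap-uniform in the axis (uniform cos precession), uniform
elsewhere.

The optimizer is a global-best PSO with inertia 0.72 and
cognitive/social weights 1.49 (standard constriction-style values; the
swarm literature's defaults, configurable), velocity clamped to half the
range, θ and azimuth wrapped, other dimensions clamped. Kick-and-reseed:
after each iteration, any particle with |v_d| < 4% of the range in every
dimension is converged; its position is recorded as a repulsion site, a
Gaussian penalty (σ = 5% of range in normalized coordinates; height
adaptive at 10% of the best raw-score magnitude seen, floor 1.0) is
subtracted from the objective near that site from then on, and the
particle restarts from a fresh uniform sample with fresh velocity and a
reset personal best (its old best refers to an abandoned basin).
Full-space resampling was chosen over local restarts — the point of the
kick is to push exploration away from exhausted basins. Repulsion sites
persist across the three independent swarm repetitions. Every particle is
evaluated exactly once per iteration, reseeded or not, so the default
schedule (80 × 300 × 3) always spends exactly 72,000 evaluations. Raw
scores are recorded for every pose; swarm dynamics follow the penalized
score, and ranking uses only raw scores. A fixed seed makes the whole
trace bit-identical.

## Ranking

Positive-score poses (surfaces actually in contact) are clustered with
K-means — k-means++ initialization, 10 restarts, 300-iteration cap, fixed
seed — on 8 features: range-normalized translations, the three axis
components (already unit scale), and (cos θ, sin θ) so the angular seam at
0/2π does not split clusters. Each cluster returns its *best-scoring*
member (not the nearest-to-centroid): the shortlist's purpose is diverse
yet high-scoring models, and centroids are not poses that were ever
evaluated. Ties break toward earlier evaluation order. Fewer than k
positive poses are returned as-is; zero positive poses yield an empty
result with a warning — an honest "docking failed" signal rather than
padding.

## Assessment

Contacts are residue pairs with any heavy-atom pair within 5 Å (hydrogens
ignored on both sides so protonated models compare fairly against
crystal-style references). f_nat divides reproduced native contacts by the
*reference* contact count — the CAPRI convention; the looser "per model
residue" reading is available behind `denominator="model_residues"` but is
not the default. Ligand RMSD superposes model receptor Cα onto reference
receptor Cα and measures ligand Cα deviation with no further fitting.
Interface RMSD selects interface residues on the reference only (any heavy
atom within 10 Å of the partner — standard practice, and the only choice
that keeps the selection independent of model quality) and reports the
minimized Cα RMSD after superposing the interfaces. Superposition is
Kabsch via SVD with the RMSD recomputed from residuals — deriving it from
singular values loses half the significant digits to cancellation, which
matters for the 1e-9 oracle agreement the tests demand. Residue
correspondence is by (chain, residue number) and any mismatch is a hard
error; silently intersecting mismatched selections would corrupt RMSD
comparability.

The tier ladder is applied in order with the incorrect gate first:
incorrect if f_nat < 0.1 or (RMSD > 10 and iRMSD > 4); else high if
f_nat ≥ 0.5 and (RMSD ≤ 1 or iRMSD ≤ 1); else intermediate if f_nat ≥ 0.3
and (RMSD ≤ 5 or iRMSD ≤ 2); else acceptable. The AND/OR precedence of the
prose inequalities is ambiguous; this bracketing follows the CAPRI
criteria and is pinned against an independently hand-coded truth table on
a dense metric grid (≈ 11,000 points) in the tests. A model with
excellent f_nat but RMSD > 10 *and* iRMSD > 4 is incorrect under the
printed ladder. Case difficulty is the bound-vs-unbound interface Cα RMSD:
< 1 Å easy, 1–2.5 Å medium, > 2.5 Å difficult.

## Synthetic fixtures — what they show and what they don't

The fixtures replace benchmark structures and MD with minimal geometry:
Cα/Cβ pseudo-atom assemblies (all carbon, so mass weighting is uniform)
spanning the TM slab, origin-centered and z-symmetric so both partners are
preoriented by construction. The `ridge_groove` dimer is two block
lattices (2 Å constant) whose unique ridge-in-groove fit defines a known
bound pose at t = (12.8, 0, 0), θ = 0; `bundle` is three helical rods with
a single-rod ligand in their groove. Rods span z ± 14.25 Å so their ends
stay inside the default TM slab under jitter. Construction verifies the
contact invariant (closest approach in [2, 6] Å, no pair under 1.5 Å) on
every build, and it holds across hundreds of seeds. Ensembles are i.i.d.
per-atom Gaussian jitter, σ = 0.3 Å over 5 frames in the pipeline tests —
enough to exercise frame-averaged map building, but with none of the
correlated, anisotropic fluctuations of real MD. Consequently a passing
pose-recovery test demonstrates that the engine's geometry, scoring,
search and ranking machinery is sound on a strongly complementary
interface; it says nothing about scoring discrimination on flat or
feature-poor biological interfaces, which remains the hard part of the
real problem.

## Operating conditions of the whole-pipeline tests

Whole-pipeline tests and the acceptance script dock the seeded
ridge/groove dimer with the full default search schedule (72,000
evaluations) but reduced-resolution maps (grid 1.5 Å, padding 6 Å), which
keeps a complete run in the tens of seconds while leaving surfaces of
~1,000 vertices per partner — comfortably enough resolution for the 2 Å
lattice features. The determinism check uses a shorter schedule (20 × 30
× 2) since reproducibility is schedule-independent. Under these
conditions the engine recovers the planted pose within the top 10 (in
practice at rank 1, ligand RMSD ≈ 1.3 Å, tier high) with roughly
two-thirds of evaluated poses scoring positive, so the 300-representative
selection always operates on an oversupplied pool.

## Known limitations

- The density stand-in ignores electrostatics and correlated dynamics; the
  isovalue is a configuration default, not SASA-calibrated.
- Docking is strictly rigid; no refinement or flexible-backbone stage.
- The score has no solvation or lipid-specific term beyond what the
  density encodes geometrically.
- K-means representative counts can fall below k if clusters empty
  (reported honestly rather than padded).
- PDB fixed-column output limits coordinates to (−999.999, 9999.999) Å;
  larger values are a hard error rather than silent truncation.
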