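# Methods

This note documents the models, algorithms, parameter choices and limitations
of the exploration engine, in the order the pipeline runs them.

## Structures, connectivity, species identity

A `Structure` is an element list with Cartesian coordinates (Å), charge and
spin multiplicity. Covalent connectivity uses the distance criterion
r<sub>ij</sub> < scale × (r<sub>cov,i</sub> + r<sub>cov,j</sub>) with
scale = 1.2 and RDKit's covalent-radius table; atoms closer than 0.3 Å are
treated as a clash.

A species id is the Weisfeiler–Lehman hash of the element-labeled bond graph
plus charge/multiplicity, so conformers of one molecule coincide and
constitutional isomers split. With chirality enabled, per-stereocenter R/S
parities (keyed by per-node canonical hashes so they survive atom relabeling)
are appended, splitting enantiomers.

Two distinct identity questions arise and get two distinct answers. *"Which
species is this?"* uses the canonical hash above. *"Did this transformation
change anything?"* uses the **labeled** bond set over the indexed atoms: a
degenerate (identity-exchange) reaction such as A + B–C → A–B + C with equal
elements changes which atoms are bonded while leaving the canonical graph
untouched, so the intermediate-proposal and IRC-connection checks compare
labeled bonds. Steps whose two endpoints are nevertheless the same canonical
species are not added to the network (a network edge needs two distinct nodes).

## Function U

U = Σ<sub>bonds</sub> a (r<sub>ij</sub> − r<sub>ij,bond</sub>)² +
Σ<sub>i&lt;j</sub> b / r<sub>ij</sub><sup>n</sup> — harmonic springs over a
declared bond list plus a soft pairwise repulsion. Defaults a = 1.0 Hartree/Å²,
b = 0.3 Hartree·Åⁿ, n = 4; reference lengths are covalent-radius sums unless a
per-element-pair table is supplied. These weights are free choices (the
functional form fixes only the shape); they are exposed in `UParams` and in the
run configuration. The repulsion sum excludes bonded pairs, which would
otherwise be doubly restrained by the spring acting on the same distance.
Relaxation is L-BFGS with analytic gradients; fixed atom sets are honored
exactly, and the relaxed U value never exceeds the input value (enforced — a
failed line search returns the input).

Intermediate proposal edits the bond list: a *form* event adds the pair (the
spring pulls the atoms together), a *break* event removes it and adds a
repulsive bias 2.0/rⁿ on that pair. After the U guess, the pair is nudged
0.05 Å in the event direction before the backend minimization — a guess poised
exactly on a symmetric ridge (the exchange surface at q = 0) would otherwise
relax to an arbitrary side; the nudge commits it to the proposed event and
keeps the pipeline deterministic.

## Calculator contract and analytic backends

All numerics run through a `Calculator`: energy, gradient (analytic in every
built-in backend), L-BFGS minimization, SLSQP constrained minimization with
the pair distance restored exactly afterwards by a symmetric projection along
the pair axis, finite-difference Hessians (step 0.005 Å), mass-weighted
frequency analysis with translation/rotation projected out (linearity detected
from the inertia tensor), and eigenvector-following saddle refinement
(partitioned rational-function step in the internal-coordinate subspace, trust
radius 0.1 Å, convergence at max internal gradient < 10⁻⁴).

Built-in surfaces, all functions of interatomic distances only (hence exactly
invariant under rotation, translation and reflection — the property the
enantiomer-energy checks rely on):

- **double_well** — diatomic, E(r) = A((r − c)² − w²)²; equal minima at c ± w,
  closed-form barrier A·w⁴. Defaults c = 1.8 Å, w = 0.6 Å, A = 0.16 Hartree/Å⁴
  (barrier ≈ 0.021 Hartree). Carbon atoms, not hydrogen, so the bonded well
  (1.2 Å) sits inside the covalent connectivity threshold and the outer well
  (2.4 Å) outside — the element choice is part of the fixture design.
- **triatomic_exchange** — collinear exchange in the two bond lengths with a
  quartic double well along the asymmetric stretch q, a harmonic symmetric
  stretch, and a collinearity restraint k<sub>b</sub>(r₁₂ + r₂₃ − r₁₃) that is
  zero exactly on collinear arrangements (triangle equality) and harmonic in
  bending. One imaginary mode at the saddle, barrier A·w⁴.
- **pseudo_reaction** — harmonic spectator bonds plus *reactive pairs* carrying
  a radial double well with a bonded and a nonbonded minimum and an optional
  linear tilt (nonzero reaction energy). Beyond the outer minimum the term is
  held constant (C¹ plateau): a real nonbonded interaction is flat at long
  range, and an unbounded quartic wall would punish unrelated fragment motion.
- **upotential** — U itself over a frozen bond list.

The tight-binding adapter (`potentials.xtb_adapter`) shells out to an
xtb-style binary, exchanging XYZ and Hartree, and records the engine/level in
the structures it touches. It is optional; nothing in the package or the test
suite requires an engine binary, and its wire protocol is tested against
canned transcripts.

## Conformers and chirality

Only active-site-relative arrangements are sampled: the fragment holding atom j
(split at connectivity components, or at the smallest edge cut between i and j,
preferring the most balanced cut among equal-size ones) is revolved around the
fragment holding atom i while spinning about the pair axis, on a default
6 × 6 × 1 grid. Each pose is U-relaxed with the pair atoms immobilized, scored
by the calculator, cut at min + 0.01 Hartree, and pruned at 0.1 Å
distance-matrix RMSD (√mean<sub>i&lt;j</sub>(Δr<sub>ij</sub>)², superposition-
free). Grid sampling is uniform and seed-free by design, so conformer sets are
reproducible. Whole-backbone conformational search is out of scope. The grid
density, window and RMSD cut are engineering defaults exposed in configuration;
none is dictated by the method itself.

Stereocenters are tetravalent carbons whose four branches have pairwise
distinct canonical hashes; parity is the sign of the signed volume over the
three highest-priority neighbors, with priority = (atomic number, atomic
weight, branch hash). This is a simplified priority scheme, not full CIP:
ties that full CIP would resolve by duplicated-atom rules are resolved by the
branch hash instead, which is consistent and deterministic but can disagree
with CIP labels on contrived inputs; within one run it always separates
enantiomers correctly, which is all the engine needs. Enantiomers are
generated by mirror + U-relax and emitted only when the mirrored chiral id
differs (a meso-like arrangement yields nothing). The rotation test classifies
two steps by rigid superposition of their endpoint minima — identical if they
match directly, enantiomeric if only after reflection (tolerance 0.2 Å).
Endpoints, not TS structures, carry the comparison, because a step's identity
is defined by what it connects.

## Active-learning TS sampling

For one event: propose IM; seed probes at s = 0 (IN), s = 1 (IM) and the
golden-section point s = 2 − φ ≈ 0.381966 nearer IN, each probe built by
linear interpolation after rigid (Kabsch) alignment of IM onto IN and then
constraint-minimized with the pair distance frozen at its interpolated value.
Iterate (default cap 8): fit the parabola through the three consecutive probes
bracketing the running maximum (exact vertex −B/2A; a boundary maximum
densifies the adjacent interval at its golden point instead — a profile with
no interior maximum therefore fails cleanly with "no bracket"); build and
constrain-optimize the vertex structure; refine to a saddle; validate. A
failed candidate becomes a new probe at its orthogonal projection onto the
IN→IM segment, clipped into (0, 1). The sampler contains no randomness:
identical inputs give bitwise-identical probe sequences.

Validation is two-step: (1) per-atom weights are the squared norms of each
atom's block of the imaginary eigenvector; the active pair's weight
w(i) + w(j) must rank within the top 10 of all atom-pair weights (ties share
the better rank; ranking per atom instead of per pair is available as an
argument, since the ranking basis is a genuine design freedom); (2) only then,
the full frequency analysis must show exactly one imaginary mode, counting
|ν| > 30 cm⁻¹ to exclude numerical noise in soft/flat modes.

IRC connection displaces ±0.05 Å along the Cartesian image of the imaginary
mode and walks damped steepest descent (step cap 0.02 Å) into the two minima,
then polishes with the minimizer. This is a connectivity check, not a
mass-weighted IRC integration — the documented stand-in. The step's barrier is
E(TS) − E(connected reactant minimum); a validated saddle is never below
either endpoint.

## Exploration, filtering, network

Breadth-wise recursion: frontier species → active pairs → conformers (worker
pool `npool`) → TS searches + IRC (pool `npool_tes`) → filter → dedup → admit
products to the next frontier. Both pools are pure, order-preserving maps over
deterministic task lists, so serial and parallel runs build identical networks.
The barrier filter keeps steps with barrier ≤ threshold (ties kept); it can
prune during exploration or only annotate at reporting time (default:
reporting, so the full network is preserved). Dedup treats two steps as the
same channel when endpoints match and TS energies agree within 10⁻⁴ Hartree
(also the edge-key bucket width); with chirality on, the rotation test keeps
mirror-image channels as distinct tagged edges. A frontier admission window
(default 0.15 Hartree above the lowest species, switchable off) prevents
runaway exploration through absurdly high-energy products. Pathways are simple
paths whose edges all pass the threshold, ranked by effective span
(max E(TS) − E(source)) ascending, ties by total ΔE.

## What the fixtures do and do not show

The analytic scenarios exercise every pipeline stage with independently
grid-scanned oracles, at desk scale: the 24-case battery (diatomic double
wells in both event directions, collinear exchanges, separable tilted
pseudo-reactions) checks the sampler's saddle energies to 10⁻⁴ Hartree and its
success rate; the pseudo-cycloaddition's two channels (0.0459 / 0.0696 Hartree)
are built so the 0.04 / 0.05 / 0.08 Hartree thresholds partition them 0/1/2.
Passing these certifies the search, validation, connection and bookkeeping
machinery — not chemical accuracy on real systems, which depends entirely on
the attached electronic-structure backend, nor performance at the scale of
thousand-step networks, where the recursion cost grows exponentially with
depth. Problem sizes throughout (2–4 atoms, depth 1–2, 24 battery cases) are
the package's own desk-scale choices.

## Known limitations

- No DFT, solvation, thermochemistry (ZPE, free energies) or rate constants;
  electronic energies only.
- Single fixed spin multiplicity per exploration; surface crossings between
  multiplicities are out of scope.
- Bond orders are not perceived on mid-exploration structures; rule SMARTS
  should use generic bonds and connectivity primitives.
- One bond event per elementary step; concerted multi-bond chemistry is
  expressed as several rules firing at the same depth.
- The rotation test assumes consistent atom ordering between the compared
  steps (true within one exploration).
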