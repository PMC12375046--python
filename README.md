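# rxnpath

Rule-guided automated exploration of multi-step reaction pathways on potential
energy surfaces (PES), for computational chemists who want mechanism networks —
species, transition states (TS), barriers — generated systematically instead of
one hand-built saddle search at a time.

## What it does

Starting from one or more seed systems (SMILES or XYZ), the engine repeats a
three-stage cycle to a configurable depth:

1. **Chemical logic.** A library of SMARTS rules, each naming two mapped atoms
   and a bond `form`/`break` action, is matched against the current species;
   all distinct *active pairs* (i, j, action) are enumerated and deduplicated.
2. **TS location.** For each pair (and each active-site conformer, generated by
   spin/orbit rotation of one fragment around the other), the product-side
   intermediate IM is proposed with the pseudo-potential

   *U* = Σ<sub>(i,j)∈bonds</sub> a (r<sub>ij</sub> − r<sub>ij,bond</sub>)² + Σ<sub>i&lt;j</sub> b / r<sub>ij</sub><sup>n</sup>,

   and the saddle between the input minimum IN (s = 0) and IM (s = 1) is found
   by *active-learning sampling*: a constrained probe at the golden-section
   point s = 2 − φ ≈ 0.382, a parabola through the three probes bracketing the
   running energy maximum, eigenvector-following refinement at the parabola
   vertex, and recycling of failed candidates as new probes. A candidate is
   accepted only if the active pair's weight in the imaginary eigenvector ranks
   in the top 10 of all atom-pair weights *and* the frequency analysis shows
   exactly one imaginary mode.
3. **Connection and filtration.** Each validated TS is connected to its two
   minima by an intrinsic-reaction-coordinate descent; steps are filtered by a
   barrier threshold (Hartree), deduplicated (optionally resolving mirror-image
   channels when `chiral` is on), and the new species seed the next depth.

The result is a species/step multigraph with full provenance, exportable to
JSON, GraphML and multi-frame XYZ, with ranked pathway extraction.

Energies are Hartree internally (1 Hartree = 627.509 kcal/mol); every numerical
stage talks to a pluggable `Calculator`, with built-in analytic surfaces for
development and testing and an optional subprocess adapter for GFN2-xTB-class
tight-binding engines.

## Worked example

Explore the built-in four-atom pseudo-cycloaddition scenario (two C₂ fragments,
two competing cross-fragment C–C bond-forming channels with different barriers):

```bash
$ rxnpath explore --fixture pseudo_cycloaddition --out net
2 species, 2 step(s) -> net

$ rxnpath report net/network.json --source <seed-species-id> --barrier-thresh-hartree 0.08
2 step(s) under 0.08 Hartree
  1cc43c7d6f8a.. -> f5fd1ebaf587..  barrier   28.79 kcal/mol  span   28.79 kcal/mol
  1cc43c7d6f8a.. -> f5fd1ebaf587..  barrier   43.68 kcal/mol  span   43.68 kcal/mol
```

The two edges are the two reactive channels: 0.0459 Hartree (28.79 kcal/mol)
and 0.0696 Hartree (43.68 kcal/mol), each located by the active-learning
sampler and matching the scenario's dense-grid oracle saddle to better than
1 × 10⁻⁶ Hartree. Filtering at 0.05 Hartree keeps only the first channel;
at 0.04 Hartree neither survives.

A single-event search on the diatomic double-well surface:

```bash
$ rxnpath fixture double_well --out fx
$ rxnpath locate-ts fx/seeds.xyz --pair 0,1,break --backend double_well --out ts.xyz
validated TS: E = 0.02073600 Hartree (13.01 kcal/mol), nimag=1, pair rank=1 -> ts.xyz
```

which is the closed-form barrier A·w⁴ of that surface to machine precision.

## Layout

| module | contents |
| --- | --- |
| `rxnpath.rules` | SMARTS rule library, active-pair enumeration |
| `rxnpath.potentials` | `Structure`, function U, connectivity/species identity, calculator contract, analytic backends, tight-binding adapter |
| `rxnpath.conformers` | active-site conformer generation, chirality (detection, enantiomers, rotation test) |
| `rxnpath.tslocate` | active-learning TS sampler, two-step validation, IRC connection |
| `rxnpath.explorer` | recursive parallel exploration, network, filtering, dedup, pathways |
| `rxnpath.iohub` | XYZ/SMILES/YAML I/O, fixtures and oracles, CLI |

See `docs/methods.md` for the model details, parameter choices and limitations.
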