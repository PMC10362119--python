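# Methods

This note records the model implemented by `hydroshell`, the parameter
choices that matter, the numerical conventions, and what the synthetic
fixtures do and do not demonstrate.

## Model

The working hypothesis is that protein–protein association is guided by
hydrophobic collapse between *low-entropy regions* of the partners'
hydration shells. Water hydrogen-bonded into ordered cages around nonpolar
surface groups has a molar entropy near that of solid water
(S_solid ≈ 41 J mol⁻¹ K⁻¹) versus bulk liquid (S_liquid ≈ 70 J mol⁻¹ K⁻¹);
expelling such a water to bulk gains ΔS = 29 J mol⁻¹ K⁻¹, i.e.
TΔS = 8961 J mol⁻¹ per mole of water at T = 309 K. `hydration_free_energy`
is exactly this arithmetic, linear in the number of waters released.

A surface patch carries a low-entropy shell when it exposes only
hydrophobic atoms and *pseudohydrophilic* polar atoms. A polar (N/O)
surface atom is pseudohydrophilic when any of these rules fires:

* **R1 (hydrogen-bond saturation).** It participates in an intramolecular
  hydrogen bond. Detection is geometric and heavy-atom only: N/O pairs of
  different residues within 3.5 Å, requiring one plausible donor (any N,
  or a Ser/Thr/Tyr hydroxyl O) and excluding the covalent peptide
  C=O(i)···N(i+1) pair. No angle criterion is used because most X-ray
  inputs carry no hydrogens; 3.5 Å is the common heavy-atom cutoff and is
  configurable. A bond whose partner is buried still saturates the surface
  atom, so it counts; each bond records whether either partner is on the
  surface.
* **R2 (backbone shielding).** It is the backbone carbonyl O or amide N of
  a residue whose side chain is hydrophobic enough to shield the backbone
  from water: Ile, Val, Leu, Phe, Tyr, Trp, Cys, Met, Lys, Arg, His, Pro,
  Ala — plus Gly, whose hydrophilicity is very weak. The set is exposed as
  configuration (`shielded_residues`) because the Gly membership is the one
  genuinely debatable entry. Each chain's N-terminal amide N and any OXT
  stay genuine: charged termini are strongly hydrated.
* **R3 (long-side-chain tips).** Trp NE1, Tyr OH and Lys NZ: single polar
  tips carried by long alkyl/aromatic side chains whose own low-entropy
  cage fixes the neighboring waters.
* **R4 (absorption).** After R1–R3, any remaining genuine hydrophilic atom
  whose entire surface-graph neighborhood (≥ 1 neighbor) is low-entropy is
  absorbed, iterated to a fixed point. The low-entropy set only grows, so
  the iteration terminates and the result is idempotent.

Arg/His side-chain polar atoms remain genuine unless R1/R4 fires — they
appear only in the backbone-shield list. The speculative idea that a pair
of like-charged side chains close in space might also lose hydrophilicity
is deliberately not implemented.

Low-entropy regions are the connected components of the surface neighbor
graph restricted to hydrophobic + pseudohydrophilic atoms, measured by the
sum of member per-atom SASA and ranked by decreasing area (ties broken by
the lower minimum atom serial for determinism). "Large" is operationalized
as top-k (default k = 3) with a minimum area (default 200 Å²), both
configurable; binding-site prediction returns the top-ranked region(s).

Two spatial-layout rules score a candidate pose of B against A:

1. the native pose maximizes the overlap of one large low-entropy region of
   each partner — measured as the buried SASA restricted to low-entropy
   atoms of either partner that contact a low-entropy atom of the other
   within the contact cutoff;
2. the pose must allow sufficient interfacial contact — measured as total
   buried SASA, SASA(A) + SASA(B) − SASA(AB).

A hard-core clash count (cross pairs closer than 0.6 × the sum of vdW
radii) guards against degenerate placements; a pose with coincident atoms
is rejected outright (zero areas, positive clash count).

The verification statistic for native complexes is the hydrophilicity
ratio: genuine-hydrophilic area divided by low-entropy area, accumulated
over the unbound monomer surface, inside the binding site versus outside.
The model predicts ratio_in ≪ ratio_out. A zero denominator is reported as
missing (NaN) rather than inventing a value.

## Parameters and defaults

| parameter | default | units | why |
| --- | --- | --- | --- |
| probe_radius | 1.4 | Å | water probe, community standard |
| n_points | 960 | – | Shrake–Rupley quadrature; doubling changes totals < 1 % |
| surface_threshold | 1.0 | Å² | excludes numerically grazed buried atoms |
| adjacency_cutoff | 5.0 | Å | one water diameter + bond length; makes contiguous patches |
| hbond_cutoff | 3.5 | Å | heavy-atom donor–acceptor convention |
| contact_cutoff | 5.0 | Å | common heavy-atom interface definition |
| vdW radii | C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 | Å | Bondi-style; unknown element → 1.70 with warning |
| S_solid, S_liquid, T | 41, 70, 309 | J mol⁻¹ K⁻¹, K | standard molar entropies of solid/liquid water; body temperature |
| hit threshold | recall ≥ 0.5 | – | operational definition of a successfully predicted site |
| k, min_area | 3, 200 | –, Å² | "large regions" per typical per-protein displays |

## Numerical choices

* SASA uses a fixed golden-section spiral point set — no RNG anywhere in
  the pipeline, so results are bit-stable across runs and atom orders. A
  sample point is accessible iff strictly outside every other inflated
  sphere. Two atoms at numerically identical coordinates (< 10⁻³ Å) are an
  input error.
* Structure sanitization keeps the first model only, resolves altlocs by
  highest occupancy (ties: lexicographically first), strips waters, hetero
  atoms, hydrogens and non-standard residues (warned), and is idempotent.
* Per-atom labels are encoded in the PDB B-factor column as 0 buried /
  1 hydrophobic / 2 pseudohydrophilic / 3 genuine hydrophilic — a bijective
  code that round-trips exactly.
* Graph edges use ≤ cutoff semantics; KD-trees make all neighbor searches
  independent of atom order.
* Region ranking ties break on the minimum atom serial; all downstream
  operations treat atom sets, not orders.

## Synthetic fixtures: what they show and what they don't

All tests run on generated structures, deterministic given their
parameters and seed:

* **Ideal peptides** (helix φ = −57°, ψ = −47°; extended φ = −135°,
  ψ = 135°) built from standard internal coordinates with single default
  rotamers. The 10-residue polyalanine helix exhibits the O(i)···N(i+4)
  ladder at 2.7–3.2 Å, validating the hydrogen-bond detector against an
  independent geometry check.
* **Residue panel**: well-separated single residues (Leu, Ser, Tyr, Lys,
  Gly) plus an Asp/Asn pair placed with OD1···ND2 at exactly 3.0 Å —
  every screening rule fires on its designed target and nowhere else.
* **Two-cap ball**: a Fibonacci-lattice sphere (radius 10 Å) with two
  antipodal nonpolar caps separated by a polar belt wider than the
  adjacency cutoff; region mapping must recover exactly the two caps with
  areas equal to the per-cap SASA sums.
* **Toy complexes**: two mostly polar balls (160 pseudo-atoms each,
  radius 10 Å, coordinate jitter σ = 0.15 Å, 12 % hydrophobic sprinkle
  outside the patch) bound patch-to-patch at 4 Å separation, patch arc
  radius 6 Å. Across seeds these give ratio_in < ratio_out, rank-1-region
  recall of the true interface ≥ 0.5, and a matched pose whose low-entropy
  overlap beats rotated decoys.

These fixtures demonstrate the *mechanics* of the method — rule
correctness, clustering, statistics, scoring — under geometry where the
ground truth is known by construction. They do not demonstrate performance
on real proteins: pseudo-atom balls have no backbone, no rotamer
diversity, no marginal surface exposure, and their interfaces are designed
to be hydrophobic. Real-structure behavior depends on crystallographic
artifacts (missing atoms, altlocs, non-standard residues) that
sanitization handles but the fixtures do not stress. The batch path for
real PDB files (`hydroshell map/predict/stats`) is functional but its
accuracy claims rest on the original large-scale analyses, not on this
test suite.

## Known limitations

* Hydrogen-bond detection has no angle term and treats any heavy-atom N/O
  pair within the cutoff as one bond; this overcounts marginal geometries.
* Per-residue granularity is not modeled: labels, regions and statistics
  are atom-level (residue rollups are derived views).
* Pose *search* is out of scope — only scoring of supplied rigid poses.
* No electrostatics, pKa, explicit water, or per-water entropy estimates;
  the energetics operation is bookkeeping over a fixed ΔS, not a solvation
  model.
* SASA is solvent-accessible area only; no molecular-surface (SES)
  triangulation.
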