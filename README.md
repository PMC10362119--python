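# hydroshell

Mapping **low-entropy hydration-shell regions** on protein surfaces, and
using them to analyze and predict protein–protein binding sites.

## The scientific problem

Water adjacent to a hydrophobic patch of a protein surface forms an
ordered, cage-like hydrogen-bond network: its molar entropy is close to
that of solid water (S ≈ 41 J mol⁻¹ K⁻¹) rather than bulk liquid water
(S ≈ 70 J mol⁻¹ K⁻¹). When two such patches meet, the ordered waters are
released to bulk, the system gains entropy, and the patches stick — the
hydrophobic driving force of protein–protein association. Releasing one
mole of shell water gains

ΔS = S_liquid − S_solid = 70 − 41 = 29 J mol⁻¹ K⁻¹,  TΔS = 8961 J mol⁻¹ at T = 309 K.

The non-obvious part is deciding *which* parts of a protein surface carry
a low-entropy shell. Counting polar (N/O) atoms is not enough, because many
polar surface atoms are **pseudohydrophilic** — they cannot actually
hydrogen-bond with water:

* **R1** — their hydrogen-bonding capacity is saturated by an
  *intramolecular* hydrogen bond (heavy-atom N/O···N/O distance ≤ 3.5 Å);
* **R2** — they are backbone carbonyl O / amide N atoms shielded by the
  protruding hydrophobic side chain of their own residue
  (Ile, Val, Leu, Phe, Tyr, Trp, Cys, Met, Lys, Arg, His, Pro, Ala, Gly);
* **R3** — they are the single polar tip of a long hydrophobic side chain
  (Trp NE1, Tyr OH, Lys NZ), embedded in the ordered cage of their own
  alkyl/aromatic moiety;
* **R4** — they are isolated genuine hydrophilic atoms whose entire surface
  neighborhood is already low-entropy (absorbed by their surroundings).

After screening these off, the surface decomposes into contiguous patches
of hydrophobic + pseudohydrophilic atoms — the **low-entropy regions** of
the hydration shell — and the largest such regions are where binding
happens: binding sites show a much lower ratio of genuine-hydrophilic to
low-entropy surface area than the rest of the surface, and a native pose
maximizes the overlap of one large low-entropy region of each partner
while keeping sufficient interfacial contact.

## What the package does

| stage | module | operation |
| --- | --- | --- |
| read / sanitize PDB & mmCIF | `hydroshell.structure_io` | `read_structure`, `sanitize` |
| per-atom SASA (Shrake–Rupley, deterministic spiral) | `hydroshell.surface` | `compute_sasa`, `surface_neighbor_graph` |
| screening rules R1–R4 | `hydroshell.labeling` | `detect_intramolecular_hbonds`, `screen_pseudohydrophilic`, `absorb_isolated_hydrophilic` |
| patch clustering & ranking | `hydroshell.regions` | `map_low_entropy_regions`, `largest_regions` |
| interface stats, prediction, pose scoring, energetics | `hydroshell.interface_analysis` | `hydrophilic_area_ratio`, `predict_binding_site`, `score_pose`, `hydration_free_energy` |
| synthetic test structures | `hydroshell.fixtures` | `make_helix`, `make_two_cap_ball`, `make_toy_complex`, … |

Everything is testable offline: the `fixtures` module generates ideal
peptides (internal-coordinate geometry), pseudo-atom spheres with known
ground-truth labels/regions, and toy complexes with known interfaces.

## Worked example

Generate a toy complex (two mostly polar balls bound patch-to-patch), map
its low-entropy regions, and compute the interface ratio statistic:

```sh
hydroshell fixtures toy_complex --seed 7 -o toyAB.pdb
hydroshell map toyAB.pdb --raw -o toyAB
```

```
 rank  n_atoms  n_residues       area  surface_fraction
    1       33          33 522.173409          0.091521
    2       13          13 276.119160          0.048395
    3        4           4  91.704268          0.016073
    ...
```

The rank-1 region (522 Å², 9 % of the surface) is the designed hydrophobic
patch — the binding site. The ratio statistic confirms the direction the
method predicts (hydrophilicity ratio *inside* the binding site far below
the ratio *outside*):

```sh
hydroshell stats toyAB.pdb -a A -b B --raw
# "partner_A": { "ratio_in": 0.0, "ratio_out": 4.24, ... }
```

And the entropic free energy of expelling 5 ordered shell waters:

```sh
hydroshell energy --n-waters 5
{
  "delta_S_per_mol": 29.0,
  "T_delta_S_per_mol": 8961.0,
  "total": 44805.0,
  "n_waters": 5,
  "T": 309.0
}
```

`hydroshell map` also writes a label-annotated PDB (labels encoded in the
B-factor column: 0 buried, 1 hydrophobic, 2 pseudohydrophilic, 3 genuine
hydrophilic) and a PyMOL `.pml` script coloring each region, plus a JSON
summary echoing every configuration value. For real PDB entries drop
`--raw` so waters, hetero atoms, hydrogens and altloc duplicates are
cleaned first, e.g. `hydroshell predict my_protein.pdb -k 3`.

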