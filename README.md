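# poreblock

Analysis of hydrophobic pore blockade in K⁺ channels from molecular-dynamics
trajectories, paired with the single-channel electrophysiology fits used to
characterise a pore blocker.

## The problem

Small hydrophobic molecules can inhibit a large-conductance Ca²⁺-activated K⁺
(BK_Ca) channel without physically closing its gate: by partitioning into the
inner pore they displace water, and a sufficiently dewetted pore segment
becomes an energetic barrier to ion conduction (hydrophobic gating).
Demonstrating this mechanism from simulation requires a small set of
well-defined trajectory statistics, and from experiment a handful of standard
single-channel fits.  `poreblock` implements both ends for people analysing
channel-blocker MD simulations and patch-clamp recordings:

- **Pore hydration** — the number of water molecules inside a z-aligned
  analysis cylinder (default radius 10 Å, height 12 Å) re-centred every frame
  on the centroid of the four pore-lining reference Cα atoms (Tyr318 in human
  Slo1 numbering).
- **Cavity volume** — a grid estimate on a 2.0 Å lattice inside the same
  cylinder, excluding points within (vdW radius + 1.0 Å) of any protein atom;
  volume = free points × spacing³.  Waters, ions, lipids and ligands do not
  occlude.
- **Water density** — hydration count divided by cavity volume, per frame.
- **Windowed statistics** — μ/σ over the final 25% of frames, compared across
  conditions with Cohen's d, `d = (X̄₁ − X̄₂)/SD_pooled`,
  `SD_pooled = √((SD₁² + SD₂²)/2)`, classified small/medium/large at
  |d| = 0.2/0.5/0.8.
- **Ligand geometry** — ligand geometric centres relative to the pore centre;
  phenyl-ring/ring and carbonyl-oxygen/K⁺ distance series; 2D distance
  histograms with their major density maxima (π-stacking and ion-coordination
  signatures).
- **K⁺ permeation** — per-ion axial traces and complete-pass counting (from
  z ≥ +20 Å to z ≤ −20 Å across the membrane span, radially gated, with
  hysteresis so each traversal counts once).
- **Electrophysiology** — Hill concentration–response
  `f = I_max·c^n_H/(IC₅₀^n_H + c^n_H)`, single-exponential dwell-time
  constants (MLE), open probability NPo, and I–V conductance by linear
  regression.

Because the underlying channel trajectories of such studies are rarely
deposited, the package ships a **synthetic pore-trajectory generator** that
plants every analysed feature (inside-water counts, ligand placements,
ion-crossing events) with exact ground truth, so the whole analysis chain is
testable end to end.

## Worked example

```bash
python examples/01_pore_hydration.py
```

```
frames analysed:        100
mean waters in pore:    30.0
planted mean:           30.0
frames recovered exact: 100%
```

The generator planted 30 waters inside the analysis cylinder on every frame;
the counter recovers exactly that on all 100 frames — the cylinder it counts
in is the same dynamically centred region the generator filled.  The other
examples cover cavity volume and density (`02`), ligand interaction geometry
(`03`), permeation counting across a 0/1/2/4-ligand-copy grid (`04`), the
electrophysiology fits (`05`), and the full condition-grid pipeline with the
Cohen's d table (`06`), e.g.:

```
0 ligand copies: 4 complete passes (planted: 4; ions considered: 4)
1 ligand copies: 4 complete passes (planted: 4; ions considered: 4)
2 ligand copies: 3 complete passes (planted: 3; ions considered: 4)
4 ligand copies: 0 complete passes (planted: 0; ions considered: 4)
```

Pass counts fall with ligand occupancy and vanish at four copies — the
blocked-pore regime.

## Command line

A thin CLI wraps the library for shell use:

```bash
poreblock generate --out out/ --seed 7            # synthetic system (PDB+DCD+JSON)
poreblock analyze --topology t.pdb --trajectory x.dcd --out out/
poreblock permeation --topology t.pdb --trajectory x.dcd --out out/
poreblock stats --kind hill --input dose_response.csv
poreblock all --config run.yaml --out out/ --seed 11
poreblock report --out out/
```

`run.yaml` lists conditions (synthetic configs or real topology/trajectory
paths), cylinder/grid geometry, window fraction and permeation thresholds;
reruns with the same config and seed are byte-identical.

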