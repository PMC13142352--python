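# Methods

## The analysis cylinder

All pore metrics are computed inside a cylinder aligned with the global z
axis (the membrane normal) and re-centred on every frame at the centroid of
the four pore-lining reference Cα atoms, one per subunit (Tyr318 in human
Slo1 numbering; the residue is configurable because construct numbering and
even the identity of the pore-lining reference differ between structures).
Defaults are radius 10 Å and height 12 Å, which span the central cavity of a
BK-type pore.  Two radius modes exist: `fixed` (the default, the 10 Å
radius) and `adaptive` (the mean xy-distance of the four reference Cα atoms
from their centroid, so the radius breathes with the pore).  Both are
provided because a hydration cylinder "large enough to track the fluctuating
pore" can be formalised either way; the fixed mode is the default for
internal consistency with the volume estimate, which uses fixed geometry.

Boundary conventions are part of the contract and are exact: a water oxygen
at xy-distance equal to the radius, or |Δz| equal to height/2, is **inside**;
a grid point at distance exactly (vdW + buffer) from a protein atom is
**occluded**.  Stating the tie-breaks makes recovery tests exact rather than
tolerance-based.

Waters are represented by their oxygen atom only (one molecule ↔ one counted
point).  Periodic images are not unwrapped; analyses assume the pore region
does not cross the box boundary.  The synthetic generator guarantees this;
real input must be pre-imaged.

## Grid cavity volume

The volume estimate lays a cubic lattice (default spacing 2.0 Å) over the
cylinder, anchored at the per-frame centre so the grid translates rigidly
with the pore.  Lattice points sit at **cell centres** (odd multiples of
spacing/2 from the centre): each point then represents a disjoint spacing³
cell, and the empty-cylinder estimate converges to the analytic πr²h as
spacing → 0 (within 2% at 0.5 Å for r = 10 Å, h = 12 Å).  A corner-anchored
lattice with inclusive boundaries would instead converge to πr²(h + s) —
a systematic one-spacing overestimate in each axis — which is why cell
centres were chosen.

Points within (vdW radius + 1.0 Å probe buffer) of any protein atom are
removed; waters, ions, lipids and ligands never occlude.  Van der Waals
radii are the Bondi set (C 1.70, N 1.55, O 1.52, H 1.20, S 1.80, P 1.80,
K 2.75 Å) with 1.50 Å for unknown elements (logged).  The neighbour search
uses a `scipy.spatial.cKDTree` queried at max(vdW) + buffer followed by an
exact per-atom check, so results are identical to the all-pairs test (the
unit tests assert this against a brute-force lattice oracle).

Water density is count/volume per frame; zero-volume frames are flagged
undefined (NaN) rather than zero and are excluded from window summaries.

## Windowed summaries and effect sizes

Summaries are taken over a contiguous fraction-of-frames window, by default
the final 25% (500 frames of a 2000-frame trajectory), after the system has
settled; σ is the sample SD (n−1).  Cohen's d uses the equal-n pooled SD
√((SD₁² + SD₂²)/2) by default — the reading consistent with "a weighted
average of standard deviations" for two equal-length windows — with the
quadrature sum √(SD₁² + SD₂²) available behind a flag for comparison with
sources using that convention.  |d| is classified by the conventional
0.2 / 0.5 / 0.8 thresholds (boundaries belong to the higher class, so
d = 0.5 is "medium").

## Permeation counting

Axial traces are referenced to the per-frame pore centre (z = 0 at the
pore-centre plane, positive toward the selectivity filter).  Region labels:
`filter` for z > height/2, `pore` for |z| ≤ height/2 within the radius,
`outside` otherwise.  A complete pass takes an ion from z ≥ +20 Å to
z ≤ −20 Å (the membrane faces) or the reverse, while staying within a 10 Å
radial cutoff whenever it is strictly between the planes; leaving the cutoff
voids the attempt.  The arming frame refreshes while the ion remains beyond
the entry plane, so `start_frame` is the last frame on the entry side, and
hysteresis ensures each traversal counts once: after completing a pass the
ion must re-cross the far plane before another pass in the same direction
can begin.  Ions that end a trajectory between the planes are in transit,
not events.  By default only ions whose first frame lies in the filter
region contribute to the headline count (the filter-resident convention); a
flag includes all ions.  No numerical pass criterion is standard in the
literature, so these thresholds are package decisions, chosen to equal the
membrane span and pore radius defaults.

## Ligand geometry

Ligand centres are unweighted means of the copy's atoms, reported relative
to the per-frame pore centre.  Ring groups are the six ring heavy atoms only
(no substituents); carbonyl-oxygen groups are the two ligand oxygens.
Distance series reduce each group to its centre first; `all-pairs` emits one
series per pair (unordered pairs when a group list is compared with itself),
`nearest` the per-frame minimum.  2D distance histograms use 0.25 Å bins and
report maxima that dominate their 8-neighbourhood and hold ≥ 1% of all
points; maxima closer than two bins are merged keeping the higher count, to
avoid double-reporting plateaus.  Bin width and threshold are package
defaults (no published values exist); both are parameters.

## Electrophysiology fits

*Hill.*  f(c) = I_max·c^n_H / (IC₅₀^n_H + c^n_H), least squares with bounds
I_max ∈ (0, 1], IC₅₀ > 0, n_H > 0 and multi-start initialisation (n_H grid ×
concentration-quantile IC₅₀ guesses) because the sigmoid has local minima.
I_max is capped at 1 (an inhibited fraction cannot exceed the full signal;
partial blockers simply fit I_max < 1).  The convergence flag is false when
the response range is < 0.1 — a flat curve leaves IC₅₀ unidentified, the
regime seen at potentials where block is already near-maximal at the lowest
tested concentration — or when IC₅₀/n_H are pinned at the box bounds.
Replicate points are fitted individually, not averaged.

*Dwell times.*  Single-exponential τ by maximum likelihood, which for an
exponential is the sample mean — binning-free, exactly testable (τ̂ of
{1, 2, 3} ms is exactly 2 ms), and unbiased.  At least 10 events are
required by default.

*NPo.*  Σ(open level × duration)/record duration from an idealised event
list; stacked openings of k channels contribute level k.  Reported
unnormalised by channel count.

*Conductance.*  Ordinary least-squares slope of current (pA) against voltage
(mV), converted to pS (× 1000), with intercept and r².

## The synthetic generator

The generator emulates the *analysed geometry* of a tetrameric channel pore,
not its physics: four reference Cα atoms on a square of side = pore radius
at z = 0; four pore-facing phenyl rings on the wall; a protein shell and a
dummy membrane annulus outside the cylinder; waters split into an inside
population (uniform in the cylinder with a 2 Å wall margin) and an outside
population; four K⁺ ions stacked on the axis above the membrane face; and
0/1/2/4 rigid two-ring/two-oxygen ligand copies at fixed offsets.  Per-frame
positional noise (default sd 0.3 Å) is clipped to 60% of the wall margin so
planted inside/outside classifications can never flip, and all pore contents
are generated relative to the per-frame (noisy) reference centroid — which
is exactly the centre the analysis uses — so planted hydration counts are
recovered bit-exactly.  Occupancy can fluctuate per frame
(`water_count_sd`): a pool of waters exchanges between inside positions and
outside parking positions, with the per-frame planted count recorded in the
ground truth.

The applied field is a deterministic axial drift on the filter ions (default
0.5 Å/frame), not a force integration: the package tests analysis code, not
dynamics.  Drift noise is clipped below the drift so ion paths are strictly
monotone, making planted crossing events unambiguous.  Drift is scaled by
(1 − copies/4), so four ligand copies block permeation entirely and pass
counts are non-increasing in copy number — the qualitative blocked-pore
ordering.  The default conditions are the 0/1/2/4-copy grid with planted
mean occupancies 43/38/17/12 waters (occupancy sd 4), membrane span ±20 Å,
field 10 mV/nm (40 mV across the 4 nm membrane), frame interval 0.1 ns.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: water–water exclusion and hydrogen-bond
structure, lipid dynamics, protein conformational change, genuine
electrostatics, and ions that linger or knock on in the filter.  Real
trajectories will produce noisier series, boundary-grazing waters and
ambiguous partial crossings that the planted data deliberately avoids; the
boundary conventions above define how such cases are resolved, but their
scientific interpretation still needs judgement.

## Problem sizes and reproducibility

Default pipeline runs use 500 frames per condition; the test-suite and the
acceptance script use 100–200-frame systems, which already exercise every
code path and keep the full analysis grid to seconds on one CPU.  A single
global seed drives everything; per-condition seeds derive from it as
(seed × 100003 + index) mod 2³¹.  Pipeline outputs are written atomically
(temp file + rename) with fixed float formatting, so identical config + seed
reruns are byte-identical; the manifest records the config hash, seed and
package version needed to regenerate every file.

## Known limitations

- Orthorhombic boxes only; no unwrapping of periodic images.
- The cylinder statistic is deliberately simple: no HOLE-style pore-radius
  profiles, solvent-accessible-surface or alpha-shape volumes.
- Ligand ring/oxygen identification is name-based (configurable name lists);
  arbitrary force-field atom naming may need a custom `SelectionConfig`.
- Event idealisation from raw current traces is out of scope — the
  electrophysiology fits consume idealised event lists and tabulated points.
- Dwell-time fitting is single-exponential; multi-component kinetics require
  external mixture fitting.
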