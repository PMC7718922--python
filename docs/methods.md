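# Methods

`origamifit` builds pseudo-atomic models of multilayer DNA-origami
objects into cryo-EM density maps and analyses the lattice mechanics
behind their global twist. This note records the model, its
assumptions, the numerical choices, and what the synthetic benchmarks
do and do not demonstrate.

## The coarse-grained model

Every nucleotide carries two pseudo-atom beads: **P** at the backbone
phosphate radius (9.0 Å from the helix axis) and **B** at the base
(3.0 Å). Helices are placed at their design-lattice positions
(inter-helix spacing 25 Å) with canonical B-form geometry: 3.4 Å rise
per base pair and a right-handed per-slot twist of 360°/ρ_L, where ρ_L
is the base-pairs-per-turn the lattice connectivity allocates per design
slot — 10.5 for honeycomb (21-slot/2-turn repeat) and 32/3 ≈ 10.67 for
square lattices (32-slot/3-turn repeat). These two constants are
structural facts of the design rules and are not configurable; the
geometric defaults are ordinary B-DNA values and can be overridden
through `GeometryParams`.

The two B beads of a Watson–Crick pair sit diametrically across the
helix axis, so their midpoint lies exactly on the axis. This is the one
deliberate departure from a "both bases between the backbones" picture:
it gives every base pair an exact on-axis anchor, which makes the
helical-property monitor and the twist measurements close exactly
against the generator (rise and twist are recovered to 1 µ-unit on
ideal models, with no systematic off-axis bias to correct for).

Deleted design slots contribute no nucleotide and no rise; insertions
take full 3.4 Å steps after their slot. All-atom detail (sequence-
dependent geometry, sugar puckers, explicit grooves beyond the two-bead
phase offset of 154°) is out of scope.

## Elastic network

Harmonic bonds fall into the three classes the fitting protocol
relieves in order:

| class | members | k (kcal/mol/Å²) |
|---|---|---|
| basepair | one bond per Watson–Crick pair (B–B) | 5.0 |
| intrahelical | covalent backbone P–P within a helix, plus all same-helix bead pairs ≤ 10 Å in the ideal model | 1.0 |
| interhelical | covalent crossover backbone bonds, plus inter-helix pairs ≤ 15 Å near crossover slots | 0.5 |

Rest lengths are ideal-model distances, so the idealized structure is
the exact zero-energy state. The stiffness values are this package's
declared defaults — the published protocol inherits its constants from
an all-atom elastic-network model whose parameters are not reproduced
here — but the class taxonomy and the short-range/long-range division
are preserved, which is what the cascade's class-relief logic needs.

Nicks are physically discontinuous: the direct P–P term across a nick
boundary is removed from every class (the surrounding duplex terms still
hold the site together, consistent with the stacking that real nicks
retain).

A single soft repulsion, ½·k_ev·(σ_ev − r)² for r < σ_ev with σ_ev =
4 Å and k_ev = 5, replaces non-bonded physics, smoothly switched off
between 8 and 10 Å (the conventional switch/cutoff pair). Excluded from
it are 1-2/1-3/1-4 covalently bonded pairs **and any pair already
closer than σ_ev in the ideal geometry**. The second rule is needed
because lane-adjacent B beads across a strand break rest at 3.83 Å —
five covalent bonds apart — and would otherwise feel a spurious
repulsion at rest; rest-state contacts are structure, not clashes.

## Grid potential and integrator

The map enters as an attractive potential per bead,
U = w·Σ(1 − ρ̂(x)), with ρ̂ the density min–max-normalised over its
positive range and interpolated trilinearly (the gradient is the exact
analytic derivative of the interpolant). This makes the published
weights w = 0.3 → 1.0 kcal/mol directly meaningful per bead.

The integrator is overdamped first-order Langevin: per step, each bead
moves μ·F plus Gaussian noise of standard deviation √(2·kT·μ) per
component, clamped to 0.5 Å. The beads have no meaningful masses, so
damping (0.1 ps⁻¹) and timestep (0.01 ps) act only through the mobility
μ = dt/γ = 0.1 Å²·mol/kcal. The default kT = 0.01 kcal/mol yields an
RMS thermal displacement of ≈ 0.1 Å per step; kT = 0 turns the dynamics
into a deterministic descent (used by the parameter-recovery tests so
they measure the protocol, not the thermostat). A pre-clamp step above
ten clamps aborts with diagnostics. Minimization is steepest descent
with backtracking; the energy is non-increasing across accepted steps.

μ is kept below the overdamped stability bound for the stiffest bond
(2/(2k_bp) = 0.2), so the descent cannot oscillate.

## The cascade schedule

`default_schedule(final_resolution)` reproduces the protocol stage by
stage (20 stages):

1. steepest-descent minimization, 4800 steps, no map;
2. eight maps blurred to 22→10 Å (linearly spaced), 12 000 dynamics
   steps each at w = 0.3, full network (the *extended* variant starts
   at 24 Å with 60 000 steps on the first map);
3. grid-off relaxation, 12 000 steps, full network;
4. eight maps 16 Å→final, 6000 steps each at w = 0.3, with the
   long-range interhelical class switched off for maps at 14 Å or
   better;
5. the original map, 12 000 steps, base-pair bonds only;
6. final minimization, 18 000 steps at w = 1.0, base-pair bonds only.

Whether the closing 18 000-step phase is a minimization or thermostatted
dynamics is ambiguous in its source; it is implemented as minimization
(the reading "energy-minimization steps" suggests), which also quenches
thermal jitter before properties are measured. If the final resolution
is worse than 16 Å the second cascade degenerates to a single stage.
Active classes never grow after the relaxation phase; progression is
not gated on the correlation (stages always run their budget), the
report only flags stages where the ccc decreased.

Blurring uses σ_add = 0.225·√(R_target² − R_map²) and periodic
convolution, which preserves total mass exactly; simulated maps are
padded six standard deviations beyond the model, so wrap-around
contributions are negligible.

Prealignment matches the model's centroid and principal axes to the
density's (proper rotations only); of the four sign-consistent axis
pairings the one whose beads land on the most density wins.

## Measurements

**Helical properties** — per base-pair step: rise as the distance
between consecutive on-axis pair centroids, twist as the signed angle
between consecutive P–P pair axes about the local step direction.

**Global twist (model)** — per design slot, each helix contributes its
pair centroid; the in-plane rotation of these helix centres against a
reference section (the first with the fullest helix complement,
registered on shared helices elsewhere) is fitted against the axial
base-pair index by ordinary least squares. Positive slope =
right-handed, matching B-DNA helicity. Models built here carry their
construction frame (origin + axis) so deformation and measurement use
the same exact axis; models without one fall back to the PCA axis.
Unwrapping assumes |Δangle| < 90° between adjacent slots — far above
physical twist densities.

**Global twist (map)** — axial slabs of the density are resampled to
polar images about the (auto-detected or given) axis; the rotation
between *consecutive* slabs maximises the rotational cross-correlation
within a ±30° window, below the first symmetry replica of typical
bundle cross-sections (60° for a six-helix ring), and the cumulative
angle is fitted per base pair (rise 3.4 Å). Maps without sufficient
axis anisotropy (ratio < 1.5) are rejected.

**FSC** — the standard symmetric per-shell correlation. Note that any
shell-constant filter (a Gaussian blur in particular) cancels exactly
in this normalisation, so a blurred copy has FSC ≡ 1 against its
source; the effective resolution of a filtered map is instead read off
`transfer_function` (reference-normalised cross-power), which for a
blurred copy equals the blur kernel's Fourier transform exactly.
Threshold accessors follow field convention: 0.143 for half-map pairs,
0.5 for map-vs-model.

**Masks** — body masks are low-passed, binarised (threshold a fraction
of the filtered maximum) and extended with raised-cosine soft-edge
layers, value ½(1 + cos(πk/L)) at layer k of L. Zoning masks are
soft-edged unions of 8 Å spheres around the beads of a helix/slot
selection — one helix radius, so a selection covers its own density
without swallowing the neighbour's. Frankenstein compositing is the
mask-weighted mean Σmᵢρᵢ/Σmᵢ where any mask is positive; a plain
stitch is the special case of non-overlapping binary masks.

**Polar moment** — J = Σ(πr⁴/2 + πr²d²) over helices as solid discs
(default radius 1.0 nm, half the B-DNA diameter) displaced d from the
section centroid. The twist-correction guide solves
ρ_L·(1 + δ) = 10.5 for the net indels-per-slot δ (for default square
spacing: −1/64, i.e. one deletion per 64 slots ≙ 0.5 per 32-slot
repeat) and, given a calibration table of (J, imposed density, observed
twist) points, interpolates the expected residual twist at the design's
(J, density); calibration data are user input, not shipped numbers.

## Synthetic benchmarks

The generator emulates the object classes such studies image: duplexes,
two-helix junction fixtures, honeycomb six-helix tubes, square 2×2 and
4×4 blocks, and a two-domain tower with two scaffold chains. Designs
are emitted as valid caDNAno 2.x JSON (serpentine scaffold, reciprocal
staple double crossovers at the lattice spacing, staple nicks away from
junctions), so every fixture exercises the real parser. Ground truths
are ideal models with injected global twist/curvature; maps are
Gaussian simulations (σ = 0.225·R) with optional white voxel noise
scaled to a fraction of the RMS density, and half-map pairs are two
independent seeded noise realisations. All randomness derives from one
seed via `numpy.random.SeedSequence` substreams.

What this does **not** model: particle images, CTF, alignment errors,
correlated noise, solvent, sequence effects, or real conformational
ensembles. Passing the recovery tests therefore shows the *protocol*
(cascade + class relief + grid forces) converges to a known deformed
state under clean conditions — not that real micrographs would yield
the same accuracy.

## Problem sizes

Benchmarks run on 64-slot six-helix tubes (1536 beads, ≈ 8600 bonds) at
10 Å/2 Å voxels, with the full 20-stage schedule scaled by an integer
step divisor of 10 (≈ 19 000 total steps, ≈ 40 s per fit on one CPU) —
the schedule *structure* (stage count, resolutions, weights, class
gating) is never altered, only the per-stage budgets. At this scale the
deterministic (T = 0) cascade recovers injected twists of 0.3–0.9 °/bp
to better than 0.01 °/bp and reduces RMSD to 12–34 % of its
post-prealignment value; these margins are what justifies the scaled
budgets. The overfitting check (fit against half-map 1 at noise 0.5,
FSC validated against half-map 2) uses divisor 20.

## Known limitations

- The parser supports the caDNAno 2.x "vstrands" dialect only.
- Lattice inference needs inter-helix crossovers; crossover-free designs
  require an explicit lattice flag.
- PDB output cycles through 62 chain identifiers; designs with more
  strands rely on the JSON sidecar for strand identity.
- The map-based twist measure assumes an approximately straight axis;
  strongly curved objects should be measured through a fitted model.
- Excluded-volume forces are exact but the pair list uses a 2 Å skin;
  beads moving faster than the clamp allows between rebuilds cannot
  occur by construction.
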