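# Methods

## Scope and model

`ifsim` studies the conformational plasticity of intermediate-filament
(IF) subunits — the soluble vimentin/keratin dimers and tetramers — with
two linked desk-scale instruments:

1. a coarse-grained (CG) bead-spring model of the subunits over an
   adhesive crystalline substrate, sampled with overdamped Langevin
   dynamics, and
2. a synthetic AFM image generator plus a morphometry pipeline that
   measures dried-subunit populations the way grain analysis measures
   real height maps.

All lengths are nm, energies kcal/mol, temperatures K; the substrate
plane is z = 0 and "height" means the +z coordinate.

## Subunit geometry

A dimer is a single bead path of 50 nm contour: two stiff coiled-coil
segments (22 and 25 nm) joined by a 3-nm flexible linker (the L12
hinge).  Resolution is 1 bead per nm of contour, bead radius 1 nm (the
coiled-coil is ~2 nm wide), so a dimer has 51 beads and a tetramer 102.
One bead stands for ~18 residues (two chains of ~466 residues over
50 nm).  The 22/3/25 split respects the 20–25 nm coil lengths and the
50-nm total; it is config-exposed.  Coil beads carry −1e (coiled-coils
are negatively charged at assembly pH), linker beads are neutral.

A tetramer is two antiparallel dimers, half-staggered by 25 nm and
2 nm apart laterally, giving the familiar ~75-nm rod.  The dimers are
held together by soft harmonic crosslinks (rest length 2 nm, k = 10
kcal/mol/nm²) between facing beads of the 25-nm overlap — a stand-in
for the A11-overlap cohesion, not a model of head-domain chemistry.
The 2-nm gap is inferred from the dimer width; no experimental value
exists for it.

The substrate is a rigid hexagonal lattice of adhesion beads with
0.98 nm spacing (one bead per silica unit cell) at z = 0.

## Energy model

Chain terms: harmonic bonds (k = 100 kcal/mol/nm², rest 1 nm); bending
`k_b (1 + cos θ)` per joint, which is harmonic `½ k_b φ²` in the
deviation from straight for small φ and numerically smooth at φ = 0
(this is why the harmonic-in-angle form was not used; at the stiffness
in play the two differ by ~2% in recovered persistence length).  Coil
joints get `k_b = Lp·kB·T/b` with Lp = 25 nm, the AFM-measured
coiled-coil persistence length, giving 14.9 kcal/mol at 300 K; hinge
joints are free (k = 0).  Excluded volume is a purely repulsive
truncated-shifted LJ at the bead diameter (ε = 0.3); electrostatics is
a screened Yukawa with Debye length 0.8 nm (NaCl assembly conditions;
a low-salt preset uses 3 nm).  At these parameters electrostatic
repulsion is a minor perturbation (≤0.1 kcal/mol per contact pair),
which is consistent with charged coils that still collapse once salt
screens them.

Substrate adhesion: every chain bead interacts with every lattice bead
within the 2.5-nm cutoff (below the 3-nm deposition start height, so
runs begin non-interacting) through
`E(r) = ε[(σ/r)¹² − 2(σ/r)⁶]`, with σ the distance of zero force.
The per-pair ε is **calibrated**, not assumed: a probe bead is scanned
in height over the lattice and ε is scaled so the summed energy
minimum equals `residues_per_bead × 1.48 kcal/mol` — the per-residue
adhesion well of an amino acid on silica, itself bracketed by the
50–60 mJ/m² adhesion energy density times the 0.28 nm² residue
footprint (2.01–2.42 kcal/mol).  Because the LJ sum is linear in ε the
calibration is exact and scales exactly linearly with the target.

Two numerical choices in the substrate model deserve a note:

* **Pair contact distance.** The atomistic zero-force distance
  (0.49 nm) is smaller than the lattice spacing, so a 1-nm CG bead with
  that σ would fall *through* the lattice: the summed potential has its
  minima inside the plane at hollow sites.  The default pair σ is
  therefore 1.0 nm — the CG bead radius — which closes the holes; it
  remains config-exposed.
* **Calibration site.** The summed well depends on the lateral site;
  the calibration uses the deepest of the on-top/bridge/hollow sites
  (the hollow), which is where an adsorbed bead actually sits.  A
  one-sided harmonic wall below z = 0.25 nm represents the bulk solid
  under the top lattice layer.

The deposition pull is a constant downward force on every bead more
than 5 nm above the substrate.  Its printed magnitude
(0.0012 kcal/mol/Å², dimensionally a pressure) is read as
0.0012 kcal/mol/Å per residue and scaled by residues_per_bead; only its
role — guaranteeing eventual descent — matters, and it is
config-exposed.

## Dynamics

Overdamped (position-)Langevin replaces the original Nose–Hoover
thermostat: appropriate for an implicit-solvent CG model, and with
fluctuation–dissipation giving kB·T(300 K) = 0.596 kcal/mol.  Time is
reduced by the bead friction γ (default 1): a free bead diffuses its
own radius in ~1 time unit.  Timesteps: 2e-4 against the stiff
calibrated adhesion well, 2e-3 for substrate-free runs (stability is
guarded at run time; a too-large step raises an error naming the
step).  One seeded generator drives each run; identical seeds give
bit-identical trajectories, and seeds are recorded in all outputs.

Equilibration is convergence-driven (trailing-window drift and
fluctuation of the RMSD-to-reference series), not fixed-time: the
all-atom 50-ns figure has no meaning at CG resolution.  Observables are
averaged over the trailing quarter of each run.

Environment modes: `calcium` adds a short-range Gaussian attraction
(default depth 0.8 kcal/mol, range 1.5 nm) between coil beads —
divalent-ion bridging; `glutaraldehyde` freezes the instantaneous
conformation by converting all non-bonded pairs within 1.5 nm into
permanent crosslinks, once, at invocation.

## Deposition protocol and what it reproduces

The subunit is built straight, placed with its lowest bead 3 nm above
the calibrated lattice, and run at 300 K with the pull active.  Five
seeds; 400k steps (80 reduced time units) — descent completes within a
few units and the remainder verifies the plateau.

Results at the default conditions: the deposited **dimer** equilibrates
at L_ee ≈ 48 nm versus ≈ 30 nm for the matched-seed solution runs — it
lands nearly extended, and adsorbed-state frame-to-frame RMSD collapses
relative to solution.  This reproduces the experimental/all-atom
picture quantitatively (on-mica dimer 47.9 nm) and the headline
property that the surface traps conformations sampled just before
adsorption.

The deposited **tetramer** stays at L_ee ≈ 73–74 nm, i.e. essentially
as extended as it was built, whereas the all-atom reference compacted
to 58.5 nm on mica.  This is a genuine, documented limitation of the
model class, not a tuning accident: the calibrated per-bead well
(18 × 1.48 ≈ 45 kB·T) makes adsorption irreversible at first contact,
and the lattice corrugation (~9 kcal/mol per-bead lateral barriers)
pins adsorbed beads in place, while in overdamped dynamics the 22-nm
terminal arms reorient about their hinges orders of magnitude more
slowly than the subunit descends 3 nm.  An extended start is therefore
frozen almost unrelaxed.  A low-friction inertial thermostat (as in the
all-atom reference) relaxes conformations much faster relative to
descent, which is how its tetramer partially compacted before trapping.
Weakening the adhesion or pre-relaxing the start would move the
tetramer number while breaking the dimer number and the prescribed
calibration, so the model is reported as-is: the solution < substrate
contrast holds for both subunits, the dimer matches numerically, the
tetramer does not.

## Synthetic AFM scenes

The generator renders what the AFM experiments measured: dried subunits
on mica as **dots** (spherical caps) and **curly threads** (2D
worm-like ribbons, width 6 nm, step 2 nm, in-plane persistence 50 nm —
invented values chosen to make threads visually and statistically
plausible), plus optional **filaments** (long, 2.5-nm-high, 40-nm-wide
ribbons — the flat-tape morphology).  Per-object footprint areas are
drawn as `16 + Exponential(mean − 16)` nm² — exponential, as the
measured area distributions decrease exponentially, shifted by a
16-nm² detectability floor so the population mean equals the preset
exactly.  Peak heights are normal, truncated at zero.  The four presets
carry the measured population statistics verbatim:

| preset | mean height (nm) | sd | mean area (nm²) | dot fraction |
|---|---|---|---|---|
| vimentin_NaCl | 0.31 | 0.07 | 570 | 0.75 |
| K5K14_NaCl | 0.62 | 0.07 | 909 | 0.60 |
| K5K14_glutaraldehyde | 0.66 | 0.07 | 587 | 0.90 |
| K5K14_CaCl2 | 0.51 | 0.06 | 246 | 0.90 |

Dot fractions are not reported quantities; NaCl conditions show dots
alongside threads and the fixed/calcium conditions "mainly dots", which
the defaults encode.  Scan geometry (2 nm pixels, 2–3 µm fields) is
likewise ours — no scan parameters are reported.  Objects are placed
without overlap by rejection sampling; a configurable fraction of dots
can be placed exactly one pixel from a filament (inside the pipeline's
contact rule yet still segmentable) to exercise the exclusion logic.
Tip convolution is grayscale dilation by a spherical cap (tip radius
2–5 nm; default 3), and instrument noise is additive Gaussian
(default 0.03 nm).  Every placed object is recorded as ground truth.

What the generator does **not** emulate: feedback artifacts, drift,
scars, tip wear, humidity-dependent spreading, or any coupling between
molecular conformation and footprint shape.  Passing recovery tests
therefore shows the *pipeline* is unbiased for this object class, not
that it would be unbiased on arbitrary real data.

## Morphometry pipeline

Flatten (two-pass least-squares plane, second pass on the lower 75% of
pixels; background median zeroed) → robust noise sd (1.4826 × MAD) →
hysteresis segmentation on a 1-px-smoothed copy (seeds at 3σ,
delineation to 1σ, 8-connectivity, ≥4 px) → border exclusion →
filament classification (area > 5000 nm² or elongation > 10) and
exclusion of any subunit whose 1-px-dilated footprint touches a
filament (only subunits not in contact with filaments are analysed) →
per-object statistics and the exponential area fit (the sample mean is
the ML estimator).

Two first-order corrections make footprints approximately unbiased:
the tip-broadening rim `√(2R(h−z))` is subtracted via the measured
perimeter (inverse Steiner), and the threshold cut of a parabolic cap
is undone by the factor `h/(h−z)`.  Heights are maxima of a
half-pixel-smoothed copy divided by the exact peak attenuation of a
Gaussian-smoothed parabolic cap of the measured radius.  All
corrections use only measured quantities plus the known tip radius and
switch off when the tip radius is zero.  At the default conditions the
full generate→measure round trip recovers preset mean heights within
~3% and mean areas within ~10% at n = 500 (areas are exponential, so
their sample mean alone has ~4.5% sd at that n).

## Problem sizes

Desk scale throughout: 51–102 beads, lattices of a few thousand sites,
free-coil recovery from 3 × 800 reduced time units, depositions of 80
units × 5 seeds, AFM scenes of 500 objects in 2–3 µm fields.  The
Langevin kernel is numba-compiled (~10 µs/step for a tetramer), so the
full acceptance recomputation completes in minutes on one core.

## Known limitations

* The tetramer-on-substrate compaction is not reproduced (see above).
* Electrostatics between protein and substrate is off: the reference
  work states both van der Waals and electrostatic substrate coupling,
  yet fits its bead at zero charge; we implement the zero-charge
  reading and expose the term in config.
* The disk-equivalent diameters printed for the 587 and 246 nm² areas
  (26 and 17 nm) are inconsistent with `2√(A/π)` (27.3 and 17.7 nm);
  the formula is implemented as stated and the discrepancy left alone.
* Sequence-level detail (heptads, head/tail domains), ULF assembly,
  explicit solvent and hydrodynamics are out of scope.
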