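# Methods

## Scope and model

fibrion analyses how ions interact with a protein surface in MD
trajectories and what that implies for drying-driven protein assembly. The
trajectory-facing half (contacts, retention, hydration) operates on any
orthorhombic-box trajectory readable by MDAnalysis; the drying mass balance
and the Hofmeister classifier are desk calculations that need no
trajectory. The package does not run MD, compute energies or electrostatic
maps, or predict binding affinities.

All internal lengths are angstrom (nm-based formats are scaled ×10 on
read), times are picoseconds for frames and hours for drying curves.
Triclinic cells are rejected rather than approximated: every distance uses
the orthorhombic minimum-image wrap d = Δ − box·round(Δ/box), which is
exact there and meaningless for sheared cells. Coordinates are used as
stored — no centering or rewrapping is applied — because the minimum-image
convention already makes distances wrap-independent.

## Contact analysis

Per ion anchor and frame we take the minimum distance to the protein's
heavy atoms (hydrogens are excluded by element, not by name heuristics;
phosphate anions are reduced to their phosphorus atom as anchor). The
pooled distances are histogrammed (defaults: 0.1 Å bins to 10 Å) and a
moving average (5 bins) is used *only* for peak/minimum finding; raw counts
are preserved. These defaults resolve first-shell peaks at 2–3 Å from
second-shell peaks at 3–5 Å, the structure this analysis cares about.

Cutoffs: with two expected peaks, cutoff₁ is the density minimum between
the two tallest local maxima and cutoff₂ the minimum between the second
peak and the density's return to near-baseline (5% of the second peak) or
the tail. Peak candidates must have prominence ≥ 5% of the maximum *and*
height ≥ 1.2× the median density, which rejects bin-count jitter on flat or
featureless histograms (those raise a degenerate-distribution error
instead of producing an arbitrary cutoff). A plateau minimum resolves to
its midpoint bin. With one expected peak, or when no second peak exists,
a fixed 5 Å cutoff is used and flagged as such; per-species fixed values
(Cl⁻ 3.5 Å, Mg²⁺ 3.0 Å, HPO₄²⁻/H₂PO₄²⁻ 5.0 Å) are shipped for fixed-mode
runs.

"In contact" is d ≤ cutoff (closed interval). The immobile flag is
strictly f₁ > 0.5: an ion inside the cutoff for exactly half the frames is
mobile. Retention (and the immobile flag) are driven by cutoff₁ only; f₂
is reported for the water-mediated class but never feeds the flag.
Residue occupancy counts a residue as contacted in a frame when any of its
heavy atoms is within cutoff₁ of any ion anchor.

## Hydration analysis

g(r) is computed from minimum-image pair counts in spherical shells,
normalized by the *exact* shell volume 4π/3·(r₊³ − r₋³) and a reference
density ρ_ref. ρ_ref defaults to the frame-averaged box density of the
water-oxygen selection (the convention of common trajectory tools); a user
override exists because protein excluded volume makes the box average
underestimate true bulk density and hence inflate g(r) slightly.
Defaults: dr = 0.05 Å, r_max = 8 Å (validated against half the smallest
box edge).

Coordination numbers come from two routes that must agree within 2%:
cumulative direct counting (the headline value) and midpoint quadrature of
4πρ g(r) r² dr. The first-shell minimum is located on a 3-bin smoothed
g(r): the first prominent maximum (prominence ≥ 1 in g units, which
ideal-gas noise never reaches) is followed to the first local minimum that
falls below half the peak; a decay to a flat stretch (e.g. zero background)
counts as the minimum at its onset, and a monotone g(r) raises a no-shell
error. CN is reported both at the first minimum and at a fixed 3.2 Å for
cross-species comparability.

The hydration summary splits ions by retention: immobile (f₁ > 0.5),
shell-resident (f₂ > 0.5 but not immobile), and bulk reference (never
inside the outer cutoff, f₂ = 0). Water loss is CN_bulk − CN_class at each
class's own first minimum. Empty classes are reported as absent, not as
errors.

## Synthetic generators

The generators define the controlled conditions every downstream number is
tested under.

*Binding*: a static ring of pseudo-residues (three heavy atoms each, the
CA being the attractor site) with ions assigned round-robin to sites. Each
ion's bound/free state is an independent two-state Markov chain with
per-frame probabilities p_on, p_off, initialized at the stationary
distribution π = p_on/(p_on+p_off) so retention estimates need no burn-in.
Bound ions are uniform in a ball of radius d_bound (default 2.5 Å) around
their site; free ions are i.i.d. uniform outside 2·d_bound of every site.
The i.i.d. choice (no diffusive memory) makes analytic error bars exact; a
contact cutoff anywhere between d_bound and the free exclusion zone
recovers the latent state sequence exactly, which the oracle tests exploit.
Defaults (20 ions, 8 sites, 60 Å box) keep site shells non-overlapping and
the free volume dominant. The time-average of the state indicator has
variance π(1−π)/T · (1+ρ)/(1−ρ) with ρ = 1 − p_on − p_off, which is the
standard error used by the recovery tests.

*Hydration*: static ions on a PBC-respecting grid, each dressed per frame
with k oxygens isotropically at shell_radius ± jitter, plus a uniform
background whose population is one Poisson(ρV) draw thinned by the
exclusion spheres (mean across seeds ρ·(V − V_excl)) and re-placed every
frame.
The `bulk_monovalent_cation` preset (k = 6 at 2.4 Å, 2.0 Å core exclusion)
emulates the intact first shell of a small monovalent cation in bulk
water. It ships with zero background density: the generator has no
second-shell depletion, so any uniform background reaching the shell edge
would leak counts into CN(first minimum); with a pure shell the preset's
coordination number is its occupancy by construction, which is what a bulk
*reference* should pin down. Water hydrogens are never generated — the
analysis uses water oxygens only.

What the generators do *not* emulate about real systems: ion diffusion and
correlated rebinding, water structure beyond the first shell, protein
flexibility, and competition between ion species. Passing tests therefore
demonstrate the correctness of the estimators under known kinetics and
geometry, not force-field realism.

Determinism: one global seed feeds named substreams (scaffold / ions /
waters), so adding waters never perturbs ion paths; identical seeds give
bit-identical coordinate tables.

## Drying mass balance

Solutes are conserved, the solution is treated as dilute (density of
water), and the non-water contribution to the droplet mass enters only
through the explicit `dry_mass` parameter, since gravimetric curves do not
separate it. The evaporated fraction at saturation, 1 − c₀/c_sat, is
curve-independent; saturation times interpolate linearly on water mass
between samples. Mass increases after a 0.5 h humidity-equilibration
window are flattened to a running-minimum envelope with a warning.
Room-temperature literature solubilities ship as an editable YAML of
defaults, not hardcoded constants. Phosphate speciation uses
Henderson–Hasselbalch with pKa₂ = 7.21.

## Hofmeister classifier

Cations and anions carry one of three classes (kosmotropic / intermediate /
chaotropic); the grid rule scores them 2/1/0 and maps the pair sum to a
morphology (4 → dense fibers, 3 → coarse or localized fibers, 2 → rough
non-fibrous, ≤1 → smooth). Na⁺ is kosmotropic and K⁺ intermediate — the
more chaotropic monovalent cation — while divalent cations sit at the
chaotropic end of this scheme because they suppress fibers regardless of
anion. Observed exceptions (K-phosphate dense, K-sulfate rough, Na-oxalate
rough, Na-citrate localized) live in an override table that takes
precedence, keeping the encoding faithful to observation rather than to
the idealized grid. The table is data (YAML), and the classifier is an
encoding of empirical calls, not a thermodynamic model.

## Numerical choices and limitations

- PDB I/O rounds to 0.001 Å and XTC to 0.01 Å; round-trip tests use those
  tolerances.
- Frame chunking bounds the memory of the all-pairs distance kernels
  (~4·10⁶ pairs per chunk); results are identical to the unchunked path.
- Test and acceptance problem sizes (≤5000 frames, ≤20 ions, ≤64 centers,
  50 seeds for recovery studies) were chosen so analytic 3-standard-error
  bands are tight enough to detect bias while runs stay desk-scale.
- Selections assume standard residue naming (amino acids, SOL/HOH/TIP
  waters, ion residue names); exotic force-field naming may need the
  topology's group tags set manually.
- The residue-occupancy kernel is exact but quadratic in (atoms × ions);
  for very large proteins a cell-list implementation would be the next
  step.
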