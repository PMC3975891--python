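# Methods

## Scope and model

`ionid` addresses one well-posed sub-problem of model completion: given a
refined macromolecular model and per-site map statistics, decide for each
modeled water whether it is actually a monoatomic ion, and if so which
element. Twelve candidate elements are supported (Na, Mg, K, Ca, Mn, Fe,
Co, Ni, Cu, Zn, Cd, Cl). The package deliberately does **not** compute
maps or refine: density and anomalous observables are inputs (a features
table), which keeps the method reproducible from plain-text artifacts and
independent of any particular refinement engine. Reciprocal-space
refinement, anomalous substructure completion and likelihood-gradient
maps are out of scope; so are polyatomic species (sulfate, acetate),
heme/Fe–S centers, and hydrogen-bond/protonation analysis.

## Screening

Screening is a short-circuit classifier per water:

1. **Unreliable** — mFo−DFc peak < −3.0σ, or 2mFo−DFc < 1.8σ. These
   sites are excluded from any conversion.
2. **Heavy candidate** — any of: B_iso < 1.0 Å²; mFo−DFc peak > 3.0σ;
   occupancy > 1.0; anomalous peak > 3.0σ; refined f″ > 0.
3. **Light candidate** — B_iso below 0.8× the solvent mean, or 2mFo−DFc
   above the solvent mean + 0.5σ; the 0.8/0.5 pair is our choice (the
   relative comparison itself is standard, but no published constants
   exist); both are configurable.
4. Environmental promotion — an O–O contact closer than 2.4 Å or a
   nucleotide-phosphate O in the shell promotes a plain water to a light
   candidate. Motifs never demote a verdict.

A missing observable is treated as *not measured* and disables only the
criteria that need it, so the pipeline runs — with reduced
discrimination — without anomalous data or entirely without a features
table (model-only occupancy/B/contacts).

## Coordination shells

Shells collect heavy atoms within 3.5 Å (configurable), with crystal
symmetry and periodic images applied in fractional space via gemmi's
neighbor search; each contact records its generating operation.
Hydrogens are ignored throughout — donor identity is defined by heavy
atoms. Carbon/phosphorus atoms covalently bonded (sum of covalent radii
+ 0.4 Å) to an included O donor are bookkept as framework (carboxylate,
phosphate) rather than disqualifying the site; a nonbonded C/P that
close is a disqualifying contact. Donors whose per-atom 2mFo−DFc support
is below 1.0σ are excluded when such data are provided. Contacts from a
second alternate conformation conflicting with the first-used altloc are
dropped; disorder in the ion itself is not modeled.

## Geometry classification

Eight ideal templates are supported (linear through pentagonal
bipyramidal). For a template with the observed donor count, the rotation
and donor-to-vertex assignment minimizing the summed squared angular
deviation are found by seeding rotations from direction pairs and
alternating optimal bipartite assignment (`scipy`
`linear_sum_assignment` on squared angles) with a least-squares rotation
fit; the result equals exhaustive permutation search (verified in the
test suite up to 6 donors). A template is accepted at angle RMSD ≤ 15°,
our tolerance choice sized to coordinate error at ~2 Å resolution. Only
Mg carries a hard geometry requirement (octahedral); with five donors a
square-pyramidal classification is accepted as an octahedron with one
unresolved vertex. For other elements geometry enters the ambiguity
ranking only.

## Bond valence and VECSUM

Each donor j contributes s_j = p · exp((r₀ − d_j)/b), with p the ion's
fractional occupancy (donor occupancies are noted but not multiplied
in). The bond-valence sum must fall within ±0.25 (strict) / ±0.5 (weak)
of the formal charge; VECSUM = |Σ s_j r̂_j| / Σ s_j ≤ 0.25 is enforced in
strict mode only. The window and VECSUM constants are our calibration:
±0.25 is chosen so that a shell at BVS ≈ 2.3 fails strict Ca while
octahedral Mg sites near 2.1–2.2 pass. r₀/b constants come from the
standard Brown–Altermatt (1985) and Brese–O'Keeffe (1991) compilations
for the biologically relevant oxidation states, shipped as a delimited
table with per-entry provenance; donors without parameters contribute
zero valence and are logged. b = 0.37 Å throughout.

## Anomalous scattering

Expected f″(λ) is computed with the Cromer–Liberman implementation in
gemmi, sampled on a 0.05 Å grid over 0.5–3.0 Å and linearly
interpolated; a user override table is accepted. A refined f″ is deemed
consistent when it lies within 0.2–1.5× the expected value — tolerant on
the low side because partial occupancy depresses refined f″, and on the
high side because anomalous data carry inherent inaccuracies. For
elements with negligible expected signal (< 0.2 e⁻) a substantial
refined f″ or a > 3σ anomalous peak is disqualifying.

## Decision tree

Candidates are filtered in the order donor identity → coordination
number → geometry → BVS window → VECSUM → f″ consistency →
electron-count consistency (heavy elements require a heavy screening
verdict; Na/Mg are rejected when the residual peak exceeds 3σ). The weak
variant — applied only when a heavy-looking site fails every candidate
and waivers are enabled — drops geometry and VECSUM, relaxes the
coordination minimum by two and widens the BVS window; `require_valence`
keeps the strict window even then (the conservative "valence required"
operating mode). Chloride bypasses the cation chain: it requires ≥ 1
positively polarized contact within 3.6 Å (backbone amide N,
Arg/Lys/His/Asn/Gln side-chain N, or a modeled cation) and 1–6 such
contacts in total.

Ambiguities are ranked by f″ consistency, then |BVS − formal charge|,
then geometry — a pragmatic ordering of the evidence classes from most
to least element-specific. When two viable candidates' expected f″
differ by < 0.2 e⁻ at the given wavelength, the report states that
anomalous data cannot discriminate them (e.g. Zn vs Cl at Cu Kα).
Transition metals in generic O/N octahedra are frequently
indistinguishable by chemistry alone; the pipeline then reports an
ambiguity with the best-fitting element first rather than forcing a
choice.

Assigned sites get occupancy 1.0 — or 1/n on a special position fixed
by n space-group operations (detected within 0.5 Å) — B set to the
solvent mean, and ADP mode anisotropic below 1.5 Å or beyond 2.5 Å for
Z ≥ 19. A resolution worse than 2.8 Å produces a prominent warning but
does not stop the run. Already-built ions are re-scored with the same
candidate machinery and flagged when they fail even the weak filter;
they are never altered. An optional writer emits a converted copy of the
model; the input file is never modified.

## Synthetic data

The fixture generator emulates the study conditions end to end: an ion
site modeled as water in a small P1 (or chosen space-group) cell, donors
placed on an ideal template under a seeded random rotation with optional
Gaussian coordinate noise, embedded in minimal residue fragments
(waters, Asp carboxylates, His imidazole stubs, Cys thiolates, backbone
amides, an AMP-PNP-like β-phosphate). "Ideal" distances solve
n·exp((r₀−d)/b) = |q| exactly. The features table mimics refinement
output with a deliberately simple synthetic model: B = 0.5× the solvent
mean for ion sites, an mFo−DFc peak of 0.5σ per electron of difference
to oxygen scaled by occupancy, a 2mFo−DFc level rising with atomic
number, and anomalous observables (f″ and a peak at 5σ per electron of
f″) emitted only when the expected f″ at the spec's wavelength exceeds
0.5 e⁻ — mimicking that anomalous substructure sites are only found for
real scatterers. The solvent means default to 30 Å² and 2.5σ
(well-ordered waters sit comfortably above the 1.8σ reliability cutoff).

What passing tests on these fixtures show: the chemistry, symmetry and
decision logic are internally consistent and recover planted ions with
zero false conversions on clean solvent. What they do not show:
robustness to real-world refinement artifacts — correlated coordinate
error, series-termination effects, disorder, peak-shape differences —
none of which the linear feature model generates.

## Numerical and design choices

* Symmetry contacts: gemmi neighbor search over all cell images;
  contacts deduplicated by (atom, position) so donors fixed by an
  operation are counted once; the brute-force oracle in the tests wraps
  symop images into the cell before scanning ±1 lattice translations.
* Special positions: an operation fixes a site when the image lies
  within 0.5 Å; multiplicity is the reciprocal of the fixing-op count.
* Geometry fits use n² rotation seeds and ≤ 20 assignment/rotation
  alternations; ideal templates score ≤ 1e-5° residual RMSD.
* Mg coordination is 6–6 in strict mode; the 5-donor octahedron-minus-
  one case is reachable only through the heavy-site waiver, consistent
  with treating a missing vertex as an incomplete model.
* Degenerate inputs: empty shells give BVS 0 with a warning; < 2 donors
  classify as irregular; models without cell/symmetry fall back to an
  all-pairs search and multiplicity 1.0, each with a logged warning.
* Determinism: identical inputs and configuration produce byte-identical
  JSON reports; all fixture randomness is seeded.

## Problem sizes

The test suite and acceptance script run on synthetic models of ~10–60
atoms; the negative control uses 50 independent 20-water models (1000
sites) and the symmetry oracle 100 random 8-atom cells across four space
groups — sizes chosen to exercise every code path while keeping the
whole suite in the seconds range.

## Known limitations

* Map and anomalous observables must be supplied; there is no MTZ/CCP4
  reader. Feature quality bounds identification quality.
* Transition-metal discrimination without informative anomalous data is
  chemically impossible in generic sites; expect ambiguity records.
* Halide identification is limited to the amide/cation environment rule
  and is unreliable for partially occupied surface chlorides.
* Ions with static disorder (split sites, correlated side-chain
  conformers) are only partially handled via altloc filtering.
* The worked-example tests against PDB entries 4dfx and 1exr require
  those coordinate files (network or a local copy under `tests/data/`).
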