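# ionid

Automated identification of elemental ions mismodeled as waters in
macromolecular crystal structures.

Solvent-picking routines in crystallographic refinement frequently build
water molecules into density that actually belongs to a bound ion — Na⁺,
Mg²⁺, K⁺, Ca²⁺, a first-row transition metal, Cd²⁺ or Cl⁻. The misassignment
is easy to miss: refinement compensates for the wrong element by adjusting
the B factor and occupancy. `ionid` is a library (plus a thin CLI) for
crystallographers and structural bioinformaticians that screens every
refined water for such mistakes, combining scattering evidence with a
chemical analysis of the coordination environment, and either assigns an
element, presents a ranked list of viable alternatives, or leaves the
site alone.

## The method

For each water, map-derived observables (supplied as a per-site features
table) are screened first. A site is a **heavy-ion candidate** if any of
the following fire: B_iso < 1.0 Å², an mFo−DFc residual peak > 3.0σ,
occupancy refined above 1, an anomalous-map peak > 3.0σ, or a refined
f″ > 0. It is a **light-ion candidate** (Na/Mg) when its B factor or
2mFo−DFc level stands out against the solvent means, or when it clashes
with another O atom (< 2.4 Å) or touches a nucleotide phosphate. Sites
with a negative difference peak (< −3.0σ) or weak density (< 1.8σ) are
rejected as unreliable.

The coordination shell — all heavy atoms within 3.5 Å, **crystal
symmetry included** — is then analyzed per candidate element:

* **donor identity**: e.g. cysteine thiolate S only for Co/Fe/Ni/Zn/Cu,
  methionine S only for Co/Ni/Cu, O-only coordination for Na/K/Ca;
  carboxylate C and phosphate P bonded to an included O donor are
  recognized as framework, not as disqualifying contacts;
* **coordination number and geometry**: octahedral coordination is
  required for Mg (angle RMSD ≤ 15° against the ideal template, donors
  matched by optimal assignment);
* **bond-valence sum**: s_ij = p_j · exp((r₀ − d_ij)/b) summed over
  donors must fall within ±0.25 (strict) or ±0.5 (weak) of the formal
  charge, using Brown–Altermatt / Brese–O'Keeffe parameters;
* **VECSUM**: |Σ s_ij r̂_ij| / Σ s_ij ≤ 0.25 — balanced coordination;
* **f″ consistency**: a refined f″ must be 0.2–1.5× the value expected
  for the element at the experiment's wavelength;
* **chloride** is judged instead by a positively polarized environment
  (backbone amide N, Arg/Lys/His/Asn/Gln side-chain N, modeled cations).

A unique pass is assigned (occupancy reset to 1.0 or the
special-position fraction, B set to the solvent mean, ADPs anisotropic
below 1.5 Å or above 2.5 Å for Z ≥ 19); ties are reported as ambiguous
with ranked alternatives; heavy-looking sites rejected by every element
are flagged as unknown heavier scatterers. Already-modeled ions are
re-validated but never modified.

## Worked example

```bash
python examples/02_identify_zinc_site.py
```

builds a synthetic structure with a Cys₄ zinc site deliberately modeled
as water among four ordinary waters, and runs the pipeline:

```
site                     status         element  triggers
A/HOH1/O                 assign         ZN       fofc_peak,anomalous_peak,refined_fpp
A/HOH200/O               keep_water     -        -
A/HOH201/O               keep_water     -        -
A/HOH202/O               keep_water     -        -
A/HOH203/O               keep_water     -        -

assigned element : ZN
bond-valence sum : 1.999 (window 1.75-2.25)
VECSUM           : 0.000 (<= 0.25 required)
f'' consistency  : yes
```

The flagged water scores a bond-valence sum of ~2.0 (the Zn²⁺ formal
charge) over its four thiolate donors, a balanced VECSUM, and an
anomalous signal matching Zn at 1.0 Å — so it is converted; the plain
waters show no trigger and are untouched. The other examples demonstrate
bond-valence arithmetic (`01`), symmetry-completed shells and
special-position occupancies (`03`), and the screening thresholds (`04`).

The CLI mirrors the library:

```bash
ionid identify --model model.pdb --features features.tsv \
      --elements Mg,Ca,Zn,Cl --wavelength 1.5418 --out-dir out/
ionid validate --model model.pdb
ionid fixtures --out fixtures/ --seed 7
```

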