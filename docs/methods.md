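# Methods

## Cremer–Pople analysis and the canonical conformer table

Ring puckering is computed with the standard Cremer–Pople construction:
atoms ordered O5→C1→C2→C3→C4→C5, geometric centering, mean plane from
the two Fourier sums of the positions, out-of-plane displacements z_j,
and the puckering amplitudes

    q2·cos φ = √(1/3) Σ z_j cos(4πj/6)
    q2·sin φ = −√(1/3) Σ z_j sin(4πj/6)
    q3       = √(1/6) Σ (−1)^j z_j,

with Q = √(q2²+q3²), tan θ = q2/q3. The phase convention places the
⁴C₁ chair of a D-pyranose at θ = 0; this is the convention consistent
with the conformer labels in common carbohydrate usage, verified here by
constructing ideal chair geometries and checking the pole they map to.
Angles are degrees at every API boundary, radians internally.

The 38 canonical conformers are **derived, not transcribed**: each
IUPAC descriptor encodes a signed displacement pattern (chair ⁴C₁ =
alternating with C4 up/C1 down; envelope ³E = C3 exo; half-chair ⁴H₃ =
C4 up, C3 down; boat ¹,⁴B = the C1/C4 para pair up; skew ¹S₃ = C1 up,
C3 down), and each pattern is pushed through the same transform used
for classification. The resulting reference positions are the familiar
ones — poles; boats/skews every 30° of φ on the equator; envelope tier
at θ = 54.7°, half-chair tier at 50.8° (and mirrored in the south) —
and are guaranteed consistent with the package's own phase convention.
Classification is nearest-reference-point by great-circle distance,
with a planarity guard: Q < 0.1 Å returns "planar/unclassifiable"
instead of a meaningless angle pair. Ties (which occur only on exact
region boundaries) resolve by fixed table order.

`ideal_ring_geometry` inverts the transform: atoms on a circle of
radius 1.45 Å (clockwise, so the ring normal is +z) displaced by the
pure q2/q3 modes. Because the constructed displacements contain no
k = 1 Fourier component, the xy-plane is exactly the Cremer–Pople mean
plane and the round trip is exact to machine precision — the basis for
the fixture generators used throughout the tests.

## Dihedral grid and constrained embedding

The grid scans the three alternating endocyclic dihedrals C1–C2–C3–C4,
C3–C4–C5–O5 and C5–O5–C1–C2 over −60…+60° in 15° steps (9³ = 729 points
per rotamer), enumerated in lexicographic order. Dihedral signs follow
the same convention as RDKit's `GetDihedralDeg`.

A six-membered ring has exactly three pucker degrees of freedom, so a
triple of alternating dihedrals pins the ring: we parametrize candidate
rings by the Cremer–Pople mode amplitudes (q2x, q2y, q3) — which
guarantees ring closure by construction — and solve the 3×3 system by
least squares from three starting basins (both chair signs and the
equator). Residuals are ~1e-14° over the whole default grid; a point
whose best residual exceeds 1° would be recorded as a failed grid point
and its CEL cell marked missing. The solver is memoized since every
rotamer and backend revisits the same 729 triples.

For a full molecule, the solved ring seeds a distance-geometry
embedding (ETKDG, seeded; retried with randomized coordinates and a
bumped seed on failure), and the structure is minimized under harmonic
torsion restraints (k = 10⁴ kcal·mol⁻¹·rad⁻²) on the three ring
dihedrals plus the acyl rotamer torsion, followed by a verification
pass: conformers deviating more than 1° on any constrained ring
dihedral are flagged failed rather than silently kept. The restrained
optimization realizes "all other internal coordinates unconstrained";
whether one should instead relax fully after a constrained start is a
genuinely open choice — we hold the constraints, since the grid's
purpose is exhaustive coverage, not stationary-point hunting.

The rotamer torsion is auto-detected as (ring-neighbor toward C1) –
C(attach) – O(ester) – C(carbonyl), with targets R1 = 0° (carbonyl syn,
pointing toward the anomeric carbon, participation-capable) and
R2 = 180°; both are configurable. The rotamer restraint is verified
more loosely (≈5°) than the ring restraints because the ester torsion
sits in a softer potential.

## Energy backends

* **Toy surface**: E(θ, φ, rotamer) = baseline − Σ depth·exp(−d²/2w²)
  (+ per-rotamer offset), d the great-circle distance to a planted well.
  Minima are known by construction, making the toy backend the
  parameter-recovery oracle: planting wells at named canonical
  conformers and asking the full pipeline to find them again tests
  grid, solver, pucker assignment, binning and minimum detection at
  once.
* **Forcefield**: RDKit MMFF94 (UFF fallback when parameters are
  missing, as for some cation centers). Vibrational analysis is a
  surrogate: central-difference Hessian of the forcefield gradient
  (step 10⁻³ Å), mass-weighted and diagonalized, the six smallest-|λ|
  modes discarded; IR intensities are |Σ q_i l_i|² from Gasteiger
  charges — a fixed-charge dipole-derivative approximation that gives
  qualitatively shaped spectra and non-negative intensities but no
  quantitative band strengths.
* **External QC adapter**: writes byte-stable input decks (route line,
  charge/multiplicity, coordinates, `modredundant` frozen-dihedral
  blocks, PCM solvent keyword on request) and parses logs (last SCF
  energy, last orientation block, frequency/intensity lines, imaginary
  count = number of negative frequencies), raising a parse error that
  names the missing section. A neutral JSON-lines interchange format is
  the canonical boundary so no test ever needs the external program.

Energies are hartree inside QC results and kJ/mol everywhere else;
kcal/mol appears only at the rotamer-comparison and contour boundaries
where that unit is conventional.

## Thermochemistry

Standard RRHO: ZPE = ½·N_A·h·c·Σν̃; vibrational entropy and thermal
energy from the harmonic partition function; optional ideal-gas
translational (1 atm) and rigid-rotor rotational terms when mass and
inertia are supplied (symmetry number 1 by default — the cations are
asymmetric). The quasi-harmonic scheme raises frequencies below a
100 cm⁻¹ cutoff to the cutoff **for the entropy only**, the
frequency-raising flavor of the quasi-harmonic family; the
entropy-interpolation flavor is a noted alternative and both schemes
coincide whenever all modes are above the cutoff. Default temperatures:
213.15 K for CEL free energies (the glycosylation temperature, −60 °C)
and 298 K for IR-ensemble weights. Boltzmann weights are computed
shift-invariantly from the minimum.

## CEL maps

Slice scheme: θ-band edges (0, 26.4, 71.4, 108.6, 153.6, 180)° — the
midpoints between the canonical tiers — with 30° φ bins centered on the
canonical φ values in the three non-polar bands and single polar-cap
cells, i.e. 38 cells in bijection with the 38 canonical conformers.
Each cell stores its lowest-energy member (ties by input order);
missing cells are listed, not dropped. Local minima are occupied cells
not exceeded by any occupied neighbor (φ-periodic, adjacent bands, with
polar caps adjacent to the whole neighboring band); on a flat surface
every occupied cell is reported — degenerate but explicit. Heat maps
are contoured at 0.5 kcal/mol by default and exported with a
byte-stable CSV (one row per occupied cell). The rotamer comparison
uses a shared energy zero across both maps and a 0.5 kcal/mol
significance threshold below which the verdict is "indeterminate".
Duplicate collapse (0.1 Å RMSD, 0.1 kJ/mol) is available for
constrained ensembles that converge onto identical structures.

## IR pipeline

Stage defaults — 500 embeddings, ≤ 40 by greedy max–min heavy-atom RMSD
(Kabsch superposition, lowest-energy record seeded first), 40 kJ/mol
energy window (80 for pyranosyl cations, whose conformer manifolds are
broader), 0.975 frequency scaling, 20 cm⁻¹ broadening, 298 K — are the
standard operating point of this workflow and are all overridable in
`PipelineConfig`. The 20 cm⁻¹ width is interpreted as **FWHM** (the
usual convention in ion spectroscopy); a switch accepts σ instead.
Broadening uses unit-area Gaussian kernels on a 1 cm⁻¹ grid over
700–1850 cm⁻¹ (the instrument range), so integrated intensity is
conserved up to grid truncation.

The match score is the cosine similarity of max-normalized traces on a
common grid (Pearson correlation available); no community-standard
quantitative metric exists for "best matching" in this setting, so the
score is a documented stand-in with the right invariances (symmetric,
scale-invariant, self-match = 1). Mixture spectra support explicit
fractions; equal fractions and equal-energy Boltzmann weighting agree
exactly.

Classification windows: 1600±25 (oxocarbenium C1=O5⁺ stretch), 1800±30
(intact acetyl C=O), 1550±25 / 1500±25 (dioxolenium stretch / bend),
1730–1790 (carbonyl of ring-opened species). Rules: oxocarbenium =
1600 ∧ 1800 ∧ ¬1550; dioxolenium = 1550 ∧ 1500 ∧ ¬1800; ring-opened =
1550 ∧ (1730–1790), checked first since its carbonyl window overlaps
the acetyl window; anything else is mixed/indeterminate. Peaks are
local maxima above 5 % of the trace maximum (configurable).

## What the surrogates do and do not show

The toy and forcefield backends exercise every pipeline contract —
counts, orderings, binning, weighting, determinism under a seed — and
the toy backend additionally validates minimum recovery against planted
ground truth. They do **not** reproduce quantum-chemical energetics:
forcefield relative energies of cationic sugars are qualitative, the
surrogate intensities are fixed-charge approximations, and production
relative energies (e.g. dioxolenium-vs-oxocarbenium gaps of a real
donor) require the external-program adapter at an appropriate level of
theory with continuum solvation. Test problem sizes (the full 729-point
grid on toy surfaces; a tetrahydropyranyl cation for the molecular
paths) were chosen so the whole suite exercises the complete default
workloads while staying desk-scale.

## Known limitations

* Furanose (five-membered) pseudorotation is out of scope.
* The dihedral-triple solver assumes the idealized equilateral ring
  template for seeding; highly distorted real rings still satisfy the
  restraints after optimization, but the seed may be strained.
* MMFF lacks parameters for some cationic centers; the UFF fallback is
  automatic but lower quality.
* No anharmonic or hindered-rotor corrections; no transition-state
  searches between grid cells.
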