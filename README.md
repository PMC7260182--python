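# glycocel

Conformational energy landscapes and infrared ion spectra of glycosyl
cations.

## The problem

When a glycosyl donor is activated, the leaving group departs and a
positively charged sugar intermediate forms. Its fate decides the
stereochemistry of the glycosidic bond: the flat oxocarbenium ion
(C1=O5⁺) is attacked from either face, while an acyl protecting group at
C-2, C-3, C-4 or C-6 can swing over and bridge to the cationic center,
forming a bicyclic **dioxolenium** ion that blocks one face. Whether that
neighboring-group or long-range participation (NGP/LRP) actually happens
is hard to observe directly; two computational/spectroscopic workflows
address it and this package implements both:

1. **CEL mapping** — the conformational preferences of the
   six-membered ring are surveyed exhaustively by scanning three
   alternating endocyclic dihedrals (C1–C2–C3–C4, C3–C4–C5–O5,
   C5–O5–C1–C2) from −60° to +60° in 15° steps: 9³ = 729 prefixed
   conformations per acyl rotamer. Each optimized structure is located
   on the Cremer–Pople puckering sphere by its amplitude Q and angles
   (θ, φ), assigned to one of 38 canonical conformer regions (²C, 6 B,
   6 S, 12 H, 12 E), and binned into a relative-free-energy heat map
   ("CEL map") per rotamer. Rotamer R1 points the acyl carbonyl toward
   C-1 (participation feasible); R2 points it away (free oxocarbenium).
   ΔΔG between the two map minima is the read-out: a deeper R1 surface
   means participation is thermodynamically favorable.
2. **IR ion-spectrum simulation** — candidate ion structures defined as
   SMILES are subjected to a staged pipeline (500 distance-geometry
   conformers → forcefield minimization → max–min RMSD selection of ≤ 40
   → 40/80 kJ·mol⁻¹ energy window → harmonic frequencies × 0.975 →
   20 cm⁻¹ FWHM Gaussian broadening → Boltzmann-weighted ensemble at
   298 K), matched against experimental traces over the 700–1850 cm⁻¹
   instrument range, and classified from diagnostic bands: oxocarbenium
   (C1=O5⁺ stretch ≈ 1600 cm⁻¹ with intact ester C=O ≈ 1800 cm⁻¹),
   dioxolenium (O–C=O⁺ stretch ≈ 1550 and bend ≈ 1500 cm⁻¹), or
   ring-opened species (dioxolenium bands plus a carbonyl at
   1730–1790 cm⁻¹).

Electronic structure is consumed through a pluggable backend contract:
an analytic toy surface over the puckering sphere (for validation with
planted minima), an RDKit MMFF94/UFF forcefield backend (including a
surrogate vibrational analysis from the numerical Hessian), and a
file-based adapter that writes input decks for — and parses logs from —
an external quantum-chemistry program.

## Worked example

Plant a 30 kJ/mol well at the ⁴C₁ chair on the R1 surface and a 20
kJ/mol well at the ⁴H₃ half-chair on R2, then run the full
grid → optimize → map → compare workflow:

```python
from glycocel import grid_enum as ge, cel_map
from glycocel.energy_backends import ToyPuckerBackend, ToyWell

wells = [ToyWell(0.0, 0.0, 30.0, width=12.0, rotamer="R1"),
         ToyWell(50.77, 210.0, 20.0, width=12.0, rotamer="R2")]
records = ge.run_grid(None, ToyPuckerBackend(wells))
ok = [r for r in records if r.ok]
ref = min(r.best_energy() for r in ok)
m1 = cel_map.build_map(records, "R1", reference_energy=ref)
m2 = cel_map.build_map(records, "R2", reference_energy=ref)
print("R1 minimum:", m1.binning.cell_label(m1.min_cell()), f"{m1.min_energy():.2f} kJ/mol")
print("R2 minimum:", m2.binning.cell_label(m2.min_cell()), f"{m2.min_energy():.2f} kJ/mol")
cmp_ = cel_map.compare_rotamers(m1, m2, threshold_kcal=0.5)
print(f"ddG(R1-R2) = {cmp_.ddg_kcal:+.2f} kcal/mol -> {cmp_.verdict}")
```

prints

```
R1 minimum: 4C1 0.00 kJ/mol
R2 minimum: 4H3 10.00 kJ/mol
ddG(R1-R2) = -2.39 kcal/mol -> LRP-favorable
```

The map minima land exactly in the planted cells, the 10 kJ/mol designed
depth difference is recovered (−2.39 kcal/mol), and because the
participating rotamer is more stable by more than the 0.5 kcal/mol
threshold the verdict is LRP-favorable.

The IR pipeline runs the same way from a SMILES:

```python
from glycocel import ir_pipeline as ir
result = ir.run_pipeline("C1CC[O+]=CC1", ir.PipelineConfig(seed=1))
print(result["stages"])   # {'generated': 500, 'selected': 4, 'filtered': 4}
```

500 random conformers of the tetrahydropyranyl oxocarbenium collapse to
4 distinct ring puckers after minimization and RMSD pruning — the
expected behavior for a bare six-membered ring cation — and the
Boltzmann-weighted broadened trace is in `result["spectrum"]`.

A thin CLI wraps the same calls: `glycocel cel`, `glycocel ir`,
`glycocel classify`, `glycocel match`.

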