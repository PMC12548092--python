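# akfray

Quantitative analysis of **helical fraying in adenylate kinases** — the
reversible loss of structure at α-helix termini that lets these enzymes
open and close their substrate-binding subdomains.

Adenylate kinase (AK) catalyzes ATP + AMP ⇌ 2 ADP and must close its
ATP-binding (ATPlid) and AMP-binding (AMPbd) subdomains over substrates to
assemble the active site. The terminal turns of several helices act as
hinges for that transition: they bend, unwind or fold depending on ligation
state. `akfray` implements the full analysis chain used to quantify these
events:

1. **¹⁵N relaxation fitting** — single-exponential fits of T₁/T₂ peak-height
   decays, I(t) = I₀·e^(−t/T_d), with Monte-Carlo errors, and heteronuclear
   NOE = I_sat/I_unsat with propagated noise errors.
2. **Lipari–Szabo model-free analysis** — spectral density
   J(ω) = S²τ_m/(1+ω²τ_m²) + (1−S²)τ/(1+ω²τ²), 1/τ = 1/τ_m + 1/τ_e;
   prediction of T₁/T₂/NOE from dipolar (r_NH = 1.02 Å) and CSA
   (Δσ = −160 ppm) interactions; global τ_m / axially symmetric diffusion
   estimation; per-residue χ² fits of S² and τ_e with model selection and
   Monte-Carlo errors.
3. **ΔS² ordering statistic** — ΔS² = S²(bound) − S²(apo), significance
   threshold = trimmed mean + 3 SD, and contiguous-stretch calling to detect
   segments that fold upon ligand binding.
4. **Chemical-shift projection analysis** — per-residue directionality
   cosθ = A·B/(|A||B|) and degree of closure X = A·B/|A|² of a variant's
   amide shift change B against the wild-type open→closed vector A.
5. **Helix geometry** — Kabsch–Sander H-bond helicity assignment, helix-axis
   fitting, core superposition (Kabsch), and from these the tilt angle,
   spatial translation, terminal fraying and bend angle of a helix between
   two structural states.
6. **Kinetics & stability** — Michaelis–Menten fits
   (V/[E]tot = k_cat[S]/(K_M+[S])) with replicate errors and
   specificity-ratio tables; k_cat from ³¹P progress curves of the
   reversible reaction; two-state van 't Hoff fits of CD thermal melts.

A seeded **synthetic-data module** generates inputs with the statistical
structure each stage assumes, so the entire pipeline is testable by
parameter recovery with no downloads.

## Worked example

Recover a programmed helix rearrangement — 21° tilt, 5.8 Å translation and
three frayed C-terminal residues, the magnitude seen for the AMPbd helix of
an archaeal AK upon closure:

```python
from akfray.synthetic import gen_helix
from akfray.helix import compare_helix

ref, moved = gen_helix(16, tilt_deg=21.0, translation_ang=5.8, n_fray=3, seed=5)
cmp = compare_helix(ref, moved, helix_range=(1, 16), core_range=(101, 120))
print(cmp.tilt_deg, cmp.translation_ang, cmp.frayed_c_terminal)
```

prints

```
21.000000000000014 5.799999999999983 [14, 15, 16]
```

i.e. after superposing the two states on the static core, the fitted helix
axes differ by exactly the programmed 21°, the axis anchor points are
5.8 Å apart, and the last three residues lost their backbone i→i+4 hydrogen
bonds. The numbered scripts under `analysis/` run each stage the same way
(`python analysis/01_catalytic_ratios.py`, …) and write their tables to
`results/`.

A CLI exposes every stage for file-based pipelines, e.g.

```
akfray simulate relaxation --seed 1 --out sim/
akfray relax-fit --t1 sim/t1_peaks.csv --t2 sim/t2_peaks.csv --noe sim/noe_peaks.csv --out relax/
akfray modelfree --relaxation relax/relaxation.csv --out mf/
```

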