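# Methods

This note documents the models implemented in `akfray`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.

## ¹⁵N relaxation fitting

Peak heights (not volumes) are the intensity observable. Each residue's
T₁/T₂ series is fitted to I(t) = I₀·e^(−t/T_d) by unweighted nonlinear
least squares; duplicated relaxation delays are kept as separate
observations, which weights them naturally. Initial guesses are I₀ = max
intensity and T_d = the delay whose intensity is nearest I₀/e — robust and
derivative-free. Parameter uncertainties come from a residual bootstrap:
`n_mc` synthetic series are drawn around the fitted curve with Gaussian
noise equal to the fit RMSE and refitted; the reported σ is the standard
deviation over refits (default n_mc = 500; with n_mc = 0 the
covariance-matrix errors are used, which is what the fast recovery suites
do). Fits with T_d ≤ 0 or no convergence are returned as flagged failures
carrying the residue id, and count as missing when the per-experiment
results are joined into relaxation records.

The heteronuclear NOE is I_sat/I_unsat with

σ_NOE = |NOE|·√((σ_sat/I_sat)² + (σ_unsat/I_unsat)²),

where the σ are the RMS noise of empty spectral regions.

## Model-free analysis

The spectral density is the two-Lorentzian Lipari–Szabo form; the function
`spectral_density` returns it without the conventional 2/5 normalization
(matching how the expression is usually quoted), and `predict_rates`
applies the 2/5 inside the rate prefactors, so absolute T₁/T₂/NOE are on
the standard physical scale. Rates use the dipolar constant
d² = (μ₀ħγ_Hγ_N/(4π r³))² with r_NH = 1.02 Å and the CSA constant
c² = (ω_N·Δσ)²/3 with Δσ = −160 ppm; γ values are CODATA and γ_N is
negative (which is why flexible amides show negative NOEs). In the extreme
narrowing limit the dipolar T₁/T₂ → 1 exactly, while CSA relaxes T₂ 7/6
faster than T₁, so the combined limit is (2.5d² + 7c²/6)/(2.5d² + c²); the
tests assert both forms rather than pretending the ratio is 1 with CSA on.

The per-residue target function is χ² = Σ((exp−cal)/σ)² over T₁, T₂ and
NOE, fitted in time-constant space. Three internal-motion models are
fitted — M1 (S²), M2 (S², τ_e), M5 (S_f², S_s², τ_s with S² = S_f²S_s²) —
with bound-constrained least squares and a small multistart. Model
selection uses AIC = χ² + 2k: with only three observables per residue the
small-sample-corrected AIC is undefined for k ≥ 2 (its correction term
divides by n−k−1 = 0), so the plain criterion is the deterministic,
parameter-penalizing choice that remains well defined. Monte-Carlo errors
come from refits of records perturbed by their stated uncertainties
(default 500 draws).

**Overall diffusion.** The isotropic estimate solves each rigid residue's
T₁/T₂ ratio for a local effective τ_m and takes a 10%-trimmed mean. "Rigid"
means NOE > 0.65 and T₁/T₂ inside the Tukey fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR]. Because internal motion biases the ratio
estimator low by a few percent whenever τ_e > 0, the pipeline then
re-optimizes τ_m by minimizing the summed per-residue χ² over a ±15%
window (`optimize_tau_m`); this removes the bias (worst-case error drops
from ~2.7% to <0.5% in the recovery suite). The axially symmetric model
fits (τ_m, D∥/D⊥, axis orientation) to the local effective τ_m versus the
Woessner three-exponential prediction at each NH vector's angle from the
candidate axis, with six multistart axis seeds; it is kept only if it
lowers the reduced residual. Rhombic diffusion and R_ex exchange terms are
out of scope.

## ΔS² ordering statistic

ΔS² = S²(bound) − S²(apo) on the shared residues; positive means ordering
upon binding. The significance threshold is the mean plus three standard
deviations of the symmetrically 10%-per-tail trimmed ΔS² sample (the SD is
computed on the trimmed sample for consistency; the trim fraction is a
tunable with default 0.1). Significance is strict (>). Maximal runs of
consecutive significant residues are reported as stretches; single-residue
runs are listed separately as "isolated" rather than treated as folding
segments, and gaps are never bridged.

## Chemical-shift projection

Reference vectors A = (Δδ¹H, w·Δδ¹⁵N) use the standard amide compound-shift
weight w = 0.2. cosθ = A·B/(|A||B|) and X = A·B/|A|², so X is signed
(anti-correlated motion gives X < 0) and X = 1 means closure equal to the
wild type. Residues with |A| < 0.025 ppm (weighted) are excluded with a
reason — near-zero reference vectors carry no directional information — and
a zero variant vector yields cosθ = NaN, X = 0, flagged. Summaries average
X over residues with cosθ above a cutoff (default 0.9).

## Helix geometry

Helicity is assigned from backbone hydrogen bonding: residue i is helical
iff it participates in an i→i+4 H-bond (as carbonyl acceptor or amide
donor) with Kabsch–Sander electrostatic energy below −0.5 kcal/mol. Amide
protons absent from the model are built 1.0 Å from N along the reversed
preceding carbonyl C→O direction. This matches the visual "frayed last
turn" criterion and handles unmodeled loops: residues missing from a
requested range are "unmodeled" (non-helical by absence), residues flanking
a chain break are "unassessable".

The helix axis is the principal direction of local helix-center points
p_i = mean(Cα_{i−1..i+2}); the anchor (centroid of the p_i) lies on the
axis by construction, and the goodness is the RMS point-to-axis distance.
A 4-Cα window leaves a small once-per-turn wobble (~0.2 Å for an ideal
helix of radius 2.3 Å), which is irrelevant for the axis direction of
segments of two or more turns but means the goodness of even a perfect
helix is not zero. Frayed residues are excluded from axis fits through
their helicity flags.

`compare_helix` superposes state B onto state A over the main-chain atoms
(N, CA, C, O) of a rigid core range by the Kabsch algorithm (proper
rotation enforced), then compares axes fitted to the longest residue run
helical and modeled in both states. Tilt is the angle between the
N→C-oriented axis directions; the translation is the distance between the
axis anchor points of that same residue window — the reference points are
recorded in the output metadata since "translation of a helix" is not
well defined without them. Fraying is reported per terminus as residues
helical in one state but non-helical/unmodeled in the other. Bend angles
are fitted independently to the two sub-segments on each side of a split
(≥ 6 residues each). Author residue numbering is used throughout; the
first model of multi-model files is read; HETATM records are ignored
unless amino acids.

## Kinetics and stability

Michaelis–Menten fits run per technical replicate with kcat/K_M reported
as mean ± SD across replicates (single-replicate tables fall back to
covariance errors); a fit whose K_M lies outside the concentration grid is
flagged rather than reported. Specificity-ratio tables propagate errors to
first order (relative errors in quadrature).

Progress curves use a reversible random bi-bi rate law collapsed to
separable Michaelis terms,

v = k_cat[E]([ATP][AMP] − [ADP]²/K_eq) / ((K_M,ATP+[ATP])(K_M,AMP+[AMP])),

with K_eq ≡ [ADP]²/([ATP][AMP]) at equilibrium fixed (default 0.5) and the
K_M values supplied, leaving k_cat as the single fitted parameter. The
state is integrated as a single reaction extent ξ (ATP = ATP₀−ξ,
AMP = AMP₀−ξ, ADP = ADP₀+2ξ), so adenine count and total phosphate are
conserved to machine precision by construction. The model form is recorded
in the fit metadata and swappable. Non-monotone early ADP buildup beyond
the noise level triggers a warning.

Thermal melts use the two-state van 't Hoff model with linear baselines,
K(T) = exp(−ΔH_vH(1 − T/T_m)/(RT)) with T absolute and ΔCp = 0; at T = T_m
the fitted signal is the midpoint of the baselines. Fits whose midpoint
falls outside the scanned temperature range are flagged.

## Synthetic data

All generators take explicit seeds (never global state) and add Gaussian
noise as a stated fraction of the maximum signal, emulating peak-height or
detector noise. Noiseless output is exactly invertible by the paired fit —
that property is tested for every stage.

- **Relaxation**: intensities decay around T₁/T₂/NOE predicted by the same
  forward model the fits use, on the published delay schedules (T₁: 50,
  100 (×2), 200, 400, 500, 600, 800, 1000 (×2), 1200, 1500 ms; T₂: 16.96 …
  288.32 ms with 169.60 duplicated). The recovery suites use a 20-residue
  protein at 850 MHz with τ_m = 9 ns, τ_e = 50 ps and per-residue S² drawn
  as a mostly rigid backbone (0.8–0.95) with a flexible quarter (0.4–0.8) —
  the composition of a folded protein, and one that leaves enough rigid
  residues for tensor estimation.
- **Shift tables**: wild-type open→closed vectors drawn with weighted
  magnitudes safely above the |A| cutoff; the variant-bound state is
  displaced by a programmed closure fraction along A plus an optional
  orthogonal (off-pathway) component; optional Gaussian peak-position noise.
- **Helices**: ideal α geometry (φ = −57°, ψ = −47°, trans ω, standard
  bond lengths/angles, backbone built by internal-coordinate chaining).
  Fraying sets terminal φ/ψ to extended values (−120°, +120°); because a
  torsion change only moves atoms downstream of the rotated bond, fraying
  the last k residues also perturbs ψ of residue n−k−1 (which moves only
  that residue's carbonyl O), so that exactly k residues lose their
  backbone H-bonds — the generated truth then matches the helicity caller
  residue-for-residue. The transformed state is rotated about an axis
  perpendicular to the helix axis through the centroid of the folded
  part's center points and displaced perpendicular to the axis, which
  makes the programmed tilt and translation equal to what `compare_helix`
  measures. A static helix at residues 101–120 serves as the superposition
  core. Optional coordinate jitter emulates refinement error.
- **Kinetics/melts**: forward models evaluated on grids bracketing K_M or
  the transition, plus noise; progress curves conserve adenine and
  phosphate exactly.

What the generators do **not** emulate: spectral (frequency-domain)
artifacts, peak overlap or misassignment, anisotropic-tensor relaxation
data, chemical-exchange line broadening, crystallographic disorder beyond
Gaussian jitter, and instrument drift in CD melts. Passing recovery tests
therefore demonstrate the correctness of the estimators under their stated
noise models, not robustness to every pathology of real spectra.

## Problem sizes

The validation suites use 20 residues × 10 seeds for the model-free
recovery, 20 instances per fitting operation for the grid-search oracles
(1000×1000 lattice for decays, 200×200 for Michaelis–Menten and model-free),
150 residues for the ΔS² pipeline, 60 residues × 4 closure levels for the
projection analysis, 20 seeds for helix recovery and 20 seeds for melt-bias
estimation — sizes chosen to give stable statistics from a single-CPU run
of about a minute.

## Known limitations

- Only isotropic and axially symmetric diffusion; no rhombic tensors, no
  R_ex terms, no reduced spectral-density mapping.
- The projection formulas implement the behavior the analysis requires
  (X = 1 ⇔ wild-type-like closure; cosθ as directionality with the 0.2
  ¹⁵N weight); published applications may differ in weighting details.
- The 21°/5.8 Å helix comparison depends on the axis and anchor
  definitions recorded in the output metadata; other choices of reference
  points will give somewhat different translations.
- The progress-curve mechanism is a separable approximation of the full
  random bi-bi rate law with fixed K_eq; k_cat estimates inherit that
  approximation.
- The CLI's `simulate` subcommand exists for pipeline testing, not for
  producing publication-grade synthetic spectra.
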