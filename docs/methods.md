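# Methods

## Scope and assumptions

The package estimates the effective homogeneous in-plane electric field
experienced by the anionic acylimine-extended (RFP-type) chromophore and
models the field dependence of its nonradiative decay. The underlying
assumptions are those of the quasi-empirical Stark approach:

1. the local field is unchanged by electronic excitation and by the
   excited-state phenolate twist (ground-state-only environment
   polarization);
2. the spatially varying microscopic field acts like one effective
   homogeneous field **E** = (Eₓ, E_y) in the chromophore plane;
3. the chromophore is planar, and the molecular frame is the principal
   frame of the polarizability-change tensor Δα (x along the
   imidazolinone→phenolate ring–ring axis, y in-plane toward the
   acylimine);
4. the 0–0 band is treated in the two-level approximation for 2PA, and
   the 1PA maximum is identified with the 0–0 transition;
5. the vertical-transition approximation: excited-state Δμ and Δα refer
   to unrelaxed nuclear positions.

Out-of-plane field components, vibronic (Herzberg–Teller) structure on
the blue side of 2PA bands, and per-atom nonuniform fields are not
modelled.

## Units

All internal computation is CGS-Gaussian (e.s.u.); the user-facing units
are D, Å³, MV/cm, GM, ns, kcal/mol. Two bookkeeping identities carry the
whole package: 1 D/Å³ = 10⁶ statvolt/cm = 299.792458 MV/cm exactly
(statvolt = 299.792458 V, CODATA-derived), and D²/Å³ = 10⁻¹² erg, which
lets the Stark conic be solved directly in practical units. The unit
registry is closed by design; it is not a general unit-algebra system.

## Key parameters

| parameter | default | units | why |
|---|---|---|---|
| n (emission, Einstein relation) | 1.33 | – | aqueous buffer; reproduces the 7.1 D series-average dipole |
| n (2PA local field, factor A) | 1.33 | – | buffer; 1.4 (protein interior) matches the reference \|Δμ\| set ~1–2% better — both supported, never mixed silently |
| Δμ₀ = (5.53, −3.17) | – | D | vacuum chromophore, ZINDO at B3LYP geometry |
| Δα = diag(−61.3, 6.9) | – | Å³ | slopes of Δμ(E) over Eₓ∈[0,20], E_y∈[0,50] MV/cm |
| ν̄₀ | 16 260 | cm⁻¹ | average of PR-CIS(Ds) values for three chromophore conformations |
| β prior | −10 | deg | calculated vacuum transition-dipole direction |
| q | 1.54e−10 (0.32 e) | esu | transferred charge in the P-twist CT step (literature QM) |
| ΔG⁰_vac | −7.9 | kcal/mol | vacuum CT free energy (literature QM) |
| T | 298.15 | K | ambient; not stated by the source analysis, exposed in config |
| η grid | −0.20…0.10 step 0.05 | – | resolves the optimum; refinable |
| ε_denatured | 44 100 | M⁻¹cm⁻¹ | alkali-denatured chromophore anchor at 452 nm |

## Numerical choices

* **Conic–circle solve.** The system is linear in (Δμx², Δμy²) and is
  solved exactly; no iterative root finding. Squared components negative
  beyond −10⁻⁹·|Δμ|² raise "no real intersection" with both residuals;
  smaller negatives are clipped to zero, and an exactly-zero square
  collapses the mirror candidates. Δαxx = Δαyy is rejected (the
  circle–circle case has no unique structure).
* **Quadrant selection** is a scored rule, not a hard-coded quadrant.
  The transition dipole is a bidirectional axis, so angular distances are
  taken mod 180°; the admissible axes of a candidate are δ ± γ and the
  score is the smaller axial distance to the β prior, normalized by 90°.
  A field prior adds Euclidean distance normalized by the prior's norm.
  Quadrants II and IV tie exactly under the axis metric (δ differs by
  180°); the tie breaks toward quadrant IV, the MD-supported default,
  and every estimate records which rule fired. Supplying a large-Eₓ
  field prior reproduces the III-over-IV choice for the far-red outlier.
* **Einstein-relation summary.** Default is the arithmetic mean of
  per-protein dipoles; a slope-through-origin fit of k_R vs ν̄³ is
  provided since "linear fit" does not specify intercept handling (the
  two differ by < 0.5%).
* **Marcus fit.** Unweighted OLS on ln k_nR (in s⁻¹; the rate unit only
  shifts b₀, leaving b₁, b₂ and all extracted parameters except B
  invariant). Optional 1/σ² weights. The inversion reduces to
  u² − b₁u − (ΔG⁰_vac/k_BT)·b₂ = 0 with u = qΔx/2k_BT; the positive root
  (Δx > 0, charge flowing phenolate→imidazolinone) is used and both
  roots are reported. b₂ ≥ 0 (flat/inverted curvature) is rejected as
  unidentifiable. Substituting extracted parameters back into the
  coefficient expressions reproduces (b₀, b₁, b₂) to 10⁻⁹ relative and
  is asserted in tests.
* **Rounded-table caveat.** Fitting the *printed* (rounded) rates and
  fields gives λ ≈ 22.7–23 kcal/mol and Δx ≈ 5.6–6.1 Å, whereas the
  reference parameter set (λ = 21.9, Δx = 6.7) evidently derives from
  unrounded inputs. The parameter algebra is therefore validated by the
  exact reverse-consistency round trip, not by pinning the forward fit
  to those numbers.
* **Uncertainties** are first-order propagations: |Δμ| from the σ₂
  (±15%) and ε (±10%) relative errors in quadrature plus the Ω standard
  deviation through γ; field components from |Δμ| (±5% typical). The
  error model of the reference tables is not stated, so these are
  approximations and the vacuum-constant errors are not propagated.
* **Ω plateaus** for the two-form decomposition are user-supplied (read
  from plateaus by eye in practice); a helper averages Ω over a
  wavelength window. Fractions are clamped to [0, 1] with a warning when
  noise pushes Ω outside [Ω_a, Ω_b].

## Synthetic data: what it emulates and what it does not

`synth_marcus_dataset` draws fields uniformly from the empirically
observed box (Eₓ 9–20, E_y 28–57 MV/cm), evaluates the Marcus rate with
the reference parameters and applies log-normal noise σ_ln = 0.05
(matching ~5–10% rate errors); 20 proteins per dataset. It emulates the
noise and leverage of a realistic protein panel but not: correlated
errors between Eₓ and E_y (which share the |Δμ| measurement), per-protein
variation of q, Δx or the twist barrier (the model holds them common, as
for the mScarlet/eqFP670 outliers), or field-estimation error itself.
Calibration at these conditions (200 replicates): λ and Δx means are
within 2.5% of truth; individual replicates scatter more (λ within 10%
of truth in ≈93% of replicates; Δx is noisier because it enters through
the root of the fitted curvature). Passing recovery tests therefore
demonstrate unbiasedness of the estimator chain at panel sizes an
experiment could reach, not per-dataset 5% accuracy.

`synth_two_form_spectrum` mixes two Gaussian 2PA bands with distinct Ω
plateaus (0.698/0.730, the published mPlum-like pair) via the additivity
rule. Noiseless mixtures are inverted to machine precision (the
decomposition is the exact algebraic inverse of the generator). With the
instrument-level Ω noise (sd 0.004, ~12% of the plateau gap) the
major-form band integral is recovered within ~5% and the minor form
(ρ_b = 0.2) within ~15%; the minor band is intrinsically noise-limited.
Real spectra additionally carry vibronic structure and wavelength-
dependent σ₂ calibration error that the generator does not emulate.

## Problem sizes

The test suite runs the 200-replicate recovery study twice (unit and
end-to-end variants), property tests at 50 examples each, and the full
pipeline on the seven-protein reference set; the whole suite completes
in a few seconds on one CPU. The acceptance script touches only the
reference tables and closed-form solves.

## Known limitations

* The method yields |Δμ| and a four-fold sign ambiguity; the quadrant
  choice rests on priors (β, optionally MD fields) and is recorded, not
  proven.
* ε(0–0) is approximated by ε_max when the 0–0 band is not exactly the
  absorption maximum.
* The Marcus treatment assumes a common (q, Δx, Δy, barrier stiffness)
  across proteins; sterically locked or conformation-switching variants
  fall off the correlation and must be excluded explicitly (the include
  list is never automatic).
* Two rows of the shipped field table carry internal rounding
  inconsistencies in the source (mPlum red-shifted E_y, eqFP670-IV Eₓ);
  derived values are always recomputed from the dipole components.
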