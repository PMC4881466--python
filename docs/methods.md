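# Methods

## Scope and model

`hemekin` analyses UV-vis spectrokinetic data of heme proteins, built
around the nitrite-reductase chemistry of plant non-symbiotic
hemoglobins (the *Arabidopsis* AHb1/AHb2 family and their distal-pocket
mutants). Three layers are modelled:

1. **Spectra.** A pure heme species is represented by a set of Gaussian
   absorption bands, `A(λ) = Σ a_i exp(−4 ln2 (λ−c_i)²/w_i²)` with
   center `c_i` (nm), FWHM `w_i` (nm) and relative extinction amplitude
   `a_i`. Only peak *positions* are tabulated experimental quantities;
   band widths and Soret:visible amplitude ratios are package choices
   (defaults: FWHM 14 nm Soret, 22 nm visible/charge-transfer,
   amplitudes 100:10). Amplitudes are on a mM⁻¹cm⁻¹-like scale, so a
   species at concentration *c* (M) contributes `c·10³·A(λ)` AU at 1 cm
   path length. No extinction-coefficient calibration is attempted.

2. **Mechanism.** Nitrite reduction by deoxy (Fe²⁺) heme:
   `Fe²⁺ + NO₂⁻ + H⁺ → Fe³⁺ + NO· + OH⁻`, followed by NO capture
   `Fe²⁺ + NO· → Fe²⁺–NO`, with ferric heme recycled to deoxy by excess
   dithionite (collapsed into one pseudo-first-order constant
   `k_rered`). With nitrite in excess the reduction is
   pseudo-first-order, `k₁' = k₂(pH)·[NO₂⁻]`, and the proton consumed
   makes the bimolecular constant pH dependent:
   `k₂(pH) = k_ref·10^(order·(ref_pH − pH))`, i.e. proportional to
   [H⁺]^order. Activity corrections are ignored and the OH⁻ product is
   assumed buffered. The ODE system in (deoxy, ferric, NO) is
   integrated with LSODA (rtol 1e−8, atol 1e−12·total heme); nitrosyl
   is obtained as `total − deoxy − ferric`, so heme conservation holds
   exactly by construction. In the fast-recycle limit
   (`k_rered ≫ k₁'`) the deoxy pool decays mono-exponentially with
   `k_obs = k₁'` and the end state is fully nitrosyl; with
   `k_rered = 0` the same equations give the two-deoxy-per-nitrite
   stoichiometry (half nitrosyl, half ferric).

3. **Titrations.** Heme alkaline transitions are single protonation
   equilibria: protonated (acid) fraction
   `c₊(pH) = 1/(1 + 10^(n(pH − pK)))`, observed as
   `A(pH) = a_alk + (a_acid − a_alk)·c₊`.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `k_nir` | M⁻¹s⁻¹ | preset per variant (13.3, 7.3, 10.6, 171.90) | published bimolecular rates at pH 7.4, 25 °C |
| `k_rered` | s⁻¹ | 1 (library); 100 (recovery protocol) | see numerical choices |
| `k_no_capture` | M⁻¹s⁻¹ | 1e7 | generic fast capture; only its "large" regime matters, the true value for these proteins is not established |
| `proton_order` | — | 1 | single-proton mechanism prediction |
| noise σ (kinetics) | AU | 0.002 | per-point i.i.d. Gaussian; a typical benchtop photometric noise floor, no instrument noise model is published |
| noise σ (titration) | AU | 0.01 | ditto, manual mixing per pH point is noisier |
| grid | nm | 350–700, 1 nm | covers Soret, visible and CT bands |
| Savitzky–Golay | — | window 11, polyorder 3 | resolves 14-nm-wide Soret components without amplifying noise |
| peak prominence | AU | 1% of region max | rejects ripple, keeps the 10:1-weaker visible bands |

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical structure the inference
assumes: multi-band reference spectra with the tabulated peak
positions; mono-exponential deoxy→nitrosyl conversion with isosbestic
points; `k_obs` linear in [NO₂⁻]; rate ∝ [H⁺]; sigmoidal titration
curves; additive Gaussian noise. Default experiment mimicry: 10 µM
heme, five nitrite concentrations log-spaced 10–500 µM, 60 spectra per
series. Each series' time grid spans six characteristic times
(`6/k₁'`), so slow (wild-type, low nitrite) and fast (H66L, high
nitrite) reactions are equally well sampled; for the mid-range series
this lands in the tens-of-seconds sampling interval regime typical of
such experiments. A single top-level seed is split deterministically
into per-series sub-streams, making whole datasets bit-reproducible.

Not emulated: baseline drift and wavelength-correlated noise, nitrite
depletion (nitrite is held constant even below 5× heme, where a warning
is emitted), mixing dead time, photobleaching, protein instability
(relevant to the H66L-K69L double mutant), and the second ferric
transition above pH 9 (single-transition fits only; its presence in
real data shows up as structured residuals). Passing recovery tests
therefore demonstrate the *estimators* are unbiased and well scaled
under the assumed noise model, not that real instruments meet that
model.

## Inference chain

- **Unmixing:** each spectrum is decomposed into nonnegative reference
  contributions by NNLS (`min ‖Ac − s‖₂, c ≥ 0`; optional constant
  baseline column). Nonnegativity encodes physical concentrations;
  for full-rank noiseless mixtures it coincides with ordinary least
  squares, which the tests exploit via an exhaustive grid-search
  oracle.
- **k_obs:** `y = amplitude·e^(−k_obs t) + offset` by Levenberg–
  Marquardt, initialised from a log-linear fit of `(y − y_∞)` with
  `y_∞` taken from the tail. Constant series raise "no decay detected".
- **k₂:** ordinary least-squares slope of `k_obs` vs [NO₂⁻]
  (≥ 3 distinct concentrations).
- **Proton order:** slope of `log₁₀ k₂` vs −pH, so the single-proton
  prediction is +1 (rate increases as [H⁺] increases).
- **pK:** nonlinear least squares of the titration model with
  endpoints co-fitted; `n` is fitted by default (pass `fix_n=1` for
  pure one-proton behaviour). Requires ≥ 4 distinct pH points spanning
  ≥ 1 pH unit, else "transition not bracketed". Standard errors come
  from the fit covariance (no bootstrap).

## Coordination/spin rule table

`classify_state` maps peak positions to a heme state deterministically:

- **ferric:** Soret < 400 nm *and* a 620–650 nm charge-transfer band →
  pentacoordinate high-spin; anything else → mixed (the 404–412 nm
  ferric forms here are penta/hexa mixtures or six-coordinate species
  that peak positions alone cannot separate).
- **ferrous:** Soret in 418–428 nm only, with a resolved α/β pair in
  520–570 nm whose β band lies ≤ 534 nm → hexacoordinate low-spin;
  Soret in 430–440 nm only → pentacoordinate high-spin; Soret
  components in both windows are disambiguated by the visible bands —
  a deoxy-like pair with β ≥ 535 nm → pentacoordinate, otherwise a
  penta/hexa mixture.

The 400-nm ferric threshold separates the tabulated pentacoordinate
Sorets (390, 397 nm) from the non-penta forms (404–412 nm); the
α/β-position criterion is the classic low-spin (527/557-type) vs
high-spin (540/560-type) marker. Spectra without any Soret-window peak
return an `indeterminate` state with a diagnostic note rather than
raising.

## Numerical and design choices

- `k_rered` defaults to 1 s⁻¹ in `MechanismParams` (fast relative to
  wild-type `k_obs ≈ 10⁻³ s⁻¹`). The recovery protocol uses 100 s⁻¹:
  the fastest series it generates (H66L at 500 µM nitrite,
  `k₁' ≈ 0.086 s⁻¹`) needs `k_rered ≫ k₁'` for the single-exponential
  fast-recycle limit to hold — with 2 mM dithionite, re-reduction is
  not rate-limiting, and the analysis presumes it.
- Dual-Soret species (e.g. the acidic H66L deoxy form, 422/436 nm) are
  encoded as two bands of one mixed species at a 100:60 amplitude
  ratio — a prominent peak with a shoulder. The shoulder does not
  survive as a distinct absorbance maximum (the rendered apex sits at
  423 nm) but is resolved as a second minimum of the Savitzky–Golay
  second derivative, which is the point of that analysis.
- Where a species' band positions are not tabulated (wild-type deoxy
  hexacoordinate component, mutant nitrosyl forms) the band file marks
  the entry `synthetic_stand_in` and reuses the nearest characterised
  form; these choices affect only the realism of the forward model,
  not the identities the tests check.
- NNLS coefficient units: reference amplitudes are mM⁻¹cm⁻¹-like, so
  `extract_timecourse` divides coefficients by 10³ to report M.
- Degenerate inputs are rejected early with named errors: non-monotone
  wavelength grids, non-finite absorbances, bands outside the grid,
  constant decay series, identical titration endpoints, < 3 distinct
  nitrite concentrations, unsorted spectrum times.

## Problem sizes

The recovery suite uses 5 nitrite series × 60 spectra × 351
wavelengths per variant for the rate constants, 50 titration
replicates × 12 pH points per pK, and single noiseless instances for
the analytic checks — sizes at which the whole reproduction harness
(`hemekin reproduce`, `scripts/acceptance.py`) completes in seconds on
one CPU while leaving the stochastic recovery errors well below the
tolerances tested.

## Known limitations

- Band shapes are idealised Gaussians; real Soret bands are asymmetric,
  so absolute fractions from unmixing real spectra depend on the
  quality of measured reference spectra, not the packaged ones.
- The hexacoordination equilibrium itself (K_H) is not modelled; the
  penta/hexa composition enters only as a static mixture.
- No global (multi-wavelength SVD) kinetic analysis: the chain is
  per-timepoint unmixing plus single-trace exponentials, by design.
- Oxidative chemistry (peroxynitrite/H₂O₂ reactions of nitrosyl heme)
  can be *unmixed* with the generic deconvolver but has no dedicated
  kinetic model here.
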