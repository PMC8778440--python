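# Methods

`oligosaxs` models the absolute-scale SAXS intensity of a protein that
can populate several states (folded oligomers and/or unfolded chains)
in a water–cosolvent binary solvent, and fits batches of curves
globally for the thermodynamics that govern the state distribution.
This note documents the model, its assumptions, the numerical choices,
and what the synthetic-data tests do and do not demonstrate.

## Forward model

For one curve labeled by (c°, T, G, C_G°) the theoretical intensity is

    dΣ/dΩ(q) = n · P(q) · S_M(q)

with n = c·N_A/M1 the nominal monomer number density, P(q) the
effective form factor of the state mixture, and S_M(q) the measured
structure factor.  The chain of computations is:

1. **Equilibrium.**  The fractions x_j of monomers in each state and
   the first-shell water occupancies φ_j solve a coupled 2·Ns system:
   state formation 1→j in water with constant
   K_W1j = exp(−(ΔG_W,nel,1j(T) + ΔG_W,el,1j)/RT), cosolvent–water
   exchange at each state surface (Schellman model) with
   K_ex,j = exp(−ΔG_ex,j(T)/RT), and solvent mass balances relating the
   bulk composition x_Gb to the nominal composition (X_P, x_G) through
   the shell occupancies.  Every ΔG(T) follows
   ΔG = ΔG° + (ΔCp − ΔS°)(T − T°) − ΔCp·T·ln(T/T°) (natural logarithm;
   the thermodynamic derivation requires ln).  The electrostatic part
   is the Debye–Hückel self-energy of a charged sphere,
   G_el = N_A q_e²Z²/(8πε₀εR)·[1 − κ_D R/(1 + κ_D(R + a))], with the
   counterion ionic strength I_ci = ½·C_P Σ x_j α_j⁻¹|Z_j| recomputed
   self-consistently (the macroion itself is excluded from I: Debye
   screening is by small ions; the macroion is the screened object).

2. **Solvent densities.**  The bulk SLD ρ₀ follows from x_Gb; the
   "local domain" (first + second hydration shell) of each state gets a
   single SLD ρ_ld,j from the occupancies: bound cosolvent molecules,
   larger than the water sites they replace, displace
   k_j = m_j(1−φ_j)(ν_Gs−ν_Ws)/ν_Wb second-shell sites; the remainder
   fills with bulk solvent.  First-shell water is compacted by the
   factor d_j ∈ [1, 1.15] (ν_Ws,j = ν_Wb/d_j); the cosolvent site
   volume equals its bulk value.

3. **Form factors.**  Each state's structure (atoms + hydration-shell
   dummy spheres on a close-packed lattice) yields the orientationally
   averaged ⟨|ΔA_j|²⟩ and ⟨ΔA_j⟩.  Atoms scatter r_e·N_e minus a
   Fraser–MacRae–Suzuki Gaussian excluded-volume term at ρ₀; shell
   sites carry contrast (ρ_ld,j − ρ₀)·v_site with a Gaussian sphere
   profile.  The per-monomer normalization P_j = ⟨|ΔA_j|²⟩/α_j² makes
   n·Σ x_j α_j P_j equal the physical mixture intensity
   Σ n_j⟨|ΔA_j|²⟩ identically (pinned by a test at 0.5%).

4. **Structure factor.**  The mixture is mapped to effective particles
   with number-weighted R and Z.  The pair potential is hard-sphere
   double-Yukawa: DLVO screened Coulomb
   (B1C = Z²q_e²/(4πε₀ε(1+κ_D R)²), B2C = κ_D) plus a generic
   attraction with contact depth J (in units of k_BT; B1A = −2JR,
   B2A = 1/d).  S(q) is the analytic Percus–Yevick hard-sphere solution
   perturbed in the random-phase approximation,
   1/S = 1/S₀ + n_part·ũ(q)/k_BT, with the closed-form transform of
   each tail truncated at contact.  Finally
   S_M = 1 + β(q)[S(q) − 1].

### Choices where the design was genuinely open

* **Average amplitude.**  The orientational average of exp(iq·r) is
  exactly j₀(q|r|), so ⟨ΔA⟩ is computed as a closed-form j₀ sum about
  the scattering-length centroid rather than by angular quadrature;
  there is no quadrature error to control.
* **Coupling function.**  β(q) is the number-weighted decoupling
  approximation β = |P^(1)|²/(P·⟨α⁻¹⟩) with P^(1) = Σ x_j α_j P_j^(1)
  and P_j^(1) = ⟨ΔA_j⟩/α_j².  Under the per-monomer normalization this
  is the unique form that keeps β ∈ [0, 1] (Cauchy–Schwarz) and gives
  β ≡ 1 for a single spherically symmetric state of any aggregation
  number.  For genuine mixtures β(0) equals (Σp_jα_j)²/Σp_jα_j² < 1,
  the standard polydisperse decoupling result.
* **Hydration lattice.**  The dummy-sphere lattice is face-centered
  close packing with one water volume (ν_Wb°/N_A ≈ 29.9 Å³, sphere
  radius 1.93 Å) per site; a site belongs to shell s when its distance
  to the nearest van der Waals surface lies in ((s−1)·2.8, s·2.8] Å.
  Counts jitter by a few percent with lattice registration (rotations
  average this below 3%); site counts m_j, m_j2 are therefore plain
  state parameters that a config can override with reference values.
* **RPA tails.**  Yukawa tails are truncated at contact (r > 2R),
  consistent with the hard core; ũ(q) is then analytic.
* **Effective ε and microion radius.**  ε(T) is the Malmberg–Maryott
  pure-water polynomial (ε ≈ 78.3 at 25 °C); the cosolvent effect on ε
  is neglected (second order at ≤0.25 M).  The mean microion radius
  defaults to a = 2.0 Å, configurable.
* **Charged state conventions.**  Z_j is either supplied directly, set
  by the protein sequence through Henderson–Hasselbalch titration with
  a packaged pKa table, or scaled from the monomer (dimer = 2× monomer
  for the two-state scenario; Z_j = α_j Z_1 in oligomer ladders).

## Global fit

The merit function is H = χ² + γL: χ² is the average reduced
chi-square over curves (each curve's mean squared standardized
residual, then the mean over curves) and L couples the per-curve
attraction parameters X_i ∈ {J, d} across neighboring conditions,
L = Σ_i Σ_k Σ_p (1 − X_{i,k'}/X_{i,k})², where k' matches curve k in
all labels but the p-th and is nearest in that label (ties toward the
smaller value; categorical cosolvent type compares by id).  γ defaults
to 10⁻⁷; an adequate γ leaves γL near 10% of H when χ² ≈ 1.

Optimization is two-stage: a seeded differential-evolution global
stage over the shared thermodynamic parameters (Sobol initialization,
per-curve parameters held), then a trust-region least-squares polish
over all free parameters with the regularization terms appended as
√γ·(1 − X'/X) residuals, so the minimized sum of squares is exactly H.
Uncertainties are covariance-based (Gauss–Newton (JᵀJ)⁻¹ of the
unscaled standardized residuals at the optimum) and labeled as such;
no profile likelihoods are computed.

Degenerate regimes are handled explicitly: mass action is solved in
log space (hydration-site exponents of several hundred cannot
overflow), oligomer fractions below 10⁻¹⁵ are clamped to zero,
second-shell overflow (k_j > m_j2) clamps with a warning, and an RPA
instability (S ≤ 0) raises with advice to weaken J or dilute.

## Synthetic data and what the tests show

The generator emulates the statistical structure the fit assumes:
labeled design points (protein concentration × temperature × cosolvent
level), the exact forward model, and Gaussian noise with
σ(q) = baseline + fraction·I + counting·√I (defaults 10⁻⁵ cm⁻¹ + 2%
relative; counting term off).  The default scenario is a monomer–dimer
association with one nonionic sugar-like cosolvent: site counts
404/465 and 753/827, radii 17.0/26.7 Å, d_j = 1.07, formation
thermodynamics ΔG° = 2.95 kJ mol⁻¹, ΔS° = 564 J mol⁻¹ K⁻¹, ΔCp = 0
(≈28 released waters per monomer drive the entropy), exchange free
energies −0.4/−2.4 kJ mol⁻¹, monomer charge +8 at pH 5 in a 10 mM
buffer, J = 1.5 k_BT and d = 8 Å attraction, 12 curves of 80 points in
q ∈ [0.01, 0.35] Å⁻¹.  Toy structures are uniformly filled pseudo-atom
spheres/dumbbells (and self-avoiding walks for unfolded chains) whose
per-atom electron counts reproduce a protein-like SLD.

Passing recovery tests show that the estimator is consistent and
approximately unbiased *under the model's own assumptions* (correct
forward model, independent Gaussian noise, exact labels).  They do not
probe real-data effects: instrument smearing, buffer-subtraction
systematics, inter-point correlations, wrong or flexible structures,
concentration errors, or cosolvent-dependent dielectric changes.
Absolute-scale calibration of raw data is out of scope.

## Problem sizes and tolerances

The shipped test suite and the acceptance script use: 12-curve
recovery (960 points, 28 free parameters, differential-evolution
popsize 8 × 25 generations + least-squares polish; a few minutes on
one CPU), a ~9,900-point grid sphere for the continuum form-factor
oracle, and 10⁵–10⁶-point Monte-Carlo volume integration for shell
counts.  Key numerical tolerances: equilibrium fixed-point damping 0.5
with residual tolerance 10⁻¹², mass-action root to machine precision
in log-concentration, pair-distance histograms at 0.02 Å bins (phase
error < 0.004 rad over the working q-range), PY kernels switch to
series below A = 2Rq = 0.1 to avoid cancellation.

## Known limitations

* One cosolvent per sample (as the exchange bookkeeping assumes).
* Monodisperse effective-particle interactions: a single (R, Z) per
  curve; no partial structure factors between states.
* Exact hydration-site counts depend on unpublished lattice details of
  reference implementations; computed counts are reproducible but
  should be overridden with reference values for benchmark work.
* q-independent atomic scattering lengths (valid for q ≤ 0.35 Å⁻¹);
  hydrogens are treated implicitly.
* ΔCp is temperature independent; no pressure dependence; ideal
  solution apart from Debye–Hückel electrostatics.
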