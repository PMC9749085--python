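# Methods

This note records the models implemented in `nnvib`, their assumptions,
the numerical choices, and what the test suite does and does not
establish.

## Energy model

The total energy of a structure is a sum of atomic energies,
E = Σᵢ Eᵢ + Σᵢ c(elementᵢ), each Eᵢ produced by a per-element
feed-forward network from that atom's descriptor vector. One network
per element is stored, so all atoms of an element share weights — the
property that makes the model size-transferable and makes
E(A ∪ B) = E(A) + E(B) exact once all cross-fragment distances exceed
the cutoff. The per-element offsets c are fitted by linear least
squares on the training set before weight training, which removes the
arbitrary electronic-energy zero from the regression target.

Descriptors are classic element-pair-resolved symmetry functions:
radial Gaussians Σⱼ exp(−η(r−r_s)²)f_c(r) and angular
2^(1−ζ)Σ_{j<k}(1+λcosθ)^ζ exp(−η(r_ij²+r_ik²+r_jk²)) f_c f_c f_c with a
cosine cutoff f_c that vanishes with zero slope at R_c. Defaults:
R_c = 15 bohr; 6 radial η log-spaced in [0.001, 0.4] bohr⁻² with
r_s = 0; 8 angular combinations (η ∈ {0.001, 0.05} bohr⁻²,
ζ ∈ {1, 4}, λ = ±1). These are conventional starting values, chosen
once; the validation rests on invariance/recovery properties, not on
any particular hyperparameter set. The descriptor ordering is frozen
and version-stamped into the model archive so that stored weights
remain interpretable.

Hidden layers use tanh and the output is linear. Smoothness matters
more than expressiveness here: Hessians and quartic force constants are
taken by finite differences of the energy, so any kink in the
activation would contaminate fourth derivatives. Two hidden layers of
12 nodes are the default (10–14 supported). Input features are shifted
to zero mean and scaled to unit range over the training set; the
statistics are frozen into the model file.

Forces are analytic: the chain rule through the network input gradient
and the analytic descriptor Jacobian. The Jacobian is tested against
central finite differences at 1e-7 and the forces at 1e-6 hartree/Å.

## Training

The default optimizer is a global adaptive extended Kalman filter: for
each training structure the innovation E_ref − E_pred and the parameter
gradient H = ∂E_pred/∂w update all weights through the running
covariance P (P₀ = 100·I, measurement-noise floor 1e-6 hartree²,
forgetting factor 0.9995, per-epoch reshuffling with the run seed).
This is a recursive Gauss–Newton method; on the small, smooth fits used
here it reaches sub-meV/atom residuals in a handful of epochs where
first-order methods need thousands. Adam and SGD remain available; the
recovery experiments accept any optimizer that meets the error targets.
Early stopping monitors the held-out RMSE (patience 50 epochs) and the
best-test-error weights are returned; the test split never enters a
weight update.

Fit quality is reported in the dual convention used for this system:
meV/atom and the per-system wavenumber equivalent
(× n_atoms × 8.06554), for the full energy range and for the window
within 0.1 hartree of the dataset minimum — the windowed number is the
spectroscopically relevant one, and the full-range number exposes
overfitting in sparsely sampled high-energy regions.

Active learning by committee: the spread (max − min)/n_atoms of the
predictions of ≥2 independently trained models flags structures for
relabelling. Channel thresholds follow the protocol this package
mirrors: 1 meV/atom for MD-sampled candidates, 20 meV/atom for
direct-product grid pools, 2 meV/atom for 2D-cut pools. MD sampling
uses velocity Verlet with a Langevin (BAOAB-split) thermostat; the
thermostat acts on all 3N degrees of freedom, so the kinetic
temperature is defined with 3N.

## Harmonic analysis

Hessians: central differences of analytic gradients when available,
otherwise 4-point energy differences, at 0.005 bohr by default
(configurable; the error is O(h²) and Richardson behaviour is tested).
The mass-weighted Hessian is diagonalized in the orthogonal complement
of the rigid translations/rotations (built by QR in the same Cartesian
frame as the Hessian — linear molecules yield 5 external vectors
automatically), giving exactly 3N−6 (3N−5) modes; imaginary modes are
reported as negative wavenumbers. B_eᵅ come from the principal moments
of inertia and ζᵅᵢⱼ from the standard cross-product sums over normal-
mode coefficients, both evaluated in the principal-axis frame.
Geometry optimization runs BFGS and then polishes with projected Newton
steps (pseudo-inverting away the six zero modes) until
max|g| < 1e-6 hartree/bohr.

Frequency-set comparisons pair modes by ascending order. Symmetry
labelling is out of scope; for the shipped benchmark tables sorted-
order pairing reproduces the printed pairing.

## Quartic force field and VPT2/GVPT2

Dimensionless normal coordinates are defined so the quadratic term is
½Σω_i q_i² (Cartesian displacement per unit q_i is M^(−1/2)l_i/√ω_i in
atomic units). The full cubic set and the semi-diagonal quartic set
(φ_iiii, φ_iijj) are computed with standard stencils (5-point 1D,
2-point×3-point mixed, 4-corner, 8-corner), each unique constant
evaluated once and broadcast over index permutations. The default step
Δq = 0.5 was fixed by the Morse-recovery requirement (0.1% on φ₁₁₁ and
φ₁₁₁₁ is reached at Δq ≲ 0.1 on analytic surfaces; 0.5 balances
truncation against the fit noise of trained potentials).

The x_ij follow the standard second-order contact-transformation
formulas, including the Coriolis term Σ_α B_eᵅ(ζᵅᵢⱼ)²(ωᵢ/ωⱼ + ωⱼ/ωᵢ)
with equilibrium rotational constants. Implementation detail that
matters for resonance handling: each cubic contribution is stored as
its partial-fraction channels,

  ω_k(ω_k²−ω_i²−ω_j²)/Δ_ijk = ¼[1/(ωᵢ+ωⱼ+ω_k) − 1/(ωᵢ+ωⱼ−ω_k)
                                + 1/(ωᵢ−ωⱼ+ω_k) − 1/(ωᵢ−ωⱼ−ω_k)],

  (8ωᵢ²−3ωⱼ²)/(ωⱼ(4ωᵢ²−ωⱼ²)) = 2/ωⱼ − ½/(2ωᵢ−ωⱼ) + ½/(2ωᵢ+ωⱼ),

so deperturbation deletes exactly the near-singular channel and nothing
else. Resonances are flagged when the detuning |ωᵢ−2ωⱼ| or
|ωᵢ−ωⱼ−ω_k| is below 100 cm⁻¹ **and** the coupling constant (φ_ijj or
φ_ijk) exceeds 1 cm⁻¹; both knobs are exposed, since no universal
criterion exists. Flagged states are collected into transitively closed
polyads (a state resonating with two partners yields one block), the
block diagonal holds deperturbed state energies from
E(v) = Σωᵢvᵢ + Σxᵢᵢ(vᵢ²+vᵢ) + Σ_{i<j}xᵢⱼ(vᵢvⱼ+(vᵢ+vⱼ)/2), and the
off-diagonal elements are φ_ijj/4 (fundamental↔overtone) and
φ_ijk/(2√2) (fundamental↔combination). These prefactors were fixed by
requiring agreement with dense variational diagonalization of the same
force field on exact-resonance fixtures (the suite holds them to
≤1 cm⁻¹; the observed agreement is ~0.03 cm⁻¹). Fundamentals outside
polyads use the deperturbed constants; eigenvalues are assigned by
dominant mixing fraction, greedily so that near-50:50 doublets still
receive one label each, and assignments with leading weight <0.5 are
reported as ambiguous.

VPT2 is exact for a Morse oscillator; this closed form
(ν = ω − 2ωx_e, x₁₁ = −ωx_e = −a²/2m) anchors the whole tier at
0.05 cm⁻¹ over random parameterizations.

## Reduced-dimensionality DVR

Curvilinear coordinates are defined by an explicit mapping
q → Cartesians with constrained coordinates frozen inside the mapping;
the metric g_kl = Σₐ mₐ tₐₖ·tₐₗ is evaluated by central differences of
the mapping at every grid point (step 1e-4), with G = g⁻¹ and
g̃ = det g. Computing g only over the active coordinates is identical
to deleting the constrained rows/columns of the full metric. Mappings
must hold the total centre of mass fixed, otherwise the metric absorbs
spurious overall translation.

The kinetic operator is assembled in the manifestly hermitian
rearranged (Podolsky-type) form
T = ½Σ g̃^(−1/4) p̂ₖ† g̃^(1/2) G_kl p̂ₗ g̃^(−1/4) with DVR first-derivative
matrices; when g is constant along a diagonal term the exact
second-derivative matrix is substituted (the two agree analytically,
but the D2 route converges faster on the bench cases). Primitive bases:
sine DVR for bounded coordinates, Fourier DVR (odd point count) for
2π-periodic ones, with a PODVR contraction (solve 1D, keep the lowest
n states, diagonalize the coordinate operator) available per
coordinate. Direct-product dimension is capped (configurable, default
2·10⁵ points) — the desk-scale regime is D ≤ 4; higher-dimensional
work needs Smolyak/FBR machinery that is deliberately out of scope.
Eigenvalues come from dense `eigh` below 1200 points and from Lanczos
(`eigsh`, fixed uniform start vector, hence deterministic) above.
Levels are reported relative to the zero-point level.

## Model potentials

* **Morse oscillator** (D_e, a, r_e, m): exact levels
  E_n = ω(n+½) − ωx_e(n+½)², exact Taylor force constants — the oracle
  for VPT2 exactness and DVR accuracy. Parameterizations with fewer
  than two bound states are rejected.
* **Toy triatomic** (O–C–O-like, bent): two equal Morse bonds, harmonic
  bend, bilinear stretch–stretch coupling. Defaults (D_e = 0.25 Eₕ,
  a = 1.08 bohr⁻¹, r_e = 2.2 bohr, k_θ = 0.17 Eₕ/rad², θ_e = 2.1 rad,
  k_rr = 0.012 Eₕ/bohr²) put the fundamentals at ≈490/1319/1684 cm⁻¹ —
  inside the fingerprint range, so cm⁻¹ tolerances transfer — with
  ~10 cm⁻¹ Morse anharmonicity. The Cartesian Hessian at equilibrium is
  closed-form (B-matrix × internal force constants), giving an
  independent harmonic reference.
* **3D dimer**: an O–H and an N–H monomer, intermolecular Morse
  stretch R between the monomer centres of mass and one bend per
  monomer measured from the centre-of-mass line, stiff intramonomer
  bonds; θ₁ optionally becomes a symmetric quartic double well with
  tunable barrier for tunneling-splitting studies. The two monomers
  carry different bend constants, so they are made chemically distinct
  on purpose: a physically asymmetric potential over two identical
  monomers would be invisible to permutation-invariant descriptors and
  hence unlearnable by construction. The full-stack regression test
  trains a potential on product-grid plus normal-mode samples of this
  oracle and requires its variational (DVR) fundamentals to match the
  oracle's within 10 cm⁻¹; it uses a single trained model — the
  committee machinery is exercised separately by the selection tests.

The normal-mode sampler draws Gaussian dimensionless displacements
(std = amplitude, or the classical thermal width √(k_BT/ω)); the
standard recovery experiment uses 2000 samples at amplitude 1.0 — the
zero-point region plus tails, which is what harmonic and quartic
recovery needs. A uniform "grid" scheme and thermostatted MD sampling
cover the other candidate-generation channels.

**What the synthetic data does not emulate:** coupled-cluster noise is
absent (labels are exact), the triatomic has 3 modes rather than 24, no
double-proton-transfer topology is mimicked, and the sampled
configuration space is near-equilibrium. Passing the recovery tests
therefore demonstrates that the machinery — descriptors, training,
differentiation, perturbation theory, DVR — is internally correct and
spectroscopically accurate on surfaces of this smoothness class, not
that any particular real cluster is fitted.

## Degenerate and edge inputs

Non-finite energies at displaced geometries abort with the offending
displacement; committees require ≥2 members; empty selection pools
return empty record lists; windows with no structures are flagged
rather than reported as 0; PODVR rejects unbound 1D cuts (ground state
piling up at the box walls); the metric builder raises on |g̃| below
1e-14; model archives carry a format version and refuse newer files.

## Known limitations

* Energy-only training is the default; a force-weight hook exists but
  force-matching is not exercised by the acceptance experiments.
* The EKF stores a dense P (n_params²); fine below ~10⁴ parameters,
  unsuitable far beyond.
* Mode pairing by sorted order can mislabel deviations when two modes
  of different character cross between the compared surfaces.
* The published benchmark statistics shipped as fixtures are printed
  (rounded) literature values; recomputing their unrounded analogues
  requires the deposited reference data, which this package does not
  download.
* No rovibrational (J > 0) levels, no intensities, no point-group
  symmetry labels.
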