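"""Analytic model potentials ("oracles") with exactly known properties.

These closed-form surfaces stand in for expensive coupled-cluster
reference data when exercising the full toolchain: a 1D Morse oscillator
(exact spectrum), a Morse/harmonic-bend triatomic with stretch–stretch
coupling (analytic Hessian, exact quartic force field by construction),
and a 3D "dimer" model (intermolecular stretch + two bends, optional
symmetric double well) for the reduced-dimensionality DVR solver.

All oracle internals are atomic units; the Cartesian interface follows
package convention (Å in, hartree out, hartree/Å gradients).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .structures import Dataset, Structure
from .units import BOHR_ANGSTROM, HARTREE_CM, mass_au

KB_HARTREE = 3.166811563e-6  # Boltzmann constant, hartree/K


# ----------------------------------------------------------------- Morse

@dataclass
class Morse1D:
    """V(r) = D_e (1 − e^{−a(r−r_e)})² with exact levels
    E_n = ω(n+½) − ωx_e(n+½)² above the potential minimum.

    Parameters are atomic units: D_e hartree, a bohr⁻¹, r_e bohr,
    mass in electron masses (the reduced mass of the oscillating pair).
    """
    D_e: float
    a: float
    r_e: float
    mass: float

    def __post_init__(self):
        if min(self.D_e, self.a, self.mass) <= 0:
            raise ValueError("D_e, a and mass must be positive")
        if self.n_bound < 2:
            raise ValueError("parameters support fewer than 2 bound states")

    @property
    def omega_au(self) -> float:
        return self.a * np.sqrt(2.0 * self.D_e / self.mass)

    @property
    def omega_xe_au(self) -> float:
        return self.a ** 2 / (2.0 * self.mass)

    @property
    def omega_cm(self) -> float:
        return self.omega_au * HARTREE_CM

    @property
    def omega_xe_cm(self) -> float:
        return self.omega_xe_au * HARTREE_CM

    @property
    def n_bound(self) -> int:
        return int(np.floor(np.sqrt(2.0 * self.mass * self.D_e) / self.a + 0.5))

    def V(self, r):
        """Potential (hartree) above the minimum; r in bohr."""
        return self.D_e * (1.0 - np.exp(-self.a * (np.asarray(r) - self.r_e))) ** 2

    def dV(self, r):
        e = np.exp(-self.a * (np.asarray(r) - self.r_e))
        return 2.0 * self.D_e * self.a * e * (1.0 - e)

    def level(self, n) -> float:
        """Exact bound level above the minimum (hartree)."""
        v = np.asarray(n) + 0.5
        return (self.omega_au * v - self.omega_xe_au * v ** 2)

    def level_cm(self, n) -> float:
        return self.level(n) * HARTREE_CM

    @property
    def fundamental_cm(self) -> float:
        """ν = ω − 2ωx_e: VPT2 reproduces this exactly."""
        return self.omega_cm - 2.0 * self.omega_xe_cm

    def taylor_phi(self) -> tuple[float, float]:
        """Exact cubic/quartic force constants (cm⁻¹) of the dimensionless
        normal-coordinate expansion V = ω q²/2 + φ₃ q³/6 + φ₄ q⁴/24."""
        b = self.a / np.sqrt(self.mass * self.omega_au)
        phi3 = -6.0 * self.D_e * b ** 3
        phi4 = 14.0 * self.D_e * b ** 4
        return phi3 * HARTREE_CM, phi4 * HARTREE_CM


def morse_1d(D_e: float, a: float, r_e: float, mass: float) -> Morse1D:
    return Morse1D(D_e, a, r_e, mass)


def morse_parameters_for(omega_cm: float, omega_xe_cm: float, mass: float,
                         r_e: float = 2.0) -> Morse1D:
    """Invert ω, ωx_e (cm⁻¹) to Morse (D_e, a) for a given reduced mass."""
    w = omega_cm / HARTREE_CM
    wx = omega_xe_cm / HARTREE_CM
    a = np.sqrt(2.0 * mass * wx)
    D_e = w ** 2 / (4.0 * wx)
    return Morse1D(D_e, a, r_e, mass)


# ------------------------------------------------- Cartesian oracle type

@dataclass
class AnalyticOracle:
    """A closed-form Cartesian PES with known reference results."""
    name: str
    params: dict
    equilibrium: Structure
    energy: Callable[[Structure], float]
    gradient: Callable[[Structure], np.ndarray] | None = None
    reference: dict = field(default_factory=dict)

    def potential(self):
        from .potentials import PotentialInterface
        return PotentialInterface(energy=self.energy, gradient=self.gradient,
                                  label=self.name)


def morse_diatomic(D_e: float = 0.18, a: float = 1.2, r_e: float = 1.75,
                   elements: tuple[str, str] = ("H", "F")) -> AnalyticOracle:
    """Two atoms bound by a Morse potential in their distance."""
    m1, m2 = mass_au(elements[0]), mass_au(elements[1])
    mu = m1 * m2 / (m1 + m2)
    morse = Morse1D(D_e, a, r_e, mu)

    def energy(s: Structure) -> float:
        r = np.linalg.norm(s.coordinates[1] - s.coordinates[0]) / BOHR_ANGSTROM
        return float(morse.V(r))

    def gradient(s: Structure) -> np.ndarray:
        d = (s.coordinates[1] - s.coordinates[0]) / BOHR_ANGSTROM
        r = np.linalg.norm(d)
        g1 = -morse.dV(r) * d / r
        return np.array([g1, -g1]) / BOHR_ANGSTROM

    eq = Structure(list(elements),
                   np.array([[0.0, 0.0, 0.0],
                             [r_e * BOHR_ANGSTROM, 0.0, 0.0]]))
    return AnalyticOracle(
        name="morse_diatomic", params=dict(D_e=D_e, a=a, r_e=r_e),
        equilibrium=eq, energy=energy, gradient=gradient,
        reference={"morse": morse, "harmonic_cm": np.array([morse.omega_cm])})


# ------------------------------------------------------- toy triatomic

def _angle_grads(x0, x1, x2):
    """Angle at x1 between (x0-x1) and (x2-x1) plus Cartesian gradients."""
    u = x0 - x1
    v = x2 - x1
    r1, r2 = np.linalg.norm(u), np.linalg.norm(v)
    u, v = u / r1, v / r2
    cos_t = np.clip(np.dot(u, v), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(max(1.0 - cos_t ** 2, 1e-14))
    d0 = (cos_t * u - v) / (r1 * sin_t)
    d2 = (cos_t * v - u) / (r2 * sin_t)
    return theta, d0, -(d0 + d2), d2, r1, r2, u, v


DEFAULT_TRIATOMIC = dict(D_e=0.25, a=1.08, r_e=2.2, k_bend=0.17,
                         theta_e=2.1, k_rr=0.012)


def toy_triatomic(D_e: float = DEFAULT_TRIATOMIC["D_e"],
                  a: float = DEFAULT_TRIATOMIC["a"],
                  r_e: float = DEFAULT_TRIATOMIC["r_e"],
                  k_bend: float = DEFAULT_TRIATOMIC["k_bend"],
                  theta_e: float = DEFAULT_TRIATOMIC["theta_e"],
                  k_rr: float = DEFAULT_TRIATOMIC["k_rr"],
                  elements: tuple[str, str, str] = ("O", "C", "O")
                  ) -> AnalyticOracle:
    """Bent symmetric triatomic: two equal Morse bonds, harmonic bend,
    bilinear stretch–stretch coupling.

    Default parameters put the three fundamentals in the fingerprint
    range (≈600–1550 cm⁻¹) with Morse anharmonicity of order 10 cm⁻¹,
    so frequency tolerances used for real clusters transfer meaningfully.
    Energies are relative to the equilibrium (V_min = 0).
    """
    morse = Morse1D(D_e, a, r_e, mass_au(elements[1]))  # mass unused for V

    def internals(s: Structure):
        x = s.coordinates / BOHR_ANGSTROM
        return _angle_grads(x[0], x[1], x[2])

    def energy(s: Structure) -> float:
        theta, *_rest = internals(s)
        _, _, _, _, r1, r2, _, _ = internals(s)
        dr1, dr2 = r1 - r_e, r2 - r_e
        return float(morse.V(r1) + morse.V(r2)
                     + 0.5 * k_bend * (theta - theta_e) ** 2
                     + k_rr * dr1 * dr2)

    def gradient(s: Structure) -> np.ndarray:
        theta, d0, d1, d2, r1, r2, u, v = internals(s)
        dV_r1 = morse.dV(r1) + k_rr * (r2 - r_e)
        dV_r2 = morse.dV(r2) + k_rr * (r1 - r_e)
        dV_th = k_bend * (theta - theta_e)
        g = np.zeros((3, 3))
        g[0] += dV_r1 * u + dV_th * d0
        g[1] += -dV_r1 * u - dV_r2 * v + dV_th * d1
        g[2] += dV_r2 * v + dV_th * d2
        return g / BOHR_ANGSTROM

    # equilibrium geometry (bohr -> Å): central atom at origin
    half = theta_e / 2.0
    xb = np.array([
        [r_e * np.sin(half), r_e * np.cos(half), 0.0],
        [0.0, 0.0, 0.0],
        [-r_e * np.sin(half), r_e * np.cos(half), 0.0],
    ])
    eq = Structure(list(elements), xb * BOHR_ANGSTROM)

    def hessian_analytic() -> np.ndarray:
        """Exact Cartesian Hessian at equilibrium (hartree/bohr²).

        At the stationary point all internal-coordinate first derivatives
        vanish, so H = Bᵀ V_qq B with the Wilson B matrix of (r1, r2, θ).
        """
        theta, d0, d1, d2, r1, r2, u, v = _angle_grads(xb[0], xb[1], xb[2])
        B = np.zeros((3, 9))
        B[0, 0:3], B[0, 3:6] = u, -u
        B[1, 6:9], B[1, 3:6] = v, -v
        B[2, 0:3], B[2, 3:6], B[2, 6:9] = d0, d1, d2
        k_str = 2.0 * D_e * a ** 2  # Morse curvature at r_e
        Vqq = np.array([[k_str, k_rr, 0.0],
                        [k_rr, k_str, 0.0],
                        [0.0, 0.0, k_bend]])
        return B.T @ Vqq @ B

    return AnalyticOracle(
        name="toy_triatomic",
        params=dict(D_e=D_e, a=a, r_e=r_e, k_bend=k_bend, theta_e=theta_e,
                    k_rr=k_rr),
        equilibrium=eq, energy=energy, gradient=gradient,
        reference={"hessian_analytic": hessian_analytic, "morse": morse})


# --------------------------------------------------------- 3D toy dimer

DEFAULT_DIMER = dict(D_R=0.02, a_R=0.9, R_e=5.5, k_theta1=0.02,
                     k_theta2=0.03, theta1_e=np.pi / 2, theta2_e=np.pi / 2,
                     barrier=0.0, delta=0.5, k_bond=0.5, L_bond=1.85)


def toy_dimer_3d(D_R: float = DEFAULT_DIMER["D_R"],
                 a_R: float = DEFAULT_DIMER["a_R"],
                 R_e: float = DEFAULT_DIMER["R_e"],
                 k_theta1: float = DEFAULT_DIMER["k_theta1"],
                 k_theta2: float = DEFAULT_DIMER["k_theta2"],
                 theta1_e: float = DEFAULT_DIMER["theta1_e"],
                 theta2_e: float = DEFAULT_DIMER["theta2_e"],
                 barrier: float = DEFAULT_DIMER["barrier"],
                 delta: float = DEFAULT_DIMER["delta"],
                 k_bond: float = DEFAULT_DIMER["k_bond"],
                 L_bond: float = DEFAULT_DIMER["L_bond"]) -> AnalyticOracle:
    """An O–H and an N–H "monomer": intermolecular Morse stretch R
    between the centres of mass and one bending angle per monomer
    measured from the centre-of-mass line, with stiff harmonic
    intramonomer bonds.  The two monomers carry different bend force
    constants; they are chemically distinct so that the physical
    asymmetry is visible to permutation-invariant descriptors.

    With ``barrier > 0`` the θ₁ potential becomes a symmetric quartic
    double well centred at θ1_e with minima at θ1_e ± delta and the given
    barrier height (hartree) — a desk-scale stand-in for tunneling
    between equivalent wells of an intermolecular mode.
    """
    elements = ["O", "H", "N", "H"]
    masses = np.array([mass_au(el) for el in elements])

    def v_theta1(t):
        d = t - theta1_e
        if barrier > 0.0:
            return barrier * ((d ** 2 - delta ** 2) ** 2) / delta ** 4
        return 0.5 * k_theta1 * d ** 2

    def dv_theta1(t):
        d = t - theta1_e
        if barrier > 0.0:
            return 4.0 * barrier * d * (d ** 2 - delta ** 2) / delta ** 4
        return k_theta1 * d

    def v_R(R):
        return D_R * (1.0 - np.exp(-a_R * (R - R_e))) ** 2

    def dv_R(R):
        e = np.exp(-a_R * (R - R_e))
        return 2.0 * D_R * a_R * e * (1.0 - e)

    def map_to_cartesian(q: np.ndarray) -> np.ndarray:
        """(R, θ1, θ2) in (bohr, rad, rad) -> Cartesian bohr (4 atoms).

        Body-fixed frame: com line along z, monomer bonds in the xz
        plane; θ measured from the com line, monomer 2 tilted the same
        sense.  Intramonomer bonds at their rest length.
        """
        R, t1, t2 = q
        out = np.zeros((4, 3))
        M1, M2 = masses[0] + masses[1], masses[2] + masses[3]
        # total COM fixed: monomer coms split R by the mass ratio
        for ifrag, (t, z0, Mf) in enumerate((
                (t1, -M2 / (M1 + M2) * R, M1),
                (t2, M1 / (M1 + M2) * R, M2))):
            u = np.array([np.sin(t), 0.0, np.cos(t)])
            com = np.array([0.0, 0.0, z0])
            iA = 2 * ifrag
            out[iA] = com - (masses[iA + 1] / Mf) * L_bond * u
            out[iA + 1] = com + (masses[iA] / Mf) * L_bond * u
        return out

    def internals(x: np.ndarray):
        com1 = (masses[0] * x[0] + masses[1] * x[1]) / (masses[0] + masses[1])
        com2 = (masses[2] * x[2] + masses[3] * x[3]) / (masses[2] + masses[3])
        c = com2 - com1
        R = np.linalg.norm(c)
        u1 = x[1] - x[0]
        u2 = x[3] - x[2]
        return c, R, u1, u2

    def energy_bohr(x: np.ndarray) -> float:
        c, R, u1, u2 = internals(x)
        chat = c / R
        e = v_R(R)
        for u, vfun in ((u1, v_theta1),
                        (u2, lambda t: 0.5 * k_theta2 * (t - theta2_e) ** 2)):
            L = np.linalg.norm(u)
            cos_t = np.clip(np.dot(u / L, chat), -1.0, 1.0)
            e += vfun(np.arccos(cos_t))
            e += 0.5 * k_bond * (L - L_bond) ** 2
        return float(e)

    def energy(s: Structure) -> float:
        return energy_bohr(s.coordinates / BOHR_ANGSTROM)

    eq_q = np.array([R_e, theta1_e + (delta if barrier > 0 else 0.0), theta2_e])
    eq = Structure(elements, map_to_cartesian(eq_q) * BOHR_ANGSTROM)

    return AnalyticOracle(
        name="toy_dimer_3d",
        params=dict(D_R=D_R, a_R=a_R, R_e=R_e, k_theta1=k_theta1,
                    k_theta2=k_theta2, barrier=barrier, delta=delta,
                    k_bond=k_bond, L_bond=L_bond),
        equilibrium=eq, energy=energy, gradient=None,
        reference={
            "map_to_cartesian": map_to_cartesian,
            "masses_au": masses,
            "energy_q": lambda q: energy_bohr(map_to_cartesian(q)),
            "coordinate_names": ["R", "theta1", "theta2"],
            "ranges": [(R_e - 1.6, R_e + 3.0), (0.6, np.pi - 0.6),
                       (0.6, np.pi - 0.6)],
        })


# ----------------------------------------------------------- samplers

def sample_structures(oracle: AnalyticOracle, n: int,
                      amplitude=1.0,
                      temperature: float | None = None,
                      seed: int = 0, scheme: str = "normal-mode",
                      max_energy: float | None = None) -> Dataset:
    """Draw energy-labelled structures from an oracle.

    Schemes: ``normal-mode`` draws Gaussian dimensionless normal-coordinate
    displacements (std = ``amplitude``, or the classical thermal width
    √(k_B T/ω) when ``temperature`` is given); ``grid`` draws uniform
    displacements in [−2·amplitude, 2·amplitude] per mode, mimicking a
    direct-product grid pool; ``md`` runs thermostatted dynamics on the
    oracle.  ``amplitude`` may be a scalar or one value per mode
    (ascending-frequency order).  Samples above ``max_energy`` (hartree
    above the minimum) are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    if scheme == "md":
        from .training import md_sample
        temp = temperature if temperature is not None else 300.0
        return md_sample(oracle.potential(), oracle.equilibrium,
                         temperature=temp, n_steps=max(10 * n, 1000),
                         stride=max(10 * n, 1000) // n, seed=seed)

    from .harmonic import harmonic_analysis, hessian_fd
    pot = oracle.potential()
    eq = oracle.equilibrium
    if "hessian_analytic" in oracle.reference:
        H = oracle.reference["hessian_analytic"]()
    else:
        H = hessian_fd(pot, eq)
    res = harmonic_analysis(H, eq.masses_au(), eq)
    omega_au = res.frequencies_cm / HARTREE_CM
    if np.any(omega_au <= 0):
        raise ValueError("normal-mode sampling needs a true minimum")
    masses = eq.masses_au()
    # Cartesian displacement per unit dimensionless q (Å)
    disp = (res.modes / np.sqrt(np.repeat(masses, 3))[:, None]
            / np.sqrt(omega_au)[None, :]) * BOHR_ANGSTROM
    if temperature is not None:
        sigma = np.sqrt(KB_HARTREE * temperature / omega_au)
    else:
        sigma = np.broadcast_to(np.asarray(amplitude, float),
                                (omega_au.size,)).copy()
    e0 = oracle.energy(eq)
    cap = np.inf if max_energy is None else max_energy
    structures = []
    n_rejected = 0
    while len(structures) < n:
        if scheme == "normal-mode":
            q = rng.normal(0.0, 1.0, size=omega_au.size) * sigma
        elif scheme == "grid":
            q = rng.uniform(-2.0, 2.0, size=omega_au.size) * sigma
        else:
            raise ValueError(f"unknown sampling scheme: {scheme!r}")
        x = eq.coordinates + (disp @ q).reshape(-1, 3)
        s = eq.with_coordinates(x)
        e = oracle.energy(s)
        if e - e0 > cap:
            n_rejected += 1
            if n_rejected > 100 * n:
                raise RuntimeError("sampling rejection rate too high")
            continue
        s.energy = e
        s.tag = scheme
        structures.append(s)
    return Dataset(structures).set_reference_to_minimum()
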