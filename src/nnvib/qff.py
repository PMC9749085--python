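"""Quartic force fields in dimensionless normal coordinates.

The potential around a minimum is expanded as

    V = ½ Σ_i ω_i q_i² + (1/6) Σ_ijk φ_ijk q_i q_j q_k
        + (1/24) Σ_ijkl φ_ijkl q_i q_j q_k q_l

with all constants in cm⁻¹ and q dimensionless (the Cartesian
displacement per unit q_i is M^(−1/2) l_i /√ω_i in atomic units).  The
cubic set is computed in full; of the quartics only the semi-diagonal
constants φ_iiii and φ_iijj needed by second-order perturbation theory
are evaluated by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np

from .harmonic import HarmonicResult
from .potentials import PotentialInterface
from .units import BOHR_ANGSTROM, HARTREE_CM


@dataclass
class QuarticForceField:
    omega_cm: np.ndarray       # harmonic wavenumbers, (n,)
    phi3: np.ndarray           # cubic constants, (n, n, n), cm⁻¹, symmetric
    phi4_semi: np.ndarray      # diag: φ_iiii; off-diag: φ_iijj; (n, n), cm⁻¹

    def __post_init__(self):
        self.omega_cm = np.asarray(self.omega_cm, float)
        self.phi3 = np.asarray(self.phi3, float)
        self.phi4_semi = np.asarray(self.phi4_semi, float)
        n = self.omega_cm.size
        if self.phi3.shape != (n, n, n) or self.phi4_semi.shape != (n, n):
            raise ValueError("inconsistent force-constant array shapes")
        if not np.all(np.isfinite(self.phi3)) or not np.all(np.isfinite(self.phi4_semi)):
            raise ValueError("non-finite force constants")

    @property
    def n_modes(self) -> int:
        return self.omega_cm.size

    def reordered(self, order) -> "QuarticForceField":
        order = np.asarray(order)
        return QuarticForceField(
            self.omega_cm[order],
            self.phi3[np.ix_(order, order, order)],
            self.phi4_semi[np.ix_(order, order)])


def resonance_denominator(w_i: float, w_j: float, w_k: float) -> float:
    """Δ_ijk = (ω_i+ω_j+ω_k)(ω_i+ω_j−ω_k)(ω_i−ω_j+ω_k)(ω_i−ω_j−ω_k)."""
    return ((w_i + w_j + w_k) * (w_i + w_j - w_k)
            * (w_i - w_j + w_k) * (w_i - w_j - w_k))


def build_qff(potential: PotentialInterface, harmonic: HarmonicResult,
              step_q: float = 0.5) -> QuarticForceField:
    """Cubic and semi-diagonal quartic constants by central finite
    differences of energies along dimensionless normal coordinates.

    Stencils: 5-point 1D for φ_iii/φ_iiii, 2×3-point products for φ_iij,
    4-corner + 1D reuse for φ_iijj, 8-corner for distinct φ_ijk.  Index
    permutation symmetry is exact by construction (each unique constant
    is evaluated once and broadcast).
    """
    omega_cm = harmonic.frequencies_cm
    if np.any(omega_cm <= 0):
        raise ValueError("QFF requires a true minimum (all ω > 0)")
    n = omega_cm.size
    eq = harmonic.structure
    masses = np.repeat(eq.masses_au(), 3)
    omega_au = omega_cm / HARTREE_CM
    # Cartesian displacement (Å) per unit q_i
    disp = (harmonic.modes / np.sqrt(masses)[:, None]
            / np.sqrt(omega_au)[None, :]) * BOHR_ANGSTROM

    cache: dict[tuple, float] = {}

    def E(*steps: tuple[int, float]) -> float:
        key = tuple(sorted(steps))
        if key not in cache:
            dq = np.zeros(n)
            for mode, amount in steps:
                dq[mode] += amount
            x = eq.coordinates + (disp @ dq).reshape(-1, 3)
            val = potential.energy(eq.with_coordinates(x))
            if not np.isfinite(val):
                raise ValueError(f"non-finite energy at displacement {key}")
            cache[key] = val
        return cache[key]

    h = step_q
    e0 = E()
    phi3 = np.zeros((n, n, n))
    phi4 = np.zeros((n, n))

    for i in range(n):
        ep1, em1 = E((i, h)), E((i, -h))
        ep2, em2 = E((i, 2 * h)), E((i, -2 * h))
        phi3[i, i, i] = (-em2 + 2 * em1 - 2 * ep1 + ep2) / (2 * h ** 3)
        phi4[i, i] = (em2 - 4 * em1 + 6 * e0 - 4 * ep1 + ep2) / h ** 4

    for i, j in combinations(range(n), 2):
        epp, epm = E((i, h), (j, h)), E((i, h), (j, -h))
        emp, emm = E((i, -h), (j, h)), E((i, -h), (j, -h))
        e_i_p, e_i_m = E((i, h)), E((i, -h))
        e_j_p, e_j_m = E((j, h)), E((j, -h))
        # ∂³V/∂q_i²∂q_j
        val_iij = (epp + emp - 2 * e_j_p - epm - emm + 2 * e_j_m) / (2 * h ** 3)
        val_ijj = (epp + epm - 2 * e_i_p - emp - emm + 2 * e_i_m) / (2 * h ** 3)
        for p in set(permutations((i, i, j))):
            phi3[p] = val_iij
        for p in set(permutations((i, j, j))):
            phi3[p] = val_ijj
        phi4[i, j] = phi4[j, i] = (
            epp + epm + emp + emm
            - 2 * (e_i_p + e_i_m + e_j_p + e_j_m) + 4 * e0) / h ** 4

    for i, j, k in combinations(range(n), 3):
        val = 0.0
        for si in (1, -1):
            for sj in (1, -1):
                for sk in (1, -1):
                    val += si * sj * sk * E((i, si * h), (j, sj * h), (k, sk * h))
        val /= 8 * h ** 3
        for p in set(permutations((i, j, k))):
            phi3[p] = val

    return QuarticForceField(omega_cm, phi3 * HARTREE_CM, phi4 * HARTREE_CM)


# ------------------------------------------------------- text format

def write_qff(qff: QuarticForceField, path) -> None:
    """Plain-text QFF: ω header, then unique `i j k value` and
    `i j k l value` lines (1-based, cm⁻¹)."""
    n = qff.n_modes
    with open(path, "w") as fh:
        fh.write("# quartic force field, dimensionless normal coordinates, cm-1\n")
        fh.write("omega " + " ".join(f"{w:.6f}" for w in qff.omega_cm) + "\n")
        for i in range(n):
            for j in range(i, n):
                for k in range(j, n):
                    v = qff.phi3[i, j, k]
                    if v != 0.0:
                        fh.write(f"{i+1} {j+1} {k+1} {v:.6f}\n")
        for i in range(n):
            fh.write(f"{i+1} {i+1} {i+1} {i+1} {qff.phi4_semi[i, i]:.6f}\n")
            for j in range(i + 1, n):
                fh.write(f"{i+1} {i+1} {j+1} {j+1} {qff.phi4_semi[i, j]:.6f}\n")


def read_qff(path) -> QuarticForceField:
    omega = None
    entries3, entries4 = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("omega"):
                omega = np.array([float(x) for x in line.split()[1:]])
                continue
            parts = line.split()
            idx = [int(p) - 1 for p in parts[:-1]]
            val = float(parts[-1])
            if len(idx) == 3:
                entries3.append((idx, val))
            elif len(idx) == 4:
                entries4.append((idx, val))
            else:
                raise ValueError(f"bad QFF line: {line!r}")
    if omega is None:
        raise ValueError("QFF file lacks an omega header line")
    n = omega.size
    phi3 = np.zeros((n, n, n))
    phi4 = np.zeros((n, n))
    for idx, val in entries3:
        for p in set(permutations(idx)):
            phi3[p] = val
    for idx, val in entries4:
        uniq = sorted(set(idx))
        if len(uniq) == 1:
            phi4[uniq[0], uniq[0]] = val
        elif len(uniq) == 2 and sorted(idx) == [uniq[0], uniq[0], uniq[1], uniq[1]]:
            phi4[uniq[0], uniq[1]] = phi4[uniq[1], uniq[0]] = val
        else:
            raise ValueError(f"unsupported quartic index pattern: {idx}")
    return QuarticForceField(omega, phi3, phi4)
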