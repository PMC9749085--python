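"""Geometry optimization, finite-difference Hessians and normal-mode
analysis, plus the rotational and Coriolis constants needed by VPT2.

The analysis mass-weights the Cartesian Hessian, projects out rigid
translations and rotations (Eckart-frame projection), and diagonalizes
in the internal subspace, so exactly 3N−6 (3N−5 for linear molecules)
vibrational frequencies are returned.  Imaginary modes are reported as
negative wavenumbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .potentials import PotentialInterface
from .structures import Structure
from .units import AMU_ME, BOHR_ANGSTROM, HARTREE_CM


@dataclass
class HarmonicResult:
    structure: Structure
    frequencies_cm: np.ndarray     # ascending; negative = imaginary
    modes: np.ndarray              # (3N, n_vib) mass-weighted, orthonormal
    reduced_masses_amu: np.ndarray
    B_e_cm: np.ndarray             # (3,) equilibrium rotational constants
    zeta: np.ndarray               # (3, n_vib, n_vib) Coriolis constants

    @property
    def n_vib(self) -> int:
        return self.frequencies_cm.size


class ConvergenceError(RuntimeError):
    pass


def optimize_geometry(potential: PotentialInterface, start: Structure,
                      grad_tol: float = 1e-6, step_tol: float = 1e-6,
                      max_iter: int = 500) -> Structure:
    """Minimize the energy until max |gradient| < grad_tol (hartree/bohr)
    and the last step norm < step_tol (bohr).

    A quasi-Newton (BFGS) search is polished with projected Newton steps
    using a finite-difference Hessian, which handles the rigid-body zero
    modes of an isolated cluster.
    """
    n = start.n_atoms

    def fun(x):
        return potential.energy(start.with_coordinates(x.reshape(n, 3)))

    def jac(x):  # hartree/Å
        return potential.grad(start.with_coordinates(x.reshape(n, 3))).ravel()

    x = start.coordinates.ravel().copy()
    res = scipy.optimize.minimize(
        fun, x, jac=jac, method="BFGS",
        options={"gtol": grad_tol * 0.5 / BOHR_ANGSTROM, "maxiter": max_iter,
                 "norm": np.inf})
    x = res.x

    def max_grad_bohr(x):
        return np.max(np.abs(jac(x))) * BOHR_ANGSTROM

    # Newton polish in the non-singular subspace
    last_step = np.inf
    for _ in range(30):
        if max_grad_bohr(x) < grad_tol and last_step < step_tol:
            break
        s = start.with_coordinates(x.reshape(n, 3))
        H = hessian_fd(potential, s)                 # hartree/bohr^2
        g = jac(x) * BOHR_ANGSTROM                   # hartree/bohr
        w, V = np.linalg.eigh(H)
        keep = np.abs(w) > 1e-8
        step = -V[:, keep] @ ((V[:, keep].T @ g) / w[keep])  # bohr
        nrm = np.linalg.norm(step)
        if nrm > 0.5:                                # trust region, bohr
            step *= 0.5 / nrm
        x = x + step * BOHR_ANGSTROM
        last_step = np.linalg.norm(step)
    else:
        raise ConvergenceError(
            f"geometry optimization did not reach grad_tol={grad_tol} "
            f"(max |g| = {max_grad_bohr(x):.2e} hartree/bohr)")
    return start.with_coordinates(x.reshape(n, 3))


def hessian_fd(potential: PotentialInterface, geometry: Structure,
               step: float = 0.005) -> np.ndarray:
    """Cartesian Hessian (hartree/bohr²) by central finite differences;
    ``step`` in bohr (default 0.005, a tight spectroscopic setting).

    Uses gradient differences when the potential has a gradient, else
    4-point energy differences for off-diagonals.  The result is
    symmetrized as (H + Hᵀ)/2.
    """
    n3 = geometry.n_atoms * 3
    x0 = geometry.coordinates.ravel()
    h_ang = step * BOHR_ANGSTROM
    H = np.zeros((n3, n3))

    def displaced(i, amount):
        x = x0.copy()
        x[i] += amount
        return geometry.with_coordinates(x.reshape(-1, 3))

    if potential.gradient is not None:
        for i in range(n3):
            gp = potential.gradient(displaced(i, h_ang)).ravel()
            gm = potential.gradient(displaced(i, -h_ang)).ravel()
            if not (np.all(np.isfinite(gp)) and np.all(np.isfinite(gm))):
                raise ValueError(f"non-finite gradient at displacement {i}")
            H[i] = (gp - gm) / (2.0 * step) * BOHR_ANGSTROM  # hartree/bohr^2
    else:
        e0 = potential.energy(geometry)

        def e_at(shifts):
            x = x0.copy()
            for i, amt in shifts:
                x[i] += amt
            e = potential.energy(geometry.with_coordinates(x.reshape(-1, 3)))
            if not np.isfinite(e):
                raise ValueError(f"non-finite energy at displacement {shifts}")
            return e

        for i in range(n3):
            H[i, i] = (e_at([(i, h_ang)]) + e_at([(i, -h_ang)])
                       - 2.0 * e0) / step ** 2
        for i in range(n3):
            for j in range(i + 1, n3):
                H[i, j] = H[j, i] = (
                    e_at([(i, h_ang), (j, h_ang)])
                    - e_at([(i, h_ang), (j, -h_ang)])
                    - e_at([(i, -h_ang), (j, h_ang)])
                    + e_at([(i, -h_ang), (j, -h_ang)])) / (4.0 * step ** 2)
    return 0.5 * (H + H.T)


def _principal_frame(geometry: Structure, masses: np.ndarray):
    """COM-centred coordinates (bohr), principal moments, and the
    rotation (columns = principal axes) into the principal frame."""
    x = geometry.coordinates / BOHR_ANGSTROM
    com = masses @ x / masses.sum()
    xc = x - com
    inertia = np.zeros((3, 3))
    for a in range(len(masses)):
        r = xc[a]
        inertia += masses[a] * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
    moments, axes = np.linalg.eigh(inertia)
    # right-handed frame
    if np.linalg.det(axes) < 0:
        axes[:, -1] *= -1
    return xc, moments, axes


def _tr_vectors(x_pa: np.ndarray, masses: np.ndarray):
    """Mass-weighted translation/rotation vectors (orthonormal columns)."""
    n = len(masses)
    sq = np.sqrt(masses)
    vecs = []
    for c in range(3):
        v = np.zeros((n, 3))
        v[:, c] = sq
        vecs.append(v.ravel())
    for c in range(3):
        v = np.cross(np.eye(3)[c][None, :], x_pa) * sq[:, None]
        vecs.append(v.ravel())
    M = np.array(vecs).T
    q, r = np.linalg.qr(M)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(r).max())
    return q[:, keep]   # 6 columns (5 for linear)


def harmonic_analysis(hessian: np.ndarray, masses: np.ndarray,
                      geometry: Structure) -> HarmonicResult:
    """Frequencies, normal modes, rotational constants B_e^α and Coriolis
    constants ζ^α_ij from a Cartesian Hessian (hartree/bohr²) and masses
    (electron masses)."""
    masses = np.asarray(masses, float)
    n = masses.size
    if hessian.shape != (3 * n, 3 * n):
        raise ValueError("Hessian shape does not match atom count")
    if not np.allclose(hessian, hessian.T, atol=1e-8 * max(1.0, np.abs(hessian).max())):
        raise ValueError("Hessian must be symmetric")
    xc, moments, axes = _principal_frame(geometry, masses)
    sq = np.repeat(np.sqrt(masses), 3)
    Hmw = hessian / np.outer(sq, sq)
    TR = _tr_vectors(xc, masses)
    # internal-space basis: orthogonal complement of TR
    full = np.linalg.svd(TR)[0]
    B = full[:, TR.shape[1]:]
    lam, V = np.linalg.eigh(B.T @ Hmw @ B)
    omega_cm = np.sign(lam) * np.sqrt(np.abs(lam)) * HARTREE_CM
    order = np.argsort(omega_cm)
    omega_cm = omega_cm[order]
    L = (B @ V)[:, order]     # (3N, n_vib), mass-weighted, orthonormal

    cart = L / sq[:, None]
    red_mass = 1.0 / np.einsum("ij,ij->j", cart, cart) / AMU_ME

    B_e_cm = np.divide(HARTREE_CM, 2.0 * moments,
                       out=np.zeros(3), where=moments > 1e-6)

    nv = omega_cm.size
    # Coriolis constants live in the principal-axis frame
    lmat = np.einsum("acv,cb->abv", L.reshape(n, 3, nv), axes)
    zeta = np.zeros((3, nv, nv))
    for al, (be, ga) in enumerate(((1, 2), (2, 0), (0, 1))):
        zeta[al] = np.einsum("ai,aj->ij", lmat[:, be, :], lmat[:, ga, :]) \
                 - np.einsum("ai,aj->ij", lmat[:, ga, :], lmat[:, be, :])
    return HarmonicResult(
        structure=geometry, frequencies_cm=omega_cm, modes=L,
        reduced_masses_amu=red_mass, B_e_cm=B_e_cm, zeta=zeta)


def harmonic_from_potential(potential: PotentialInterface, start: Structure,
                            optimize: bool = True,
                            step: float = 0.005) -> HarmonicResult:
    """Optimize (optionally), differentiate and analyze in one call."""
    geom = optimize_geometry(potential, start) if optimize else start
    H = hessian_fd(potential, geom, step=step)
    return harmonic_analysis(H, geom.masses_au(), geom)


def compare_harmonics(freqs: np.ndarray, reference: np.ndarray):
    """Per-mode deviations Δω_i = ω_i − ω_ref,i (modes paired by sorted
    order), their RMSE and the maximum absolute deviation."""
    a = np.sort(np.asarray(freqs, float))
    b = np.sort(np.asarray(reference, float))
    if a.size != b.size:
        raise ValueError("mode counts differ")
    d = a - b
    return d, float(np.sqrt(np.mean(d ** 2))), float(np.max(np.abs(d)))
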