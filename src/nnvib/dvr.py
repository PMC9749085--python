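"""Reduced-dimensionality variational vibrational solver.

Curvilinear coordinates q_k are defined by a user-supplied mapping to
all-atom Cartesians (constrained coordinates stay frozen at reference
values inside the mapping).  The kinetic energy enters through the
mass-weighted metric tensor g_kl = Σ_a m_a (∂r_a/∂q_k)·(∂r_a/∂q_l),
evaluated numerically at every grid point; constraints are imposed by
deleting rows/columns of g before inversion (G = g⁻¹, g̃ = det g).  The
Hamiltonian is assembled on a direct product of per-coordinate DVR
grids in the manifestly hermitian rearranged (Podolsky-type) form

    T = ½ Σ_kl g̃^(−1/4) p̂_k† g̃^(1/2) G_kl p̂_l g̃^(−1/4),

with p̂ = −i d/dq as DVR first-derivative matrices; when g is constant
along a diagonal term the exact second-derivative matrix is used
instead.  Everything here is atomic units internally; levels are
reported in cm⁻¹ relative to the zero-point level.  Intended desk
scale: D ≤ 4 active coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh

from .units import HARTREE_CM


@dataclass
class CurvilinearModel:
    """Mapping from D active curvilinear coordinates to Cartesians (bohr)."""
    names: list[str]
    ranges: list[tuple[float, float]]
    mapping: Callable[[np.ndarray], np.ndarray]   # q -> (n_atoms, 3) bohr
    masses_au: np.ndarray
    periodic: list[bool] | None = None

    def __post_init__(self):
        self.masses_au = np.asarray(self.masses_au, float)
        if len(self.names) != len(self.ranges):
            raise ValueError("names/ranges length mismatch")
        if self.periodic is None:
            self.periodic = [False] * len(self.names)

    @property
    def ndim(self) -> int:
        return len(self.names)


@dataclass
class MetricTensors:
    g: np.ndarray
    G: np.ndarray
    gdet: float


@dataclass
class DVRGrid:
    points: np.ndarray
    weights: np.ndarray
    d1: np.ndarray            # first-derivative matrix (antisymmetric)
    d2: np.ndarray            # second-derivative matrix (symmetric)
    basis: str                # "sine" | "fourier" | "podvr(...)"

    @property
    def n(self) -> int:
        return self.points.size


@dataclass
class VibrationalLevels:
    zpe_cm: float
    excitations_cm: np.ndarray
    labels: list[str] = field(default_factory=list)


class SingularMetricError(RuntimeError):
    pass


def gmatrix_numeric(model: CurvilinearModel, point: np.ndarray,
                    fd_step: float = 1e-4) -> MetricTensors:
    """g, G = g⁻¹ and g̃ = det g at one coordinate point, from central
    differences of the Cartesian mapping."""
    point = np.asarray(point, float)
    D = model.ndim
    n_atoms = model.masses_au.size
    t = np.zeros((D, n_atoms, 3))
    for k in range(D):
        qp, qm = point.copy(), point.copy()
        qp[k] += fd_step
        qm[k] -= fd_step
        t[k] = (model.mapping(qp) - model.mapping(qm)) / (2.0 * fd_step)
    g = np.einsum("a,kac,lac->kl", model.masses_au, t, t)
    gdet = float(np.linalg.det(g))
    if gdet < 1e-14:
        raise SingularMetricError(
            f"singular metric (det g = {gdet:.3g}) at point {point}")
    return MetricTensors(g=g, G=np.linalg.inv(g), gdet=gdet)


# --------------------------------------------------- primitive grids

def sine_dvr(n: int, a: float, b: float) -> DVRGrid:
    """Particle-in-a-box (sine) DVR on (a, b) with n interior points."""
    if n < 2 or b <= a:
        raise ValueError("need n >= 2 and b > a")
    L = b - a
    j = np.arange(1, n + 1)
    points = a + j * L / (n + 1)
    weights = np.full(n, L / (n + 1))
    k = np.arange(1, n + 1)
    U = np.sqrt(2.0 / (n + 1)) * np.sin(np.outer(k, j) * np.pi / (n + 1))
    # FBR first-derivative matrix <phi_j | d/dx | phi_k>
    D1f = np.zeros((n, n))
    jj, kk = np.meshgrid(k, k, indexing="ij")
    mask = (jj + kk) % 2 == 1
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (2.0 / L) * 2.0 * jj * kk / (jj ** 2 - kk ** 2)
    D1f[mask] = vals[mask]
    d1 = U.T @ D1f @ U
    d2 = -(U.T * (k * np.pi / L) ** 2) @ U
    return DVRGrid(points, weights, d1, d2, "sine")


def fourier_dvr(n: int, period: float = 2.0 * np.pi) -> DVRGrid:
    """Periodic (exponential/Fourier) DVR with n (odd) points."""
    if n % 2 == 0:
        raise ValueError("fourier DVR needs an odd point count")
    points = np.arange(n) * period / n
    weights = np.full(n, period / n)
    d1 = np.zeros((n, n))
    d2 = np.zeros((n, n))
    scale = 2.0 * np.pi / period
    m = n // 2
    for i in range(n):
        for j in range(n):
            if i == j:
                d2[i, j] = -scale ** 2 * m * (m + 1) / 3.0
            else:
                arg = np.pi * (i - j) / n
                d1[i, j] = scale * (-1.0) ** (i - j) / (2.0 * np.sin(arg))
                d2[i, j] = -scale ** 2 * (-1.0) ** (i - j) * \
                    np.cos(arg) / (2.0 * np.sin(arg) ** 2)
    return DVRGrid(points, weights, d1, d2, "fourier")


def podvr_1d(potential_cut: Callable[[float], float], mass_or_G: float,
             coord_range: tuple[float, float], n_primitive: int = 80,
             n_podvr: int = 12) -> DVRGrid:
    """Potential-optimized DVR for one vibrational degree of freedom.

    Solves the 1D Schrödinger problem (constant effective inverse mass
    ``G = 1/μ`` — pass G directly) on a primitive sine DVR, keeps the
    ``n_podvr`` lowest eigenstates and diagonalizes the coordinate
    operator in that subspace.
    """
    if n_podvr > n_primitive:
        raise ValueError("n_podvr must not exceed n_primitive")
    G = mass_or_G if mass_or_G < 1.0 else 1.0 / mass_or_G
    prim = sine_dvr(n_primitive, *coord_range)
    V = np.array([potential_cut(x) for x in prim.points])
    H = -0.5 * G * prim.d2 + np.diag(V)
    vals, vecs = np.linalg.eigh(0.5 * (H + H.T))
    # localized (bound) states live inside the range; a cut with no bound
    # states gives eigenfunctions piling at the box walls
    psi = vecs[:, :n_podvr]
    # an unbound cut has no localized states: its ground "state" piles up
    # at the box walls
    if np.abs(psi[[0, -1], 0]).max() > 0.1:
        raise ValueError("potential cut appears unbound on the given range")
    Xpo = psi.T @ (prim.points[:, None] * psi)
    xvals, xvecs = np.linalg.eigh(0.5 * (Xpo + Xpo.T))
    T = psi @ xvecs                       # (n_primitive, n_podvr), orthonormal
    sgn = np.sign(T[np.abs(T).argmax(axis=0), np.arange(n_podvr)])
    T = T * sgn
    d1 = T.T @ prim.d1 @ T
    d2 = T.T @ prim.d2 @ T
    w = np.interp(xvals, prim.points, prim.weights)
    return DVRGrid(xvals, w, d1, d2, f"podvr[{n_podvr}/{n_primitive}]")


def podvr_levels(potential_cut, mass_or_G, coord_range,
                 n_primitive: int = 80, n_states: int = 8) -> np.ndarray:
    """1D eigenlevels (cm⁻¹ above the potential minimum of the cut) on the
    primitive grid — the PODVR contraction's own reference spectrum."""
    import scipy.optimize
    G = mass_or_G if mass_or_G < 1.0 else 1.0 / mass_or_G
    prim = sine_dvr(n_primitive, *coord_range)
    V = np.array([potential_cut(x) for x in prim.points])
    H = -0.5 * G * prim.d2 + np.diag(V)
    vals = np.linalg.eigvalsh(0.5 * (H + H.T))
    vmin = scipy.optimize.minimize_scalar(
        potential_cut, bounds=coord_range, method="bounded",
        options={"xatol": 1e-10}).fun
    vmin = min(vmin, V.min())
    return (vals[:n_states] - vmin) * HARTREE_CM


# ------------------------------------------------- product Hamiltonian

def build_hamiltonian(model: CurvilinearModel, grids: Sequence[DVRGrid],
                      potential_q: Callable[[np.ndarray], float],
                      product_cap: int = 200_000) -> sp.csr_matrix:
    """Direct-product DVR Hamiltonian (hartree) for all active coordinates.

    ``potential_q`` maps a coordinate vector to energy (hartree).  The
    metric is evaluated pointwise; diagonal kinetic terms with constant
    metric use the exact second-derivative matrix, everything else the
    hermitian Podolsky-form product of first-derivative matrices.
    """
    D = model.ndim
    if len(grids) != D:
        raise ValueError("one grid per active coordinate required")
    shape = tuple(g.n for g in grids)
    N = int(np.prod(shape))
    if N > product_cap:
        raise MemoryError(f"product grid size {N} exceeds cap {product_cap}")

    pts = np.array(np.meshgrid(*[g.points for g in grids],
                               indexing="ij")).reshape(D, N)
    V = np.empty(N)
    Gmat = np.empty((N, D, D))
    gdet = np.empty(N)
    for p in range(N):
        q = pts[:, p]
        V[p] = potential_q(q)
        mt = gmatrix_numeric(model, q)
        Gmat[p] = mt.G
        gdet[p] = mt.gdet

    def op_1d(mat, axis):
        mats = [sp.identity(g.n, format="csr") for g in grids]
        mats[axis] = sp.csr_matrix(mat)
        out = mats[0]
        for m in mats[1:]:
            out = sp.kron(out, m, format="csr")
        return out

    const_metric = (np.ptp(gdet) < 1e-10 * max(1.0, np.abs(gdet).max()))
    Finv4 = sp.diags(gdet ** -0.25)
    H = sp.diags(V).tolil()
    T = sp.csr_matrix((N, N))
    for k in range(D):
        for l in range(D):
            Gkl = Gmat[:, k, l]
            if np.ptp(Gkl) < 1e-12 * max(1.0, np.abs(Gkl).max()) and \
                    abs(Gkl[0]) < 1e-14:
                continue
            if k == l and const_metric and \
                    np.ptp(Gkl) < 1e-12 * max(1.0, np.abs(Gkl).max()):
                T = T - 0.5 * Gkl[0] * op_1d(grids[k].d2, k)
            else:
                Dk = op_1d(grids[k].d1, k)
                Dl = op_1d(grids[l].d1, l)
                mid = sp.diags(np.sqrt(gdet) * Gkl)
                T = T + 0.5 * (Finv4 @ Dk.T.tocsr() @ mid @ Dl @ Finv4)
    H = (H.tocsr() + T)
    H = 0.5 * (H + H.T)
    return H.tocsr()


def solve_levels(hamiltonian, n_states: int = 10,
                 labels: list[str] | None = None) -> VibrationalLevels:
    """Lowest eigenvalues by a deterministic iterative sparse solver;
    excitation energies in cm⁻¹ relative to the zero-point level."""
    N = hamiltonian.shape[0]
    if N <= 1200:
        dense = hamiltonian.toarray() if sp.issparse(hamiltonian) \
            else np.asarray(hamiltonian)
        vals = scipy.linalg.eigh(dense, eigvals_only=True,
                                 subset_by_index=[0, min(n_states, N - 1)])
    else:
        v0 = np.full(N, 1.0 / np.sqrt(N))
        vals = eigsh(hamiltonian, k=min(n_states + 1, N - 1), which="SA",
                     v0=v0, return_eigenvectors=False)
        vals = np.sort(vals)
    zpe = vals[0]
    exc = (vals[1:n_states + 1] - zpe) * HARTREE_CM
    return VibrationalLevels(zpe_cm=float(zpe * HARTREE_CM),
                             excitations_cm=exc,
                             labels=labels or [])
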