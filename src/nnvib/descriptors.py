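"""Atom-centered symmetry functions (ACSFs).

Each atom's chemical environment within a cutoff radius is mapped to a
fixed-length descriptor vector that is invariant under rotation,
translation and permutation of same-element atoms by construction.  Two
families are used, following classic second-generation high-dimensional
neural network potential practice:

* radial ("G2"): Σ_j exp(−η(r_ij − r_s)²)·f_c(r_ij), resolved per
  neighbour element;
* angular ("G4"): 2^(1−ζ) Σ_{j<k} (1 + λ cosθ_jik)^ζ ·
  exp(−η(r_ij²+r_ik²+r_jk²))·f_c(r_ij)f_c(r_ik)f_c(r_jk), resolved per
  unordered neighbour-element pair.

All distances are in bohr.  The descriptor ordering is frozen (see
:meth:`ACSFConfig.feature_names`) and versioned into serialized models so
trained weights stay valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import yaml

from .structures import Structure
from .units import BOHR_ANGSTROM

ACSF_FORMAT_VERSION = 1


def cutoff_fn(r, R_c: float):
    """Cosine cutoff: 0.5·[cos(π r/R_c) + 1] inside R_c, exactly 0 outside.

    Value and first derivative both vanish at r = R_c, so every symmetry
    function decays smoothly to zero in value and slope at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("negative distance")
    if R_c <= 0:
        raise ValueError("cutoff radius must be positive")
    out = np.where(r <= R_c, 0.5 * (np.cos(np.pi * r / R_c) + 1.0), 0.0)
    return out if out.ndim else float(out)


def cutoff_fn_deriv(r, R_c: float):
    r = np.asarray(r, dtype=float)
    out = np.where(r <= R_c, -0.5 * np.pi / R_c * np.sin(np.pi * r / R_c), 0.0)
    return out if out.ndim else float(out)


@dataclass
class ACSFConfig:
    """Hyperparameters of the symmetry-function set.

    The same parameter lists apply to every atom of a given element
    (required for transferability).  Defaults: cutoff 15 bohr — large
    enough that all atoms of an equilibrium-sized 10-atom cluster such as
    the formic acid dimer see each other — 6 radial η values log-spaced
    in [0.001, 0.4] bohr⁻² with r_s = 0, and 8 angular (η, ζ, λ)
    combinations.
    """
    elements: list[str]
    cutoff: float = 15.0  # bohr
    radial_params: list[tuple[float, float]] = field(default_factory=list)
    angular_params: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.elements = sorted(self.elements)
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not self.radial_params:
            self.radial_params = [(float(eta), 0.0) for eta in
                                  np.geomspace(0.001, 0.4, 6)]
        if not self.angular_params:
            self.angular_params = [
                (eta, zeta, lam)
                for eta in (0.001, 0.05)
                for zeta in (1.0, 4.0)
                for lam in (1.0, -1.0)
            ]
        for _, zeta, lam in self.angular_params:
            if zeta < 1:
                raise ValueError("zeta must be >= 1")
            if lam not in (1.0, -1.0):
                raise ValueError("lambda must be +1 or -1")

    @property
    def element_pairs(self) -> list[tuple[str, str]]:
        return list(combinations_with_replacement(self.elements, 2))

    @property
    def n_features(self) -> int:
        return (len(self.elements) * len(self.radial_params)
                + len(self.element_pairs) * len(self.angular_params))

    def feature_names(self) -> list[str]:
        """Frozen descriptor ordering: radial blocks by neighbour element
        (alphabetical), then angular blocks by element pair, parameters in
        listed order within each block."""
        names = []
        for el in self.elements:
            for eta, rs in self.radial_params:
                names.append(f"G2[{el}] eta={eta:g} rs={rs:g}")
        for ea, eb in self.element_pairs:
            for eta, zeta, lam in self.angular_params:
                names.append(f"G4[{ea}{eb}] eta={eta:g} zeta={zeta:g} "
                             f"lambda={lam:+g}")
        return names

    def to_dict(self) -> dict:
        return {
            "format_version": ACSF_FORMAT_VERSION,
            "elements": list(self.elements),
            "cutoff": float(self.cutoff),
            "radial_params": [[float(a), float(b)] for a, b in self.radial_params],
            "angular_params": [[float(a), float(b), float(c)]
                               for a, b, c in self.angular_params],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ACSFConfig":
        version = d.get("format_version", 1)
        if version > ACSF_FORMAT_VERSION:
            raise ValueError(f"ACSF config format version {version} is newer "
                             f"than supported {ACSF_FORMAT_VERSION}")
        return cls(elements=list(d["elements"]), cutoff=float(d["cutoff"]),
                   radial_params=[tuple(p) for p in d["radial_params"]],
                   angular_params=[tuple(p) for p in d["angular_params"]])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "ACSFConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class DescriptorMatrix:
    values: np.ndarray        # (n_atoms, n_features)
    elements: list[str]       # element of each row (selects the atomic net)


def _coords_bohr(structure: Structure) -> np.ndarray:
    return structure.coordinates / BOHR_ANGSTROM


def radial_sf(structure: Structure, center: int, neighbor_element: str,
              eta: float, r_shift: float, R_c: float) -> float:
    """Single radial symmetry function value at one atom."""
    x = _coords_bohr(structure)
    total = 0.0
    for j, el in enumerate(structure.elements):
        if j == center or el != neighbor_element:
            continue
        r = float(np.linalg.norm(x[j] - x[center]))
        if r <= R_c:
            total += np.exp(-eta * (r - r_shift) ** 2) * cutoff_fn(r, R_c)
    return total


def angular_sf(structure: Structure, center: int, element_pair,
               eta: float, zeta: float, lam: float, R_c: float) -> float:
    """Single angular symmetry function value at one atom."""
    ea, eb = sorted(element_pair)
    x = _coords_bohr(structure)
    idx_a = [j for j, el in enumerate(structure.elements)
             if el == ea and j != center]
    idx_b = [j for j, el in enumerate(structure.elements)
             if el == eb and j != center]
    if ea == eb:
        pairs = list(combinations_with_replacement(idx_a, 2))
        pairs = [(j, k) for j, k in pairs if j != k]
    else:
        pairs = [(j, k) for j in idx_a for k in idx_b]
    total = 0.0
    for j, k in pairs:
        u, v = x[j] - x[center], x[k] - x[center]
        w = x[k] - x[j]
        ru, rv, rw = (np.linalg.norm(u), np.linalg.norm(v), np.linalg.norm(w))
        if ru > R_c or rv > R_c or rw > R_c:
            continue
        cos_t = float(np.dot(u, v) / (ru * rv))
        base = max(1.0 + lam * cos_t, 0.0)
        total += (base ** zeta * np.exp(-eta * (ru**2 + rv**2 + rw**2))
                  * cutoff_fn(ru, R_c) * cutoff_fn(rv, R_c) * cutoff_fn(rw, R_c))
    return 2.0 ** (1.0 - zeta) * total


def build_descriptors(structure: Structure, config: ACSFConfig,
                      jacobian: bool = False):
    """Assemble the full descriptor matrix; optionally also its analytic
    Jacobian with respect to Cartesian coordinates (in Å⁻¹).

    Returns a :class:`DescriptorMatrix` or, with ``jacobian=True``, a
    tuple ``(DescriptorMatrix, J)`` where ``J`` has shape
    ``(n_atoms, n_features, n_atoms, 3)``.
    """
    missing = set(structure.elements) - set(config.elements)
    if missing:
        raise ValueError(f"elements not covered by ACSF config: {sorted(missing)}")
    x = _coords_bohr(structure)
    n = structure.n_atoms
    nf = config.n_features
    R_c = config.cutoff
    G = np.zeros((n, nf))
    J = np.zeros((n, nf, n, 3)) if jacobian else None

    # pairwise geometry
    diff = x[:, None, :] - x[None, :, :]          # diff[i,j] = x_i - x_j
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)

    el_idx = {el: [j for j, e in enumerate(structure.elements) if e == el]
              for el in config.elements}

    # --- radial block ---
    fidx = 0
    for el in config.elements:
        neigh = el_idx[el]
        for eta, rs in config.radial_params:
            for i in range(n):
                for j in neigh:
                    if j == i:
                        continue
                    r = dist[i, j]
                    if r > R_c:
                        continue
                    gauss = np.exp(-eta * (r - rs) ** 2)
                    fc = cutoff_fn(r, R_c)
                    G[i, fidx] += gauss * fc
                    if jacobian:
                        dterm = (-2.0 * eta * (r - rs) * gauss * fc
                                 + gauss * cutoff_fn_deriv(r, R_c))
                        grad = dterm * diff[i, j] / r   # d/dx_i, bohr^-1
                        J[i, fidx, i] += grad
                        J[i, fidx, j] -= grad
            fidx += 1

    # --- angular block ---
    for ea, eb in config.element_pairs:
        pair_lists = {}
        for i in range(n):
            ia = [j for j in el_idx[ea] if j != i]
            ib = [j for j in el_idx[eb] if j != i]
            if ea == eb:
                pairs = [(p, q) for ii, p in enumerate(ia) for q in ia[ii + 1:]]
            else:
                pairs = [(p, q) for p in ia for q in ib]
            pair_lists[i] = pairs
        for eta, zeta, lam in config.angular_params:
            pref = 2.0 ** (1.0 - zeta)
            for i in range(n):
                for j, k in pair_lists[i]:
                    ru, rv, rw = dist[i, j], dist[i, k], dist[j, k]
                    if ru > R_c or rv > R_c or rw > R_c:
                        continue
                    u, v = -diff[i, j], -diff[i, k]   # x_j - x_i, x_k - x_i
                    w = x[k] - x[j]
                    cos_t = np.dot(u, v) / (ru * rv)
                    base = 1.0 + lam * cos_t
                    if base < 0.0:
                        base = 0.0
                    gauss = np.exp(-eta * (ru**2 + rv**2 + rw**2))
                    fcu, fcv, fcw = (cutoff_fn(ru, R_c), cutoff_fn(rv, R_c),
                                     cutoff_fn(rw, R_c))
                    A = base ** zeta
                    T = A * gauss * fcu * fcv * fcw
                    G[i, fidx] += pref * T
                    if jacobian:
                        # dA/dcos = zeta*lam*base^(zeta-1)
                        dA = (zeta * lam * base ** (zeta - 1.0)
                              if base > 0.0 else 0.0)
                        dcos_du = v / (ru * rv) - cos_t * u / ru**2
                        dcos_dv = u / (ru * rv) - cos_t * v / rv**2
                        gfff = gauss * fcu * fcv * fcw
                        dT_du = (dA * dcos_du * gfff
                                 + A * (-2.0 * eta * u) * gfff
                                 + A * gauss * cutoff_fn_deriv(ru, R_c)
                                 * (u / ru) * fcv * fcw)
                        dT_dv = (dA * dcos_dv * gfff
                                 + A * (-2.0 * eta * v) * gfff
                                 + A * gauss * fcu
                                 * cutoff_fn_deriv(rv, R_c) * (v / rv) * fcw)
                        dT_dw = (A * (-2.0 * eta * w) * gfff
                                 + A * gauss * fcu * fcv
                                 * cutoff_fn_deriv(rw, R_c) * (w / rw))
                        J[i, fidx, i] += pref * (-dT_du - dT_dv)
                        J[i, fidx, j] += pref * (dT_du - dT_dw)
                        J[i, fidx, k] += pref * (dT_dv + dT_dw)
            fidx += 1

    dm = DescriptorMatrix(values=G, elements=list(structure.elements))
    if jacobian:
        # descriptors are functions of bohr distances; coordinates are Å
        return dm, J / BOHR_ANGSTROM
    return dm


def descriptor_jacobian(structure: Structure, config: ACSFConfig) -> np.ndarray:
    """Analytic derivative of every descriptor entry with respect to every
    Cartesian coordinate (Å⁻¹); shape (n_atoms, n_features, n_atoms, 3)."""
    _, J = build_descriptors(structure, config, jacobian=True)
    return J
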