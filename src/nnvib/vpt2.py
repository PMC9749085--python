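"""Second-order vibrational perturbation theory (VPT2) with Fermi-
resonance deperturbation and polyad diagonalization (GVPT2).

From a quartic force field the anharmonicity constants x_ij follow from
the standard second-order contact transformation:

    x_ii = φ_iiii/16 − (1/16) Σ_j φ_iij² (8ω_i² − 3ω_j²)/(ω_j(4ω_i² − ω_j²))

    x_ij = φ_iijj/4 − (1/4) Σ_k φ_iik φ_jjk/ω_k
           − (1/2) Σ_k φ_ijk² ω_k(ω_k² − ω_i² − ω_j²)/Δ_ijk
           + Σ_α B_e^α (ζ^α_ij)² (ω_i/ω_j + ω_j/ω_i)

with Δ_ijk the four-factor resonance denominator.  Fundamentals are
ν_i = ω_i + 2x_ii + ½ Σ_{j≠i} x_ij.  Near-degeneracies ω_i ≈ 2ω_j and
ω_i ≈ ω_j + ω_k make individual denominator channels blow up; GVPT2
removes exactly those channels from the sums ("deperturbed" constants
x*) and recovers the interaction by diagonalizing a small effective
Hamiltonian per polyad whose off-diagonal elements are φ_ijj/4
(fundamental↔overtone) and φ_ijk/(2√2) (fundamental↔combination).

The denominator-channel bookkeeping used here was fixed by requiring
agreement with dense variational diagonalization of the same force
field on exact-resonance fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qff import QuarticForceField, resonance_denominator

__all__ = [
    "ResonanceRecord", "Polyad", "AnharmonicAnalysis",
    "anharmonic_constants", "detect_resonances", "gvpt2_fundamentals",
    "vpt2_fundamentals", "state_energy",
]

_DENOM_FLOOR = 1e-8  # cm⁻¹; smaller magnitudes flag a hard degeneracy


@dataclass
class ResonanceRecord:
    """A flagged near-degeneracy.

    ``kind == "fermi1"``: ω_i ≈ 2ω_j (modes = (i, j), coupling φ_ijj);
    ``kind == "fermi2"``: ω_i ≈ ω_j + ω_k (modes = (i, j, k), coupling φ_ijk).
    """
    kind: str
    modes: tuple[int, ...]
    detuning_cm: float
    coupling_cm: float

    @property
    def bright_state(self) -> tuple:
        return ("fund", (self.modes[0],))

    @property
    def dark_state(self) -> tuple:
        if self.kind == "fermi1":
            return ("over", (self.modes[1],))
        return ("comb", tuple(sorted(self.modes[1:])))


@dataclass
class Polyad:
    states: list[tuple]          # ("fund"|"over"|"comb", mode tuple)
    hamiltonian: np.ndarray      # cm⁻¹, symmetric
    eigenvalues: np.ndarray
    mixing: np.ndarray           # eigenvector components squared, rows=eigstates
    assignments: list[tuple]     # dominant state label per eigenvalue
    ambiguous: list[list[tuple]] # >1 candidate when leading fraction < 0.5


@dataclass
class AnharmonicAnalysis:
    omega_cm: np.ndarray
    x: np.ndarray                    # anharmonicity constants (n, n)
    x_deperturbed: np.ndarray
    resonances: list[ResonanceRecord]
    polyads: list[Polyad]
    nu_cm: np.ndarray                # GVPT2 fundamentals
    nu_plain_cm: np.ndarray          # plain VPT2 (Eq.-2) fundamentals
    warnings: list[str] = field(default_factory=list)


def _x_matrix(qff: QuarticForceField, B_e=None, zeta=None,
              removals: list[tuple] | None = None,
              warnings_out: list[str] | None = None) -> np.ndarray:
    """x matrix with optional resonance-channel removals.

    Each removal is ("fermi1", i, j) or ("fermi2", i, j, k) and deletes
    the corresponding small-denominator channels from the affected sums.
    """
    w = qff.omega_cm
    p3 = qff.phi3
    p4 = qff.phi4_semi
    n = w.size
    removals = removals or []
    rem1 = set()
    rem2 = set()
    for t in removals:
        if t[0] == "fermi1":
            rem1.add((t[1], t[2]))
        elif t[0] == "fermi2":
            rem2.add((t[1],) + tuple(sorted(t[2:4])))
        else:
            raise ValueError(f"unknown removal kind {t[0]!r}")

    def guard(denom, context):
        if abs(denom) < _DENOM_FLOOR:
            msg = (f"near-singular denominator {denom:.3g} cm-1 in {context}; "
                   f"deperturbation required")
            if warnings_out is not None:
                warnings_out.append(msg)
            return np.sign(denom) * _DENOM_FLOOR if denom != 0 else _DENOM_FLOOR
        return denom

    x = np.zeros((n, n))
    for i in range(n):
        acc = p4[i, i] / 16.0
        for j in range(n):
            # kernel channels: 2/ω_j − 1/[2(2ω_i−ω_j)] + 1/[2(2ω_i+ω_j)]
            kern = 2.0 / w[j] + 1.0 / (2.0 * (2.0 * w[i] + w[j]))
            if (j, i) not in rem1:   # resonance ω_j ≈ 2ω_i, coupling φ_iij
                kern -= 1.0 / (2.0 * guard(2.0 * w[i] - w[j],
                                           f"x[{i},{i}] (j={j})"))
            acc -= p3[i, i, j] ** 2 * kern / 16.0
        x[i, i] = acc

    for i in range(n):
        for j in range(i + 1, n):
            acc = p4[i, j] / 4.0
            for k in range(n):
                acc -= 0.25 * p3[i, i, k] * p3[j, j, k] / w[k]
                # cubic kernel channels of φ_ijk²
                kern = (1.0 / (w[i] + w[j] + w[k])
                        + 1.0 / (w[i] - w[j] + w[k]))
                # channel −1/(ω_i+ω_j−ω_k): resonant when ω_k ≈ ω_i+ω_j
                if (k, min(i, j), max(i, j)) not in rem2:
                    kern -= 1.0 / guard(w[i] + w[j] - w[k],
                                        f"x[{i},{j}] (k={k})")
                # channel −1/(ω_i−ω_j−ω_k):
                #   k == j: type-I ω_i ≈ 2ω_j;  k != j: type-II ω_i ≈ ω_j+ω_k
                resonant = ((i, j) in rem1 if k == j else
                            (i,) + tuple(sorted((j, k))) in rem2)
                if not resonant:
                    kern -= 1.0 / guard(w[i] - w[j] - w[k],
                                        f"x[{i},{j}] (k={k})")
                acc -= 0.125 * p3[i, j, k] ** 2 * kern
            if B_e is not None and zeta is not None:
                acc += float(np.sum(np.asarray(B_e) * zeta[:, i, j] ** 2)) \
                    * (w[i] / w[j] + w[j] / w[i])
            x[i, j] = x[j, i] = acc
    return x


def anharmonic_constants(qff: QuarticForceField, B_e=None,
                         zeta=None) -> np.ndarray:
    """Plain (non-deperturbed) anharmonicity constant matrix (cm⁻¹)."""
    warns: list[str] = []
    x = _x_matrix(qff, B_e, zeta, warnings_out=warns)
    if warns:
        raise FloatingPointError(
            "resonant denominator below floor; deperturb first: "
            + "; ".join(warns))
    return x


def detect_resonances(qff: QuarticForceField,
                      detuning_threshold: float = 100.0,
                      coupling_floor: float = 1.0) -> list[ResonanceRecord]:
    """Flag ω_i ≈ 2ω_j and ω_i ≈ ω_j + ω_k near-degeneracies whose
    detuning is below ``detuning_threshold`` (cm⁻¹) and whose cubic
    coupling magnitude exceeds ``coupling_floor`` (cm⁻¹)."""
    w = qff.omega_cm
    n = w.size
    records = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            det = w[i] - 2.0 * w[j]
            if abs(det) < detuning_threshold and \
                    abs(qff.phi3[i, j, j]) > coupling_floor:
                records.append(ResonanceRecord(
                    "fermi1", (i, j), float(det),
                    float(qff.phi3[i, j, j])))
    for i in range(n):
        for j in range(n):
            for k in range(j + 1, n):
                if i in (j, k):
                    continue
                det = w[i] - w[j] - w[k]
                if abs(det) < detuning_threshold and \
                        abs(qff.phi3[i, j, k]) > coupling_floor:
                    records.append(ResonanceRecord(
                        "fermi2", (i, j, k), float(det),
                        float(qff.phi3[i, j, k])))
    return records


def state_energy(state: tuple, omega: np.ndarray, x: np.ndarray) -> float:
    """Energy above the ground state of a fundamental/overtone/combination
    from E(v) = Σ ω_i(v_i+½) + Σ_{i≤j} x_ij(v_i+½)(v_j+½)."""
    kind, modes = state
    n = omega.size
    v = np.zeros(n)
    if kind == "fund":
        v[modes[0]] = 1
    elif kind == "over":
        v[modes[0]] = 2
    elif kind == "comb":
        for m in modes:
            v[m] += 1
    else:
        raise ValueError(f"unknown state kind {kind!r}")
    e = float(omega @ v)
    for i in range(n):
        e += x[i, i] * (v[i] ** 2 + v[i])
        for j in range(i + 1, n):
            e += x[i, j] * (v[i] * v[j] + 0.5 * (v[i] + v[j]))
    return e


def vpt2_fundamentals(omega: np.ndarray, x: np.ndarray) -> np.ndarray:
    """ν_i = ω_i + 2x_ii + ½ Σ_{j≠i} x_ij."""
    n = omega.size
    off = x.sum(axis=1) - np.diag(x)
    return omega + 2.0 * np.diag(x) + 0.5 * off


def gvpt2_fundamentals(qff: QuarticForceField, B_e=None, zeta=None,
                       detuning_threshold: float = 100.0,
                       coupling_floor: float = 1.0) -> AnharmonicAnalysis:
    """Full GVPT2: detect resonances, deperturb, diagonalize polyads.

    Polyads are transitively closed (a state resonating with two partners
    produces one block).  Fundamentals inside a polyad are read off the
    eigenvalue whose eigenvector has its dominant weight on that
    fundamental's basis state; when the leading fraction is below 0.5
    both candidates are recorded as ambiguous.
    """
    warns: list[str] = []
    records = detect_resonances(qff, detuning_threshold, coupling_floor)
    x = _x_matrix(qff, B_e, zeta, warnings_out=warns)
    removals = [(r.kind, *r.modes) for r in records]
    x_dep = _x_matrix(qff, B_e, zeta, removals=removals, warnings_out=warns)
    omega = qff.omega_cm
    nu_plain = vpt2_fundamentals(omega, x)
    # fundamentals outside polyads use the deperturbed constants; the
    # removed channels reappear as explicit polyad couplings below
    nu_base = vpt2_fundamentals(omega, x_dep)

    # union-find over polyad states
    parent: dict[tuple, tuple] = {}

    def find(s):
        parent.setdefault(s, s)
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    def union(a, b):
        parent[find(a)] = find(b)

    couplings: dict[frozenset, float] = {}
    for r in records:
        a, b = r.bright_state, r.dark_state
        union(a, b)
        if r.kind == "fermi1":
            w_el = r.coupling_cm / 4.0
        else:
            w_el = r.coupling_cm / (2.0 * np.sqrt(2.0))
        couplings[frozenset((a, b))] = w_el

    groups: dict[tuple, list[tuple]] = {}
    for s in parent:
        groups.setdefault(find(s), []).append(s)

    polyads = []
    nu = nu_base.copy()
    for states in groups.values():
        states = sorted(states)
        m = len(states)
        H = np.zeros((m, m))
        for a in range(m):
            H[a, a] = state_energy(states[a], omega, x_dep)
            for b in range(a + 1, m):
                key = frozenset((states[a], states[b]))
                if key in couplings:
                    H[a, b] = H[b, a] = couplings[key]
        vals, vecs = np.linalg.eigh(H)
        mixing = vecs.T ** 2
        assignments, ambiguous = [], []
        taken = set()
        for e_idx in np.argsort(-np.max(mixing, axis=1)):
            # greedy: strongest-mixed eigenstates claim their label first
            order = np.argsort(-mixing[e_idx])
            lab = next((states[s] for s in order if s not in taken), None)
            taken.add(states.index(lab))
            assignments.append((e_idx, lab))
            if mixing[e_idx].max() < 0.5:
                cand = [states[s] for s in order[:2]]
                ambiguous.append(cand)
        assignments = [lab for _, lab in sorted(assignments)]
        polyads.append(Polyad(states, H, vals, mixing, assignments, ambiguous))
        for e_idx, lab in enumerate(assignments):
            if lab[0] == "fund":
                nu[lab[1][0]] = vals[e_idx]

    return AnharmonicAnalysis(
        omega_cm=omega, x=x, x_deperturbed=x_dep, resonances=records,
        polyads=polyads, nu_cm=nu, nu_plain_cm=nu_plain, warnings=warns)
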