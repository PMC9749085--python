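"""Shared fixtures: oracles, untrained/trained models, and the dense
variational diagonalization used as an independent check on VPT2."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest

from nnvib.descriptors import ACSFConfig
from nnvib.model import NNPModel
from nnvib.oracles import toy_triatomic, sample_structures
from nnvib.qff import QuarticForceField
from nnvib.training import TrainingConfig, fit


@pytest.fixture(scope="session")
def triatomic():
    return toy_triatomic()


@pytest.fixture(scope="session")
def acsf_oc():
    return ACSFConfig(elements=["O", "C"])


@pytest.fixture(scope="session")
def acsf_och():
    return ACSFConfig(elements=["O", "C", "H"])


@pytest.fixture(scope="session")
def random_model(acsf_och):
    """Untrained (random-weight) model: full architecture, cheap."""
    model = NNPModel.create(acsf_och, hidden=(12, 12), seed=7)
    rng = np.random.default_rng(11)
    model.fit_scaling(rng.uniform(0.0, 2.0, size=(50, acsf_och.n_features)))
    model.offsets = {"O": -75.0, "C": -37.8, "H": -0.5}
    return model


@pytest.fixture(scope="session")
def trained_triatomic(triatomic, acsf_oc):
    """Model trained on 600 oracle samples (scaled-down recovery run used
    by several tests; the acceptance script runs the full-size one)."""
    ds = sample_structures(triatomic, 600, amplitude=1.0, seed=5,
                           scheme="normal-mode")
    model = NNPModel.create(acsf_oc, hidden=(12, 12), seed=0)
    model, history = fit(model, ds,
                         TrainingConfig(optimizer="kalman", epochs=6, seed=0))
    return model, history, ds


def set_phi3(phi3: np.ndarray, i: int, j: int, k: int, value: float) -> None:
    for p in set(permutations((i, j, k))):
        phi3[p] = value


def make_qff(omega, cubic: dict, quartic: dict) -> QuarticForceField:
    """Build a QFF from sparse {index tuple: value} force constants."""
    omega = np.asarray(omega, float)
    n = omega.size
    phi3 = np.zeros((n, n, n))
    phi4 = np.zeros((n, n))
    for (i, j, k), v in cubic.items():
        set_phi3(phi3, i, j, k, v)
    for idx, v in quartic.items():
        if len(set(idx)) == 1:
            phi4[idx[0], idx[0]] = v
        else:
            i, j = sorted(set(idx))
            phi4[i, j] = phi4[j, i] = v
    return QuarticForceField(omega, phi3, phi4)


def variational_levels(qff: QuarticForceField, n_basis: int = 24,
                       n_states: int = 10) -> np.ndarray:
    """Dense diagonalization of the QFF Hamiltonian in a harmonic-
    oscillator product basis; energies above the ground state (cm⁻¹).

    Independent of the perturbative machinery: only ladder-operator
    matrix elements of q are used.
    """
    n = qff.n_modes
    nb = n_basis
    q1 = np.zeros((nb, nb))
    for k in range(nb - 1):
        q1[k, k + 1] = q1[k + 1, k] = np.sqrt((k + 1) / 2.0)
    eye = np.eye(nb)

    def kron_list(mats):
        out = mats[0]
        for m in mats[1:]:
            out = np.kron(out, m)
        return out

    Q = []
    for i in range(n):
        mats = [eye] * n
        mats[i] = q1
        Q.append(kron_list(mats))
    H = np.zeros_like(Q[0])
    for i in range(n):
        mats = [eye] * n
        mats[i] = np.diag(np.arange(nb) + 0.5)
        H += qff.omega_cm[i] * kron_list(mats)
        H += qff.phi3[i, i, i] / 6.0 * Q[i] @ Q[i] @ Q[i]
        H += qff.phi4_semi[i, i] / 24.0 * Q[i] @ Q[i] @ Q[i] @ Q[i]
        for j in range(n):
            if j != i:
                H += 0.5 * qff.phi3[i, i, j] * Q[i] @ Q[i] @ Q[j]
            if j > i:
                H += 0.25 * qff.phi4_semi[i, j] * Q[i] @ Q[i] @ Q[j] @ Q[j]
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                H += qff.phi3[i, j, k] * Q[i] @ Q[j] @ Q[k]
    vals = np.linalg.eigvalsh(H)
    return vals[:n_states] - vals[0]
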