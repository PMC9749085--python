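"""Atomic feed-forward networks and the high-dimensional NNP energy sum.

The total energy of a structure is a sum of atomic energies, each the
output of a small per-element feed-forward network fed with that atom's
symmetry-function descriptor.  All atoms of one element share a single
network (one set of weights per element), which is what makes the
potential transferable across system sizes.  Analytic forces follow from
the chain rule through the descriptor Jacobian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .descriptors import ACSFConfig, build_descriptors
from .structures import Structure
from .units import HARTREE_EV

MODEL_FORMAT_VERSION = 1


def _act(x):
    return np.tanh(x)


def _act_deriv(x):
    c = np.cosh(x)
    return 1.0 / (c * c)


@dataclass
class AtomicNetwork:
    """Feed-forward net: descriptor -> atomic energy (hartree).

    Hidden layers use tanh (smooth, so finite-difference Hessians and
    quartic force fields of the resulting PES are well behaved); the
    output is linear.
    """
    weights: list[np.ndarray]   # weights[l]: (n_in_l, n_out_l)
    biases: list[np.ndarray]    # biases[l]: (n_out_l,)

    def __post_init__(self):
        self.weights = [np.asarray(w, float) for w in self.weights]
        self.biases = [np.asarray(b, float) for b in self.biases]
        for w, b in zip(self.weights, self.biases):
            if w.shape[1] != b.shape[0]:
                raise ValueError("inconsistent weight/bias shapes")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise ValueError("non-finite network parameters")
        for wa, wb in zip(self.weights, self.weights[1:]):
            if wa.shape[1] != wb.shape[0]:
                raise ValueError("inconsistent layer sizes")
        if self.weights[-1].shape[1] != 1:
            raise ValueError("output layer must have a single node")

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    @classmethod
    def create(cls, n_inputs: int, hidden: tuple[int, ...] = (12, 12),
               rng: np.random.Generator | None = None) -> "AtomicNetwork":
        rng = rng or np.random.default_rng(0)
        sizes = [n_inputs, *hidden, 1]
        weights, biases = [], []
        for a, b in zip(sizes, sizes[1:]):
            weights.append(rng.normal(0.0, 1.0 / np.sqrt(a), size=(a, b)))
            biases.append(np.zeros(b))
        return cls(weights, biases)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Evaluate on (n, n_inputs) scaled descriptors -> (n,) energies."""
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[1] != self.n_inputs:
            raise ValueError(f"descriptor length {x.shape[1]} does not match "
                             f"network input {self.n_inputs}")
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = _act(h @ w + b)
        return (h @ self.weights[-1] + self.biases[-1])[:, 0]

    def forward_with_cache(self, x: np.ndarray):
        x = np.atleast_2d(np.asarray(x, float))
        pre, post = [], [x]
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            z = h @ w + b
            pre.append(z)
            h = _act(z)
            post.append(h)
        out = (h @ self.weights[-1] + self.biases[-1])[:, 0]
        return out, pre, post

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(output)/d(input), shape (n, n_inputs)."""
        _, pre, _ = self.forward_with_cache(x)
        g = np.repeat(self.weights[-1].T, np.atleast_2d(x).shape[0], axis=0)
        for w, z in zip(reversed(self.weights[:-1]), reversed(pre)):
            g = (g * _act_deriv(z)) @ w.T
        return g

    def param_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(Σ outputs)/d(params) for a batch, flattened; shape (n_params,).

        Gradients of a *sum* of atomic outputs is exactly what energy
        training needs (total energy is the sum over atoms).
        """
        _, pre, post = self.forward_with_cache(x)
        n = post[0].shape[0]
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = np.ones((n, 1))
        grads_w[-1] = post[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        d = delta @ self.weights[-1].T
        for l in range(len(self.weights) - 2, -1, -1):
            d = d * _act_deriv(pre[l])
            grads_w[l] = post[l].T @ d
            grads_b[l] = d.sum(axis=0)
            if l > 0:
                d = d @ self.weights[l].T
        return np.concatenate([np.concatenate([w.ravel(), b.ravel()])
                               for w, b in zip(grads_w, grads_b)])

    def get_params(self) -> np.ndarray:
        return np.concatenate([np.concatenate([w.ravel(), b.ravel()])
                               for w, b in zip(self.weights, self.biases)])

    def set_params(self, theta: np.ndarray) -> None:
        pos = 0
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[l] = theta[pos:pos + w.size].reshape(w.shape).copy()
            pos += w.size
            self.biases[l] = theta[pos:pos + b.size].copy()
            pos += b.size
        if pos != theta.size:
            raise ValueError("parameter vector length mismatch")


@dataclass
class NNPModel:
    """One atomic network per element + descriptor config + input scaling
    + per-element atomic energy offsets (hartree)."""
    acsf: ACSFConfig
    networks: dict[str, AtomicNetwork]
    offsets: dict[str, float] = field(default_factory=dict)
    scale_shift: np.ndarray | None = None   # per-feature shift
    scale_factor: np.ndarray | None = None  # per-feature scale

    def __post_init__(self):
        for el in self.networks:
            if el not in self.acsf.elements:
                raise ValueError(f"network for element {el} not in ACSF config")

    @property
    def elements(self) -> list[str]:
        return sorted(self.networks)

    def _check_cover(self, structure: Structure):
        missing = set(structure.elements) - set(self.networks)
        if missing:
            raise ValueError(f"model does not cover elements: {sorted(missing)}")

    def fit_scaling(self, descriptor_rows: np.ndarray) -> None:
        """Freeze input scaling (zero mean, unit range) from training-set
        descriptor rows."""
        rows = np.asarray(descriptor_rows, float)
        self.scale_shift = rows.mean(axis=0)
        rng = rows.max(axis=0) - rows.min(axis=0)
        rng[rng < 1e-12] = 1.0
        self.scale_factor = rng

    def scaled(self, values: np.ndarray) -> np.ndarray:
        if self.scale_shift is None:
            raise ValueError("scaling statistics missing; fit scaling first")
        return (values - self.scale_shift) / self.scale_factor

    def total_energy(self, structure: Structure) -> float:
        """E = Σ_i E_i(descriptor_i) + Σ_i offset(element_i), hartree."""
        self._check_cover(structure)
        dm = build_descriptors(structure, self.acsf)
        x = self.scaled(dm.values)
        e = 0.0
        for el in set(structure.elements):
            rows = [i for i, s in enumerate(structure.elements) if s == el]
            e += float(self.networks[el].forward(x[rows]).sum())
            e += self.offsets.get(el, 0.0) * len(rows)
        return e

    def forces(self, structure: Structure) -> np.ndarray:
        """Analytic F = −∇E, hartree/Å, shape (n_atoms, 3)."""
        self._check_cover(structure)
        dm, J = build_descriptors(structure, self.acsf, jacobian=True)
        x = self.scaled(dm.values)
        grad = np.zeros((structure.n_atoms, 3))
        for el in set(structure.elements):
            rows = [i for i, s in enumerate(structure.elements) if s == el]
            dEdG = self.networks[el].input_gradient(x[rows]) / self.scale_factor
            for r, i in enumerate(rows):
                grad += np.einsum("f,fkc->kc", dEdG[r], J[i])
        return -grad

    def energy_fn(self, structure_template: Structure):
        """Callable energy(coords Å flat or (n,3)) for optimizers."""
        def e(coords):
            s = structure_template.with_coordinates(
                np.asarray(coords, float).reshape(-1, 3))
            return self.total_energy(s)
        return e

    # --- serialization (portable JSON text archive) ---
    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "acsf": self.acsf.to_dict(),
            "offsets": {k: float(v) for k, v in self.offsets.items()},
            "scale_shift": None if self.scale_shift is None
            else self.scale_shift.tolist(),
            "scale_factor": None if self.scale_factor is None
            else self.scale_factor.tolist(),
            "networks": {
                el: {"weights": [w.tolist() for w in net.weights],
                     "biases": [b.tolist() for b in net.biases]}
                for el, net in self.networks.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "NNPModel":
        version = d.get("format_version", 1)
        if version > MODEL_FORMAT_VERSION:
            raise ValueError(f"model format version {version} is newer than "
                             f"supported {MODEL_FORMAT_VERSION}")
        model = cls(
            acsf=ACSFConfig.from_dict(d["acsf"]),
            networks={el: AtomicNetwork(
                [np.array(w) for w in nd["weights"]],
                [np.array(b) for b in nd["biases"]])
                for el, nd in d["networks"].items()},
            offsets=dict(d["offsets"]))
        if d["scale_shift"] is not None:
            model.scale_shift = np.array(d["scale_shift"])
            model.scale_factor = np.array(d["scale_factor"])
        return model

    @classmethod
    def load(cls, path) -> "NNPModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def create(cls, acsf: ACSFConfig, hidden: tuple[int, ...] = (12, 12),
               seed: int = 0) -> "NNPModel":
        rng = np.random.default_rng(seed)
        nets = {el: AtomicNetwork.create(acsf.n_features, hidden, rng)
                for el in acsf.elements}
        return cls(acsf=acsf, networks=nets,
                   offsets={el: 0.0 for el in acsf.elements})

    # --- flat parameter vector across all element networks ---
    def get_params(self) -> np.ndarray:
        return np.concatenate([self.networks[el].get_params()
                               for el in self.elements])

    def set_params(self, theta: np.ndarray) -> None:
        pos = 0
        for el in self.elements:
            n = self.networks[el].n_params
            self.networks[el].set_params(theta[pos:pos + n])
            pos += n


def atomic_energy(network: AtomicNetwork, descriptor: np.ndarray) -> float:
    """Deterministic feed-forward evaluation of one (already scaled)
    descriptor vector."""
    return float(network.forward(np.atleast_2d(descriptor))[0])


@dataclass
class Committee:
    """Two or more independently trained models used for query-by-
    disagreement active learning."""
    members: list[NNPModel]

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a committee needs at least 2 members")
        cover = {tuple(m.elements) for m in self.members}
        if len(cover) != 1:
            raise ValueError("committee members must cover the same elements")

    def spread(self, structure: Structure) -> float:
        """(max − min) predicted energy per atom, in meV/atom."""
        e = [m.total_energy(structure) for m in self.members]
        spread_hartree = max(e) - min(e)
        return spread_hartree / structure.n_atoms * HARTREE_EV * 1000.0


def committee_spread(committee: Committee, structure: Structure) -> float:
    return committee.spread(structure)
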