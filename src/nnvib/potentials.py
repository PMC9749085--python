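"""Uniform callable-potential wrapper used by the optimizer, Hessian,
QFF and DVR machinery.

Energies are hartree as a function of a :class:`~nnvib.structures.Structure`
(coordinates in Å); gradients, when available, are hartree/Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .structures import Structure


@dataclass
class PotentialInterface:
    energy: Callable[[Structure], float]
    gradient: Callable[[Structure], np.ndarray] | None = None
    label: str = ""

    @classmethod
    def from_model(cls, model, label: str = "nnp") -> "PotentialInterface":
        """Wrap an NNPModel (analytic forces -> gradient)."""
        return cls(energy=model.total_energy,
                   gradient=lambda s: -model.forces(s),
                   label=label)

    def gradient_fd(self, structure: Structure, step: float = 1e-4) -> np.ndarray:
        """Central-difference gradient fallback (hartree/Å); step in Å."""
        x0 = structure.coordinates
        g = np.zeros_like(x0)
        for a in range(x0.shape[0]):
            for c in range(3):
                for sgn in (1.0, -1.0):
                    x = x0.copy()
                    x[a, c] += sgn * step
                    g[a, c] += sgn * self.energy(structure.with_coordinates(x))
        return g / (2.0 * step)

    def grad(self, structure: Structure) -> np.ndarray:
        if self.gradient is not None:
            return self.gradient(structure)
        return self.gradient_fd(structure)
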