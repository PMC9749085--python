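"""Molecular structures, datasets and extended-XYZ file I/O.

A :class:`Structure` is a gas-phase cluster: chemical symbols, Cartesian
coordinates in Å, and optionally a total electronic energy (hartree) and
per-atom forces (hartree/Å).  A :class:`Dataset` is an ordered list of
structures with a reference (zero) energy, conventionally the energy of
the global-minimum structure, so that fit-error windows such as
"below 0.1 E_h above the minimum" are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .units import ATOMIC_MASS_AMU, mass_au


class ExtXYZParseError(ValueError):
    """Malformed extended-XYZ input; message carries frame and line numbers."""


@dataclass
class Structure:
    elements: list[str]
    coordinates: np.ndarray  # (n_atoms, 3), Å
    energy: float | None = None
    forces: np.ndarray | None = None  # (n_atoms, 3), hartree/Å
    tag: str = ""

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.elements), 3):
            raise ValueError(
                f"coordinate shape {self.coordinates.shape} does not match "
                f"{len(self.elements)} elements")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        for el in self.elements:
            if el not in ATOMIC_MASS_AMU:
                raise ValueError(f"unknown element symbol: {el!r}")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.coordinates.shape:
                raise ValueError("forces must be one 3-vector per atom")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def masses_au(self) -> np.ndarray:
        return np.array([mass_au(el) for el in self.elements])

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        return replace(self, coordinates=np.asarray(coords, float),
                       energy=None, forces=None)


@dataclass
class Dataset:
    structures: list[Structure] = field(default_factory=list)
    reference_energy: float | None = None

    def __len__(self) -> int:
        return len(self.structures)

    def __iter__(self):
        return iter(self.structures)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Dataset(self.structures[i], self.reference_energy)
        return self.structures[i]

    def energies(self) -> np.ndarray:
        return np.array([np.nan if s.energy is None else s.energy
                         for s in self.structures])

    def set_reference_to_minimum(self) -> "Dataset":
        e = self.energies()
        if np.all(np.isnan(e)):
            raise ValueError("dataset has no energies")
        self.reference_energy = float(np.nanmin(e))
        return self


def read_extxyz(path) -> Dataset:
    """Read all frames of an extended-XYZ file.

    Frame layout: atom-count line; comment line of ``key=value`` pairs
    (``energy=`` in hartree is recognised); then one ``El x y z [fx fy fz]``
    row per atom (Å, hartree/Å).  Parse failures raise
    :class:`ExtXYZParseError` naming the frame and line.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    structures = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError:
            raise ExtXYZParseError(
                f"frame {frame}: line {i + 1}: expected atom count, "
                f"got {lines[i]!r}") from None
        if i + 2 + nat > len(lines):
            raise ExtXYZParseError(
                f"frame {frame}: line {i + 1}: {nat} atoms declared but "
                f"file ends early")
        comment = lines[i + 1]
        kv = {}
        for tok in comment.split():
            if "=" in tok:
                k, _, v = tok.partition("=")
                kv[k.strip().lower()] = v.strip().strip('"')
        energy = float(kv["energy"]) if "energy" in kv else None
        elements, coords, forces = [], [], []
        has_forces = None
        for a in range(nat):
            ln = i + 2 + a
            parts = lines[ln].split()
            if len(parts) not in (4, 7):
                raise ExtXYZParseError(
                    f"frame {frame}: line {ln + 1}: expected "
                    f"'El x y z [fx fy fz]', got {lines[ln]!r}")
            if has_forces is None:
                has_forces = len(parts) == 7
            elif has_forces != (len(parts) == 7):
                raise ExtXYZParseError(
                    f"frame {frame}: line {ln + 1}: inconsistent force columns")
            elements.append(parts[0])
            try:
                vals = [float(x) for x in parts[1:]]
            except ValueError:
                raise ExtXYZParseError(
                    f"frame {frame}: line {ln + 1}: non-numeric field") from None
            coords.append(vals[:3])
            if has_forces:
                forces.append(vals[3:])
        try:
            structures.append(Structure(
                elements, np.array(coords), energy=energy,
                forces=np.array(forces) if forces else None,
                tag=kv.get("tag", "")))
        except ValueError as exc:
            raise ExtXYZParseError(f"frame {frame}: {exc}") from None
        i += 2 + nat
        frame += 1
    return Dataset(structures)


def write_extxyz(dataset: Dataset, path) -> None:
    """Write a dataset as extended XYZ with a fixed 12-significant-digit
    float format (deterministic byte output for fixed input)."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    with open(path, "w") as fh:
        for s in dataset:
            fh.write(f"{s.n_atoms}\n")
            comment = []
            if s.energy is not None:
                comment.append(f"energy={s.energy:.12e}")
            if s.tag:
                comment.append(f"tag={s.tag}")
            fh.write(" ".join(comment) + "\n")
            for a in range(s.n_atoms):
                row = f"{s.elements[a]:<2s} " + " ".join(
                    f"{x:20.12e}" for x in s.coordinates[a])
                if s.forces is not None:
                    row += " " + " ".join(f"{x:20.12e}" for x in s.forces[a])
                fh.write(row + "\n")


def split_dataset(dataset: Dataset, train_fraction: float = 0.9,
                  seed: int = 0) -> tuple[Dataset, Dataset]:
    """Random disjoint train/test partition (default 90/10).

    Reproducible for a fixed seed; sizes are the rounded split of the
    total.  Both halves inherit the parent's reference energy.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 structures to split")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    idx_train = np.sort(perm[:n_train])
    idx_test = np.sort(perm[n_train:])
    ref = dataset.reference_energy
    return (Dataset([dataset.structures[i] for i in idx_train], ref),
            Dataset([dataset.structures[i] for i in idx_test], ref))
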