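"""Weight optimization, fit-error reporting in the dual meV/atom–cm⁻¹
convention, committee-disagreement candidate selection, and MD sampling.

Training minimizes the energy residual over a 90/10 train/test split.
The default optimizer is a global adaptive extended Kalman filter
(per-structure recursive Gauss–Newton updates of all network weights),
which converges in a handful of passes for the small fits used here;
plain Adam and SGD are available as alternatives.  The test split is
never used for weight updates, only for early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Committee, NNPModel
from .potentials import PotentialInterface
from .structures import Dataset, Structure, split_dataset
from .units import BOHR_ANGSTROM, HARTREE_EV, MEV_CM
from .descriptors import build_descriptors

KB_HARTREE = 3.166811563e-6     # hartree/K
FS_AU = 41.341374575751         # atomic time units per femtosecond

#: default committee-disagreement thresholds (meV/atom) per selection channel
CHANNEL_THRESHOLDS = {"md": 1.0, "grid": 20.0, "2dcut": 2.0}


@dataclass
class TrainingConfig:
    train_fraction: float = 0.9
    optimizer: str = "kalman"        # kalman | adam | sgd
    epochs: int = 30
    seed: int = 0
    batch_size: int = 16             # gradient optimizers only
    learning_rate: float = 1e-3
    force_weight: float = 0.0        # energy-only training by default
    patience: int = 50               # early stopping on test RMSE
    kalman_p0: float = 100.0         # initial parameter covariance
    kalman_noise: float = 1e-6       # measurement noise floor (hartree^2)
    kalman_forgetting: float = 0.9995

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer not in ("kalman", "adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class EnergyRMSEReport:
    window: str                  # "full range" | "below threshold"
    threshold: float             # hartree above dataset minimum
    n_structures: int
    train_rmse_mev_atom: float
    test_rmse_mev_atom: float
    train_rmse_cm: float
    test_rmse_cm: float


@dataclass
class SelectionRecord:
    index: int
    spread_mev_atom: float
    threshold_mev_atom: float
    channel: str
    selected: bool


class _DescriptorCache:
    """Precomputed, scaled descriptors and element row-groups per structure."""

    def __init__(self, model: NNPModel, dataset: Dataset):
        self.rows = []
        self.groups = []
        self.n_atoms = []
        for s in dataset:
            dm = build_descriptors(s, model.acsf)
            self.rows.append(dm.values)
            self.groups.append({
                el: [i for i, e in enumerate(s.elements) if e == el]
                for el in set(s.elements)})
            self.n_atoms.append(s.n_atoms)

    def predict(self, model: NNPModel, i: int) -> float:
        x = model.scaled(self.rows[i])
        e = 0.0
        for el, rows in self.groups[i].items():
            e += float(model.networks[el].forward(x[rows]).sum())
            e += model.offsets.get(el, 0.0) * len(rows)
        return e

    def predict_all(self, model: NNPModel) -> np.ndarray:
        return np.array([self.predict(model, i) for i in range(len(self.rows))])

    def param_gradient(self, model: NNPModel, i: int) -> np.ndarray:
        """dE_pred/d(all weights), flattened in model.elements order."""
        x = model.scaled(self.rows[i])
        parts = []
        for el in model.elements:
            if el in self.groups[i]:
                parts.append(model.networks[el].param_gradient(
                    x[self.groups[i][el]]))
            else:
                parts.append(np.zeros(model.networks[el].n_params))
        return np.concatenate(parts)


def _fit_offsets(model: NNPModel, dataset: Dataset) -> None:
    """Least-squares per-element atomic energy offsets (reference shift)."""
    els = model.elements
    A = np.array([[s.elements.count(el) for el in els] for s in dataset],
                 dtype=float)
    b = dataset.energies()
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    model.offsets = {el: float(c) for el, c in zip(els, coef)}


def _rmse_mev_atom(pred, ref, n_atoms) -> float:
    d = (np.asarray(pred) - np.asarray(ref)) / np.asarray(n_atoms)
    return float(np.sqrt(np.mean(d ** 2)) * HARTREE_EV * 1000.0)


def fit(model: NNPModel, dataset: Dataset,
        config: TrainingConfig | None = None
        ) -> tuple[NNPModel, pd.DataFrame]:
    """Train the model's weights on the dataset energies.

    Returns the trained model (best weights under the early-stopping
    policy) and a per-epoch history with train/test RMSE in meV/atom.
    Reproducible for a fixed config seed.
    """
    config = config or TrainingConfig()
    energies = dataset.energies()
    if np.any(np.isnan(energies)):
        raise ValueError("training requires energies for all structures")
    train, test = split_dataset(dataset, config.train_fraction, config.seed)

    _fit_offsets(model, train)
    cache_tr = _DescriptorCache(model, train)
    cache_te = _DescriptorCache(model, test)
    model.fit_scaling(np.vstack(cache_tr.rows))

    e_tr = train.energies()
    e_te = test.energies()
    n_tr = np.array(cache_tr.n_atoms, float)
    n_te = np.array(cache_te.n_atoms, float)
    rng = np.random.default_rng(config.seed + 1)

    theta = model.get_params()
    best = (np.inf, theta.copy())
    history = []
    since_best = 0

    if config.optimizer == "kalman":
        P = np.eye(theta.size) * config.kalman_p0
        lam = config.kalman_forgetting

    adam_m = np.zeros_like(theta)
    adam_v = np.zeros_like(theta)
    adam_t = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        if config.optimizer == "kalman":
            for i in order:
                model.set_params(theta)
                pred = cache_tr.predict(model, i)
                h = cache_tr.param_gradient(model, i)
                innov = e_tr[i] - pred
                Ph = P @ h
                denom = float(h @ Ph) + config.kalman_noise
                k = Ph / denom
                theta = theta + k * innov
                P = (P - np.outer(k, Ph)) / lam
                P = 0.5 * (P + P.T)
        else:
            for start_i in range(0, len(order), config.batch_size):
                batch = order[start_i:start_i + config.batch_size]
                model.set_params(theta)
                grad = np.zeros_like(theta)
                for i in batch:
                    pred = cache_tr.predict(model, i)
                    h = cache_tr.param_gradient(model, i)
                    grad += 2.0 * (pred - e_tr[i]) * h
                grad /= len(batch)
                if config.optimizer == "adam":
                    adam_t += 1
                    adam_m = 0.9 * adam_m + 0.1 * grad
                    adam_v = 0.999 * adam_v + 0.001 * grad ** 2
                    mhat = adam_m / (1.0 - 0.9 ** adam_t)
                    vhat = adam_v / (1.0 - 0.999 ** adam_t)
                    theta -= config.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
                else:
                    theta -= config.learning_rate * grad

        model.set_params(theta)
        rmse_tr = _rmse_mev_atom(cache_tr.predict_all(model), e_tr, n_tr)
        rmse_te = _rmse_mev_atom(cache_te.predict_all(model), e_te, n_te)
        if not (np.isfinite(rmse_tr) and np.isfinite(rmse_te)):
            raise RuntimeError(f"training diverged at epoch {epoch}")
        history.append({"epoch": epoch, "train_rmse_mev_atom": rmse_tr,
                        "test_rmse_mev_atom": rmse_te})
        if rmse_te < best[0]:
            best = (rmse_te, theta.copy())
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    model.set_params(best[1])
    return model, pd.DataFrame(history)


def rmse_report(model: NNPModel, train: Dataset, test: Dataset,
                window_threshold: float = 0.1) -> list[EnergyRMSEReport]:
    """Train/test energy RMSE for the full range and for structures within
    ``window_threshold`` hartree of the combined dataset minimum, each in
    meV/atom and as the per-system wavenumber equivalent."""
    e_tr, e_te = train.energies(), test.energies()
    if np.any(np.isnan(e_tr)) or np.any(np.isnan(e_te)):
        raise ValueError("reference energies required")
    e_min = min(e_tr.min(), e_te.min())
    p_tr = np.array([model.total_energy(s) for s in train])
    p_te = np.array([model.total_energy(s) for s in test])
    n_tr = np.array([s.n_atoms for s in train], float)
    n_te = np.array([s.n_atoms for s in test], float)
    mean_atoms = float(np.mean(np.concatenate([n_tr, n_te])))
    reports = []
    for window, m_tr, m_te in (
            ("full range", np.ones_like(e_tr, bool), np.ones_like(e_te, bool)),
            ("below threshold", e_tr - e_min <= window_threshold,
             e_te - e_min <= window_threshold)):
        n_in = int(m_tr.sum() + m_te.sum())
        if m_tr.sum() == 0 or m_te.sum() == 0:
            reports.append(EnergyRMSEReport(window, window_threshold, n_in,
                                            np.nan, np.nan, np.nan, np.nan))
            continue
        r_tr = _rmse_mev_atom(p_tr[m_tr], e_tr[m_tr], n_tr[m_tr])
        r_te = _rmse_mev_atom(p_te[m_te], e_te[m_te], n_te[m_te])
        reports.append(EnergyRMSEReport(
            window, window_threshold, n_in, r_tr, r_te,
            r_tr * mean_atoms * MEV_CM, r_te * mean_atoms * MEV_CM))
    return reports


def select_candidates(committee: Committee, pool: Dataset,
                      threshold: float | None = None,
                      channel: str = "md") -> list[SelectionRecord]:
    """Flag pool structures whose committee energy spread exceeds the
    channel threshold (md: 1, grid: 20, 2dcut: 2 meV/atom by default)."""
    if threshold is None:
        try:
            threshold = CHANNEL_THRESHOLDS[channel]
        except KeyError:
            raise ValueError(f"unknown selection channel {channel!r}") from None
    records = []
    for i, s in enumerate(pool):
        spread = committee.spread(s)
        records.append(SelectionRecord(
            index=i, spread_mev_atom=spread, threshold_mev_atom=threshold,
            channel=channel, selected=spread > threshold))
    return records


def md_sample(potential: PotentialInterface | NNPModel, start: Structure,
              temperature: float = 300.0, n_steps: int = 5000,
              timestep_fs: float = 0.5, seed: int = 0, stride: int = 10,
              friction_fs: float = 0.02, log: dict | None = None) -> Dataset:
    """Langevin dynamics sampling: velocity-Verlet integration with a
    stochastic (BAOAB-split) thermostat; snapshots every ``stride`` steps,
    labelled with the potential's energy.  Reproducible per seed."""
    if isinstance(potential, NNPModel):
        potential = PotentialInterface.from_model(potential)
    if timestep_fs <= 0:
        raise ValueError("timestep must be positive")
    rng = np.random.default_rng(seed)
    masses = start.masses_au()[:, None]            # m_e
    dt = timestep_fs * FS_AU
    gamma = friction_fs / FS_AU
    kT = KB_HARTREE * max(temperature, 0.0)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 ** 2))

    x = start.coordinates / BOHR_ANGSTROM          # bohr
    if temperature > 0.0:
        v = rng.normal(0.0, 1.0, x.shape) * np.sqrt(kT / masses)
    else:
        v = np.zeros_like(x)

    def force_bohr(xb):
        g = potential.grad(start.with_coordinates(xb * BOHR_ANGSTROM))
        if not np.all(np.isfinite(g)):
            raise RuntimeError("non-finite forces")
        return -g * BOHR_ANGSTROM                  # hartree/bohr

    f = force_bohr(x)
    snapshots = []
    temps = []
    for step in range(n_steps):
        try:
            v += 0.5 * dt * f / masses
            x += 0.5 * dt * v
            v = c1 * v + c2 * rng.normal(0.0, 1.0, v.shape) / np.sqrt(masses)
            x += 0.5 * dt * v
            f = force_bohr(x)
            v += 0.5 * dt * f / masses
        except RuntimeError as exc:
            raise RuntimeError(f"MD aborted at step {step}: {exc}") from None
        temps.append(kinetic_temperature(masses_au=masses[:, 0], velocities=v))
        if (step + 1) % stride == 0:
            s = start.with_coordinates(x * BOHR_ANGSTROM)
            s.energy = potential.energy(s)
            s.tag = f"md T={temperature:g}K step={step + 1}"
            snapshots.append(s)
    if log is not None:
        burn = len(temps) // 5
        log["mean_temperature"] = float(np.mean(temps[burn:]))
    return Dataset(snapshots)


def kinetic_temperature(masses_au: np.ndarray, velocities: np.ndarray) -> float:
    """Instantaneous kinetic temperature (K) from 3N degrees of freedom."""
    ke = 0.5 * float(np.sum(masses_au[:, None] * velocities ** 2))
    return 2.0 * ke / (3.0 * masses_au.size * KB_HARTREE)
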