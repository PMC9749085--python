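"""Comparison statistics for frequency sets and equilibrium geometries,
plus rendering of the standard benchmark tables.

The headline numbers of a potential-validation study are frequency-set
RMSEs and maximum deviations against a reference (with resonance-
affected or hydrogen-stretch modes optionally excluded) and separate
bond-length/angle RMSEs for the equilibrium structure.  Small literature
benchmark tables for the formic acid dimer ship with the package as TSV
fixtures (see :func:`load_benchmark`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd


@dataclass
class ComparisonReport:
    labels: list[str]
    deviations: np.ndarray
    rmse: float
    max_abs_deviation: float
    max_label: str
    exclusions: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.deviations.size


@dataclass
class GeometryComparison:
    parameters: list[str]
    kinds: list[str]
    deviations: np.ndarray
    rmse_lengths: float
    rmse_angles: float


def compare_frequency_sets(values, reference, labels=None,
                           exclusions: dict[str, str] | None = None
                           ) -> ComparisonReport:
    """Per-item deviations value − reference, their RMSE, and the maximum
    absolute deviation.  ``exclusions`` maps labels to reason strings;
    excluded items are dropped before the statistics."""
    values = np.asarray(values, float)
    reference = np.asarray(reference, float)
    if values.size != reference.size:
        raise ValueError("value/reference length mismatch")
    labels = list(labels) if labels is not None else \
        [str(i + 1) for i in range(values.size)]
    exclusions = exclusions or {}
    unknown = set(exclusions) - set(labels)
    if unknown:
        raise ValueError(f"unknown exclusion labels: {sorted(unknown)}")
    keep = [i for i, lab in enumerate(labels) if lab not in exclusions]
    dev = values[keep] - reference[keep]
    if dev.size == 0:
        raise ValueError("no items left after exclusions")
    imax = int(np.argmax(np.abs(dev)))
    return ComparisonReport(
        labels=[labels[i] for i in keep], deviations=dev,
        rmse=float(np.sqrt(np.mean(dev ** 2))),
        max_abs_deviation=float(np.max(np.abs(dev))),
        max_label=[labels[i] for i in keep][imax],
        exclusions=dict(exclusions))


def compare_geometries(params_a, params_b, kinds,
                       parameters=None) -> GeometryComparison:
    """Separate RMSEs over bond lengths (Å) and angles (degrees)."""
    a = np.asarray(params_a, float)
    b = np.asarray(params_b, float)
    kinds = list(kinds)
    if not (a.size == b.size == len(kinds)):
        raise ValueError("parameter/kind list length mismatch")
    bad = set(kinds) - {"length", "angle"}
    if bad:
        raise ValueError(f"unknown parameter kinds: {sorted(bad)}")
    dev = a - b
    is_len = np.array([k == "length" for k in kinds])

    def rmse(mask):
        return float(np.sqrt(np.mean(dev[mask] ** 2))) if mask.any() else np.nan

    return GeometryComparison(
        parameters=list(parameters) if parameters is not None
        else [str(i) for i in range(a.size)],
        kinds=kinds, deviations=dev,
        rmse_lengths=rmse(is_len), rmse_angles=rmse(~is_len))


def render_table(report, style: str = "frequencies") -> str:
    """TSV rendering with the conventional precision: integers for cm⁻¹
    frequency deviations, 4 decimals for Å.  Excluded items gain footnote
    markers listing the exclusion reason."""
    lines = []
    if isinstance(report, ComparisonReport):
        lines.append("label\tdeviation")
        fmt = (lambda v: f"{v:.0f}") if style != "geometry" else \
            (lambda v: f"{v:.4f}")
        for lab, d in zip(report.labels, report.deviations):
            lines.append(f"{lab}\t{fmt(d)}")
        lines.append(f"RMSE\t{fmt(report.rmse)}")
        lines.append(f"max\t{fmt(report.max_abs_deviation)}")
        for i, (lab, why) in enumerate(sorted(report.exclusions.items())):
            lines.append(f"# [{chr(97 + i)}] {lab} excluded: {why}")
    elif isinstance(report, GeometryComparison):
        lines.append("parameter\tkind\tdeviation")
        for p, k, d in zip(report.parameters, report.kinds, report.deviations):
            prec = 4 if k == "length" else 2
            lines.append(f"{p}\t{k}\t{d:.{prec}f}")
        lines.append(f"RMSE(lengths)\t\t{report.rmse_lengths:.4f}")
        lines.append(f"RMSE(angles)\t\t{report.rmse_angles:.2f}")
    else:
        raise TypeError(f"cannot render {type(report).__name__}")
    return "\n".join(lines) + "\n"


def parse_rendered_table(text: str) -> dict[str, float]:
    """Inverse of :func:`render_table` for the numeric rows."""
    out = {}
    for line in text.splitlines()[1:]:
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        out[parts[0]] = float(parts[-1])
    return out


_BENCHMARKS = {
    "harmonic": "harmonic_frequencies.tsv",
    "geometry": "equilibrium_geometry.tsv",
    "vpt2": "vpt2_fundamentals.tsv",
}


def load_benchmark(name: str) -> pd.DataFrame:
    """Load one of the shipped formic-acid-dimer benchmark tables
    ("harmonic", "geometry", "vpt2")."""
    try:
        fname = _BENCHMARKS[name]
    except KeyError:
        raise ValueError(f"unknown benchmark {name!r}; "
                         f"choose from {sorted(_BENCHMARKS)}") from None
    ref = resources.files("nnvib").joinpath("data", fname)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
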