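"""Efficiency-based X0 quantification of qPCR Cq values.

The X0 method back-calculates the starting template amount from the
exponential amplification model: after ``Cq`` cycles at per-cycle
amplification efficiency ``E`` (in (1, 2], 2 = perfect doubling) a fixed
detection threshold is reached, so the initial amount is, in arbitrary
units,

    X0 = E ** (-Cq)

Relative expression of a target gene in a sample versus a control sample,
normalized to a reference (housekeeping) gene, is then

    value = (X0_target / X0_reference)_sample / (X0_target / X0_reference)_control

Technical replicates are aggregated on the linear X0 scale (mean of
per-replicate X0, not mean Cq), and the replicate scatter is propagated to
the ratio by first-order (relative-variance) error propagation.  When all
efficiencies equal 2 this reduces exactly to the classic 2^(-ddCq) value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Cq values for one (sample, gene) assay."""

    sample: str
    gene: str
    cq: tuple
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cq", tuple(float(c) for c in self.cq))
        if len(self.cq) < 1:
            raise ValueError("at least one Cq replicate required")
        if any(c <= 0 for c in self.cq):
            raise ValueError("Cq values must be positive")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError(
                f"amplification efficiency must lie in (1, 2], got {self.efficiency}"
            )

    def x0_values(self) -> np.ndarray:
        return np.array([x0(c, self.efficiency) for c in self.cq])


def x0(cq: float, efficiency: float = 2.0) -> float:
    """Initial template amount (arbitrary units) from one Cq value."""
    if not (1.0 < efficiency <= 2.0):
        raise ValueError(f"amplification efficiency must lie in (1, 2], got {efficiency}")
    if cq <= 0:
        raise ValueError("Cq must be positive")
    return float(efficiency) ** (-float(cq))


@dataclass(frozen=True)
class RelativeExpression:
    gene: str
    sample: str
    control: str
    value: float
    sd: float


def _mean_cv(m: QpcrMeasurement) -> tuple[float, float]:
    """Mean X0 and its relative scatter (replicate SD / mean)."""
    values = m.x0_values()
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return mean, sd / mean


def relative_expression(
    target: QpcrMeasurement,
    reference: QpcrMeasurement,
    target_ctrl: QpcrMeasurement,
    reference_ctrl: QpcrMeasurement,
) -> RelativeExpression:
    """Reference-normalized fold change of a target gene vs a control sample."""
    if target.gene != target_ctrl.gene:
        raise ValueError(
            f"target genes differ between sample and control: "
            f"{target.gene!r} vs {target_ctrl.gene!r}"
        )
    if reference.gene != reference_ctrl.gene:
        raise ValueError(
            f"reference genes differ between sample and control: "
            f"{reference.gene!r} vs {reference_ctrl.gene!r}"
        )
    if target.efficiency != target_ctrl.efficiency:
        raise ValueError("target assay efficiency must match between sample and control")
    if reference.efficiency != reference_ctrl.efficiency:
        raise ValueError("reference assay efficiency must match between sample and control")
    mt, cvt = _mean_cv(target)
    mr, cvr = _mean_cv(reference)
    mtc, cvtc = _mean_cv(target_ctrl)
    mrc, cvrc = _mean_cv(reference_ctrl)
    value = (mt / mr) / (mtc / mrc)
    sd = value * math.sqrt(cvt**2 + cvr**2 + cvtc**2 + cvrc**2)
    return RelativeExpression(
        gene=target.gene,
        sample=target.sample,
        control=target_ctrl.sample,
        value=value,
        sd=sd,
    )


# -- tabular input ---------------------------------------------------------


def read_qpcr_table(path) -> dict[tuple, QpcrMeasurement]:
    """Read a wells TSV (columns: sample, gene, cq, efficiency).

    Rows sharing (sample, gene) are collected into one measurement; their
    efficiencies must agree.  Returns a map keyed by (sample, gene).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "cq", "efficiency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out: dict[tuple, QpcrMeasurement] = {}
    for (sample, gene), grp in df.groupby(["sample", "gene"], sort=False):
        eff = grp["efficiency"].unique()
        if len(eff) != 1:
            raise ValueError(
                f"inconsistent efficiency for sample {sample!r}, gene {gene!r}"
            )
        out[(str(sample), str(gene))] = QpcrMeasurement(
            sample=str(sample),
            gene=str(gene),
            cq=tuple(grp["cq"].astype(float)),
            efficiency=float(eff[0]),
        )
    return out


def quantify_all(
    measurements: dict[tuple, QpcrMeasurement],
    reference_gene: str,
    control_sample: str,
) -> list[RelativeExpression]:
    """Relative expression of every (sample, target) pair vs the control sample."""
    results = []
    for (sample, gene), m in measurements.items():
        if gene == reference_gene or sample == control_sample:
            continue
        try:
            ref = measurements[(sample, reference_gene)]
            tc = measurements[(control_sample, gene)]
            rc = measurements[(control_sample, reference_gene)]
        except KeyError as exc:
            raise KeyError(
                f"missing measurement needed to quantify {gene!r} in {sample!r}: {exc}"
            ) from None
        results.append(relative_expression(m, ref, tc, rc))
    return results
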