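"""Background-subtracted ratio DEG calling for single-replicate contrasts.

With one array per condition there is no within-condition variance, so
differential expression is decided by a fold-change rule on
background-subtracted intensities combined with the detection p-value:

    ratio = (treated - background) / (control - background)

A probe is called *up* when ratio > 2 and the treated-array detection
p-value is < 0.05 (the gene must be reliably detected where it is claimed
high), and *down* when ratio < 0.5 and the control-array detection p-value
is < 0.05.  All inequalities are strict.  Probes whose background-subtracted
signal is non-positive on either side are flagged invalid: a signal at or
below background carries no fold-change information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ContrastSpec, ProbeProfileTable
from .preprocess import (
    BackgroundEstimate,
    NormalizedMatrix,
    estimate_background,
    filter_expressed,
    quantile_normalize,
)

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass(frozen=True)
class DegThresholds:
    up_threshold: float = 2.0
    down_threshold: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.down_threshold < self.up_threshold:
            raise ValueError("down_threshold must be below up_threshold")


def compute_ratio(treated_signal: float, control_signal: float, background: float) -> float:
    """Background-subtracted expression ratio; NaN when undefined.

    Returns ``(treated - background) / (control - background)`` when both
    background-subtracted signals are strictly positive, otherwise NaN
    (the record is invalid data, not an error).
    """
    num = treated_signal - background
    den = control_signal - background
    if num > 0 and den > 0:
        return num / den
    return math.nan


def classify(
    ratio: float,
    treated_detection_p: float,
    control_detection_p: float,
    thresholds: DegThresholds = DegThresholds(),
) -> str:
    """Apply the up/down fold-change + detection rule to one probe."""
    if math.isnan(ratio):
        return NONE
    if ratio > thresholds.up_threshold and treated_detection_p < thresholds.alpha:
        return UP
    if ratio < thresholds.down_threshold and control_detection_p < thresholds.alpha:
        return DOWN
    return NONE


@dataclass
class DegTable:
    """Per-probe ratio statistics and classification for one contrast.

    ``records`` has one row per retained probe with columns
    treated_signal, control_signal, treated_p, control_p, ratio, valid,
    direction.  Thresholds and the background constant are recorded for
    provenance.
    """

    contrast: ContrastSpec
    records: pd.DataFrame
    thresholds: DegThresholds
    background: float

    @property
    def n_up(self) -> int:
        return int((self.records["direction"] == UP).sum())

    @property
    def n_down(self) -> int:
        return int((self.records["direction"] == DOWN).sum())

    @property
    def n_deg(self) -> int:
        return self.n_up + self.n_down

    def deg_ids(self, direction: str | None = None) -> set[str]:
        """Probe ids called differentially expressed (optionally one direction)."""
        d = self.records["direction"]
        if direction is None:
            mask = d != NONE
        else:
            mask = d == direction
        return set(self.records.index[mask])

    def write(self, path) -> None:
        cols = [
            "treated_signal",
            "control_signal",
            "ratio",
            "direction",
            "treated_p",
            "control_p",
        ]
        out = self.records[cols]
        out.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")


def call_degs(
    matrix: NormalizedMatrix,
    table: ProbeProfileTable,
    contrast: ContrastSpec,
    background: BackgroundEstimate | float,
    thresholds: DegThresholds = DegThresholds(),
    use_raw: bool = False,
) -> DegTable:
    """Classify every retained probe for one treated-vs-control contrast.

    ``matrix`` is the (normalized, filtered) expression matrix whose rows
    define the retained-probe universe; detection p-values are looked up in
    the original ``table``.  ``use_raw`` switches the ratio computation to
    the table's raw signals (literal reading of the ratio formula) while
    keeping the same probe universe.
    """
    bg = background.value if isinstance(background, BackgroundEstimate) else float(background)
    for sample in (contrast.treated_sample, contrast.control_sample):
        if sample not in matrix.data.columns or sample not in table.samples:
            raise KeyError(f"unknown sample id {sample!r} in contrast {contrast.name!r}")
    source = table.signal if use_raw else matrix.data
    probes = matrix.data.index
    treated = source.loc[probes, contrast.treated_sample].to_numpy(dtype=float)
    control = source.loc[probes, contrast.control_sample].to_numpy(dtype=float)
    tp = table.detection_p.loc[probes, contrast.treated_sample].to_numpy(dtype=float)
    cp = table.detection_p.loc[probes, contrast.control_sample].to_numpy(dtype=float)

    num = treated - bg
    den = control - bg
    valid = (num > 0) & (den > 0)
    ratio = np.full(len(probes), np.nan)
    np.divide(num, den, out=ratio, where=valid)

    up = valid & (ratio > thresholds.up_threshold) & (tp < thresholds.alpha)
    down = valid & (ratio < thresholds.down_threshold) & (cp < thresholds.alpha)
    direction = np.where(up, UP, np.where(down, DOWN, NONE))

    records = pd.DataFrame(
        {
            "treated_signal": treated,
            "control_signal": control,
            "treated_p": tp,
            "control_p": cp,
            "ratio": ratio,
            "valid": valid,
            "direction": direction,
        },
        index=probes,
    )
    return DegTable(contrast=contrast, records=records, thresholds=thresholds, background=bg)


# -- whole-experiment convenience ------------------------------------------


def default_contrasts() -> list[ContrastSpec]:
    """The four knockdown-vs-matched-control contrasts of the 6-array design.

    Single knockdowns pair with the low-concentration control (control "+"),
    the triple knockdown with the high-concentration control ("+++") so that
    each comparison is at equal total siRNA concentration.
    """
    return [
        ContrastSpec("siFUS_vs_control", "siFUS", "controlPlus"),
        ContrastSpec("siEWS_vs_control", "siEWS", "controlPlus"),
        ContrastSpec("siTAF15_vs_control", "siTAF15", "controlPlus"),
        ContrastSpec("siTriple_vs_control", "siTriple", "controlTriplePlus"),
    ]


@dataclass
class PipelineResult:
    matrix: NormalizedMatrix
    removed_count: int
    background: BackgroundEstimate
    deg_tables: dict[str, DegTable] = field(default_factory=dict)


def run_deg_pipeline(
    table: ProbeProfileTable,
    contrasts: list[ContrastSpec] | None = None,
    alpha: float = 0.05,
    thresholds: DegThresholds = DegThresholds(),
    use_raw: bool = False,
) -> PipelineResult:
    """normalize -> filter -> background -> call DEGs for every contrast."""
    if contrasts is None:
        contrasts = default_contrasts()
    # normalization acts on the regular-probe universe; negative controls
    # only inform the background constant
    normalized = quantile_normalize(table.regular_signal())
    matrix, removed = filter_expressed(table, alpha=alpha, matrix=normalized)
    background = estimate_background(table)
    result = PipelineResult(matrix=matrix, removed_count=removed, background=background)
    for contrast in contrasts:
        result.deg_tables[contrast.name] = call_degs(
            matrix, table, contrast, background, thresholds=thresholds, use_raw=use_raw
        )
    return result
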