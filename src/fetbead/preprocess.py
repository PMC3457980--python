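"""Normalization, detection filtering, and background estimation.

The preprocessing chain for a single-replicate BeadChip experiment is

1. quantile-normalize the raw signal matrix across arrays,
2. drop probes whose detection p-value is >= alpha on every array
   ("not expressed in any array"),
3. estimate the background constant as the mean of the negative-control
   probe intensities pooled over all arrays (from the *raw* signals, since
   the negative controls define absolute background, not rank structure).

Detection p-values on real arrays come from the vendor software and are
taken as-is; :func:`compute_detection_p` provides the equivalent rank-based
empirical p for synthetic data, comparing each probe against the
negative-control intensity distribution of its own array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ProbeProfileTable


@dataclass
class NormalizedMatrix:
    """Probe x sample intensity matrix with provenance flags."""

    data: pd.DataFrame
    normalized: bool = False
    filtered: bool = False

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_probes(self) -> int:
        return len(self.data.index)


@dataclass(frozen=True)
class BackgroundEstimate:
    """Background intensity derived from negative-control probes.

    ``value`` keeps full floating-point precision; ``reported`` is the
    nearest-integer summary used when quoting the constant.
    """

    value: float
    n_control_probes_used: int
    method: str = "mean of negative-control intensities pooled over all arrays"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("background must be non-negative")
        if self.n_control_probes_used < 1:
            raise ValueError("at least one control probe required")

    @property
    def reported(self) -> int:
        return int(round(self.value))


def quantile_normalize(matrix) -> NormalizedMatrix:
    """Force every array onto the common average intensity distribution.

    After normalization each column's sorted value vector equals the
    across-column mean of sorted vectors, and within-column rank order is
    preserved.  Ties within a column receive the mean of the tied target
    values, so the column sum is conserved exactly.

    Parameters
    ----------
    matrix : DataFrame or NormalizedMatrix
        Non-negative intensities, no missing values.
    """
    df = matrix.data if isinstance(matrix, NormalizedMatrix) else matrix
    X = df.to_numpy(dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values")
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = target
        # ties: every occurrence of a tied value gets the mean of the target
        # values its occurrences were mapped to
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return NormalizedMatrix(
        pd.DataFrame(out, index=df.index, columns=df.columns),
        normalized=True,
        filtered=matrix.filtered if isinstance(matrix, NormalizedMatrix) else False,
    )


def compute_detection_p(intensity, negctrl_intensities):
    """Rank-based empirical detection p-value against negative controls.

    ``p = (1 + #{controls >= intensity}) / (N + 1)``, which lies in (0, 1]:
    a probe brighter than all N controls scores 1/(N+1), one dimmer than all
    of them scores 1.  Accepts a scalar or an array of intensities.
    """
    nc = np.asarray(negctrl_intensities, dtype=float).ravel()
    if nc.size == 0:
        raise ValueError("negative-control intensity vector is empty")
    nc_sorted = np.sort(nc)
    x = np.asarray(intensity, dtype=float)
    n_ge = nc.size - np.searchsorted(nc_sorted, x, side="left")
    p = (1.0 + n_ge) / (nc.size + 1.0)
    if np.isscalar(intensity) or x.ndim == 0:
        return float(p)
    return p


def filter_expressed(
    table: ProbeProfileTable,
    alpha: float = 0.05,
    matrix: NormalizedMatrix | pd.DataFrame | None = None,
    drop_zero_variance: bool = False,
) -> tuple[NormalizedMatrix, int]:
    """Keep regular probes detected (p < alpha) on at least one array.

    Negative-control probes are always excluded from the expression matrix;
    they are consumed separately by :func:`estimate_background`.  When
    ``matrix`` is given (typically the quantile-normalized signals) its rows
    are filtered; otherwise the table's raw signals are used.  Returns the
    retained matrix and the number of regular probes removed.

    ``drop_zero_variance`` additionally removes probes that are constant
    across all arrays after filtering (they carry no contrast information);
    off by default.
    """
    if isinstance(matrix, NormalizedMatrix):
        data, normalized = matrix.data, matrix.normalized
    elif matrix is not None:
        data, normalized = matrix, False
    else:
        data, normalized = table.signal, False
    regular = table.is_regular()
    detected = (table.detection_p.loc[regular] < alpha).any(axis=1)
    keep = detected[detected].index
    removed = int((~detected).sum())
    out = data.loc[data.index.isin(set(keep))]  # preserves input probe order
    if drop_zero_variance and len(out) > 0:
        variable = out.std(axis=1, ddof=0) > 0
        out = out.loc[variable]
    return NormalizedMatrix(out, normalized=normalized, filtered=True), removed


def estimate_background(table: ProbeProfileTable) -> BackgroundEstimate:
    """Mean negative-control intensity pooled across all arrays.

    Raises a ``ValueError`` when the table carries no negative-control
    probes; supply an explicit background constant in that case.
    """
    nc = table.negative_control_signal()
    if nc.empty:
        raise ValueError(
            "no negative-control probes in table: cannot estimate background; "
            "supply a background constant explicitly"
        )
    values = nc.to_numpy(dtype=float).ravel()
    return BackgroundEstimate(value=float(values.mean()), n_control_probes_used=len(nc))
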