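"""Tabular and tree I/O.

All writers are deterministic (same object -> byte-identical file) so that
pipeline artifacts can be diffed and version-controlled.  The canonical
probe-profile format is a tab-delimited UTF-8 table with header

    PROBE_ID  PROBE_CLASS  <sample>.AVG_Signal  <sample>.Detection_Pval  ...

one signal/detection-p column pair per sample, mirroring the layout of
Illumina sample-probe-profile exports.  Signals are written with full
round-trip precision, detection p-values with 6 significant digits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

REGULAR = "regular"
NEGATIVE_CONTROL = "negative_control"
_PROBE_CLASSES = (REGULAR, NEGATIVE_CONTROL)

_SIGNAL_SUFFIX = ".AVG_Signal"
_DETECTION_SUFFIX = ".Detection_Pval"


class ProbeProfileError(ValueError):
    """Structured parse/validation error for probe-profile tables."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class ContrastSpec:
    """A knockdown array paired with its concentration-matched control array."""

    name: str
    treated_sample: str
    control_sample: str

    def __post_init__(self) -> None:
        if self.treated_sample == self.control_sample:
            raise ValueError(
                f"contrast {self.name!r}: treated and control sample must differ"
            )


class ProbeProfileTable:
    """Probes x samples raw intensities with per-probe detection p-values.

    Parameters
    ----------
    signal : DataFrame
        Average signal per probe (rows, indexed by probe id) and sample
        (columns).  All values must be >= 0.
    detection_p : DataFrame
        Detection p-value per probe and sample, same index/columns as
        ``signal``, values in [0, 1].
    probe_class : Series
        ``"regular"`` or ``"negative_control"`` per probe.
    """

    def __init__(
        self,
        signal: pd.DataFrame,
        detection_p: pd.DataFrame,
        probe_class: pd.Series,
    ):
        signal = signal.astype(float)
        detection_p = detection_p.astype(float)
        if not signal.index.equals(detection_p.index) or not signal.columns.equals(
            detection_p.columns
        ):
            raise ProbeProfileError(
                "signal and detection_p must share probe index and sample columns"
            )
        if not signal.index.equals(probe_class.index):
            raise ProbeProfileError("probe_class index must match the probe index")
        if signal.index.duplicated().any():
            dup = signal.index[signal.index.duplicated()][0]
            raise ProbeProfileError(f"duplicate probe_id {dup!r}")
        if (signal.to_numpy() < 0).any():
            raise ProbeProfileError("negative signal values are not allowed")
        p = detection_p.to_numpy()
        if ((p < 0) | (p > 1)).any():
            raise ProbeProfileError("detection p-values must lie in [0, 1]")
        bad = set(probe_class.unique()) - set(_PROBE_CLASSES)
        if bad:
            raise ProbeProfileError(f"unknown probe class {sorted(bad)[0]!r}")
        self.signal = signal
        self.detection_p = detection_p
        self.probe_class = probe_class.astype(str)

    # -- basic views -------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.signal.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.signal.index

    @property
    def n_probes(self) -> int:
        return len(self.signal.index)

    def is_regular(self) -> pd.Series:
        return self.probe_class == REGULAR

    def regular_signal(self) -> pd.DataFrame:
        return self.signal.loc[self.is_regular()]

    def negative_control_signal(self) -> pd.DataFrame:
        return self.signal.loc[~self.is_regular()]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeProfileTable):
            return NotImplemented
        return (
            self.signal.equals(other.signal)
            and self.detection_p.equals(other.detection_p)
            and self.probe_class.equals(other.probe_class)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_nc = int((~self.is_regular()).sum())
        return (
            f"ProbeProfileTable({self.n_probes} probes, {len(self.samples)} samples, "
            f"{n_nc} negative controls)"
        )


def _parse_header(header: Sequence[str]) -> list[str]:
    if len(header) < 2 or header[0] != "PROBE_ID" or header[1] != "PROBE_CLASS":
        raise ProbeProfileError(
            "header must start with PROBE_ID\tPROBE_CLASS", line=1
        )
    samples: list[str] = []
    rest = header[2:]
    if len(rest) % 2 != 0:
        raise ProbeProfileError(
            "sample columns must come in AVG_Signal/Detection_Pval pairs", line=1
        )
    for i in range(0, len(rest), 2):
        sig, det = rest[i], rest[i + 1]
        if not sig.endswith(_SIGNAL_SUFFIX):
            raise ProbeProfileError(f"expected an AVG_Signal column, got {sig!r}", line=1)
        name = sig[: -len(_SIGNAL_SUFFIX)]
        if det != name + _DETECTION_SUFFIX:
            raise ProbeProfileError(
                f"column {sig!r} is not paired with {name + _DETECTION_SUFFIX!r}",
                line=1,
            )
        samples.append(name)
    if not samples:
        raise ProbeProfileError("at least one sample column pair required", line=1)
    return samples


def read_probe_profile(path) -> ProbeProfileTable:
    """Read the canonical probe-profile TSV, validating as it goes.

    Errors carry the 1-based line number of the offending row.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ProbeProfileError("empty file", line=1)
    samples = _parse_header(lines[0].split("\t"))
    ncol = 2 + 2 * len(samples)
    probe_ids: list[str] = []
    classes: list[str] = []
    sig_rows: list[list[float]] = []
    det_rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ProbeProfileError(
                f"expected {ncol} fields, found {len(fields)}", line=lineno
            )
        pid, pclass = fields[0], fields[1]
        if pid in seen:
            raise ProbeProfileError(f"duplicate probe_id {pid!r}", line=lineno)
        seen.add(pid)
        if pclass not in _PROBE_CLASSES:
            raise ProbeProfileError(f"unknown probe class {pclass!r}", line=lineno)
        srow: list[float] = []
        drow: list[float] = []
        for k, sample in enumerate(samples):
            try:
                s = float(fields[2 + 2 * k])
                d = float(fields[3 + 2 * k])
            except ValueError as exc:
                raise ProbeProfileError(
                    f"non-numeric value for sample {sample!r}: {exc}", line=lineno
                ) from None
            if s < 0:
                raise ProbeProfileError(
                    f"negative signal {s!r} for probe {pid!r}, sample {sample!r}",
                    line=lineno,
                )
            if not (0.0 <= d <= 1.0):
                raise ProbeProfileError(
                    f"detection p-value {d!r} outside [0, 1] for probe {pid!r}, "
                    f"sample {sample!r}",
                    line=lineno,
                )
            srow.append(s)
            drow.append(d)
        probe_ids.append(pid)
        classes.append(pclass)
        sig_rows.append(srow)
        det_rows.append(drow)
    index = pd.Index(probe_ids, name="probe_id")
    signal = pd.DataFrame(sig_rows, index=index, columns=samples, dtype=float)
    detection = pd.DataFrame(det_rows, index=index, columns=samples, dtype=float)
    probe_class = pd.Series(classes, index=index, name="probe_class")
    return ProbeProfileTable(signal, detection, probe_class)


def _fmt_signal(x: float) -> str:
    return repr(float(x))


def _fmt_p(x: float) -> str:
    return format(float(x), ".6g")


def write_probe_profile(table: ProbeProfileTable, path) -> None:
    """Write the canonical probe-profile TSV (deterministic byte layout)."""
    samples = table.samples
    header = ["PROBE_ID", "PROBE_CLASS"]
    for s in samples:
        header += [s + _SIGNAL_SUFFIX, s + _DETECTION_SUFFIX]
    sig = table.signal.to_numpy()
    det = table.detection_p.to_numpy()
    classes = table.probe_class.to_numpy()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for i, pid in enumerate(table.probe_ids):
            fields = [str(pid), classes[i]]
            for k in range(len(samples)):
                fields.append(_fmt_signal(sig[i, k]))
                fields.append(_fmt_p(det[i, k]))
            fh.write("\t".join(fields) + "\n")


# -- gene lists ------------------------------------------------------------


def read_gene_list(path) -> list[str]:
    """One identifier per line; de-duplicated preserving first occurrence."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            ident = line.strip()
            if ident and ident not in seen:
                seen.add(ident)
                out.append(ident)
    return out


def write_gene_list(ids: Iterable[str], path) -> None:
    seen: set[str] = set()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for ident in ids:
            if ident not in seen:
                seen.add(ident)
                fh.write(ident + "\n")


# -- Newick export ---------------------------------------------------------

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,']")


def _newick_name(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_len(x: float) -> str:
    return format(float(x), "g")


def _node_label(node) -> str:
    if node.au is None or node.bp is None:
        return ""
    return f"{round(100 * node.au)}|{round(100 * node.bp)}"


def to_newick(tree) -> str:
    """Render a (possibly support-annotated) sample dendrogram as Newick.

    Branch lengths are merge-height differences; internal nodes are labelled
    ``AU|BP`` as integer-rounded percentages when supports are present.
    Leaf names containing whitespace or Newick metacharacters are quoted.
    """

    def render(node, parent_height: float | None) -> str:
        if not node.children:
            s = _newick_name(next(iter(node.members)))
        else:
            inner = ",".join(render(ch, node.height) for ch in node.children)
            s = f"({inner})" + _node_label(node)
        if parent_height is not None:
            s += ":" + _fmt_len(parent_height - node.height)
        return s

    return render(tree.root, None) + ";"


def export_newick(tree, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(to_newick(tree) + "\n")


# -- flat key = value configuration files ----------------------------------


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value


def load_config(path) -> dict:
    """Parse a flat ``key = value`` configuration file.

    Nesting is expressed by dotted keys (``fold_range.low = 3``).  Values are
    coerced to int/float/bool when they parse as such, else kept as strings.
    Lines starting with ``#`` and blank lines are ignored.
    """
    out: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if "=" not in stripped:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, _, value = stripped.partition("=")
            out[key.strip()] = _coerce(value.strip())
    return out


def save_config(config: Mapping, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in config:
            fh.write(f"{key} = {config[key]}\n")
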