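"""Synthetic BeadChip-like experiments with known ground truth.

The generator emulates a six-array siRNA knockdown experiment: three single
knockdowns (siFUS, siEWS, siTAF15), a triple knockdown (siTriple), and two
controls matched to the low ("+") and high ("+++") siRNA concentrations.
Each regular probe has a log-normal baseline intensity shared by all
arrays; a knockdown perturbs a configurable fraction of probes by a
multiplicative fold, with a configurable sharing structure (FUS/TAF15
overlap, all-three overlap, triple-unique effects).  Independent log-normal
measurement noise is added per array.  Negative-control probes are drawn
identically in every array with a configurable mean, so the
negative-control mean is the intended background constant.

Effects are planted only on probes whose baseline is comfortably above the
background floor: a fold change on a probe at or below background is
unobservable by background-subtracted ratios, so planting there would make
"ground truth" unrecoverable by construction rather than by noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ContrastSpec, ProbeProfileTable
from .preprocess import compute_detection_p

GROUPS = ("siFUS", "siEWS", "siTAF15", "siTriple", "controlPlus", "controlTriplePlus")
SINGLE_KNOCKDOWNS = ("siFUS", "siEWS", "siTAF15")
TRIPLE = "siTriple"

# spread of the negative-control intensity distribution (log2 units)
_NEGCTRL_LOG_SD = 0.5

# a down-regulated probe stays observable only if baseline / fold remains
# this many times above background after subtraction
_DOWN_MARGIN = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a six-array knockdown experiment.

    Log-scale parameters are in log2 intensity units.  The DEG-structure
    fractions default to the proportions of the study design they emulate:
    roughly 1% of probes differentially expressed per knockdown, a modest
    FUS-TAF15 overlap containing a smaller all-three core, and a triple
    knockdown dominated by effects absent from every single knockdown.
    """

    n_probes: int = 48803
    n_negative_controls: int = 800
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 2.0
    noise_log_sd: float = 0.15
    negctrl_mean: float = 28.0
    frac_deg_per_group: float = 0.006
    frac_shared_fus_taf15: float = 0.14
    frac_shared_all: float = 0.07
    frac_triple_unique: float = 0.8
    fold_range: tuple = (3.0, 6.0)
    down_fraction: float = 0.55
    expressed_floor: float | None = None  # default: 4 x negctrl_mean
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_deg_per_group",
            "frac_shared_fus_taf15",
            "frac_shared_all",
            "frac_triple_unique",
            "down_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_shared_all > self.frac_shared_fus_taf15:
            raise ValueError(
                "frac_shared_all must not exceed frac_shared_fus_taf15"
            )
        low, high = self.fold_range
        if not low > 1.0:
            raise ValueError(f"fold_range low bound must exceed 1, got {low}")
        if high < low:
            raise ValueError("fold_range must be (low, high) with high >= low")
        for name in ("baseline_log_sd", "noise_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.negctrl_mean <= 0:
            raise ValueError("negctrl_mean must be positive")
        if not self.n_negative_controls < self.n_probes:
            raise ValueError("n_negative_controls must be smaller than n_probes")
        if self.n_negative_controls < 1:
            raise ValueError("n_negative_controls must be >= 1")
        if self.frac_triple_unique >= 1.0 and self.frac_deg_per_group > 0:
            raise ValueError("frac_triple_unique must be < 1 when effects are planted")

    @property
    def floor(self) -> float:
        """Minimum baseline for planting an up-regulation effect."""
        return (
            self.expressed_floor
            if self.expressed_floor is not None
            else 4.0 * self.negctrl_mean
        )

    @property
    def down_floor(self) -> float:
        """Minimum baseline for planting a down-regulation effect.

        Dividing the baseline by the largest fold must leave the signal
        well above background, or the planted effect would be invisible to
        background-subtracted ratios by construction.
        """
        return max(self.floor, _DOWN_MARGIN * self.negctrl_mean * self.fold_range[1])

    @property
    def n_regular(self) -> int:
        return self.n_probes - self.n_negative_controls


@dataclass
class SyntheticTruth:
    """Planted effects: per group, probe id -> signed log2 fold."""

    effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def degs(self, group: str) -> set[str]:
        return set(self.effects.get(group, {}))

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("probe_id\tgroup\tlog2_fold\n")
            for group in sorted(self.effects):
                for pid in sorted(self.effects[group]):
                    fh.write(f"{pid}\t{group}\t{self.effects[group][pid]:.6g}\n")


def default_contrasts() -> list[ContrastSpec]:
    from .deg import default_contrasts as _dc

    return _dc()


def _draw_effects(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    """Signed log2 folds: magnitude log-uniform in fold_range, sign by down_fraction."""
    low, high = config.fold_range
    mag = rng.uniform(math.log2(low), math.log2(high), size=n)
    sign = np.where(rng.random(n) < config.down_fraction, -1.0, 1.0)
    return sign * mag


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ProbeProfileTable, SyntheticTruth]:
    """Generate a six-array probe-profile table and its planted ground truth.

    Deterministic for a fixed config (the seed is part of the config): the
    same config yields a bit-identical table and truth.
    """
    rng = np.random.default_rng(config.seed)
    n_reg = config.n_regular
    n_nc = config.n_negative_controls

    regular_ids = np.array([f"PROBE_{i:06d}" for i in range(n_reg)])
    nc_ids = np.array([f"NEGCTRL_{i:04d}" for i in range(n_nc)])

    log_baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_reg)
    baseline = 2.0**log_baseline

    truth = SyntheticTruth(effects={g: {} for g in SINGLE_KNOCKDOWNS + (TRIPLE,)})
    n_deg = round(config.frac_deg_per_group * n_reg)
    if n_deg > 0:
        n_all = round(config.frac_shared_all * n_deg)
        n_ft = max(round(config.frac_shared_fus_taf15 * n_deg), n_all)
        n_pair_ft = n_ft - n_all
        n_fus_u = n_deg - n_ft
        n_taf_u = n_deg - n_ft
        n_ews_u = n_deg - n_all
        block_sizes = (
            ("all", n_all),
            ("pair_ft", n_pair_ft),
            ("fus_u", n_fus_u),
            ("taf_u", n_taf_u),
            ("ews_u", n_ews_u),
        )
        n_singles = sum(size for _, size in block_sizes)
        n_triple_total = (
            round(n_singles / (1.0 - config.frac_triple_unique)) if n_singles else 0
        )
        n_triple_u = max(n_triple_total - n_singles, 0)
        block_sizes = block_sizes + (("triple_u", n_triple_u),)

        # draw effects first, then place them on probes bright enough for
        # the effect to be observable (down-effects need a brighter pool)
        effects = {name: _draw_effects(rng, size, config) for name, size in block_sizes}
        all_effects = np.concatenate([effects[name] for name, _ in block_sizes])
        is_down = all_effects < 0
        n_down = int(is_down.sum())
        n_up = len(all_effects) - n_down
        eligible_down = np.flatnonzero(baseline >= config.down_floor)
        eligible_up = np.flatnonzero(baseline >= config.floor)
        if n_down > len(eligible_down):
            raise ValueError(
                f"cannot plant {n_down} down-effects on {len(eligible_down)} probes "
                f"above the down floor ({config.down_floor:g}); lower "
                f"frac_deg_per_group or fold_range.high, or raise baseline_log_mean"
            )
        down_idx = rng.choice(eligible_down, size=n_down, replace=False)
        up_pool = np.setdiff1d(eligible_up, down_idx)
        if n_up > len(up_pool):
            raise ValueError(
                f"cannot plant {n_up} up-effects on {len(up_pool)} probes above "
                f"the expressed floor ({config.floor:g}); lower frac_deg_per_group "
                f"or raise baseline_log_mean"
            )
        up_idx = rng.choice(up_pool, size=n_up, replace=False)
        placement = np.empty(len(all_effects), dtype=int)
        placement[is_down] = down_idx
        placement[~is_down] = up_idx
        blocks = {}
        start = 0
        for name, size in block_sizes:
            blocks[name] = placement[start : start + size]
            start += size

        def plant(group: str, block: str) -> None:
            for idx, f in zip(blocks[block], effects[block]):
                truth.effects[group][regular_ids[idx]] = float(f)

        for block in ("all", "pair_ft", "fus_u"):
            plant("siFUS", block)
        for block in ("all", "pair_ft", "taf_u"):
            plant("siTAF15", block)
        for block in ("all", "ews_u"):
            plant("siEWS", block)
        # triple knockdown: union of single effects (shared folds reused) plus
        # an independent triple-unique block
        for group in SINGLE_KNOCKDOWNS:
            truth.effects[TRIPLE].update(truth.effects[group])
        plant(TRIPLE, "triple_u")

    # intensities per group: baseline x planted fold x log-normal noise
    effect_matrix = np.zeros((n_reg, len(GROUPS)))
    id_to_row = {pid: i for i, pid in enumerate(regular_ids)}
    for gi, group in enumerate(GROUPS):
        for pid, f in truth.effects.get(group, {}).items():
            effect_matrix[id_to_row[pid], gi] = f

    signal = np.empty((n_reg, len(GROUPS)))
    for gi in range(len(GROUPS)):
        noise = (
            rng.normal(0.0, config.noise_log_sd, n_reg)
            if config.noise_log_sd > 0
            else 0.0
        )
        signal[:, gi] = 2.0 ** (log_baseline + effect_matrix[:, gi] + noise)

    # negative controls: identically distributed in every array, arithmetic
    # mean equal to negctrl_mean in expectation
    mu_nc = math.log2(config.negctrl_mean) - math.log(2) * _NEGCTRL_LOG_SD**2 / 2
    nc_signal = 2.0 ** rng.normal(mu_nc, _NEGCTRL_LOG_SD, size=(n_nc, len(GROUPS)))

    detection = np.empty_like(signal)
    nc_detection = np.empty_like(nc_signal)
    for gi in range(len(GROUPS)):
        detection[:, gi] = compute_detection_p(signal[:, gi], nc_signal[:, gi])
        nc_detection[:, gi] = compute_detection_p(nc_signal[:, gi], nc_signal[:, gi])

    index = pd.Index(np.concatenate([regular_ids, nc_ids]), name="probe_id")
    columns = list(GROUPS)
    table = ProbeProfileTable(
        signal=pd.DataFrame(
            np.vstack([signal, nc_signal]), index=index, columns=columns
        ),
        detection_p=pd.DataFrame(
            np.vstack([detection, nc_detection]), index=index, columns=columns
        ),
        probe_class=pd.Series(
            ["regular"] * n_reg + ["negative_control"] * n_nc,
            index=index,
            name="probe_class",
        ),
    )
    return table, truth


def config_from_mapping(mapping: Mapping) -> SimulationConfig:
    """Build a SimulationConfig from a flat (possibly dotted-key) mapping."""
    kwargs: dict = {}
    fold = {}
    for key, value in mapping.items():
        if key == "fold_range.low":
            fold["low"] = float(value)
        elif key == "fold_range.high":
            fold["high"] = float(value)
        else:
            kwargs[key] = value
    if fold:
        base = SimulationConfig()
        kwargs["fold_range"] = (
            fold.get("low", base.fold_range[0]),
            fold.get("high", base.fold_range[1]),
        )
    return SimulationConfig(**kwargs)
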