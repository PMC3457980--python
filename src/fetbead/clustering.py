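"""Hierarchical clustering of arrays with multiscale-bootstrap supports.

Samples (array columns) are clustered by average-linkage agglomeration on
the correlation distance ``d(x, y) = 1 - r(x, y)`` (Pearson), after an
optional standard-deviation gene selection that discards probes expressed
near-identically in all samples.

Cluster support is assessed by the multiscale bootstrap: probe rows are
resampled with replacement at several relative sizes ``r`` (default 0.5 ...
1.4), the samples are re-clustered, and for every cluster of the original
tree the appearance fraction ``BP_r`` across ``B`` replicates is recorded.
The probit-transformed fractions ``z_r = Phi^{-1}(1 - BP_r)`` are fitted by
weighted least squares to

    z_r  ~=  v * sqrt(r)  +  c / sqrt(r)

where ``v`` estimates a signed distance and ``c`` a curvature term of the
cluster boundary.  The approximately unbiased support is
``AU = 1 - Phi(v - c)`` and the (bias-prone) plain bootstrap probability is
``BP = 1 - Phi(v + c)``.  AU corrects the size-bias of plain bootstrap
probabilities; clusters with AU above 0.95 are conventionally reported as
strongly supported.

Appearance fractions are clipped away from 0 and 1 (default by 1/(B+1)) so
the probit transform stays finite; a cluster at the clip ceiling (or floor)
at every scale is snapped to AU = BP = 1 (or 0) and flagged instead of
being extrapolated from a degenerate fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri


@dataclass
class Node:
    """A dendrogram node: a set of sample labels merged at ``height``.

    Internal nodes additionally carry multiscale-bootstrap diagnostics once
    supports have been computed: AU/BP probabilities, the fitted signed
    distance ``v`` and curvature ``c``, the weighted fit residual, the
    per-scale appearance table, and a flag for degenerate cases
    (``"at_ceiling"``, ``"never_observed"``).
    """

    members: frozenset
    height: float
    children: tuple = ()
    au: float | None = None
    bp: float | None = None
    v: float | None = None
    c: float | None = None
    fit_residual: float | None = None
    bp_table: dict | None = None
    flag: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        label = ",".join(sorted(self.members))
        sup = f" au={self.au:.3f} bp={self.bp:.3f}" if self.au is not None else ""
        return f"Node({{{label}}}, h={self.height:.4g}{sup})"


@dataclass
class SupportedDendrogram:
    """Sample dendrogram; internal nodes may carry AU/BP support values."""

    root: Node
    nodes: list[Node] = field(default_factory=list)  # all nodes, leaves first

    @property
    def leaves(self) -> list[str]:
        return sorted(next(iter(n.members)) for n in self.nodes if n.is_leaf)

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.nodes if not n.is_leaf]

    def clusters(self) -> set[frozenset]:
        return {n.members for n in self.internal_nodes()}

    def find(self, members: Sequence[str] | frozenset) -> Node | None:
        target = frozenset(members)
        for n in self.nodes:
            if n.members == target:
                return n
        return None

    def smallest_containing(self, members: Sequence[str]) -> Node:
        """Smallest node whose member set contains all given labels."""
        target = set(members)
        best = None
        for n in self.nodes:
            if target <= n.members and (best is None or len(n.members) < len(best.members)):
                best = n
        if best is None:
            raise KeyError(f"labels {sorted(target)} not all present in tree")
        return best

    def is_laminar(self) -> bool:
        """Nodes form a laminar family: any two are nested or disjoint."""
        sets = [n.members for n in self.nodes]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                a, b = sets[i], sets[j]
                if a & b and not (a <= b or b <= a):
                    return False
        return True


@dataclass(frozen=True)
class MultiscaleConfig:
    """Parameters of the multiscale bootstrap.

    ``scales`` are relative resample sizes (must include 1.0 so the plain
    bootstrap is observable); ``replicates`` is the number of bootstrap
    trees per scale; ``bp_clip`` bounds appearance fractions away from 0/1
    before the probit transform (default 1/(replicates + 1)).
    """

    scales: tuple = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)
    replicates: int = 1000
    seed: int = 0
    bp_clip: float | None = None

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.scales):
            raise ValueError("all scales must be positive")
        if not any(math.isclose(r, 1.0) for r in self.scales):
            raise ValueError("scales must include 1.0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def clip(self) -> float:
        return self.bp_clip if self.bp_clip is not None else 1.0 / (self.replicates + 1)


# -- gene selection --------------------------------------------------------


def sd_select(
    matrix, min_sd: float | None = None, top_k: int | None = None
) -> pd.DataFrame:
    """Discard probes expressed near-identically across all samples.

    Keeps probes whose across-sample standard deviation (ddof=1) exceeds
    ``min_sd``, or the ``top_k`` most variable probes.  Exactly one of the
    two criteria must be given; at least two probes must survive.
    """
    df = matrix.data if hasattr(matrix, "data") else matrix
    if df.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (min_sd is None) == (top_k is None):
        raise ValueError("give exactly one of min_sd or top_k")
    sd = df.std(axis=1, ddof=1)
    if min_sd is not None:
        out = df.loc[sd > min_sd]
    else:
        order = np.argsort(-sd.to_numpy(), kind="mergesort")[: int(top_k)]
        out = df.iloc[np.sort(order)]
    if len(out) < 2:
        raise ValueError(
            "fewer than 2 probes survive the SD selection; lower the threshold"
        )
    return out


# -- agglomeration ---------------------------------------------------------


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between sample columns of X (probes x samples)."""
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance sample column: correlation undefined")
    R = np.corrcoef(X, rowvar=False)
    return 1.0 - R


def _agglomerate(D: np.ndarray, labels: Sequence[str]) -> SupportedDendrogram:
    """Average-linkage agglomeration with a deterministic tie-break.

    Among equally close pairs, the pair whose merged member tuple sorts
    lexicographically smallest is merged first.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    nodes: list[Node] = [Node(frozenset({lab}), 0.0) for lab in labels]
    members: list[tuple] = [tuple([lab]) for lab in labels]
    sizes = [1] * n
    total = 2 * n - 1
    dist = np.full((total, total), np.inf)
    dist[:n, :n] = D
    active = list(range(n))
    while len(active) > 1:
        best: tuple | None = None
        best_pair = (-1, -1)
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = dist[i, j]
                key = (d, tuple(sorted(members[i] + members[j])))
                if best is None or key < best:
                    best = key
                    best_pair = (i, j)
        i, j = best_pair
        k = len(nodes)
        merged = frozenset(nodes[i].members | nodes[j].members)
        nodes.append(Node(merged, float(best[0]), (nodes[i], nodes[j])))
        members.append(tuple(sorted(members[i] + members[j])))
        sizes.append(sizes[i] + sizes[j])
        for m in active:
            if m in (i, j):
                continue
            dnew = (sizes[i] * dist[i, m] + sizes[j] * dist[j, m]) / (sizes[i] + sizes[j])
            dist[k, m] = dist[m, k] = dnew
        active = [m for m in active if m not in (i, j)] + [k]
    return SupportedDendrogram(root=nodes[-1], nodes=nodes)


def cluster_samples(matrix) -> SupportedDendrogram:
    """Average-linkage dendrogram of samples on 1 - Pearson correlation.

    ``matrix`` is a probes x samples DataFrame (or an object with a ``data``
    attribute holding one), typically after :func:`sd_select`.
    """
    df = matrix.data if hasattr(matrix, "data") else matrix
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least 2 probes and 2 samples")
    D = _correlation_distance(df.to_numpy(dtype=float))
    return _agglomerate(D, [str(c) for c in df.columns])


def _replicate_clusters(X: np.ndarray, labels: Sequence[str]) -> set[frozenset]:
    return _agglomerate(_correlation_distance(X), labels).clusters()


# -- multiscale bootstrap --------------------------------------------------


def multiscale_bootstrap(
    matrix, config: MultiscaleConfig = MultiscaleConfig()
) -> SupportedDendrogram:
    """Cluster samples and attach AU/BP supports to every internal node.

    Random streams are derived per (scale, replicate) from the master seed,
    so results do not depend on evaluation order.  Replicates in which a
    resampled matrix yields an undefined correlation (a constant sample
    column) are discarded for all clusters alike.
    """
    df = matrix.data if hasattr(matrix, "data") else matrix
    labels = [str(c) for c in df.columns]
    X = df.to_numpy(dtype=float)
    tree = cluster_samples(df)
    internal = tree.internal_nodes()
    n_rows = X.shape[0]
    scales = tuple(config.scales)
    B = config.replicates

    counts = {node.members: np.zeros(len(scales)) for node in internal}
    valid = np.zeros(len(scales))
    scale_streams = np.random.SeedSequence(config.seed).spawn(len(scales))
    for si, r in enumerate(scales):
        m = max(2, math.ceil(n_rows * r))
        rep_streams = scale_streams[si].spawn(B)
        for b in range(B):
            rng = np.random.default_rng(rep_streams[b])
            idx = rng.integers(0, n_rows, size=m)
            try:
                observed = _replicate_clusters(X[idx], labels)
            except ValueError:
                continue  # degenerate resample, discarded for all clusters
            valid[si] += 1
            for node in internal:
                if node.members in observed:
                    counts[node.members][si] += 1

    clip = config.clip
    sqrt_r = np.sqrt(np.asarray(scales))
    for node in internal:
        cnt = counts[node.members]
        ok = valid > 0
        node.bp_table = {
            float(scales[i]): (int(cnt[i]), int(valid[i])) for i in range(len(scales))
        }
        if not ok.any():
            node.au, node.bp, node.flag = 0.0, 0.0, "never_observed"
            continue
        if (cnt[ok] == valid[ok]).all():
            node.au, node.bp, node.flag = 1.0, 1.0, "at_ceiling"
            continue
        if (cnt[ok] == 0).all():
            node.au, node.bp, node.flag = 0.0, 0.0, "never_observed"
            continue
        bp_r = np.clip(cnt[ok] / valid[ok], clip, 1.0 - clip)
        z = ndtri(1.0 - bp_r)
        w = valid[ok] / (bp_r * (1.0 - bp_r))
        A = np.column_stack([sqrt_r[ok], 1.0 / sqrt_r[ok]])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], z * sw, rcond=None)
        v, c = float(coef[0]), float(coef[1])
        node.v, node.c = v, c
        node.fit_residual = float(np.sum(w * (z - A @ coef) ** 2))
        node.au = float(np.clip(1.0 - ndtr(v - c), 0.0, 1.0))
        node.bp = float(np.clip(1.0 - ndtr(v + c), 0.0, 1.0))
    return tree


def highlight_clusters(
    tree: SupportedDendrogram, au_threshold: float = 0.95
) -> list[Node]:
    """Internal nodes (excluding the root) whose AU support exceeds the cut."""
    return [
        n
        for n in tree.internal_nodes()
        if n is not tree.root and n.au is not None and n.au > au_threshold
    ]
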