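"""Hierarchical clustering of prognostic probes, nested-branch subcluster
extraction at an average-correlation threshold, metagene scoring and tertiles.

Clustering is agglomerative average linkage on correlation distance
(1 - Pearson r, or 1 - cosine for the 'uncentered' variant used for heatmap
style views).  Subclusters are the MAXIMAL dendrogram branches whose leaf
sets reach a recomputed average pairwise Pearson correlation >= threshold
(default 0.6) with at least ``min_size`` members.  A metagene is the per
sample mean over genes of the per-gene probe means (probes collapse to genes
first to guard against overrepresentation of multi-probe genes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix

__all__ = [
    "Dendrogram",
    "Subcluster",
    "MetageneDefinition",
    "mean_center",
    "hcluster",
    "average_pairwise_correlation",
    "extract_subclusters",
    "build_metagene",
    "metagene_values",
    "tertile_cutpoints",
    "assign_tertiles",
]


def mean_center(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center each probe row to mean 0 (genes only; columns untouched)."""
    if expr.n_probes == 0:
        raise ValueError("empty matrix")
    centered = expr.values - expr.values.mean(axis=1, keepdims=True)
    return ExpressionMatrix(list(expr.probe_ids), list(expr.sample_ids), centered)


def _correlation_distance(values: np.ndarray, probe_ids: list[str], metric: str) -> np.ndarray:
    if metric == "pearson":
        sd = values.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"zero-variance probe under pearson metric: {probe_ids[bad[0]]!r}")
        corr = np.corrcoef(values)
    elif metric == "uncentered_pearson":
        norms = np.linalg.norm(values, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(f"zero-norm probe under uncentered metric: {probe_ids[bad[0]]!r}")
        unit = values / norms[:, None]
        corr = unit @ unit.T
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d = 1.0 - corr
    np.fill_diagonal(d, np.inf)
    return np.maximum(d, 0.0)


@dataclass
class Dendrogram:
    """Binary agglomerative merge tree.

    Leaves are numbered 0..n-1 in probe order; internal node i (>= n) is
    created by merge i-n.  ``merges`` lists (left_id, right_id, height) with
    heights non-decreasing under average linkage.
    """

    probe_ids: list[str]
    merges: list[tuple[int, int, float]]
    metric: str = "pearson"
    _members: dict[int, list[int]] = field(default_factory=dict, repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.probe_ids)

    def members(self, node: int) -> list[int]:
        """Leaf indices under ``node`` (sorted)."""
        if node < self.n_leaves:
            return [node]
        if node not in self._members:
            left, right, _ = self.merges[node - self.n_leaves]
            self._members[node] = sorted(self.members(left) + self.members(right))
        return self._members[node]

    def to_linkage(self) -> np.ndarray:
        """scipy-style (n-1, 4) linkage matrix."""
        Z = np.zeros((len(self.merges), 4))
        for i, (l, r, h) in enumerate(self.merges):
            Z[i] = [l, r, h, len(self.members(self.n_leaves + i))]
        return Z

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if node < self.n_leaves:
                return self.probe_ids[node]
            l, r, h = self.merges[node - self.n_leaves]
            return f"({render(l)},{render(r)}):{h:.6g}"

        root = self.n_leaves + len(self.merges) - 1
        return render(root) + ";"


def hcluster(
    expr: ExpressionMatrix, metric: str = "pearson", linkage: str = "average"
) -> Dendrogram:
    """Average-linkage agglomerative clustering of probe rows.

    Distance is 1 - correlation.  Ties are broken deterministically by the
    lexicographically smallest (row, column) slot pair.
    """
    if linkage != "average":
        raise ValueError("only average linkage is supported")
    n = expr.n_probes
    if n < 2:
        raise ValueError("need at least 2 probes")
    D = _correlation_distance(expr.values, expr.probe_ids, metric)
    # Lance-Williams updates on a full symmetric matrix; dead rows -> inf
    W = D.copy()
    sizes = np.ones(n)
    node_id = np.arange(n)
    alive = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        flat = int(np.argmin(W))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h = float(W[i, j])
        merges.append((int(node_id[i]), int(node_id[j]), h))
        # merged cluster occupies slot i
        new_row = (sizes[i] * W[i] + sizes[j] * W[j]) / (sizes[i] + sizes[j])
        W[i, :] = new_row
        W[:, i] = new_row
        W[i, i] = np.inf
        W[j, :] = np.inf
        W[:, j] = np.inf
        sizes[i] += sizes[j]
        alive[j] = False
        node_id[i] = n + step
    return Dendrogram(list(expr.probe_ids), merges, metric=metric)


def average_pairwise_correlation(values: np.ndarray) -> float:
    """Mean off-diagonal Pearson correlation among rows."""
    k = values.shape[0]
    if k < 2:
        raise ValueError("need at least 2 rows")
    corr = np.corrcoef(values)
    return float((corr.sum() - k) / (k * (k - 1)))


@dataclass
class Subcluster:
    probes: list[str]
    average_pairwise_correlation: float
    label: str = ""

    @property
    def size(self) -> int:
        return len(self.probes)


def extract_subclusters(
    dend: Dendrogram,
    expr: ExpressionMatrix,
    r_threshold: float = 0.6,
    min_size: int = 10,
) -> list[Subcluster]:
    """Maximal dendrogram branches with avg pairwise Pearson r >= threshold.

    A node qualifies when its leaf set has >= ``min_size`` members and mean
    off-diagonal correlation >= ``r_threshold``; only qualifying nodes with
    no qualifying ancestor are returned (disjoint by construction), sorted
    by size descending.
    """
    if dend.probe_ids != list(expr.probe_ids):
        expr = expr.subset_probes(dend.probe_ids)
    n = dend.n_leaves
    corr = np.corrcoef(expr.values)
    # pair-sum recursion: per-node sum of correlations over within-node pairs
    colsum: dict[int, np.ndarray] = {}
    pairsum: dict[int, float] = {}
    sizes: dict[int, int] = {}
    member_mask: dict[int, np.ndarray] = {}
    for leaf in range(n):
        colsum[leaf] = corr[leaf].copy()
        pairsum[leaf] = 0.0
        sizes[leaf] = 1
        mask = np.zeros(n, dtype=bool)
        mask[leaf] = True
        member_mask[leaf] = mask
    qualifies: dict[int, float] = {}
    for step, (l, r, _) in enumerate(dend.merges):
        node = n + step
        cross = float(colsum[l][member_mask[r]].sum())
        pairsum[node] = pairsum[l] + pairsum[r] + cross
        colsum[node] = colsum[l] + colsum[r]
        sizes[node] = sizes[l] + sizes[r]
        member_mask[node] = member_mask[l] | member_mask[r]
        k = sizes[node]
        avg_r = pairsum[node] / (k * (k - 1) / 2.0)
        if k >= min_size and avg_r >= r_threshold:
            qualifies[node] = avg_r

    results: list[Subcluster] = []
    root = n + len(dend.merges) - 1

    def collect(node: int) -> None:
        if node in qualifies:
            probes = [dend.probe_ids[i] for i in dend.members(node)]
            results.append(Subcluster(probes, qualifies[node]))
            return
        if node >= n:
            l, r, _ = dend.merges[node - n]
            collect(l)
            collect(r)

    collect(root)
    results.sort(key=lambda sc: (-sc.size, sc.probes[0]))
    for i, sc in enumerate(results, start=1):
        sc.label = f"SC{i}"
    return results


@dataclass
class MetageneDefinition:
    """Named probe list, probe->gene collapse groups and training cut-points."""

    name: str
    probes: list[str]
    collapse_groups: dict[str, list[str]]  # gene symbol -> its probes
    tertile_cutpoints: tuple[float, float] | None = None
    metric: str = "pearson"
    r_threshold: float | None = None
    boundary_rule: str = "ties_to_lower_tertile"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "probes": self.probes,
            "collapse_groups": self.collapse_groups,
            "tertile_cutpoints": list(self.tertile_cutpoints)
            if self.tertile_cutpoints is not None
            else None,
            "metric": self.metric,
            "r_threshold": self.r_threshold,
            "boundary_rule": self.boundary_rule,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MetageneDefinition":
        payload = json.loads(Path(path).read_text())
        cp = payload.get("tertile_cutpoints")
        payload["tertile_cutpoints"] = tuple(cp) if cp is not None else None
        return cls(**payload)

    def score(self, expr: ExpressionMatrix) -> pd.Series:
        """Recompute metagene values on a (possibly different) cohort."""
        return metagene_values(expr, self.collapse_groups, name=self.name)


def metagene_values(
    expr: ExpressionMatrix, collapse_groups: dict[str, list[str]], name: str = "metagene"
) -> pd.Series:
    """Per-sample mean over genes of (mean over that gene's probes)."""
    if not collapse_groups:
        raise ValueError("empty probe list")
    gene_means = []
    for gene, probes in collapse_groups.items():
        idx = expr.probe_index(probes)
        gene_means.append(expr.values[idx].mean(axis=0))
    vals = np.mean(gene_means, axis=0)
    return pd.Series(vals, index=expr.sample_ids, name=name)


def build_metagene(
    expr: ExpressionMatrix,
    probes: list[str],
    probe_map: pd.Series,
    name: str = "metagene",
) -> tuple[pd.Series, MetageneDefinition]:
    """Construct a metagene from a probe subcluster.

    Probes mapping to the same gene symbol are averaged first, then the
    gene-level values are averaged, so multi-probe genes are not
    overrepresented.  Cut-points are left unset until
    :func:`tertile_cutpoints` is applied.
    """
    if not probes:
        raise ValueError("empty probe list")
    missing = [p for p in probes if p not in probe_map.index]
    if missing:
        raise ValueError(f"probes not covered by probe map: {missing[:10]}")
    collapse: dict[str, list[str]] = {}
    for p in probes:
        collapse.setdefault(str(probe_map[p]), []).append(p)
    definition = MetageneDefinition(name=name, probes=list(probes), collapse_groups=collapse)
    values = metagene_values(expr, collapse, name=name)
    return values, definition


def tertile_cutpoints(values) -> tuple[float, float]:
    """Empirical 1/3 and 2/3 quantiles (linear interpolation, 'type 7')."""
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 3:
        raise ValueError("need at least 3 distinct values for tertile cut-points")
    q1, q2 = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0], method="linear")
    if not q1 < q2:
        raise ValueError("degenerate cut-points (q1 == q2)")
    return float(q1), float(q2)


def assign_tertiles(values, cutpoints: tuple[float, float]) -> pd.Series:
    """Code values as tertile levels 1/2/3; boundary ties go to the lower
    tertile (level 1 if v <= q1, 2 if q1 < v <= q2, else 3)."""
    q1, q2 = cutpoints
    if not q1 < q2:
        raise ValueError("cutpoints must satisfy q1 < q2")
    v = np.asarray(values, dtype=float)
    levels = np.where(v <= q1, 1, np.where(v <= q2, 2, 3))
    if isinstance(values, pd.Series):
        return pd.Series(levels, index=values.index, name=values.name)
    return pd.Series(levels)
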