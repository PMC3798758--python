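"""Iterative balanced cohort randomization monitored by standardized
differences and a survival log-rank equivalence criterion.

A candidate half-split is accepted when every monitored variable shows a
standardized difference below ``max_std_diff_pct`` (default 10%) AND the
two-group DMFS log-rank p-value exceeds ``min_logrank_p`` (default 0.99).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .survival import logrank_test

__all__ = [
    "BalanceCriteria",
    "SplitResult",
    "BalanceNotAchievedError",
    "standardized_difference",
    "balanced_split",
]

#: kind of each monitorable clinical variable
VARIABLE_KINDS = {
    "dmfs_time": "continuous",
    "dmfs_event": "binary",
    "study": "categorical",
    "subtype": "categorical",
    "er_status": "categorical",
}


@dataclass
class BalanceCriteria:
    max_std_diff_pct: float = 10.0
    min_logrank_p: float = 0.99
    monitored_variables: list[str] = field(
        default_factory=lambda: ["dmfs_time", "dmfs_event", "study", "subtype", "er_status"]
    )
    max_iterations: int = 10000


@dataclass
class SplitResult:
    group_a_ids: list[str]
    group_b_ids: list[str]
    achieved_std_diffs: dict[str, float]
    logrank_p: float
    iterations_used: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitResult":
        return cls(**json.loads(Path(path).read_text()))


class BalanceNotAchievedError(RuntimeError):
    """Iteration cap reached; carries the best split seen and its diagnostics."""

    def __init__(self, msg: str, best: SplitResult):
        super().__init__(msg)
        self.best = best


def _std_diff_continuous(a: np.ndarray, b: np.ndarray) -> float:
    ma, mb = a.mean(), b.mean()
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    pooled = (va + vb) / 2.0
    if pooled == 0:
        return 0.0 if ma == mb else float("inf")
    return 100.0 * abs(ma - mb) / np.sqrt(pooled)


def _std_diff_binary(a: np.ndarray, b: np.ndarray) -> float:
    pa, pb = a.mean(), b.mean()
    pooled = (pa * (1 - pa) + pb * (1 - pb)) / 2.0
    if pooled == 0:
        return 0.0 if pa == pb else float("inf")
    return 100.0 * abs(pa - pb) / np.sqrt(pooled)


def standardized_difference(group_a_values, group_b_values, kind: str) -> float:
    """Between-group standardized difference, in percent.

    continuous: 100*|mean_a - mean_b| / sqrt((s_a^2 + s_b^2)/2) with sample
    variances; binary: proportions with p(1-p) variances; categorical:
    maximum over per-level binary standardized differences.
    """
    a = np.asarray(group_a_values)
    b = np.asarray(group_b_values)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "continuous":
        return _std_diff_continuous(a.astype(float), b.astype(float))
    if kind == "binary":
        a = a.astype(float)
        b = b.astype(float)
        if not (np.isin(a, [0, 1]).all() and np.isin(b, [0, 1]).all()):
            raise ValueError("binary kind requires 0/1 values")
        return _std_diff_binary(a, b)
    if kind == "categorical":
        levels = np.union1d(np.unique(a), np.unique(b))
        return max(
            _std_diff_binary((a == lev).astype(float), (b == lev).astype(float))
            for lev in levels
        )
    raise ValueError(f"unknown kind {kind!r}")


def _split_diagnostics(
    clinical: pd.DataFrame, ia: np.ndarray, ib: np.ndarray, variables: list[str]
) -> dict[str, float]:
    diffs = {}
    for var in variables:
        kind = VARIABLE_KINDS.get(var, "categorical")
        col = clinical[var].to_numpy()
        diffs[var] = standardized_difference(col[ia], col[ib], kind)
    return diffs


def balanced_split(
    clinical: pd.DataFrame, criteria: BalanceCriteria | None = None, seed: int = 0
) -> SplitResult:
    """Repeat uniform half-splits until all balance criteria are met.

    Returns the first accepted split; raises :class:`BalanceNotAchievedError`
    (carrying the best split found) if ``max_iterations`` is exhausted.  For
    odd n the larger group is chosen at random each iteration.
    """
    criteria = criteria or BalanceCriteria()
    n = len(clinical)
    if n < 2:
        raise ValueError("need at least 2 samples")
    missing = [v for v in criteria.monitored_variables if v not in clinical.columns]
    if missing:
        raise ValueError(f"monitored variables absent from clinical table: {missing}")
    rng = np.random.default_rng(seed)
    ids = clinical["sample_id"].to_numpy()
    times = clinical["dmfs_time"].to_numpy(dtype=float)
    events = clinical["dmfs_event"].to_numpy(dtype=int)
    best: SplitResult | None = None
    best_score = np.inf
    for it in range(1, criteria.max_iterations + 1):
        perm = rng.permutation(n)
        n_a = n // 2
        if n % 2 == 1 and rng.random() < 0.5:
            n_a = n - n // 2
        ia, ib = perm[:n_a], perm[n_a:]
        diffs = _split_diagnostics(clinical, ia, ib, criteria.monitored_variables)
        max_diff = max(diffs.values()) if diffs else 0.0
        if max_diff < criteria.max_std_diff_pct:
            p = logrank_test([(times[ia], events[ia]), (times[ib], events[ib])]).p_value
        else:
            p = float("nan")
        candidate = SplitResult(
            group_a_ids=[str(x) for x in ids[ia]],
            group_b_ids=[str(x) for x in ids[ib]],
            achieved_std_diffs=diffs,
            logrank_p=p,
            iterations_used=it,
            seed=seed,
        )
        if max_diff < criteria.max_std_diff_pct and p > criteria.min_logrank_p:
            return candidate
        # best-so-far: smallest max std diff, log-rank p as tie-breaker
        score = max_diff - (p if np.isfinite(p) else 0.0)
        if score < best_score:
            best_score = score
            best = candidate
    raise BalanceNotAchievedError(
        f"no split met criteria within {criteria.max_iterations} iterations", best
    )
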