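"""Genome-wide per-probe Cox screening with FDR control.

Each probe's log2 expression is used as a single continuous covariate in a
univariable Cox model; significance comes from the likelihood-ratio test and
q-values from Benjamini-Hochberg step-up adjustment (a Storey estimator with
lambda=0.5 is available behind a flag).  Probes pass the screen when
lrt_p < 0.01 AND q < 0.10.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix
from .survival import ConvergenceError, cox_fit

__all__ = ["adjust_fdr", "screen_genes", "select_prognostic"]


def adjust_fdr(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, clipped to 1).

    ``method='storey'`` scales BH values by the pi0 estimate
    min(1, mean(p > 0.5) / 0.5).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam))
        q_sorted = np.minimum(q_sorted * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    q = np.empty(m)
    q[order] = q_sorted
    return q


def screen_genes(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Univariable Cox screen of every probe against DMFS.

    Sample alignment uses the intersection of expression columns and clinical
    ``sample_id``; follow-up is expected to be delimited already.  Constant
    (or non-converging) probes are retained with p=1 and a flag so the
    screen and the downstream BH adjustment see one row per probe.

    Returns a DataFrame indexed by probe with columns: coef, hazard_ratio,
    ci95_low, ci95_high, lrt_p, q_value, direction, flag.
    """
    sample_set = set(expr.sample_ids)
    clin = clinical[clinical["sample_id"].isin(sample_set)]
    if clin.empty:
        raise ValueError("no samples shared between expression and clinical table")
    sub = expr.subset_samples(list(clin["sample_id"]))
    times = clin["dmfs_time"].to_numpy(dtype=float)
    events = clin["dmfs_event"].to_numpy(dtype=int)
    if events.sum() == 0:
        raise ValueError("no events in aligned cohort")

    rows = []
    for i, probe in enumerate(sub.probe_ids):
        x = sub.values[i]
        if np.ptp(x) == 0:
            rows.append((np.nan, np.nan, np.nan, np.nan, 1.0, "none", "constant"))
            continue
        try:
            res = cox_fit(x, times, events, names=[probe])
        except ConvergenceError:
            rows.append((np.nan, np.nan, np.nan, np.nan, 1.0, "none", "nonconverged"))
            continue
        direction = "favorable" if res.coef[0] < 0 else "adverse"
        rows.append(
            (
                float(res.coef[0]),
                float(res.hazard_ratio[0]),
                float(res.ci95_low[0]),
                float(res.ci95_high[0]),
                float(res.lrt_p),
                direction,
                "",
            )
        )
    table = pd.DataFrame(
        rows,
        index=pd.Index(sub.probe_ids, name="probe_id"),
        columns=["coef", "hazard_ratio", "ci95_low", "ci95_high", "lrt_p", "direction", "flag"],
    )
    table["q_value"] = adjust_fdr(table["lrt_p"].to_numpy(), method=fdr_method)
    table.attrs["fdr_method"] = fdr_method
    return table[
        ["coef", "hazard_ratio", "ci95_low", "ci95_high", "lrt_p", "q_value", "direction", "flag"]
    ]


def select_prognostic(
    table: pd.DataFrame, p_thresh: float = 0.01, q_thresh: float = 0.10
) -> list[str]:
    """Probes with lrt_p < p_thresh AND q_value < q_thresh (order preserved)."""
    mask = (table["lrt_p"] < p_thresh) & (table["q_value"] < q_thresh)
    return list(table.index[mask])
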