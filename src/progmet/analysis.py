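"""Proliferation-conditional and subtype-stratified prognostic analyses.

Within each stratum (proliferation tertile, subtype or treatment group) the
immune metagene tertiles are tested by 3-group Kaplan-Meier / log-rank and
by univariable Cox with the tertile level coded ordinally as 1/2/3 (one
hazard ratio per tertile step).  Multivariable models combine metagene
tertiles with conventionally coded clinical covariates.  The combinatorial
classifier summarizes the triple of immune tertiles by counts of low and
high assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import ConvergenceError, CoxResult, KMCurve, cox_fit, km_estimate, logrank_test

__all__ = [
    "StratifiedResult",
    "ImmuneProfile",
    "conditional_analysis",
    "multivariable_models",
    "combinatorial_profile",
    "profile_table",
    "compare_profiles",
    "PROLIF_TERTILE_LABELS",
]

PROLIF_TERTILE_LABELS = {1: "P_L", 2: "P_I", 3: "P_H"}

#: Conventional covariate codings used by the multivariable model.  The
#: direction of every binary coding is stated here rather than guessed:
#: 1 = LN positive, 1 = age <= 40 years, 1 = ER negative, 1 = treated.
CONVENTIONAL_CODINGS = {
    "ln_positive": "ln_status: negative=0, positive=1",
    "tumor_size": "tumor_size_class: T1=1, T2=2, T3=3 (ordinal)",
    "grade": "grade: 1/2/3 (ordinal)",
    "age_le_40": "age_years: >40=0, <=40=1",
    "er_negative": "er_status: positive=0, negative=1",
    "treated": "treatment: none=0, tamoxifen or chemotherapy=1",
}


@dataclass
class StratifiedResult:
    """Survival analysis of one metagene's tertiles within one stratum."""

    stratum: dict
    metagene: str
    n: int
    n_events: int
    skipped: bool = False
    reason: str = ""
    km_curves: list[KMCurve] = field(default_factory=list)
    logrank_chi2: float = float("nan")
    logrank_p: float = float("nan")
    cox: CoxResult | None = None

    @property
    def hazard_ratio(self) -> float:
        return float("nan") if self.cox is None else float(self.cox.hazard_ratio[0])

    def summary_row(self) -> dict:
        row = {
            **{f"stratum_{k}": v for k, v in self.stratum.items()},
            "metagene": self.metagene,
            "n": self.n,
            "n_events": self.n_events,
            "skipped": self.skipped,
            "reason": self.reason,
            "logrank_p": self.logrank_p,
        }
        if self.cox is not None:
            row.update(
                hazard_ratio=float(self.cox.hazard_ratio[0]),
                ci95_low=float(self.cox.ci95_low[0]),
                ci95_high=float(self.cox.ci95_high[0]),
                cox_lrt_p=self.cox.lrt_p,
            )
        return row


def _aligned_frame(tertiles: dict[str, pd.Series], clinical: pd.DataFrame) -> pd.DataFrame:
    df = clinical.set_index("sample_id", drop=False)
    for name, levels in tertiles.items():
        df[f"tertile_{name}"] = pd.Series(levels)
    df = df.dropna(subset=[f"tertile_{n}" for n in tertiles])
    for name in tertiles:
        df[f"tertile_{name}"] = df[f"tertile_{name}"].astype(int)
    return df


def _strata_labels(df: pd.DataFrame, strata_by: str, prolif_name: str) -> pd.Series:
    if strata_by == "proliferation_tertile":
        return df[f"tertile_{prolif_name}"].map(PROLIF_TERTILE_LABELS)
    if strata_by == "subtype":
        if "subtype" not in df.columns:
            raise KeyError("clinical table has no subtype column")
        return df["subtype"]
    if strata_by == "treatment":
        return df["treatment"]
    raise KeyError(f"unknown stratum key {strata_by!r}")


def _analyze_stratum(sub: pd.DataFrame, metagene: str, stratum: dict, min_n: int) -> StratifiedResult:
    levels = sub[f"tertile_{metagene}"]
    n = len(sub)
    n_events = int(sub["dmfs_event"].sum())
    res = StratifiedResult(stratum=stratum, metagene=metagene, n=n, n_events=n_events)
    if n < min_n:
        res.skipped, res.reason = True, f"n={n} < min_n={min_n}"
        return res
    if n_events == 0:
        res.skipped, res.reason = True, "no events"
        return res
    present = sorted(levels.unique())
    if len(present) < 2:
        res.skipped, res.reason = True, "single tertile level present"
        return res
    groups = []
    for lev in present:
        g = sub[levels == lev]
        res.km_curves.append(
            km_estimate(g["dmfs_time"], g["dmfs_event"], group_label=f"{metagene}={lev}")
        )
        groups.append((g["dmfs_time"].to_numpy(), g["dmfs_event"].to_numpy()))
    lr = logrank_test(groups)
    res.logrank_chi2, res.logrank_p = lr.chi2, lr.p_value
    try:
        res.cox = cox_fit(
            levels.to_numpy(dtype=float),
            sub["dmfs_time"].to_numpy(),
            sub["dmfs_event"].to_numpy(),
            names=[f"{metagene} (L,I,H)"],
        )
    except (ConvergenceError, ValueError) as exc:
        res.reason = f"cox failed: {exc}"
    return res


def conditional_analysis(
    metagene_tertiles: dict[str, pd.Series],
    clinical: pd.DataFrame,
    strata_by: str = "proliferation_tertile",
    prolif_name: str = "proliferation",
    min_n: int = 10,
) -> list[StratifiedResult]:
    """Per-stratum KM/log-rank and ordinal Cox for each immune metagene.

    ``metagene_tertiles`` maps metagene name -> per-sample tertile levels
    (1/2/3) and must include ``prolif_name`` when stratifying by
    proliferation tertile.  Strata with fewer than ``min_n`` samples or no
    events are reported as skipped with a reason rather than dropped.
    """
    if strata_by == "proliferation_tertile" and prolif_name not in metagene_tertiles:
        raise KeyError(f"tertiles for {prolif_name!r} required to stratify by proliferation")
    df = _aligned_frame(metagene_tertiles, clinical)
    if df.empty:
        raise ValueError("no samples with complete tertile assignments")
    labels = _strata_labels(df, strata_by, prolif_name)
    immune = [m for m in metagene_tertiles if m != prolif_name]
    results = []
    for stratum_value in sorted(labels.unique()):
        sub = df[labels == stratum_value]
        for metagene in immune:
            results.append(
                _analyze_stratum(sub, metagene, {strata_by: stratum_value}, min_n)
            )
    return results


def _conventional_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Complete-case conventional covariates, coded per CONVENTIONAL_CODINGS."""
    known = (
        (df["ln_status"] != "unknown")
        & (df["tumor_size_class"] != "unknown")
        & (df["grade"] != "unknown")
        & df["age_years"].notna()
        & (df["er_status"] != "unknown")
        & (df["treatment"] != "unknown")
    )
    d = df[known]
    return pd.DataFrame(
        {
            "ln_positive": (d["ln_status"] == "positive").astype(float),
            "tumor_size": d["tumor_size_class"].map({"T1": 1.0, "T2": 2.0, "T3": 3.0}),
            "grade": d["grade"].astype(float),
            "age_le_40": (d["age_years"] <= 40).astype(float),
            "er_negative": (d["er_status"] == "negative").astype(float),
            "treated": (d["treatment"] != "none").astype(float),
        },
        index=d.index,
    )


def multivariable_models(
    metagene_tertiles: dict[str, pd.Series],
    clinical: pd.DataFrame,
    metagenes: list[str] | None = None,
    prolif_name: str = "proliferation",
    stratum_level: int = 3,
    include_conventional: bool = False,
) -> dict[str, CoxResult]:
    """Multivariable Cox models of metagene tertiles within one
    proliferation stratum (default: the high tertile).

    Without conventional covariates, fits the pairwise combinations of the
    three immune metagenes (models 1-3) and all three jointly (model 4).
    With ``include_conventional=True``, fits a single combined model of the
    three metagenes plus LN status, tumor size, grade, age, ER status and
    treatment on complete cases.  Tertiles enter ordinally as 1/2/3.
    """
    if metagenes is None:
        metagenes = [m for m in metagene_tertiles if m != prolif_name]
    if len(metagenes) != 3:
        raise ValueError("expected exactly 3 immune metagenes")
    df = _aligned_frame(metagene_tertiles, clinical)
    if prolif_name in metagene_tertiles:
        df = df[df[f"tertile_{prolif_name}"] == stratum_level]
    if df.empty:
        raise ValueError("stratum is empty")
    times = "dmfs_time"
    events = "dmfs_event"

    def fit(cov_df: pd.DataFrame, d: pd.DataFrame) -> CoxResult:
        if d[events].sum() == 0:
            raise ValueError("no events")
        res = cox_fit(cov_df, d[times].to_numpy(), d[events].to_numpy())
        res.meta["codings"] = dict(CONVENTIONAL_CODINGS)
        res.meta["tertile_coding"] = "low=1, intermediate=2, high=3 (ordinal)"
        return res

    out: dict[str, CoxResult] = {}
    if include_conventional:
        conv = _conventional_covariates(df)
        d = df.loc[conv.index]
        cov = pd.concat(
            [d[[f"tertile_{m}" for m in metagenes]].astype(float), conv], axis=1
        )
        cov.columns = [f"{m} (L,I,H)" for m in metagenes] + list(conv.columns)
        out["conventional"] = fit(cov, d)
        return out

    pairs = [
        (metagenes[0], metagenes[1]),
        (metagenes[0], metagenes[2]),
        (metagenes[1], metagenes[2]),
    ]
    for i, combo in enumerate([*pairs, tuple(metagenes)], start=1):
        cov = df[[f"tertile_{m}" for m in combo]].astype(float)
        cov.columns = [f"{m} (L,I,H)" for m in combo]
        out[f"model_{i}"] = fit(cov, df)
    return out


@dataclass(frozen=True)
class ImmuneProfile:
    """Triple of immune-metagene tertile levels and its combinatorial class."""

    levels: tuple[int, int, int]
    n_low: int
    n_high: int
    group: str


def combinatorial_profile(levels: tuple[int, int, int]) -> ImmuneProfile:
    """Classify a triple of tertile levels (order-invariant).

    Priority: all_high > two_high_plus_intermediate > two_high_plus_low >
    ge1_low > one_high > all_intermediate.
    """
    if len(levels) != 3 or any(l not in (1, 2, 3) for l in levels):
        raise ValueError(f"levels must be a triple from {{1,2,3}}, got {levels!r}")
    n_low = sum(1 for l in levels if l == 1)
    n_high = sum(1 for l in levels if l == 3)
    if n_high == 3:
        group = "all_high"
    elif n_high == 2 and n_low == 0:
        group = "two_high_plus_intermediate"
    elif n_high == 2 and n_low == 1:
        group = "two_high_plus_low"
    elif n_low >= 1:
        group = "ge1_low"
    elif n_high == 1:
        group = "one_high"
    else:
        group = "all_intermediate"
    return ImmuneProfile(tuple(int(l) for l in levels), n_low, n_high, group)


def profile_table(metagene_tertiles: dict[str, pd.Series], metagenes: list[str]) -> pd.DataFrame:
    """Per-sample combinatorial profile over three immune metagenes."""
    if len(metagenes) != 3:
        raise ValueError("expected exactly 3 immune metagenes")
    aligned = pd.concat([metagene_tertiles[m].rename(m) for m in metagenes], axis=1).dropna()
    rows = []
    for sid, row in aligned.iterrows():
        prof = combinatorial_profile(tuple(int(v) for v in row))
        rows.append((sid, *prof.levels, prof.n_low, prof.n_high, prof.group))
    return pd.DataFrame(
        rows, columns=["sample_id", *metagenes, "n_low", "n_high", "group"]
    ).set_index("sample_id")


#: Named groupings for profile comparisons (ordered; first match wins).
PROFILE_GROUPINGS: dict[str, dict[str, callable]] = {
    "all_high_vs_rest": {
        "all_high": lambda p: p["group"] == "all_high",
        "rest": lambda p: True,
    },
    "n_low": {
        "one_low": lambda p: p["n_low"] == 1,
        "two_low": lambda p: p["n_low"] == 2,
        "three_low": lambda p: p["n_low"] == 3,
    },
    "high_count_no_low": {
        "all_high": lambda p: p["n_low"] == 0 and p["n_high"] == 3,
        "two_high": lambda p: p["n_low"] == 0 and p["n_high"] == 2,
        "one_high": lambda p: p["n_low"] == 0 and p["n_high"] == 1,
    },
    "all_high_vs_ge1_low": {
        "all_high": lambda p: p["group"] == "all_high",
        "ge1_low": lambda p: p["n_low"] >= 1,
    },
}


def compare_profiles(
    profiles: pd.DataFrame,
    clinical: pd.DataFrame,
    grouping: str | dict = "all_high_vs_rest",
    stratum_mask: pd.Series | None = None,
) -> StratifiedResult:
    """KM + log-rank across named profile groups (optionally within a
    stratum given as a boolean mask over sample ids)."""
    if isinstance(grouping, str):
        try:
            grouping = PROFILE_GROUPINGS[grouping]
        except KeyError:
            raise KeyError(f"unknown grouping {grouping!r}") from None
    if len(grouping) < 2:
        raise ValueError("grouping must define at least 2 groups")
    clin = clinical.set_index("sample_id", drop=False)
    shared = profiles.index.intersection(clin.index)
    if stratum_mask is not None:
        shared = shared.intersection(stratum_mask[stratum_mask].index)
    prof = profiles.loc[shared]
    clin = clin.loc[shared]
    assignment = pd.Series(pd.NA, index=shared, dtype=object)
    for name, predicate in grouping.items():
        unset = assignment.isna()
        if not unset.any():
            break
        hits = prof[unset].apply(predicate, axis=1)
        assignment.loc[hits[hits].index] = name
    groups, km_curves = [], []
    for name in grouping:
        members = assignment[assignment == name].index
        if len(members) == 0:
            raise ValueError(f"profile group {name!r} is empty after restriction")
        g = clin.loc[members]
        groups.append((g["dmfs_time"].to_numpy(), g["dmfs_event"].to_numpy()))
        km_curves.append(km_estimate(g["dmfs_time"], g["dmfs_event"], group_label=name))
    lr = logrank_test(groups)
    assigned = assignment[assignment.notna()].index
    n = len(assigned)
    n_events = int(clin.loc[assigned, "dmfs_event"].sum())
    return StratifiedResult(
        stratum={"grouping": ",".join(grouping)},
        metagene="immune_profile",
        n=n,
        n_events=n_events,
        km_curves=km_curves,
        logrank_chi2=lr.chi2,
        logrank_p=lr.p_value,
    )
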