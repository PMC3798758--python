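"""Synthetic multi-study expression + survival cohorts with planted
proliferation and immune latent structure.

The generator plants four gene modules (proliferation, B/P-like, T/NK-like,
M/D-like) driven by latent factors.  The three immune factors share a common
component u: f_k = a*u + sqrt(1-a^2)*eps_k with a = sqrt(rho), so every
pairwise immune-factor correlation equals ``immune_intercorrelation``.
Survival times are exponential given covariates, with the immune log-hazard
effect active only in the top (and optionally bottom) proliferation tertile
of the latent proliferation factor -- the conditional structure the analysis
pipeline is designed to detect.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_io import ExpressionMatrix
from .cluster import tertile_cutpoints, assign_tertiles
from .subtype import CentroidSet

__all__ = [
    "SimConfig",
    "GroundTruth",
    "MODULE_NAMES",
    "simulate_cohort",
    "simulate_null_cohort",
    "probe_map_for",
    "make_centroid_set",
    "simulate_from_centroids",
]

MODULE_NAMES = ("proliferation", "bp", "tnk", "md")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Effect sizes are chosen for test power, not to mimic any real cohort.
    ``beta_immune_high`` applies per immune factor only to samples in the top
    proliferation tertile; ``beta_immune_low`` (default 0) to the bottom one.
    """

    n_samples: int = 800
    n_studies: int = 4
    n_genes_total: int = 2000
    module_sizes: tuple[int, int, int, int] = (40, 30, 25, 25)
    probe_redundancy_rate: float = 0.2
    within_module_loading: float = 2.0
    immune_intercorrelation: float = 0.3
    batch_sd: float = 0.3
    noise_sd: float = 1.0
    baseline_hazard_rate: float = 0.1
    beta_prolif: float = 0.6
    beta_immune_high: float = -1.0
    beta_immune_low: float = 0.0
    censor_rate: float = 0.05
    followup_horizon: float = 10.0
    seed: int = 0
    # clinical covariate dependency strengths
    er_negative_logit_base: float = -1.4
    er_negative_logit_slope: float = 1.0
    unknown_rate: float = 0.05

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if len(self.module_sizes) != 4 or any(s <= 0 for s in self.module_sizes):
            raise ValueError("module_sizes must be 4 positive counts")
        if sum(self.module_sizes) > self.n_genes_total:
            raise ValueError("module sizes exceed total gene count")
        if not 0.0 <= self.immune_intercorrelation < 1.0:
            raise ValueError("immune_intercorrelation must be in [0, 1)")
        for name in ("batch_sd", "noise_sd", "censor_rate", "baseline_hazard_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.probe_redundancy_rate <= 1.0:
            raise ValueError("probe_redundancy_rate must be in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["module_sizes"] = list(d["module_sizes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "module_sizes" in d:
            d["module_sizes"] = tuple(d["module_sizes"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure: gene module labels, latent factors, true tertiles."""

    gene_modules: pd.Series  # gene symbol -> module name (module genes only)
    factors: pd.DataFrame  # samples x 4 latent factors
    true_prolif_tertile: pd.Series  # sample -> 1/2/3
    study: pd.Series

    def module_probes(self, probe_map: pd.Series, module: str) -> list[str]:
        genes = set(self.gene_modules[self.gene_modules == module].index)
        return [p for p, g in probe_map.items() if g in genes]

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.gene_modules.rename_axis("gene_symbol").rename("module").to_frame().to_csv(
            f"{prefix}_gene_modules.tsv", sep="\t"
        )
        truth = self.factors.copy()
        truth["true_prolif_tertile"] = self.true_prolif_tertile
        truth["study"] = self.study
        truth.rename_axis("sample_id").to_csv(f"{prefix}_samples.tsv", sep="\t", float_format="%.12g")


def _draw_survival(rng, log_hazard, base_rate, censor_rate, horizon):
    """Exponential event times with exponential + administrative censoring."""
    n = log_hazard.size
    rate = base_rate * np.exp(log_hazard)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def _clinical_covariates(rng, config, f_P, er_negative):
    n = f_P.size
    ln = np.where(rng.random(n) < 0.25, "positive", "negative")
    size_latent = 0.5 * f_P + rng.normal(size=n)
    size = np.select([size_latent < 0.6, size_latent < 1.8], ["T1", "T2"], default="T3")
    grade_latent = 0.8 * f_P + rng.normal(size=n)
    grade = np.select([grade_latent < -0.5, grade_latent < 0.7], ["1", "2"], default="3")
    age = np.round(rng.normal(56, 12, size=n)).clip(25, 90)
    treatment = np.full(n, "none", dtype=object)
    treat_draw = rng.random(n)
    treatment[(~er_negative) & (treat_draw < 0.45)] = "tamoxifen"
    treatment[er_negative & (treat_draw < 0.4)] = "chemotherapy"
    return ln, size, grade, age, treatment


def _subtypes(rng, f_P, er_negative):
    """Crude intrinsic-subtype labels correlated with ER and proliferation."""
    n = f_P.size
    out = np.empty(n, dtype=object)
    u = rng.random(n)
    high = f_P > np.quantile(f_P, 2 / 3)
    for i in range(n):
        if er_negative[i]:
            if high[i]:
                out[i] = "Basal" if u[i] < 0.7 else ("HER2-E" if u[i] < 0.9 else "Claudin-Low")
            else:
                out[i] = "Basal" if u[i] < 0.5 else ("Claudin-Low" if u[i] < 0.7 else "HER2-E")
        else:
            if high[i]:
                out[i] = "LumB" if u[i] < 0.7 else ("HER2-E" if u[i] < 0.85 else "LumA")
            else:
                out[i] = "LumA" if u[i] < 0.7 else "LumB"
    return out


def _apply_unknowns(rng, rate, *arrays):
    out = []
    for a in arrays:
        a = a.astype(object).copy()
        a[rng.random(a.size) < rate] = "unknown"
        out.append(a)
    return out


def simulate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate (expression, clinical, ground truth) for one synthetic cohort.

    Probe ids follow the pattern ``<gene>_p1`` / ``<gene>_p2``; use
    :func:`probe_map_for` to recover the probe->gene map.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # latent factors
    f_P = rng.normal(size=n)
    a = np.sqrt(config.immune_intercorrelation)
    u = rng.normal(size=n)
    eps = rng.normal(size=(3, n))
    immune = a * u + np.sqrt(1.0 - a * a) * eps
    factors = pd.DataFrame(
        {"proliferation": f_P, "bp": immune[0], "tnk": immune[1], "md": immune[2]},
        index=sample_ids,
    )

    # gene-level signal
    n_genes = config.n_genes_total
    gene_symbols = [f"G{g:05d}" for g in range(n_genes)]
    module_of = np.full(n_genes, "", dtype=object)
    start = 0
    for mname, msize in zip(MODULE_NAMES, config.module_sizes):
        module_of[start : start + msize] = mname
        start += msize
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    study = rng.integers(config.n_studies, size=n)
    study_labels = np.array([f"study_{s + 1}" for s in study], dtype=object)
    batch = rng.normal(0.0, config.batch_sd, size=(n_genes, config.n_studies))
    G = baseline[:, None] + batch[:, study]
    for k, mname in enumerate(MODULE_NAMES):
        rows = np.flatnonzero(module_of == mname)
        G[rows] += config.within_module_loading * factors.iloc[:, k].to_numpy()[None, :]

    # probe level: every gene gets probe 1; a seeded fraction gets probe 2
    second = rng.random(n_genes) < config.probe_redundancy_rate
    probe_ids = [f"{g}_p1" for g in gene_symbols] + [
        f"{gene_symbols[i]}_p2" for i in np.flatnonzero(second)
    ]
    gene_rows = np.concatenate([np.arange(n_genes), np.flatnonzero(second)])
    values = G[gene_rows] + rng.normal(0.0, config.noise_sd, size=(len(probe_ids), n))
    expr = ExpressionMatrix(probe_ids, sample_ids, values)

    # true proliferation tertile on the latent factor (population terciles)
    cuts = tertile_cutpoints(f_P)
    tert = assign_tertiles(pd.Series(f_P, index=sample_ids), cuts)
    immune_sum = immune.sum(axis=0)
    log_hazard = config.beta_prolif * f_P
    log_hazard = log_hazard + np.where(tert.to_numpy() == 3, config.beta_immune_high * immune_sum, 0.0)
    log_hazard = log_hazard + np.where(tert.to_numpy() == 1, config.beta_immune_low * immune_sum, 0.0)
    time, event = _draw_survival(
        rng, log_hazard, config.baseline_hazard_rate, config.censor_rate, config.followup_horizon
    )

    er_negative = rng.random(n) < _sigmoid(
        config.er_negative_logit_base + config.er_negative_logit_slope * f_P
    )
    ln, size, grade, age, treatment = _clinical_covariates(rng, config, f_P, er_negative)
    subtype = _subtypes(rng, f_P, er_negative)
    er = np.where(er_negative, "negative", "positive").astype(object)
    er, ln, size, grade = _apply_unknowns(rng, config.unknown_rate, er, ln, size, grade)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "dmfs_time": time,
            "dmfs_event": event,
            "er_status": er,
            "ln_status": ln,
            "tumor_size_class": size,
            "grade": grade,
            "age_years": age,
            "treatment": treatment,
            "study": study_labels,
            "subtype": subtype,
        }
    )
    truth = GroundTruth(
        gene_modules=pd.Series(
            module_of[module_of != ""], index=np.array(gene_symbols)[module_of != ""]
        ),
        factors=factors,
        true_prolif_tertile=tert,
        study=pd.Series(study_labels, index=sample_ids),
    )
    return expr, clinical, truth


def probe_map_for(expr: ExpressionMatrix) -> pd.Series:
    """Probe->gene map implied by the simulator's ``<gene>_p<k>`` probe ids."""
    genes = [p.rsplit("_p", 1)[0] for p in expr.probe_ids]
    return pd.Series(genes, index=expr.probe_ids, name="gene_symbol")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_null_cohort(
    config: SimConfig,
    n_null: int = 450,
    n_alt: int = 50,
    effect_per_sd: float = 0.5,
    alt_loading: float = 0.9,
) -> tuple[ExpressionMatrix, pd.DataFrame, list[str]]:
    """Cohort where a designated probe set is survival-associated and the
    rest are null, for FDR-control checks.

    Alternative probes load on a single latent risk factor f ~ N(0,1):
    x_g = alt_loading*f + sqrt(1-alt_loading^2)*noise, and the log hazard is
    ``effect_per_sd * f``; null probes are independent N(baseline, 1).
    Returns (expression, clinical, alt_probe_ids).
    """
    config.validate()
    if n_null < 0 or n_alt < 0:
        raise ValueError("probe counts must be >= 0")
    if n_null + n_alt == 0:
        raise ValueError("empty design: no null and no alternative probes")
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    f = rng.normal(size=n)
    probe_ids = [f"alt{k:04d}" for k in range(n_alt)] + [f"null{k:04d}" for k in range(n_null)]
    values = np.empty((n_alt + n_null, n))
    if n_alt:
        values[:n_alt] = alt_loading * f[None, :] + np.sqrt(1 - alt_loading**2) * rng.normal(
            size=(n_alt, n)
        )
    if n_null:
        values[n_alt:] = rng.normal(size=(n_null, n))
    values += rng.normal(8.0, 1.0, size=(n_alt + n_null, 1))
    expr = ExpressionMatrix(probe_ids, sample_ids, values)
    time, event = _draw_survival(
        rng,
        effect_per_sd * f,
        config.baseline_hazard_rate,
        config.censor_rate,
        config.followup_horizon,
    )
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "dmfs_time": time,
            "dmfs_event": event,
            "er_status": "unknown",
            "ln_status": "unknown",
            "tumor_size_class": "unknown",
            "grade": "unknown",
            "age_years": np.nan,
            "treatment": "unknown",
            "study": "study_1",
        }
    )
    return expr, clinical, probe_ids[:n_alt]


def make_centroid_set(
    n_genes: int = 50, subtypes: tuple[str, ...] = ("LumA", "LumB", "Basal", "HER2-E"), seed: int = 0
) -> CentroidSet:
    """Random orthogonal-ish centroid set for classifier tests (plumbing)."""
    rng = np.random.default_rng(seed)
    genes = [f"G{g:05d}" for g in range(n_genes)]
    matrix = rng.normal(size=(n_genes, len(subtypes)))
    matrix -= matrix.mean(axis=0, keepdims=True)
    return CentroidSet(genes, list(subtypes), matrix)


def simulate_from_centroids(
    centroids: CentroidSet, n_per_subtype: int = 20, noise_sd: float = 0.5, seed: int = 0
) -> tuple[ExpressionMatrix, pd.Series, pd.Series]:
    """Samples generated as centroid + Gaussian noise.

    Returns (probe-level expression with one probe per gene, probe_map,
    true subtype labels per sample).
    """
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for name in centroids.subtype_names:
        j = centroids.subtype_names.index(name)
        base = centroids.matrix[:, j]
        for _ in range(n_per_subtype):
            cols.append(base + rng.normal(0.0, noise_sd, size=base.size))
            labels.append(name)
    values = np.array(cols).T
    sample_ids = [f"S{i:04d}" for i in range(values.shape[1])]
    probe_ids = [f"{g}_p1" for g in centroids.gene_symbols]
    expr = ExpressionMatrix(probe_ids, sample_ids, values)
    probe_map = pd.Series(centroids.gene_symbols, index=probe_ids, name="gene_symbol")
    return expr, probe_map, pd.Series(labels, index=sample_ids, name="subtype")
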