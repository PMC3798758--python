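"""End-to-end orchestration: delimit follow-up, balanced split, per-half gene
screening, clustering, metagene construction, cross-applied tertiles and the
conditional prognostic analyses.  Every stage writes its artifact and the run
manifest records seeds, thresholds and per-stage counts."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    conditional_analysis,
    multivariable_models,
    profile_table,
    compare_profiles,
)
from .cluster import (
    Subcluster,
    assign_tertiles,
    build_metagene,
    extract_subclusters,
    hcluster,
    tertile_cutpoints,
)
from .cohort_io import (
    delimit_followup,
    read_clinical,
    read_expression,
    read_probe_map,
    write_clinical,
    write_expression,
    write_probe_map,
)
from .randomization import BalanceCriteria, balanced_split
from .selection import screen_genes, select_prognostic
from .simulate import SimConfig, simulate_cohort, probe_map_for
from .subtype import read_centroids, ssp_classify, claudin_low_classify, combine_subtype_calls

log = logging.getLogger("progmet")


@dataclass
class PipelineConfig:
    """Single-config driver for `run_pipeline` / the `run-all` CLI command."""

    output_dir: str = "progmet_run"
    # inputs: either file paths, or synthetic=True with a SimConfig
    synthetic: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    expression_path: str | None = None
    clinical_path: str | None = None
    probe_map_path: str | None = None
    centroids_path: str | None = None
    cl_centroids_path: str | None = None
    # thresholds
    horizon_years: float = 10.0
    p_thresh: float = 0.01
    q_thresh: float = 0.10
    r_threshold: float = 0.6
    min_size: int = 10
    min_corr: float = 0.1
    max_std_diff_pct: float = 10.0
    min_logrank_p: float = 0.99
    max_iterations: int = 10000
    min_n: int = 10
    seed: int = 0
    per_study_center: bool = False  # plumbing hook, not batch correction

    def validate(self) -> None:
        if not 0 <= self.p_thresh <= 1 or not 0 <= self.q_thresh <= 1:
            raise ValueError("p/q thresholds must be in [0, 1]")
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must be in (0, 1)")
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")
        if not self.synthetic:
            for p in (self.expression_path, self.clinical_path, self.probe_map_path):
                if p is None:
                    raise ValueError("file inputs require expression, clinical and probe map paths")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sim"]["module_sizes"] = list(d["sim"]["module_sizes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("sim", None)
        cfg = cls(**d)
        if sim is not None:
            sim["module_sizes"] = tuple(sim.get("module_sizes", SimConfig().module_sizes))
            cfg.sim = SimConfig(**sim)
        return cfg


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


def _per_study_center(expr, clinical):
    """Subtract per-study probe means (plumbing hook; not batch correction)."""
    vals = expr.values.copy()
    sample_study = clinical.set_index("sample_id")["study"]
    studies = sample_study.loc[expr.sample_ids].to_numpy()
    for s in np.unique(studies):
        cols = np.flatnonzero(studies == s)
        vals[:, cols] -= vals[:, cols].mean(axis=1, keepdims=True)
    from .cohort_io import ExpressionMatrix

    return ExpressionMatrix(list(expr.probe_ids), list(expr.sample_ids), vals)


def _match_modules(subclusters: list[Subcluster], probe_map, truth) -> dict[str, str]:
    """Map each subcluster label to the dominant planted module (or '')."""
    out = {}
    for sc in subclusters:
        genes = [probe_map[p] for p in sc.probes]
        modules = [truth.gene_modules.get(g, "") for g in genes]
        counts = pd.Series([m for m in modules if m]).value_counts()
        out[sc.label] = counts.index[0] if len(counts) and counts.iloc[0] >= sc.size / 2 else ""
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written to
    ``<output_dir>/manifest.json``)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in {"sim", "output_dir"}
        },
        "stages": {},
        "codings": {
            "tertiles": "low=1, intermediate=2, high=3; boundary ties to lower tertile",
            "cox_ties": "breslow",
        },
    }

    # ------------------------------------------------------ inputs
    if config.synthetic:
        expr, clinical, truth = simulate_cohort(config.sim)
        probe_map = probe_map_for(expr)
        write_expression(expr, out / "expression.tsv")
        write_clinical(clinical, out / "clinical.tsv")
        write_probe_map(probe_map, out / "probe_map.tsv")
        truth.write(out / "truth")
        manifest["stages"]["simulate"] = {
            "n_samples": expr.n_samples,
            "n_probes": expr.n_probes,
            "sim_seed": config.sim.seed,
        }
    else:
        expr = read_expression(config.expression_path)
        clinical = read_clinical(config.clinical_path)
        probe_map = read_probe_map(config.probe_map_path)
        truth = None
    if config.per_study_center:
        expr = _per_study_center(expr, clinical)

    # ------------------------------------------------------ follow-up window
    clinical = delimit_followup(clinical, config.horizon_years)
    manifest["stages"]["delimit_followup"] = {
        "horizon_years": config.horizon_years,
        "n_events": int(clinical["dmfs_event"].sum()),
    }

    # ------------------------------------------------------ balanced split
    criteria = BalanceCriteria(
        max_std_diff_pct=config.max_std_diff_pct,
        min_logrank_p=config.min_logrank_p,
        monitored_variables=[
            v
            for v in ["dmfs_time", "dmfs_event", "study", "subtype", "er_status"]
            if v in clinical.columns
        ],
        max_iterations=config.max_iterations,
    )
    split = balanced_split(clinical, criteria, seed=config.seed)
    split.to_json(out / "split.json")
    manifest["stages"]["balanced_split"] = {
        "iterations_used": split.iterations_used,
        "max_std_diff_pct": max(split.achieved_std_diffs.values()),
        "logrank_p": split.logrank_p,
    }

    halves = {"A": split.group_a_ids, "B": split.group_b_ids}
    clin_by = {
        h: clinical[clinical["sample_id"].isin(ids)].reset_index(drop=True)
        for h, ids in halves.items()
    }
    expr_by = {h: expr.subset_samples(ids) for h, ids in halves.items()}

    # ------------------------------------------------------ subtype calls
    if config.centroids_path:
        centroids = read_centroids(config.centroids_path)
        calls = ssp_classify(expr, probe_map, centroids, min_corr=config.min_corr)
        if config.cl_centroids_path:
            cl = claudin_low_classify(expr, probe_map, read_centroids(config.cl_centroids_path))
            combined = combine_subtype_calls(calls, cl)
        else:
            combined = calls["subtype"]
        calls.to_csv(out / "subtype_calls.tsv", sep="\t", float_format="%.12g")
        clinical = clinical.drop(columns=["subtype"], errors="ignore").merge(
            combined.rename("subtype").rename_axis("sample_id").reset_index(), on="sample_id", how="left"
        )
        manifest["stages"]["subtype"] = {
            "n_unassigned": int((combined == "UNASSIGNED").sum())
        }

    # ------------------------------------------------------ two-way train/test
    results_summary = {}
    for train, test in (("A", "B"), ("B", "A")):
        tag = f"train{train}_test{test}"
        tdir = out / tag
        tdir.mkdir(exist_ok=True)
        # 1. screen genes on the training half
        table = screen_genes(expr_by[train], clin_by[train])
        table.to_csv(tdir / "gene_screen.tsv", sep="\t", float_format="%.6g")
        selected = select_prognostic(table, config.p_thresh, config.q_thresh)
        if not selected:
            raise PipelineError("select_prognostic", f"no probes selected in half {train}")
        if len(selected) < 2:
            raise PipelineError("hcluster", f"only {len(selected)} probe selected in half {train}")
        # 2. cluster and extract subclusters
        train_sel = expr_by[train].subset_probes(selected)
        dend = hcluster(train_sel, metric="pearson")
        (tdir / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
        subclusters = extract_subclusters(dend, train_sel, config.r_threshold, config.min_size)
        module_match = _match_modules(subclusters, probe_map, truth) if truth is not None else {}
        with open(tdir / "subclusters.json", "w") as fh:
            json.dump(
                [
                    {
                        "label": sc.label,
                        "size": sc.size,
                        "average_pairwise_correlation": sc.average_pairwise_correlation,
                        "matched_module": module_match.get(sc.label, ""),
                        "probes": sc.probes,
                    }
                    for sc in subclusters
                ],
                fh,
                indent=2,
            )
        # 3. metagenes + training cut-points, applied to the held-out half
        tertiles_train: dict[str, pd.Series] = {}
        tertiles_test: dict[str, pd.Series] = {}
        name_of = {}
        for sc in subclusters:
            name = module_match.get(sc.label) or sc.label
            if name in name_of.values():
                name = f"{name}_{sc.label}"
            name_of[sc.label] = name
            vals_train, definition = build_metagene(expr_by[train], sc.probes, probe_map, name)
            definition.r_threshold = config.r_threshold
            definition.tertile_cutpoints = tertile_cutpoints(vals_train)
            definition.to_json(tdir / f"metagene_{name}.json")
            vals_test = definition.score(expr_by[test])
            tertiles_train[name] = assign_tertiles(vals_train, definition.tertile_cutpoints)
            tertiles_test[name] = assign_tertiles(vals_test, definition.tertile_cutpoints)
        pd.DataFrame(tertiles_test).rename_axis("sample_id").to_csv(
            tdir / "tertiles_test.tsv", sep="\t"
        )
        stage = {
            "n_selected": len(selected),
            "n_subclusters": len(subclusters),
            "subcluster_sizes": [sc.size for sc in subclusters],
            "matched_modules": sorted(m for m in module_match.values() if m),
        }
        # 4. conditional analysis on the held-out half
        immune = [n for n in tertiles_test if n != "proliferation"]
        if "proliferation" in tertiles_test and immune:
            cond = conditional_analysis(
                tertiles_test, clin_by[test], "proliferation_tertile", min_n=config.min_n
            )
            pd.DataFrame([r.summary_row() for r in cond]).to_csv(
                tdir / "conditional_analysis.tsv", sep="\t", index=False, float_format="%.6g"
            )
            stage["conditional_strata"] = len(cond)
            if len(immune) >= 3:
                try:
                    models = multivariable_models(
                        tertiles_test, clin_by[test], metagenes=immune[:3]
                    )
                    with open(tdir / "multivariable.json", "w") as fh:
                        json.dump(
                            {
                                name: json.loads(res.to_frame().to_json(orient="index"))
                                for name, res in models.items()
                            },
                            fh,
                            indent=2,
                        )
                    profs = profile_table(tertiles_test, immune[:3])
                    ph = tertiles_test["proliferation"] == 3
                    comp = compare_profiles(
                        profs, clin_by[test], "all_high_vs_rest", stratum_mask=ph
                    )
                    stage["profile_logrank_p"] = comp.logrank_p
                except (ValueError, KeyError) as exc:
                    stage["profile_error"] = str(exc)
        manifest["stages"][tag] = stage
        results_summary[tag] = stage

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
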