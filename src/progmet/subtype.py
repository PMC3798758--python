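"""Nearest-centroid intrinsic subtype assignment.

Single Sample Predictor (SSP) style: per-gene mean centering across samples,
then per-sample Spearman correlation to each subtype centroid over shared
genes; samples whose best correlation does not exceed a floor (default 0.1)
stay UNASSIGNED.  Claudin-Low calls use Euclidean nearest-centroid distance
to a dedicated centroid set and override the SSP label when positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ExpressionMatrix

__all__ = [
    "CentroidSet",
    "read_centroids",
    "write_centroids",
    "collapse_to_genes",
    "ssp_classify",
    "claudin_low_classify",
    "UNASSIGNED",
]

UNASSIGNED = "UNASSIGNED"


@dataclass
class CentroidSet:
    """Gene x subtype centroid matrix in mean-centered expression units."""

    gene_symbols: list[str]
    subtype_names: list[str]
    matrix: np.ndarray  # genes x subtypes

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("duplicate gene symbols in centroid set")
        if len(self.subtype_names) < 2:
            raise ValueError("need at least 2 subtypes")
        if self.matrix.shape != (len(self.gene_symbols), len(self.subtype_names)):
            raise ValueError("centroid matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_symbols, columns=self.subtype_names)


def read_centroids(path: str | Path) -> CentroidSet:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CentroidSet(
        [str(g) for g in df.index], [str(c) for c in df.columns], df.to_numpy(dtype=float)
    )


def write_centroids(centroids: CentroidSet, path: str | Path) -> None:
    centroids.to_frame().to_csv(path, sep="\t", float_format="%.12g", index_label="gene_symbol")


def collapse_to_genes(expr: ExpressionMatrix, probe_map: pd.Series) -> pd.DataFrame:
    """Average probes sharing a gene symbol -> gene x sample DataFrame."""
    covered = [p for p in expr.probe_ids if p in probe_map.index]
    if not covered:
        raise ValueError("probe map covers no probes in the matrix")
    sub = expr.subset_probes(covered)
    genes = probe_map.loc[covered].to_numpy()
    df = pd.DataFrame(sub.values, index=genes, columns=sub.sample_ids)
    return df.groupby(level=0, sort=True).mean()


def _shared_centered(expr, probe_map, centroids):
    gene_df = collapse_to_genes(expr, probe_map)
    gene_df = gene_df.sub(gene_df.mean(axis=1), axis=0)  # mean-center per gene
    shared = [g for g in centroids.gene_symbols if g in gene_df.index]
    if not shared:
        raise ValueError("no genes shared between expression data and centroids")
    if len(shared) < 10:
        warnings.warn(
            f"only {len(shared)} genes shared with centroids; assignments may be unstable",
            stacklevel=3,
        )
    cent_df = centroids.to_frame().loc[shared]
    return gene_df.loc[shared], cent_df


def ssp_classify(
    expr: ExpressionMatrix,
    probe_map: pd.Series,
    centroids: CentroidSet,
    min_corr: float = 0.1,
) -> pd.DataFrame:
    """Assign each sample to the subtype centroid with highest Spearman r.

    Returns a DataFrame indexed by sample with ``subtype`` (or UNASSIGNED
    when best r <= min_corr), ``best_corr``, ``tie`` flag, and one
    ``corr_<subtype>`` column per centroid.  Ties go to the first subtype in
    centroid column order, flagged.
    """
    sample_df, cent_df = _shared_centered(expr, probe_map, centroids)
    sr = stats.rankdata(sample_df.to_numpy(), axis=0)
    cr = stats.rankdata(cent_df.to_numpy(), axis=0)

    def standardize(a):
        a = a - a.mean(axis=0, keepdims=True)
        norm = np.linalg.norm(a, axis=0, keepdims=True)
        norm[norm == 0] = np.nan
        return a / norm

    R = standardize(sr).T @ standardize(cr)  # samples x subtypes
    best = np.nanargmax(R, axis=1)
    best_r = R[np.arange(R.shape[0]), best]
    tie = (np.isclose(R, best_r[:, None], rtol=0, atol=1e-12)).sum(axis=1) > 1
    labels = np.array(centroids.subtype_names, dtype=object)[best]
    labels[best_r <= min_corr] = UNASSIGNED
    out = pd.DataFrame(
        {"subtype": labels, "best_corr": best_r, "tie": tie},
        index=pd.Index(sample_df.columns, name="sample_id"),
    )
    for j, name in enumerate(centroids.subtype_names):
        out[f"corr_{name}"] = R[:, j]
    return out


def claudin_low_classify(
    expr: ExpressionMatrix,
    probe_map: pd.Series,
    cl_centroids: CentroidSet,
    cl_label: str = "Claudin-Low",
) -> pd.DataFrame:
    """Euclidean nearest-centroid Claudin-Low call.

    A sample is CL iff the CL centroid is STRICTLY nearest (equidistant ties
    resolve to not-CL).  Returns DataFrame with ``claudin_low`` bool and one
    ``dist_<subtype>`` column per centroid.
    """
    if cl_label not in cl_centroids.subtype_names:
        raise ValueError(f"centroid set has no {cl_label!r} column")
    sample_df, cent_df = _shared_centered(expr, probe_map, cl_centroids)
    S = sample_df.to_numpy().T  # samples x genes
    C = cent_df.to_numpy().T  # subtypes x genes
    d2 = ((S[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    dist = np.sqrt(d2)
    j_cl = cl_centroids.subtype_names.index(cl_label)
    others = [j for j in range(len(cl_centroids.subtype_names)) if j != j_cl]
    is_cl = dist[:, j_cl] < dist[:, others].min(axis=1)
    out = pd.DataFrame(
        {"claudin_low": is_cl},
        index=pd.Index(sample_df.columns, name="sample_id"),
    )
    for j, name in enumerate(cl_centroids.subtype_names):
        out[f"dist_{name}"] = dist[:, j]
    return out


def combine_subtype_calls(ssp: pd.DataFrame, cl: pd.DataFrame, cl_label: str = "Claudin-Low") -> pd.Series:
    """CL overrides the SSP label; disagreement is visible via the inputs."""
    combined = ssp["subtype"].copy()
    combined.loc[cl.index[cl["claudin_low"]]] = cl_label
    combined.name = "subtype"
    return combined
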