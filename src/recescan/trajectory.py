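"""Developmental expression trajectories and coexpression hub scoring.

Given an expression matrix (genes x samples, RPKM-like) with per-sample
ages and brain-region labels, this module computes background-corrected
trajectories for gene sets (per-sample median log2 expression of the set
minus the median over all expressed genes), module eigengenes (first
principal component of the gene-standardized module submatrix), module-
trait correlations against age, and module-membership / gene-significance
hub calls.  Network construction itself (soft thresholds, TOM, tree
cutting) is out of scope: module assignments are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

EXPRESSED_MIN_RPKM = 1.0
EXPRESSED_MIN_FRACTION = 0.10


def expressed_genes(expr: pd.DataFrame, min_rpkm: float = EXPRESSED_MIN_RPKM,
                    min_fraction: float = EXPRESSED_MIN_FRACTION) -> pd.Index:
    """Genes with expression >= min_rpkm in >= min_fraction of the samples."""
    frac = (expr >= min_rpkm).mean(axis=1)
    return expr.index[frac >= min_fraction]


def corrected_trajectory(expr: pd.DataFrame, meta: pd.DataFrame, gene_set,
                         region: str | None = None, mode: str = "difference") -> pd.DataFrame:
    """Background-corrected trajectory of a gene set, ordered by age.

    Per sample: median log2(x+1) over the set minus (``difference`` mode,
    the default) or divided by (``ratio`` mode) the median over all
    expressed genes.  Returns a DataFrame with sample, age, region and the
    corrected statistic, sorted by age.
    """
    if region is not None:
        keep = meta.index[meta["region"] == region]
        if len(keep) < 3:
            raise ValueError(f"fewer than 3 samples in region {region!r}")
        expr = expr[keep]
        meta = meta.loc[keep]
    bg = expressed_genes(expr)
    genes = [g for g in gene_set if g in expr.index]
    missing = sorted(set(gene_set) - set(genes))
    if not genes:
        raise ValueError(f"no gene of the set is in the matrix; missing: {missing[:10]}")
    logx = np.log2(expr + 1.0)
    set_med = logx.loc[genes].median(axis=0)
    bg_med = logx.loc[bg].median(axis=0)
    if mode == "difference":
        stat = set_med - bg_med
    elif mode == "ratio":
        stat = set_med / bg_med
    else:
        raise ValueError("mode must be 'difference' or 'ratio'")
    out = pd.DataFrame({
        "sample": expr.columns, "age": meta["age"].to_numpy(),
        "region": meta.get("region", pd.Series(".", index=meta.index)).to_numpy(),
        "corrected": stat.to_numpy(),
    })
    return out.sort_values("age", kind="mergesort").reset_index(drop=True)


def trajectory_age_correlation(traj: pd.DataFrame):
    """Spearman correlation of the corrected statistic with age."""
    rho, p = spearmanr(traj["age"], traj["corrected"])
    return float(rho), float(p)


@dataclass
class Eigengene:
    values: pd.Series           # per-sample, unit norm
    variance_explained: float
    dropped_genes: list


def eigengene(module_expr: pd.DataFrame) -> Eigengene:
    """First principal component of the gene-standardized module matrix.

    Genes are centred and scaled to unit variance; zero-variance genes are
    dropped (reported).  The sign is oriented so the eigengene correlates
    non-negatively with the module's mean standardized profile.
    """
    if module_expr.shape[0] < 2 or module_expr.shape[1] < 3:
        raise ValueError("eigengene needs >= 2 genes and >= 3 samples")
    X = module_expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    dropped = list(module_expr.index[sd == 0])
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes with variance")
    X = X[keep]
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    pc1 = Vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(pc1, mean_profile) < 0:
        pc1 = -pc1
    var_exp = float(S[0] ** 2 / np.sum(S ** 2))
    return Eigengene(pd.Series(pc1, index=module_expr.columns),
                     var_exp, dropped)


def module_trait(eig: pd.Series, ages, r_threshold: float = 0.5,
                 p_threshold: float = 0.05):
    """Pearson module-trait correlation against age with the joint criterion.

    A module relates to development iff |r| > r_threshold and p <
    p_threshold (two-sided t-based p).
    """
    eig = np.asarray(eig, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(eig) < 3:
        raise ValueError("need >= 3 samples")
    if np.std(eig) == 0 or np.std(ages) == 0:
        return float("nan"), float("nan"), False
    r, p = pearsonr(eig, ages)
    return float(r), float(p), bool(abs(r) > r_threshold and p < p_threshold)


def hub_genes(module_expr: pd.DataFrame, eig: pd.Series, ages,
              p_threshold: float = 0.05) -> pd.DataFrame:
    """Module membership / gene significance report with hub flags.

    MM is the Pearson correlation of each gene with the eigengene, GS its
    correlation with sample age; a gene is a hub iff p.MM < 0.05 and
    p.GS < 0.05 (strict inequalities).
    """
    ages = np.asarray(ages, dtype=float)
    ev = np.asarray(eig, dtype=float)
    rows = []
    for gene, x in module_expr.iterrows():
        xv = x.to_numpy(dtype=float)
        if np.std(xv) == 0:
            rows.append(dict(gene=gene, MM=np.nan, p_MM=np.nan,
                             GS=np.nan, p_GS=np.nan, hub=False))
            continue
        mm, p_mm = pearsonr(xv, ev)
        gs, p_gs = pearsonr(xv, ages)
        rows.append(dict(gene=gene, MM=float(mm), p_MM=float(p_mm),
                         GS=float(gs), p_GS=float(p_gs),
                         hub=bool(p_mm < p_threshold and p_gs < p_threshold)))
    return pd.DataFrame(rows).set_index("gene")
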