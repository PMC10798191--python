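"""Branch-acceleration likelihood-ratio tests and RECE calling.

For each conserved element the null model fits one free rate scale ``s``
over the whole tree; the alternative adds a multiplier ``lam >= 1`` on a
named target branch (the one-sided acceleration direction).  Because
``lam`` is tested at the boundary of its parameter space, the LRT statistic
``T = 2 (lnL1 - lnL0)`` is referred to the 50:50 mixture of a point mass at
zero and chi-square with one degree of freedom.  Benjamini-Hochberg
adjustment across all tested elements and a q <= 0.05 cut (with
Y-chromosome elements removed) yields the rapidly evolving conserved
elements (RECEs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io import gc_content
from .phylo import MISSING, PhyloTree, SubstitutionModel, encode_columns, fit_scale

RESULT_COLUMNS = [
    "chrom", "start", "end", "name", "n_cols",
    "s0", "lnL0", "s1", "lam1", "lnL1", "T", "p", "tested", "reason",
]

MIN_TEST_COLUMNS = 10  # ML on shorter elements is unstable; they are flagged


def extract_columns(blocks, chrom, start, end, leaf_names) -> np.ndarray:
    """Encoded columns of [start, end) on ``chrom`` from the covering block.

    Species absent from the block become missing rows; the element must be
    contained in a single alignment block.
    """
    for b in blocks:
        if b.chrom == chrom and b.start <= start and end <= b.end:
            lo, hi = start - b.start, end - b.start
            seqs = {sp: s[lo:hi] for sp, s in b.sequences.items()}
            return encode_columns(seqs, leaf_names)
    raise KeyError(f"no alignment block fully covers {chrom}:{start}-{end}")


def mixture_pvalue(T: float, tol: float = 1e-8) -> float:
    """Upper tail of 0.5*delta_0 + 0.5*chi2_1 at ``T``."""
    if T <= tol:
        return 1.0
    return float(0.5 * chi2.sf(T, df=1))


def branch_lrt(cols: np.ndarray, tree: PhyloTree, model: SubstitutionModel,
               target: int, min_columns: int = MIN_TEST_COLUMNS) -> dict:
    """One-sided branch-acceleration LRT on encoded element columns."""
    cols = np.atleast_2d(cols)
    informative = int((cols != MISSING).any(axis=0).sum())
    if informative < min_columns:
        return dict(n_cols=informative, s0=np.nan, lnL0=np.nan, s1=np.nan,
                    lam1=np.nan, lnL1=np.nan, T=np.nan, p=np.nan,
                    tested=False, reason=f"only {informative} informative columns")
    null = fit_scale(tree, model, cols, free="s")
    alt = fit_scale(tree, model, cols, free="s,lam", target=target, lam_lower=1.0)
    if not (null.converged and alt.converged):
        return dict(n_cols=informative, s0=null.s, lnL0=null.loglik, s1=alt.s,
                    lam1=alt.lam, lnL1=alt.loglik, T=np.nan, p=np.nan,
                    tested=False, reason="optimizer did not converge")
    T = 2.0 * (alt.loglik - null.loglik)
    if T < -1e-4:  # nested models: a real violation, not rounding
        return dict(n_cols=informative, s0=null.s, lnL0=null.loglik, s1=alt.s,
                    lam1=alt.lam, lnL1=alt.loglik, T=T, p=np.nan,
                    tested=False, reason="alternative fit below null")
    T = max(T, 0.0)
    return dict(n_cols=informative, s0=null.s, lnL0=null.loglik, s1=alt.s,
                lam1=alt.lam, lnL1=alt.loglik, T=T, p=mixture_pvalue(T),
                tested=True, reason="")


def test_elements(elements: pd.DataFrame, blocks, tree: PhyloTree,
                  model: SubstitutionModel, target) -> pd.DataFrame:
    """Run the branch LRT on every element; returns the result table.

    ``target`` is a branch spec accepted by ``PhyloTree.find_branch``.
    Untestable elements (too short, non-converged) are flagged with a
    reason and excluded from FDR by the caller.
    """
    node = target if isinstance(target, (int, np.integer)) else tree.find_branch(target)
    rows = []
    for el in elements.itertuples(index=False):
        cols = extract_columns(blocks, el.chrom, el.start, el.end, tree.leaf_names)
        res = branch_lrt(cols, tree, model, node)
        res.update(chrom=el.chrom, start=int(el.start), end=int(el.end),
                   name=getattr(el, "name", "."))
        rows.append(res)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


run_branch_tests = test_elements  # alias: importable without pytest collecting it


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values (step-up), monotone in p-rank."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~((p >= 0) & (p <= 1))):  # catches NaN as well
        raise ValueError("p-values must lie in [0, 1] and not be NaN")
    return multipletests(p, method="fdr_bh")[1]


def call_reces(results: pd.DataFrame, q_threshold: float = 0.05,
               drop_chroms=("chrY",)) -> pd.DataFrame:
    """RECEs: tested elements with q <= threshold, minus dropped chromosomes.

    Adds a ``q`` column to the tested subset (BH across the whole family)
    and returns a sorted BED6 DataFrame with the LRT statistic as score.
    """
    drop = set(drop_chroms or ())
    tested = results[results["tested"].astype(bool)].copy()
    if tested.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand", "q"])
    tested["q"] = adjust_fdr(tested["p"].to_numpy())
    hit = tested[(tested["q"] <= q_threshold) & (~tested["chrom"].isin(drop))]
    out = pd.DataFrame({
        "chrom": hit["chrom"], "start": hit["start"].astype(int),
        "end": hit["end"].astype(int), "name": hit["name"],
        "score": hit["T"], "strand": ".", "q": hit["q"],
    })
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def summarize_elements(bed: pd.DataFrame, seqs: dict | None = None) -> dict:
    """Length (and, with sequence, GC) summary of an element set.

    ``seqs`` maps chromosome name to its full sequence string; when absent
    GC is reported as unavailable rather than failing.
    """
    n = len(bed)
    if n == 0:
        return dict(count=0, length_min=None, length_median=None,
                    length_max=None, gc_median=None)
    lengths = (bed["end"] - bed["start"]).to_numpy()
    out = dict(count=int(n), length_min=int(lengths.min()),
               length_median=float(np.median(lengths)),
               length_max=int(lengths.max()), gc_median=None)
    if seqs is not None:
        gcs = []
        for el in bed.itertuples(index=False):
            if el.chrom not in seqs:
                raise KeyError(f"no sequence for chromosome {el.chrom}")
            gcs.append(gc_content(seqs[el.chrom][el.start:el.end]))
        out["gc_median"] = float(np.nanmedian(gcs))
    return out
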