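"""Canonical benchmark experiments for the pipeline's statistical claims.

Each function regenerates its inputs with the synthetic-data module under a
single seed, runs the relevant stage, and returns the summary quantities
(calibration rates, sensitivity/FDR, recovery fractions, enrichment
statistics).  The test suite and the reproduction script both call these,
so the measured numbers always come from the same code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import conserved, enrichment, simulate, targets, trajectory
from .acceleration import adjust_fdr, branch_lrt, extract_columns
from .phylo import SubstitutionModel
from .simulate import RegionSpec, element_in_flanks_specs, simulate_alignment

DEFAULT_PI = np.array([0.3, 0.2, 0.2, 0.3])
DEFAULT_KAPPA = 3.0


def default_setup():
    tree = simulate.default_tree()
    model = SubstitutionModel.hky85(DEFAULT_PI, kappa=DEFAULT_KAPPA)
    target = tree.find_branch(simulate.TARGET_BRANCH_LABEL)
    return tree, model, target


def _element_seeds(seed: int, stream: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed, spawn_key=(stream,))
    return ss.generate_state(n, dtype=np.uint32) % (2**31)


def _lrt_p(tree, model, target, regime, seed, lam=1.0, length=200, rho=0.3):
    specs = [RegionSpec("chr1", 0, length, regime, rho, lam)]
    blocks, _ = simulate_alignment(tree, model, specs, int(seed))
    cols = extract_columns(blocks, "chr1", 0, length, tree.leaf_names)
    r = branch_lrt(cols, tree, model, target)
    return r["p"] if r["tested"] else np.nan


def lrt_null_calibration(seed: int = 0, n: int = 500) -> dict:
    """Branch-LRT p-values for conserved-but-not-accelerated elements.

    Returns the fraction of tested elements with p < 0.05 (nominal 0.05;
    the boundary mixture makes the test conservative-to-nominal).
    """
    tree, model, target = default_setup()
    seeds = _element_seeds(seed, 11, n)
    ps = np.array([_lrt_p(tree, model, target, "conserved", s) for s in seeds])
    tested = ps[~np.isnan(ps)]
    return dict(fraction_p_lt_05=float((tested < 0.05).mean()),
                n_tested=int(tested.size), n=n)


def acceleration_recovery(seed: int = 0, n_true: int = 100, n_null: int = 400,
                          lam: float = 4.0, q_threshold: float = 0.05) -> dict:
    """Sensitivity and empirical FDR of RECE calling on planted acceleration.

    ``n_true`` elements carry the branch multiplier ``lam`` among
    ``n_true + n_null`` conserved elements; discovery at BH q <= 0.05.
    """
    tree, model, target = default_setup()
    s_true = _element_seeds(seed, 12, n_true)
    s_null = _element_seeds(seed, 13, n_null)
    ps = [ _lrt_p(tree, model, target, "accelerated", s, lam=lam) for s in s_true]
    ps += [_lrt_p(tree, model, target, "conserved", s) for s in s_null]
    truth = np.array([True] * n_true + [False] * n_null)
    ps = np.array(ps)
    ok = ~np.isnan(ps)
    q = np.full(ps.shape, np.nan)
    q[ok] = adjust_fdr(ps[ok])
    called = q <= q_threshold
    return dict(sensitivity=float(called[truth].mean()),
                fdr=float(called[~truth].sum() / max(1, called.sum())),
                n_called=int(called.sum()), n=n_true + n_null)


def conserved_recovery(seed: int = 0, n_reps: int = 50, element_len: int = 200,
                       flank: int = 400, rho: float = 0.3,
                       jaccard_min: float = 0.7) -> dict:
    """Fraction of planted conserved elements recovered at Jaccard >= 0.7."""
    tree, model, _ = default_setup()
    hmm = conserved.ConservationHMM()
    seeds = _element_seeds(seed, 14, n_reps)
    lo, hi = flank, flank + element_len
    hits, jacs = 0, []
    for s in seeds:
        specs = element_in_flanks_specs("chr1", 0, element_len, flank,
                                        "conserved", rho)
        blocks, _ = simulate_alignment(tree, model, specs, int(s))
        els = conserved.call_elements(blocks[0], hmm, tree, model)
        best = 0.0
        for e in els.itertuples(index=False):
            inter = max(0, min(e.end, hi) - max(e.start, lo))
            union = max(e.end, hi) - min(e.start, lo)
            best = max(best, inter / union)
        jacs.append(best)
        hits += best >= jaccard_min
    return dict(recovery_rate=hits / n_reps, mean_jaccard=float(np.mean(jacs)),
                n=n_reps)


ENRICH_SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}


def _grid_elements(n=60, length=200, spacing=15_000):
    rows = []
    for i in range(n):
        c = "chr1" if i % 2 == 0 else "chr2"
        s = 7_000 + (i // 2) * spacing
        rows.append(dict(chrom=c, start=s, end=s + length, name=f"e{i}"))
    return pd.DataFrame(rows)


def enrichment_experiment(seed: int = 0, factor: float = 4.0,
                          n_sets: int = 1000, n_elements: int = 60,
                          n_peaks: int = 1000) -> dict:
    """Permutation enrichment of elements in a planted-factor peak set."""
    els = _grid_elements(n_elements)
    epi = simulate.simulate_epigenome(ENRICH_SIZES, els, seed=seed,
                                      n_peaks=n_peaks,
                                      enrichment_factor=factor,
                                      n_genes=30, n_loops=20)
    controls = enrichment.sample_matched_controls(
        els, ENRICH_SIZES, n_sets=n_sets,
        seed=int(np.random.SeedSequence(seed, spawn_key=(15,)).generate_state(1)[0] % 2**31))
    fish = enrichment.fisher_enrichment(els, controls, epi["peaks"])
    binom = enrichment.binomial_enrichment(els, controls, {"peaks": epi["peaks"]})
    return dict(mean_odds_ratio=fish.odds_ratio, mean_p=fish.p_value,
                binomial_adjusted_p=float(binom.iloc[0]["adjusted_p"]),
                observed=int(fish.observed), n=n_elements, n_sets=n_sets)


def enrichment_null_rate(seed: int = 0, n_runs: int = 20,
                         n_sets: int = 1000) -> dict:
    """Fraction of null (factor 1) runs that stay non-significant."""
    non_sig = 0
    for r in range(n_runs):
        res = enrichment_experiment(seed=seed * 1000 + r, factor=1.0,
                                    n_sets=n_sets)
        non_sig += res["binomial_adjusted_p"] > 0.05
    return dict(non_significant_fraction=non_sig / n_runs, n=n_runs)


def trajectory_experiment(seed: int = 0, n_genes: int = 300,
                          n_trend: int = 30, n_samples: int = 40,
                          beta: float = 0.5, noise_sd: float = 0.2) -> dict:
    """Age correlation of the corrected trajectory of a planted trend set."""
    genes = [f"G{i}" for i in range(n_genes)]
    expr, meta = simulate.simulate_expression(genes, seed=seed,
                                              n_samples=n_samples,
                                              trend_genes=genes[:n_trend],
                                              beta=beta, noise_sd=noise_sd)
    traj = trajectory.corrected_trajectory(expr, meta, genes[:n_trend])
    rho, p = trajectory.trajectory_age_correlation(traj)
    return dict(spearman_rho=rho, spearman_p=p, n=n_samples)


def hub_recovery(seed: int = 0, n_samples: int = 40) -> dict:
    """Sensitivity/FDR of hub calling on a planted coexpression module."""
    mat, ages, hub_ids = simulate.simulate_coexpression_module(
        seed, n_samples=n_samples)
    eg = trajectory.eigengene(mat)
    report = trajectory.hub_genes(mat, eg.values, ages)
    called = set(report.index[report["hub"]])
    sens = len(called & set(hub_ids)) / len(hub_ids)
    fdr = len(called - set(hub_ids)) / max(1, len(called))
    r, p, sig = trajectory.module_trait(eg.values, ages)
    return dict(sensitivity=sens, fdr=fdr, module_trait_r=r,
                module_trait_significant=bool(sig), n=n_samples)
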