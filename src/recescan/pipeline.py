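"""Stage orchestration: wire the modules into a reproducible pipeline.

Each stage reads standard files (MAF/Newick/BED/BEDPE/TSV), writes its
outputs into the run directory, and appends a manifest line recording the
parameters, seed and input hashes actually used, so a rerun with the same
config is byte-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acceleration, conserved, enrichment, simulate, targets, trajectory
from .io import (read_bed, read_bedpe, read_chrom_sizes, read_expression,
                 read_maf, read_tss_table, write_bed, write_bedpe,
                 write_chrom_sizes, write_maf)
from .phylo import PhyloTree, SubstitutionModel

STAGE_ORDER = ["simulate", "scan-conserved", "test-acceleration", "annotate",
               "enrich", "link-genes", "trajectory"]

DEFAULTS = dict(
    rho=0.3, mu=1.0 / 45.0, nu=(1.0 / 45.0) * 0.3 / 0.7,
    q_threshold=0.05, n_control_sets=1000, drop_chroms=["chrY"],
    min_species_fraction=0.90, target_branch=simulate.TARGET_BRANCH_LABEL,
    ref_species=simulate.DEFAULT_REF,
    # synthetic-genome defaults: three 1 Mb autosome stand-ins plus a small
    # chrY to exercise the Y-removal rule
    chrom_sizes={"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000,
                 "chrY": 200_000},
    n_elements=30, element_length=200, flank=400, accelerated_fraction=0.3,
    lam=4.0, dropout=0.05, n_peaks=1000, enrichment_factor=4.0,
    n_genes=60, n_loops=40, n_samples=40, beta=0.5, noise_sd=0.2,
)


class StageError(RuntimeError):
    pass


def load_config(path=None, **overrides) -> dict:
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            cfg.update(yaml.safe_load(fh) or {})
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def _hash(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def _manifest(outdir: Path, stage: str, params: dict, seed, inputs, outputs):
    entry = dict(stage=stage, seed=seed,
                 params={k: v for k, v in sorted(params.items())
                         if isinstance(v, (int, float, str, bool, list))},
                 inputs={str(p): _hash(p) for p in inputs},
                 outputs=[str(p) for p in outputs],
                 time=time.strftime("%Y-%m-%dT%H:%M:%S"))
    with open(outdir / "manifest.jsonl", "a") as fh:
        fh.write(json.dumps(entry, default=str) + "\n")


def _require(outdir: Path, name: str, produced_by: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise StageError(f"missing {name}; run the '{produced_by}' stage first")
    return p


def _element_specs(cfg, rng):
    """Non-overlapping element-in-flanks windows over the synthetic genome."""
    specs, truth_regimes = [], []
    sizes = cfg["chrom_sizes"]
    chroms = sorted(sizes)
    width = cfg["element_length"] + 2 * cfg["flank"]
    slots = [(c, s) for c in chroms
             for s in range(1000, sizes[c] - width - 1000, width + 500)]
    if len(slots) < cfg["n_elements"]:
        raise StageError("synthetic genome too small for requested elements")
    pick = sorted(rng.permutation(len(slots))[: cfg["n_elements"]])
    n_acc = int(round(cfg["accelerated_fraction"] * cfg["n_elements"]))
    acc_flags = np.zeros(cfg["n_elements"], dtype=bool)
    acc_flags[rng.permutation(cfg["n_elements"])[:n_acc]] = True
    for i, si in enumerate(pick):
        c, s = slots[si]
        regime = "accelerated" if acc_flags[i] else "conserved"
        lam = cfg["lam"] if acc_flags[i] else 1.0
        specs += simulate.element_in_flanks_specs(
            c, s, cfg["element_length"], cfg["flank"], regime, cfg["rho"], lam)
        truth_regimes.append(regime)
    return specs


def run_stage(name: str, cfg: dict, outdir, seed: int = 0) -> dict:
    """Run one pipeline stage into ``outdir``; returns its main outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name not in STAGE_ORDER:
        raise StageError(f"unknown stage {name!r}; choose from {STAGE_ORDER}")
    return _STAGES[name](cfg, outdir, seed)


def _stage_simulate(cfg, outdir, seed):
    tree = (PhyloTree.from_newick(Path(cfg["tree"]).read_text())
            if cfg.get("tree") else simulate.default_tree())
    model = (SubstitutionModel.from_text(Path(cfg["model"]).read_text())
             if cfg.get("model") else SubstitutionModel.hky85(
                 np.array([0.3, 0.2, 0.2, 0.3]), kappa=3.0))
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    specs = _element_specs(cfg, rng)
    blocks, truth = simulate.simulate_alignment(
        tree, model, specs, seed, ref=cfg["ref_species"],
        target=cfg["target_branch"])
    blocks, presence = simulate.apply_species_dropout(
        blocks, cfg["dropout"], seed, total_species=tree.n_leaves,
        keep=(cfg["ref_species"],), min_fraction=cfg["min_species_fraction"])
    (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
    (outdir / "model.tsv").write_text(model.to_text())
    write_maf(blocks, outdir / "alignment.maf", cfg["chrom_sizes"])
    write_bed(truth, outdir / "truth_elements.bed")
    presence.to_csv(outdir / "block_presence.tsv", sep="\t", index=False)
    write_chrom_sizes(cfg["chrom_sizes"], outdir / "chrom.sizes")

    epi = simulate.simulate_epigenome(
        cfg["chrom_sizes"], truth, seed, n_peaks=cfg["n_peaks"],
        enrichment_factor=cfg["enrichment_factor"], n_genes=cfg["n_genes"],
        n_loops=cfg["n_loops"])
    write_bed(epi["peaks"], outdir / "peaks.bed")
    write_bed(epi["promoter_peaks"], outdir / "h3k4me3.bed")
    epi["genes"].to_csv(outdir / "genes.tsv", sep="\t", index=False)
    write_bedpe(epi["loops"], outdir / "loops.bedpe")
    epi["loop_truth"].to_csv(outdir / "loop_truth.tsv", sep="\t", index=False)
    epi["proximal_candidates"].to_csv(outdir / "proximal_candidates.tsv",
                                      sep="\t", index=False)

    gene_ids = list(epi["genes"]["gene_id"])
    trend = [g for g in epi["loop_truth"]["gene_id"].unique() if g in gene_ids]
    expr, meta = simulate.simulate_expression(
        gene_ids, seed, n_samples=cfg["n_samples"], trend_genes=trend,
        beta=cfg["beta"], noise_sd=cfg["noise_sd"])
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    meta.to_csv(outdir / "meta.tsv", sep="\t")
    pd.Series(sorted(trend)).to_csv(outdir / "trend_genes.txt", index=False,
                                    header=False)
    outputs = [outdir / f for f in
               ("tree.nwk", "model.tsv", "alignment.maf", "truth_elements.bed",
                "peaks.bed", "h3k4me3.bed", "genes.tsv", "loops.bedpe",
                "expression.tsv", "meta.tsv")]
    _manifest(outdir, "simulate", cfg, seed, [], outputs)
    manifest = simulate.SimulationManifest(
        seed=seed, tree=str(outdir / "tree.nwk"), model=str(outdir / "model.tsv"),
        regions=[{k: getattr(s, k) for k in ("chrom", "start", "end", "regime", "rho", "lam")}
                 for s in specs],
        dropout=cfg["dropout"], files=[str(p) for p in outputs])
    manifest.to_yaml(outdir / "simulation_manifest.yaml")
    return dict(blocks=blocks, truth=truth)


def _load_phylo(cfg, outdir):
    tree = PhyloTree.from_newick(_require(outdir, "tree.nwk", "simulate").read_text())
    model = SubstitutionModel.from_text(_require(outdir, "model.tsv", "simulate").read_text())
    blocks = read_maf(_require(outdir, "alignment.maf", "simulate"), ref=cfg["ref_species"])
    return tree, model, blocks


def _stage_scan(cfg, outdir, seed):
    tree, model, blocks = _load_phylo(cfg, outdir)
    hmm = conserved.ConservationHMM(cfg["rho"], cfg["mu"], cfg["nu"])
    elements = conserved.scan_blocks(blocks, hmm, tree, model,
                                     min_fraction=cfg["min_species_fraction"])
    write_bed(elements, outdir / "conserved_elements.bed")
    _manifest(outdir, "scan-conserved", cfg, seed,
              [outdir / "alignment.maf", outdir / "tree.nwk"],
              [outdir / "conserved_elements.bed"])
    return dict(elements=elements)


def _stage_accel(cfg, outdir, seed):
    tree, model, blocks = _load_phylo(cfg, outdir)
    elements = read_bed(_require(outdir, "conserved_elements.bed", "scan-conserved"))
    results = acceleration.test_elements(elements, blocks, tree, model,
                                         cfg["target_branch"])
    results.to_csv(outdir / "acceleration_results.tsv", sep="\t", index=False)
    reces = acceleration.call_reces(results, cfg["q_threshold"],
                                    cfg["drop_chroms"])
    write_bed(reces, outdir / "reces.bed")
    summary = acceleration.summarize_elements(reces)
    (outdir / "rece_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    _manifest(outdir, "test-acceleration", cfg, seed,
              [outdir / "conserved_elements.bed"],
              [outdir / "acceleration_results.tsv", outdir / "reces.bed"])
    return dict(results=results, reces=reces, summary=summary)


def _annotation(cfg, outdir):
    sizes = read_chrom_sizes(_require(outdir, "chrom.sizes", "simulate"))
    genes = read_tss_table(_require(outdir, "genes.tsv", "simulate"))
    return enrichment.GenomeAnnotation(sizes, genes)


def _stage_annotate(cfg, outdir, seed):
    reces = read_bed(_require(outdir, "reces.bed", "test-acceleration"))
    ann = _annotation(cfg, outdir)
    cats = enrichment.classify_elements(reces, ann)
    out = reces.assign(category=cats.values)
    out.to_csv(outdir / "rece_categories.tsv", sep="\t", index=False)
    counts = cats.value_counts().reindex(enrichment.CATEGORIES, fill_value=0)
    counts.rename_axis("category").rename("count").to_csv(
        outdir / "category_counts.tsv", sep="\t")
    _manifest(outdir, "annotate", cfg, seed, [outdir / "reces.bed"],
              [outdir / "rece_categories.tsv"])
    return dict(categories=out, counts=counts)


def _stage_enrich(cfg, outdir, seed):
    reces = read_bed(_require(outdir, "reces.bed", "test-acceleration"))
    peaks = read_bed(_require(outdir, "peaks.bed", "simulate"))
    sizes = read_chrom_sizes(_require(outdir, "chrom.sizes", "simulate"))
    if reces.empty:
        raise StageError("no RECEs to test; inspect the acceleration stage")
    controls = enrichment.sample_matched_controls(
        reces, sizes, n_sets=cfg["n_control_sets"], seed=seed)
    fisher = enrichment.fisher_enrichment(reces, controls, peaks, category="peaks")
    binom = enrichment.binomial_enrichment(reces, controls, {"peaks": peaks})
    pd.DataFrame([fisher.__dict__]).to_csv(outdir / "fisher_enrichment.tsv",
                                           sep="\t", index=False)
    binom.to_csv(outdir / "binomial_enrichment.tsv", sep="\t", index=False)
    _manifest(outdir, "enrich", cfg, seed,
              [outdir / "reces.bed", outdir / "peaks.bed"],
              [outdir / "fisher_enrichment.tsv", outdir / "binomial_enrichment.tsv"])
    return dict(fisher=fisher, binomial=binom)


def _stage_link(cfg, outdir, seed):
    reces = read_bed(_require(outdir, "reces.bed", "test-acceleration"))
    genes = read_tss_table(_require(outdir, "genes.tsv", "simulate"))
    peaks = read_bed(_require(outdir, "h3k4me3.bed", "simulate"))
    loops = read_bedpe(_require(outdir, "loops.bedpe", "simulate"))
    sizes = read_chrom_sizes(_require(outdir, "chrom.sizes", "simulate"))
    promoters = targets.promoter_windows(genes, sizes)
    active = targets.active_promoters(promoters, peaks)
    prox_genes, prox_pairs = targets.proximal_genes(reces, active)
    lp_genes, lp_triples = targets.loop_genes(reces, loops, promoters)
    prox_pairs.to_csv(outdir / "proximal_pairs.tsv", sep="\t", index=False)
    lp_triples.to_csv(outdir / "loop_triples.tsv", sep="\t", index=False)
    (outdir / "proximal_genes.txt").write_text("\n".join(prox_genes) + "\n")
    (outdir / "loop_genes.txt").write_text("\n".join(lp_genes) + "\n")
    _manifest(outdir, "link-genes", cfg, seed,
              [outdir / "reces.bed", outdir / "loops.bedpe"],
              [outdir / "proximal_pairs.tsv", outdir / "loop_triples.tsv"])
    return dict(proximal=(prox_genes, prox_pairs), loop=(lp_genes, lp_triples))


def _stage_trajectory(cfg, outdir, seed):
    expr, meta = read_expression(_require(outdir, "expression.tsv", "simulate"),
                                 _require(outdir, "meta.tsv", "simulate"))
    gene_list_path = cfg.get("gene_list") or (outdir / "loop_genes.txt")
    if not Path(gene_list_path).exists():
        raise StageError("missing gene list; run the 'link-genes' stage first")
    gene_set = [g for g in Path(gene_list_path).read_text().split() if g]
    frames = []
    for region in sorted(meta["region"].unique()):
        traj = trajectory.corrected_trajectory(expr, meta, gene_set, region)
        rho, p = trajectory.trajectory_age_correlation(traj)
        traj["spearman_rho"], traj["spearman_p"] = rho, p
        frames.append(traj)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(outdir / "trajectory.tsv", sep="\t", index=False)
    _manifest(outdir, "trajectory", cfg, seed,
              [outdir / "expression.tsv"], [outdir / "trajectory.tsv"])
    return dict(trajectory=out)


_STAGES = {
    "simulate": _stage_simulate,
    "scan-conserved": _stage_scan,
    "test-acceleration": _stage_accel,
    "annotate": _stage_annotate,
    "enrich": _stage_enrich,
    "link-genes": _stage_link,
    "trajectory": _stage_trajectory,
}


def run_all(cfg, outdir, seed=0):
    out = {}
    for name in STAGE_ORDER:
        out[name] = run_stage(name, cfg, outdir, seed)
    return out


# ---------------------------------------------------------------------------
# supplementary-table validation


def validate_supplement(path) -> dict:
    """Parse a deposited element table and summarize it for comparison.

    Accepts tab- or comma-separated text with either named chrom/start/end
    columns (case-insensitive) or those fields in the first three columns.
    Unparseable rows are listed with their line numbers; valid rows are
    still summarized.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    sep = "\t" if (text and "\t" in text[0]) else ","
    header = [h.strip().lower() for h in text[0].split(sep)] if text else []

    def find(names):
        for n in names:
            if n in header:
                return header.index(n)
        return None

    ci = find(["chrom", "chr", "chromosome", "seqnames"])
    si = find(["start", "chromstart"])
    ei = find(["end", "chromend", "stop"])
    has_header = ci is not None and si is not None and ei is not None
    if not has_header:
        ci, si, ei = 0, 1, 2
    rows, bad = [], []
    start_line = 1 if has_header or (header and not _looks_numeric(header, 1, 2)) else 0
    for ln, line in enumerate(text[start_line:], start=start_line + 1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(sep)]
        try:
            chrom, s, e = parts[ci], int(float(parts[si])), int(float(parts[ei]))
            if e <= s:
                raise ValueError("empty interval")
            rows.append((chrom, s, e))
        except (ValueError, IndexError) as exc:
            bad.append((ln, str(exc)))
    if rows:
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        summary = acceleration.summarize_elements(df)
    else:
        summary = acceleration.summarize_elements(
            pd.DataFrame(columns=["chrom", "start", "end"]))
        summary["empty"] = True
    summary["invalid_rows"] = bad
    summary["valid_rows"] = len(rows)
    return summary


def _looks_numeric(parts, *idx):
    try:
        for i in idx:
            float(parts[i])
        return True
    except (ValueError, IndexError):
        return False
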