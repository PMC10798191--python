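"""Synthetic ground-truth data for every pipeline stage.

The generators stand in for the genome-scale inputs the method was designed
for: a primate-like multi-species alignment with planted conserved and
branch-accelerated elements, epigenomic peak/loop/gene-model files with
planted enrichment and promoter wiring, and developmental expression
matrices with planted age trends.  Every generator is deterministic under
its seed; all randomness flows from one seed through named substreams so
stages can be regenerated independently.

Truth tables are emitted alongside each file and are sufficient to score
the downstream stage without reaching back into simulator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io import AlignmentBlock
from .phylo import PhyloTree, SubstitutionModel, BASES

# Desk-scale stand-in for a 49-way primate alignment tree: 12 simiiform and
# 8 strepsirrhine species, branch lengths in expected substitutions/site
# (total ~1.0, comparable to a primate neutral tree).  The labelled internal
# branch "simiiformes" (its ancestral stem) is the default acceleration
# target.
DEFAULT_TREE_NEWICK = (
    "((((((Homo:0.009,Pan:0.010):0.005,Gorilla:0.013):0.013,Pongo:0.027):0.045,"
    "((Macaca:0.010,Papio:0.010):0.006,(Chlorocebus:0.013,Rhinopithecus:0.016):0.005):0.038)"
    ":0.018,"
    "(Callithrix:0.045,(Saimiri:0.038,(Cebus:0.033,Aotus:0.030):0.006):0.008):0.060)"
    "simiiformes:0.060,"
    "((((Microcebus:0.030,Cheirogaleus:0.030):0.030,"
    "((Lemur:0.018,Eulemur:0.018):0.015,Propithecus:0.030):0.015):0.022,"
    "Daubentonia:0.075):0.030,(Otolemur:0.060,Nycticebus:0.068):0.045):0.030);"
)
DEFAULT_REF = "Homo"
TARGET_BRANCH_LABEL = "simiiformes"

# substream ids: one per generator so stages can be re-run independently
_STREAMS = {"alignment": 1, "dropout": 2, "epigenome": 3, "expression": 4, "module": 5}


def default_tree() -> PhyloTree:
    return PhyloTree.from_newick(DEFAULT_TREE_NEWICK)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of the run seed (stable across runs)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


@dataclass
class RegionSpec:
    """One simulated region with its substitution regime.

    ``regime`` is ``neutral``, ``conserved`` (all branches scaled by
    ``rho`` < 1) or ``accelerated`` (conserved background plus a ``lam`` >= 1
    multiplier on the target branch).
    """

    chrom: str
    start: int
    end: int
    regime: str = "neutral"
    rho: float = 1.0
    lam: float = 1.0

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty region")
        if self.regime not in ("neutral", "conserved", "accelerated"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if self.lam < 1.0:
            raise ValueError("lam must be >= 1")

    @property
    def scales(self):
        rho = self.rho if self.regime != "neutral" else 1.0
        lam = self.lam if self.regime == "accelerated" else 1.0
        return rho, lam


@dataclass
class SimulationManifest:
    seed: int
    tree: str
    model: str
    regions: list = field(default_factory=list)
    dropout: float = 0.0
    files: list = field(default_factory=list)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _check_disjoint(specs):
    by_chrom = {}
    for sp in specs:
        by_chrom.setdefault(sp.chrom, []).append(sp)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping region specs on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
    return by_chrom


def _sample_markov(tree: PhyloTree, model: SubstitutionModel, scales_per_col,
                   target: int, rng: np.random.Generator) -> np.ndarray:
    """Sample leaf states column-wise down the tree.

    ``scales_per_col`` is an (n_cols, 2) array of (rho, lam); lam applies on
    the target branch only.  Returns an int matrix (n_leaves, n_cols).
    """
    n_cols = scales_per_col.shape[0]
    states = np.empty((tree.n_nodes, n_cols), dtype=np.int8)
    states[tree.root] = rng.choice(4, size=n_cols, p=model.pi)
    # group columns by regime so each branch needs one P matrix per regime
    uniq, inv = np.unique(scales_per_col, axis=0, return_inverse=True)
    groups = [np.where(inv == g)[0] for g in range(len(uniq))]
    for node in range(tree.n_nodes - 2, -1, -1):  # preorder: parents first
        par = states[tree.parent[node]]
        t = tree.length[node]
        for g, cols in enumerate(groups):
            rho, lam = uniq[g]
            scale = rho * (lam if node == target else 1.0)
            P = model.transition_matrix(t, scale)
            cum = np.cumsum(P, axis=1)
            u = rng.random(len(cols))
            states[node, cols] = (u[:, None] > cum[par[cols]]).sum(axis=1)
    return states[: tree.n_leaves]


def simulate_alignment(tree, model, specs, seed, ref=DEFAULT_REF,
                       target=TARGET_BRANCH_LABEL):
    """Simulate alignment blocks from region specs; returns (blocks, truth).

    Specs that abut on the same chromosome are merged into one contiguous
    alignment block (so a planted element can sit inside neutral flanks).
    The truth table records every non-neutral planted region with its
    regime and scales.
    """
    _check_disjoint(specs)
    target_node = tree.find_branch(target) if target is not None else None
    rng = substream(seed, "alignment")
    # merge abutting specs into blocks, in deterministic order
    ordered = sorted(specs, key=lambda s: (s.chrom, s.start))
    blocks_specs, current = [], []
    for sp in ordered:
        if current and sp.chrom == current[-1].chrom and sp.start == current[-1].end:
            current.append(sp)
        else:
            if current:
                blocks_specs.append(current)
            current = [sp]
    if current:
        blocks_specs.append(current)

    blocks, truth = [], []
    for group in blocks_specs:
        chrom, start, end = group[0].chrom, group[0].start, group[-1].end
        scales = np.empty((end - start, 2))
        for sp in group:
            scales[sp.start - start : sp.end - start] = sp.scales
            if sp.regime != "neutral":
                truth.append(
                    dict(chrom=sp.chrom, start=sp.start, end=sp.end,
                         name=sp.regime, score=sp.lam if sp.regime == "accelerated" else sp.rho,
                         strand="."))
        leaf_states = _sample_markov(tree, model, scales, target_node, rng)
        seqs = {
            name: "".join(BASES[s] for s in leaf_states[i])
            for i, name in enumerate(tree.leaf_names)
        }
        blocks.append(AlignmentBlock(chrom, start, end, seqs, ref))
    truth_df = pd.DataFrame(truth, columns=["chrom", "start", "end", "name", "score", "strand"])
    return blocks, truth_df


def element_in_flanks_specs(chrom, start, element_len=200, flank=400,
                            regime="conserved", rho=0.3, lam=1.0):
    """Convenience: neutral flank + planted element + neutral flank."""
    a = RegionSpec(chrom, start, start + flank)
    b = RegionSpec(chrom, start + flank, start + flank + element_len, regime, rho, lam)
    c = RegionSpec(chrom, start + flank + element_len,
                   start + 2 * flank + element_len)
    return [a, b, c]


def apply_species_dropout(blocks, p, seed, total_species=None, keep=(),
                          min_fraction=0.9):
    """Remove whole species per block with probability ``p``.

    Species in ``keep`` (the reference, typically) are never removed so the
    block keeps its coordinates.  Returns the thinned blocks and a truth
    table with per-block species presence and whether the block clears the
    presence threshold.
    """
    if not (0.0 <= p < 1.0):
        raise ValueError("dropout probability must be in [0, 1)")
    rng = substream(seed, "dropout")
    out, rows = [], []
    for i, b in enumerate(blocks):
        species = sorted(b.sequences)
        drop = {sp for sp in species if sp not in keep and rng.random() < p}
        seqs = {sp: s for sp, s in b.sequences.items() if sp not in drop}
        nb = AlignmentBlock(b.chrom, b.start, b.end, seqs, b.ref)
        total = total_species or len(species)
        frac = len(nb.present_species()) / total
        rows.append(dict(block=i, chrom=b.chrom, start=b.start, end=b.end,
                         present=len(nb.present_species()), total=total,
                         fraction=frac, passes=frac >= min_fraction))
        out.append(nb)
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# epigenome: peaks, loops, gene models


def _merged(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def _place_peaks(chrom_sizes, elements, n_peaks, factor, width, rng):
    """Place peaks so the element-overlap rate is ``factor`` x uniform."""
    chroms = sorted(chrom_sizes)
    hit_zones, free_zones, hit_total, pos_total = {}, {}, 0, 0
    for c in chroms:
        size = chrom_sizes[c]
        n_pos = size - width + 1
        if n_pos <= 0:
            raise ValueError(f"peaks of width {width} cannot fit on {c}")
        merged = _merged([(s, e) for cc, s, e in elements if cc == c])
        zones = [(max(0, s - width + 1), min(e, n_pos)) for s, e in merged]
        zones = [(a, b) for a, b in _merged(zones) if b > a]
        hit_zones[c] = zones
        hit_len = sum(b - a for a, b in zones)
        free = []
        prev = 0
        for a, b in zones:
            if a > prev:
                free.append((prev, a))
            prev = b
        if prev < n_pos:
            free.append((prev, n_pos))
        free_zones[c] = free
        hit_total += hit_len
        pos_total += n_pos
    p_uniform = hit_total / pos_total
    q = min(factor * p_uniform, 0.95)
    if factor >= 1 and p_uniform == 0 and n_peaks > 0 and factor > 1:
        raise ValueError("no elements to enrich peaks in")

    def sample_from(zones_by_chrom, total_len):
        # one uniform draw over the concatenated zones of all chromosomes
        x = rng.integers(total_len)
        for c in chroms:
            for a, b in zones_by_chrom[c]:
                if x < b - a:
                    return c, a + int(x)
                x -= b - a
        raise AssertionError("zone sampling out of range")

    free_total = pos_total - hit_total
    rows = []
    for i in range(n_peaks):
        if rng.random() < q and hit_total > 0:
            c, x = sample_from(hit_zones, hit_total)
        elif free_total > 0:
            c, x = sample_from(free_zones, free_total)
        else:
            c, x = sample_from(hit_zones, hit_total)
        rows.append(dict(chrom=c, start=x, end=x + width,
                         name=f"peak{i}", score=1000, strand="."))
    return pd.DataFrame(rows), p_uniform, q


def _enumerate_loop_wiring(loops: pd.DataFrame, genes: pd.DataFrame,
                           elements) -> pd.DataFrame:
    """O(loops x genes x elements) wiring enumeration over emitted files.

    Promoter = 2 kb upstream + 1 kb downstream of the TSS, strand-aware;
    if one anchor overlaps a promoter, elements in the partner anchor are
    wired to that gene.  Deliberately naive: this is the scoring oracle.
    """
    proms = []
    for g in genes.itertuples(index=False):
        if g.strand == "+":
            lo, hi = g.tss - 2000, g.tss + 1000
        else:
            lo, hi = g.tss - 1000, g.tss + 2000
        proms.append((g.gene_id, g.chrom, max(0, lo), hi))
    rows = set()
    for lp in loops.itertuples(index=False):
        anchors = ((lp.chrom1, lp.start1, lp.end1), (lp.chrom2, lp.start2, lp.end2))
        for pa, da in (anchors, anchors[::-1]):
            for gid, c, lo, hi in proms:
                if c == pa[0] and lo < pa[2] and hi > pa[1]:
                    for ec, es, ee in elements:
                        if ec == da[0] and es < da[2] and ee > da[1]:
                            rows.add((lp.name, gid, ec, es, ee))
    return pd.DataFrame(sorted(rows),
                        columns=["loop", "gene_id", "chrom", "start", "end"])


def simulate_epigenome(chrom_sizes, elements_bed, seed, n_peaks=1000,
                       enrichment_factor=1.0, peak_width=500, n_genes=60,
                       n_loops=40, loop_element_fraction=0.5,
                       promoter_element_count=5, anchor_width=2000,
                       active_fraction=0.85):
    """Synthesize peaks, gene models, promoter peaks and chromatin loops.

    Peaks (a DHS/cCRE stand-in) overlap the supplied elements at
    ``enrichment_factor`` times the uniform rate.  Genes are spaced along
    the chromosomes; a fraction carry an H3K4me3-style promoter peak
    (active promoters).  Loops tie gene-promoter anchors to distal anchors,
    and ``loop_element_fraction`` of them get a distal anchor centred on one
    of the supplied elements (that wiring is the loop truth table).  The
    ``proximal_candidates`` table holds intervals placed inside the first
    ``promoter_element_count`` active promoters; appending them to the
    element set plants known promoter-proximal element-gene pairs.

    Returns a dict of DataFrames: peaks, genes, promoter_peaks, loops,
    loop_truth, proximal_candidates, plus placement diagnostics.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment factor must be >= 1")
    rng = substream(seed, "epigenome")
    elements = list(zip(elements_bed["chrom"], elements_bed["start"].astype(int),
                        elements_bed["end"].astype(int)))
    peaks, p_uniform, q = _place_peaks(chrom_sizes, elements, n_peaks,
                                       enrichment_factor, peak_width, rng)

    # gene models on a fixed grid: territories of 25 kb, gene body 4-12 kb
    chroms = sorted(c for c in chrom_sizes if c.lower() != "chry")
    territories = []
    for c in chroms:
        n_slots = max(0, (chrom_sizes[c] - 5000) // 25000)
        territories += [(c, 5000 + k * 25000) for k in range(n_slots)]
    if len(territories) < n_genes:
        raise ValueError("genome too small for the requested gene count")
    order = rng.permutation(len(territories))[:n_genes]
    genes = []
    for gi, slot in enumerate(sorted(order)):
        c, base = territories[slot]
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(rng.integers(4000, 12000))
        gstart = base + int(rng.integers(0, 2000))
        gend = gstart + glen
        tss, tes = (gstart, gend) if strand == "+" else (gend, gstart)
        n_ex = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(200, glen - 200), size=2 * n_ex - 2,
                                  replace=False))
        bounds = [0, *cuts.tolist(), glen]
        exons = [(gstart + bounds[2 * k], gstart + bounds[2 * k + 1])
                 for k in range(n_ex)]
        cds_lo = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
        cds_hi = exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2
        genes.append(dict(gene_id=f"G{gi:04d}", chrom=c, strand=strand,
                          tss=tss, tes=tes,
                          exons=",".join(f"{a}-{b}" for a, b in exons),
                          cds_start=cds_lo, cds_end=cds_hi))
    genes = pd.DataFrame(genes)

    # promoter peaks mark the active subset
    n_active = int(round(active_fraction * n_genes))
    active_idx = np.sort(rng.permutation(n_genes)[:n_active])
    prom_rows = []
    for gi in active_idx:
        g = genes.iloc[gi]
        lo = g.tss - 500 if g.strand == "+" else g.tss - 300
        prom_rows.append(dict(chrom=g.chrom, start=max(0, lo), end=lo + 800,
                              name=f"h3k4me3_{g.gene_id}", score=1000, strand="."))
    promoter_peaks = pd.DataFrame(prom_rows)
    active_ids = set(genes.iloc[active_idx]["gene_id"])

    # loops: promoter anchor at the gene TSS, distal anchor either centred
    # on a planted element (same chromosome) or in empty intergenic space
    loops, intended = [], []
    active_genes = genes.iloc[active_idx].reset_index(drop=True)
    n_loops = min(n_loops, len(active_genes))
    loop_gene_idx = rng.permutation(len(active_genes))[:n_loops]
    el_by_chrom = {}
    for e in elements:
        el_by_chrom.setdefault(e[0], []).append(e)
    for li, gi in enumerate(sorted(loop_gene_idx)):
        g = active_genes.iloc[gi]
        pa_lo = max(0, g.tss - anchor_width // 2)
        pa = (g.chrom, pa_lo, pa_lo + anchor_width)
        wired = None
        pool = el_by_chrom.get(g.chrom, [])
        if pool and rng.random() < loop_element_fraction:
            e = pool[int(rng.integers(len(pool)))]
            mid = (e[1] + e[2]) // 2
            da_lo = max(0, mid - anchor_width // 2)
            wired = e
        else:
            da_lo = int(rng.integers(0, chrom_sizes[g.chrom] - anchor_width))
        da = (g.chrom, da_lo, da_lo + anchor_width)
        loops.append(dict(chrom1=pa[0], start1=pa[1], end1=pa[2],
                          chrom2=da[0], start2=da[1], end2=da[2],
                          name=f"loop{li}", score=1.0))
        if wired is not None:
            intended.append((f"loop{li}", g.gene_id))
    loops = pd.DataFrame(loops, columns=["chrom1", "start1", "end1", "chrom2",
                                         "start2", "end2", "name", "score"])
    # the scoring truth is the wiring actually implied by the emitted files
    # (including accidental overlaps), enumerated brute-force and
    # independently of the link-genes implementation
    loop_truth = _enumerate_loop_wiring(loops, genes, elements)

    # candidate proximal wiring: elements that happen to sit in promoters is
    # geometry-dependent; emit intervals inside a few active promoters that
    # callers can append to the element set to plant proximal pairs
    prox = []
    pick = active_idx[: min(promoter_element_count, len(active_idx))]
    for gi in pick:
        g = genes.iloc[gi]
        if g.strand == "+":
            lo = g.tss - 1500
        else:
            lo = g.tss + 500
        prox.append(dict(chrom=g.chrom, start=max(0, lo), end=max(0, lo) + 300,
                         name=f"prox_{g.gene_id}", score=0, strand=".",
                         gene_id=g.gene_id))
    proximal = pd.DataFrame(prox)

    return dict(peaks=peaks, genes=genes, promoter_peaks=promoter_peaks,
                active_gene_ids=sorted(active_ids), loops=loops,
                loop_truth=loop_truth, intended_wiring=intended,
                proximal_candidates=proximal,
                p_uniform=p_uniform, target_overlap_rate=q)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(gene_ids, seed, n_samples=40, regions=("NCX",),
                        trend_genes=(), beta=0.5, noise_sd=0.2,
                        age_range=(0.0, 1.0), base_log2_mean=3.0,
                        base_log2_sd=1.0):
    """Expression matrix (RPKM-like) with a planted age trend.

    Ages are evenly spread over ``age_range`` within each region; trend
    genes gain ``beta`` log2 units of expression per unit age on top of a
    flat gene-specific baseline; Gaussian noise on the log2 scale.
    """
    rng = substream(seed, "expression")
    gene_ids = list(gene_ids)
    trend = set(trend_genes)
    missing = trend - set(gene_ids)
    if missing:
        raise ValueError(f"trend genes not in gene list: {sorted(missing)[:5]}")
    samples, ages, regs = [], [], []
    per_region = int(np.ceil(n_samples / len(regions)))
    k = 0
    for r in regions:
        n_r = min(per_region, n_samples - k)
        a = np.linspace(age_range[0], age_range[1], n_r)
        for j in range(n_r):
            samples.append(f"S{k:03d}")
            ages.append(float(a[j]))
            regs.append(r)
            k += 1
    if len(set(ages)) < 3:
        raise ValueError("need at least 3 distinct ages")
    ages = np.array(ages)
    base = rng.normal(base_log2_mean, base_log2_sd, size=len(gene_ids))
    log2x = base[:, None] + rng.normal(0.0, noise_sd, size=(len(gene_ids), len(samples)))
    is_trend = np.array([g in trend for g in gene_ids])
    log2x[is_trend] += beta * ages[None, :]
    expr = pd.DataFrame(np.power(2.0, log2x), index=gene_ids, columns=samples)
    meta = pd.DataFrame({"age": ages, "region": regs}, index=samples)
    meta.index.name = "sample"
    return expr, meta


def simulate_coexpression_module(seed, n_hub=40, n_noise=60, n_samples=40,
                                 hub_noise_sd=0.4, profile_wiggle=0.7,
                                 age_range=(0.0, 1.0)):
    """A module matrix with planted hub genes among unrelated noise genes.

    The module profile is an age trend plus an orthogonal "biological
    wiggle" component (``profile_wiggle`` controls its weight), so the
    module eigengene correlates with age imperfectly (~0.8 by default), as
    developmental coexpression modules do — with a perfectly age-aligned
    eigengene the membership and age-significance criteria would collapse
    into one test.  Hub genes follow the profile closely (so they pass both
    the eigengene- and age-correlation criteria); noise genes are
    independent Gaussians.  About 40% of the module being genuine
    profile-followers mirrors the coherence of clustered modules.
    Returns (matrix, ages, hub_gene_ids).
    """
    rng = substream(seed, "module")
    ages = np.linspace(*age_range, n_samples)
    za = (ages - ages.mean()) / ages.std()
    w = rng.normal(size=n_samples)
    w = w - w.mean() - np.dot(w, za) / np.dot(za, za) * za  # orthogonalize
    zw = w / w.std()
    profile = za + profile_wiggle * zw
    profile = (profile - profile.mean()) / profile.std()
    rows, names = [], []
    for i in range(n_hub):
        rows.append(profile + rng.normal(0, hub_noise_sd, n_samples))
        names.append(f"HUB{i:03d}")
    for i in range(n_noise):
        rows.append(rng.normal(0, 1.0, n_samples))
        names.append(f"NOISE{i:03d}")
    mat = pd.DataFrame(rows, index=names,
                       columns=[f"S{j:03d}" for j in range(n_samples)])
    return mat, ages, names[:n_hub]
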