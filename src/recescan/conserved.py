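"""Conserved-element detection with a two-state phylogenetic HMM.

A neutral state emits alignment columns under the input model at scale 1;
a conserved state emits them with all branches scaled by ``rho`` < 1.
Forward-backward gives per-column conserved-state posteriors; elements are
maximal runs of the Viterbi conserved state, scored by the summed
column-wise log-odds of conserved over neutral emission.  Blocks are first
filtered on species presence (at least 90% of the tree's species by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .phylo import PhyloTree, SubstitutionModel, encode_columns, tree_loglik


@dataclass
class ConservationHMM:
    """Two-state chain: state 0 = neutral, state 1 = conserved (scale rho).

    ``mu`` is the conserved->neutral switch probability (1/expected element
    length), ``nu`` the neutral->conserved probability; the chain starts
    from its stationary distribution.  Defaults follow common conservation
    scans: rho = 0.3, expected element length 45 bp, expected conserved
    coverage 0.3.
    """

    rho: float = 0.3
    mu: float = 1.0 / 45.0
    nu: float = (1.0 / 45.0) * 0.3 / 0.7

    def __post_init__(self):
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must be in (0, 1)")
        if not (0.0 < self.mu < 1.0 and 0.0 < self.nu < 1.0):
            raise ValueError("mu and nu must be in (0, 1)")

    @property
    def transitions(self) -> np.ndarray:
        return np.array([[1 - self.nu, self.nu], [self.mu, 1 - self.mu]])

    @property
    def stationary(self) -> np.ndarray:
        z = self.mu + self.nu
        return np.array([self.mu / z, self.nu / z])


def filter_blocks(blocks, total_species, min_fraction=0.90):
    """Keep blocks where >= ``min_fraction`` of all species have data.

    A species counts as present only if it contributes at least one
    non-missing base; an all-gap row is absent.
    """
    kept = []
    for b in blocks:
        if len(b.present_species()) / total_species >= min_fraction:
            kept.append(b)
    return kept


def emission_logliks(block, hmm, tree: PhyloTree, model: SubstitutionModel):
    """(n_cols, 2) per-column log-likelihoods under neutral and conserved."""
    cols = encode_columns(
        {sp: seq for sp, seq in block.sequences.items()}, tree.leaf_names
    )
    neutral = tree_loglik(tree, model, cols, s=1.0, per_column=True)
    conserved = tree_loglik(tree, model, cols, s=hmm.rho, per_column=True)
    return np.column_stack([neutral, conserved])


def _forward_backward(emis: np.ndarray, hmm: ConservationHMM):
    n = emis.shape[0]
    logA = np.log(hmm.transitions)
    logpi = np.log(hmm.stationary)
    fwd = np.empty((n, 2))
    fwd[0] = logpi + emis[0]
    for t in range(1, n):
        fwd[t] = emis[t] + logsumexp(fwd[t - 1][:, None] + logA, axis=0)
    bwd = np.empty((n, 2))
    bwd[-1] = 0.0
    for t in range(n - 2, -1, -1):
        bwd[t] = logsumexp(logA + (emis[t + 1] + bwd[t + 1])[None, :], axis=1)
    ll_fwd = logsumexp(fwd[-1])
    ll_bwd = logsumexp(logpi + emis[0] + bwd[0])
    post = fwd + bwd - ll_fwd
    return np.exp(post), float(ll_fwd), float(ll_bwd)


def posterior_decode(block, hmm, tree, model):
    """Per-column conserved-state posterior probabilities in [0, 1]."""
    emis = emission_logliks(block, hmm, tree, model)
    post, ll_fwd, ll_bwd = _forward_backward(emis, hmm)
    return post[:, 1], ll_fwd, ll_bwd


def _viterbi(emis: np.ndarray, hmm: ConservationHMM) -> np.ndarray:
    # ties broken toward neutral (state 0): strict > required to prefer 1
    n = emis.shape[0]
    logA = np.log(hmm.transitions)
    logpi = np.log(hmm.stationary)
    delta = logpi + emis[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + logA  # cand[i, j]: best via previous state i
        choice = (cand[1] > cand[0]).astype(np.int8)
        back[t] = choice
        delta = emis[t] + np.where(choice == 1, cand[1], cand[0])
    path = np.empty(n, dtype=np.int8)
    path[-1] = 1 if delta[1] > delta[0] else 0
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def call_elements(block, hmm, tree, model) -> pd.DataFrame:
    """Maximal Viterbi conserved runs as a BED6 DataFrame.

    The score is the summed log-odds of conserved over neutral emission
    across the element's columns.
    """
    emis = emission_logliks(block, hmm, tree, model)
    path = _viterbi(emis, hmm)
    logodds = emis[:, 1] - emis[:, 0]
    rows = []
    i = 0
    n = len(path)
    while i < n:
        if path[i] == 1:
            j = i
            while j < n and path[j] == 1:
                j += 1
            rows.append(dict(
                chrom=block.chrom,
                start=block.start + i,
                end=block.start + j,
                name=f"CE_{block.chrom}_{block.start + i}",
                score=float(logodds[i:j].sum()),
                strand=".",
            ))
            i = j
        else:
            i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def scan_blocks(blocks, hmm, tree, model, total_species=None, min_fraction=0.90):
    """Filter blocks on species presence, then call elements on each."""
    total = total_species or tree.n_leaves
    kept = filter_blocks(blocks, total, min_fraction)
    frames = [call_elements(b, hmm, tree, model) for b in kept]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
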