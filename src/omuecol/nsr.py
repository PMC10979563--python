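"""Stochasticity ratio (SR) and normalized stochasticity ratio (NSR).

The framework asks how far observed pairwise community similarities
deviate from a null model in which assembly is purely stochastic.  With
C_ij the observed Ružička similarity of samples i and j and Ē_ij the
null-expected similarity (averaged over simulated metacommunities):

* deterministic forces that make communities more similar (C > Ē) give a
  type A ratio  SR^A_ij = Ē_ij / C_ij;
* deterministic forces that make communities more dissimilar (C < Ē) give
  a type B ratio SR^B_ij = (1 - Ē_ij) / (1 - C_ij);
* SR is the weighted mean of both types over all pairs; SR = 1 when every
  observed similarity equals its null expectation (pure stochasticity)
  and 0 when similarity is observed where none is expected.

The normalized ratio rescales each pair by the distance to the
deterministic extreme: NSR_ij = (1 - C)/(1 - Ē) for type A pairs and
C/Ē for type B pairs, so every pair contributes a value in [0, 1] that is
1 exactly when the observation matches the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .omu_table import OmuTable, relative_abundance


@dataclass
class SimilaritySet:
    """Observed and null-expected pairwise similarities of a metacommunity."""

    n_communities: int
    C: np.ndarray        # observed pairwise similarity, symmetric
    E_bar: np.ndarray    # null-expected similarity, symmetric
    n_null: int = 0

    def pairs(self) -> list[tuple[int, int]]:
        m = self.n_communities
        return [(i, j) for i in range(m) for j in range(i + 1, m)]


@dataclass
class NsrResult:
    SR: float
    NSR: float
    n_A: int
    n_B: int
    sr_A: dict[tuple[int, int], float]
    sr_B: dict[tuple[int, int], float]
    excluded_pairs: list[tuple[int, int]]


def ruzicka(col_i: np.ndarray, col_j: np.ndarray) -> float:
    """Abundance-based (quantitative Jaccard) similarity: sum min / sum max."""
    col_i = np.asarray(col_i, dtype=float)
    col_j = np.asarray(col_j, dtype=float)
    if col_i.shape != col_j.shape:
        raise ValueError("columns must have equal length")
    if np.any(col_i < 0) or np.any(col_j < 0):
        raise ValueError("abundances must be non-negative")
    denom = np.maximum(col_i, col_j).sum()
    if denom == 0:
        warnings.warn("both columns all-zero; similarity defined as 0")
        return 0.0
    return float(np.minimum(col_i, col_j).sum() / denom)


def pairwise_ruzicka(rel: np.ndarray) -> np.ndarray:
    """Pairwise Ružička over the columns of a relative-abundance matrix."""
    n = rel.shape[1]
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            C[i, j] = C[j, i] = ruzicka(rel[:, i], rel[:, j])
    return C


def null_expected_similarity(
    table: OmuTable, n_sims: int = 1000, seed: int = 0,
    null_model: str = "regional",
) -> np.ndarray:
    """Null-expected pairwise similarity matrix Ē.

    ``regional`` (default): each simulated metacommunity preserves every
    sample's richness and read total; the sample's occupied OMUs are
    re-drawn (without replacement) with probability proportional to
    regional occurrence frequency, and its reads are then distributed
    multinomially over the occupants proportionally to their regional
    mean relative abundances.  Samples assembled purely by dispersal
    from the shared regional pool are then statistically exchangeable
    with their null draws, so observed similarity matches Ē.

    ``permute``: occupancy as above, but each sample's observed nonzero
    abundance multiset is permuted onto the occupants (no regional
    abundance structure preserved).

    Ē is the mean Ružička matrix over ``n_sims`` draws.
    """
    if n_sims < 1:
        raise ValueError("need at least one null simulation")
    if null_model not in {"regional", "permute"}:
        raise ValueError(f"unknown null model {null_model!r}")
    rng = np.random.default_rng(seed)
    counts = table.values()
    n_omu, n_samp = counts.shape
    occurrence = (counts > 0).sum(axis=1).astype(float)
    if occurrence.sum() == 0:
        raise ValueError("empty table")
    weights = occurrence / occurrence.sum()
    totals = counts.sum(axis=0)
    safe_tot = np.where(totals == 0, 1.0, totals)
    regional_mean = (counts / safe_tot).mean(axis=1)
    nonzero_sets = [np.flatnonzero(counts[:, j]) for j in range(n_samp)]
    E_sum = np.zeros((n_samp, n_samp))
    for _ in range(n_sims):
        null = np.zeros_like(counts)
        for j in range(n_samp):
            occupied = nonzero_sets[j]
            r = len(occupied)
            if r == 0:
                continue
            occupants = rng.choice(n_omu, size=r, replace=False, p=weights)
            if null_model == "permute":
                null[occupants, j] = rng.permutation(counts[occupied, j])
            else:
                probs = regional_mean[occupants]
                if probs.sum() == 0:
                    probs = np.ones(r)
                null[occupants, j] = rng.multinomial(
                    int(totals[j]), probs / probs.sum()
                )
        tot = null.sum(axis=0)
        tot[tot == 0] = 1.0
        E_sum += pairwise_ruzicka(null / tot)
    return E_sum / n_sims


def stochasticity_ratio(sims: SimilaritySet) -> NsrResult:
    """SR from observed and null-expected similarities.

    Pairs with C = Ē contribute ratio 1 and are booked as type A.  Pairs
    whose branch denominator vanishes (C = 0 in type A, C = 1 in type B)
    are excluded with a warning.
    """
    sr_A: dict[tuple[int, int], float] = {}
    sr_B: dict[tuple[int, int], float] = {}
    nsr_vals: list[float] = []
    excluded: list[tuple[int, int]] = []
    for i, j in sims.pairs():
        C, E = float(sims.C[i, j]), float(sims.E_bar[i, j])
        if C > E:
            if C == 0:  # pragma: no cover - unreachable since C > E >= 0
                excluded.append((i, j))
                continue
            sr_A[(i, j)] = E / C
            nsr_vals.append((1.0 - C) / (1.0 - E) if E < 1 else 1.0)
        elif C < E:
            if C == 1:  # pragma: no cover - unreachable since C < E <= 1
                excluded.append((i, j))
                continue
            sr_B[(i, j)] = (1.0 - E) / (1.0 - C)
            nsr_vals.append(C / E)
        else:
            sr_A[(i, j)] = 1.0
            nsr_vals.append(1.0)
    if excluded:
        warnings.warn(f"pairs excluded from SR (degenerate denominator): {excluded}")
    n_A, n_B = len(sr_A), len(sr_B)
    if n_A + n_B == 0:
        raise ValueError("no valid pairs for SR")
    SR = (sum(sr_A.values()) + sum(sr_B.values())) / (n_A + n_B)
    NSR = float(np.clip(np.mean(nsr_vals), 0.0, 1.0))
    return NsrResult(SR=SR, NSR=NSR, n_A=n_A, n_B=n_B,
                     sr_A=sr_A, sr_B=sr_B, excluded_pairs=excluded)


def normalized_stochasticity_ratio(
    table: OmuTable, n_sims: int = 1000, seed: int = 0
) -> NsrResult:
    """Full pipeline: observed Ružička, null expectation, SR and NSR."""
    rel = relative_abundance(table).to_numpy()
    C = pairwise_ruzicka(rel)
    E_bar = null_expected_similarity(table, n_sims=n_sims, seed=seed)
    sims = SimilaritySet(table.n_samples, C, E_bar, n_null=n_sims)
    return stochasticity_ratio(sims)


def compare_nsr(
    tableH: OmuTable, tableD: OmuTable, n_sims: int = 1000, seed: int = 0
) -> dict[str, NsrResult]:
    """Intra-healthy, intra-diseased and inter-treatment stochasticity.

    The two tables are outer-joined on OMU id; the inter scheme restricts
    the pair set to cross-treatment pairs of the pooled metacommunity.
    """
    ids = sorted(set(tableH.omu_ids) | set(tableD.omu_ids))
    H = tableH.counts.reindex(ids, fill_value=0.0)
    D = tableD.counts.reindex(ids, fill_value=0.0)
    if tableH.n_samples < 2 or tableD.n_samples < 2:
        raise ValueError("each treatment needs at least 2 samples")
    out: dict[str, NsrResult] = {}
    out["intra_healthy"] = normalized_stochasticity_ratio(
        OmuTable(H, level=tableH.level, mode=tableH.mode), n_sims=n_sims, seed=seed
    )
    out["intra_diseased"] = normalized_stochasticity_ratio(
        OmuTable(D, level=tableD.level, mode=tableD.mode), n_sims=n_sims, seed=seed + 1
    )
    pooled = OmuTable(
        H.join(D, lsuffix="_H", rsuffix="_D"),
        level=tableH.level, mode=tableH.mode,
    )
    rel = relative_abundance(pooled).to_numpy()
    C = pairwise_ruzicka(rel)
    E_bar = null_expected_similarity(pooled, n_sims=n_sims, seed=seed + 2)
    nH = tableH.n_samples
    n_tot = pooled.n_samples
    # inter scheme: only cross-treatment pairs contribute
    sr_A: dict[tuple[int, int], float] = {}
    sr_B: dict[tuple[int, int], float] = {}
    nsr_vals: list[float] = []
    for i in range(nH):
        for j in range(nH, n_tot):
            C_ij, E_ij = float(C[i, j]), float(E_bar[i, j])
            if C_ij > E_ij:
                sr_A[(i, j)] = E_ij / C_ij
                nsr_vals.append((1 - C_ij) / (1 - E_ij) if E_ij < 1 else 1.0)
            elif C_ij < E_ij:
                sr_B[(i, j)] = (1 - E_ij) / (1 - C_ij)
                nsr_vals.append(C_ij / E_ij)
            else:
                sr_A[(i, j)] = 1.0
                nsr_vals.append(1.0)
    SR = (sum(sr_A.values()) + sum(sr_B.values())) / max(len(sr_A) + len(sr_B), 1)
    out["inter"] = NsrResult(
        SR=SR, NSR=float(np.clip(np.mean(nsr_vals), 0, 1)),
        n_A=len(sr_A), n_B=len(sr_B), sr_A=sr_A, sr_B=sr_B, excluded_pairs=[],
    )
    return out
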