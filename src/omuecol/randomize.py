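"""Randomization (permutation) tests for treatment comparisons.

Two resampling algorithms:

* **A1 — remix of OMUs**: within every sample, the observed abundances
  are randomly reassigned to OMU ids; each sample's abundance multiset
  and total are preserved, the OMU identity structure is destroyed.
* **A2 — remix of samples**: samples from both treatments are pooled and
  treatment labels reassigned at random, preserving group sizes; each
  sample column is preserved exactly.

Significance is summarized by the add-one pseudo p-value
(1 + #{null >= observed}) / (1 + B), which can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .networks import CpnResult, build_network, detect_core_periphery
from .omu_table import OmuTable
from .sloan import NeutralityClassification, SloanFit, classify, estimate_m


@dataclass
class RandomizationResult:
    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    null_quantiles: dict[str, float]
    pseudo_p: float
    algorithm: str
    B: int
    seed: int


@dataclass
class SharedNodesResult:
    observed: dict[str, int]          # shared core / periphery / total
    null_mean: dict[str, float]
    pseudo_p_decline: dict[str, float]
    pseudo_p_rise: dict[str, float]
    B_effective: int


def permute(
    tableH: OmuTable, tableD: OmuTable, algorithm: str, seed: int
) -> tuple[OmuTable, OmuTable]:
    """One permuted (healthy*, diseased*) pair under algorithm A1 or A2."""
    rng = np.random.default_rng(seed)
    if algorithm == "A2":
        left, right = tableH.counts, tableD.counts
        if set(left.columns) & set(right.columns):
            left = left.rename(columns=lambda c: f"H:{c}")
            right = right.rename(columns=lambda c: f"D:{c}")
        pooled = pd.concat([left, right], axis=1)
        cols = np.array(pooled.columns)
        rng.shuffle(cols)
        nH = tableH.n_samples
        H = pooled[cols[:nH]]
        D = pooled[cols[nH:]]
        return (
            OmuTable(H, level=tableH.level, mode=tableH.mode),
            OmuTable(D, level=tableD.level, mode=tableD.mode),
        )
    if algorithm == "A1":
        out = []
        for table in (tableH, tableD):
            arr = table.values().copy()
            for j in range(arr.shape[1]):
                arr[:, j] = arr[rng.permutation(arr.shape[0]), j]
            out.append(
                OmuTable(
                    pd.DataFrame(arr, index=table.omu_ids, columns=table.sample_ids),
                    level=table.level,
                    mode=table.mode,
                )
            )
        return out[0], out[1]
    raise ValueError(f"unknown algorithm {algorithm!r}; expected 'A1' or 'A2'")


def randomization_test(
    stat_fn: Callable[[OmuTable, OmuTable], float],
    tableH: OmuTable,
    tableD: OmuTable,
    algorithm: str = "A2",
    B: int = 1000,
    seed: int = 0,
    statistic: str = "statistic",
) -> RandomizationResult:
    """Two-sided permutation test of a table-pair statistic.

    The null distribution is ``stat_fn`` over B permuted pairs; the
    pseudo p compares absolute values (two-sided on the difference).
    Aborts if the statistic fails on more than 10% of permutations.
    """
    observed = float(stat_fn(tableH, tableD))
    null = []
    failures = 0
    for b in range(B):
        H_star, D_star = permute(tableH, tableD, algorithm, seed=seed + b + 1)
        try:
            null.append(float(stat_fn(H_star, D_star)))
        except Exception:
            failures += 1
            if failures > 0.1 * B:
                raise RuntimeError(
                    f"statistic failed on {failures} of {b + 1} permutations"
                )
    null_arr = np.array(null)
    pseudo_p = (1 + int((np.abs(null_arr) >= abs(observed)).sum())) / (1 + len(null_arr))
    qs = np.quantile(null_arr, [0.025, 0.5, 0.975]) if len(null_arr) else [np.nan] * 3
    return RandomizationResult(
        statistic=statistic,
        observed=observed,
        null_mean=float(null_arr.mean()) if len(null_arr) else np.nan,
        null_sd=float(null_arr.std(ddof=1)) if len(null_arr) > 1 else np.nan,
        null_quantiles={"q025": float(qs[0]), "q50": float(qs[1]), "q975": float(qs[2])},
        pseudo_p=pseudo_p,
        algorithm=algorithm,
        B=len(null_arr),
        seed=seed,
    )


def _shared_counts(cpnH: CpnResult, cpnD: CpnResult) -> dict[str, int]:
    coreH, coreD = set(cpnH.core), set(cpnD.core)
    periH, periD = set(cpnH.periphery), set(cpnD.periphery)
    return {
        "core": len(coreH & coreD),
        "periphery": len(periH & periD),
        "total": len((coreH | periH) & (coreD | periD)),
    }


def shared_core_periphery(
    tableH: OmuTable,
    tableD: OmuTable,
    B: int = 1000,
    algorithm: str = "A2",
    seed: int = 0,
    alpha: float = 0.05,
    cpn_seed: int = 1,
    fast: bool = False,
) -> SharedNodesResult:
    """Do the two treatments share more or fewer core/periphery OMUs than
    expected by chance?

    Networks and core/periphery splits are recomputed on every permuted
    pair; ``fast=True`` instead permutes node labels of the two fixed
    networks (an approximation, cheap enough for large B).
    """
    netH = build_network(tableH, alpha=alpha)
    netD = build_network(tableD, alpha=alpha)
    cpnH = detect_core_periphery(netH, seed=cpn_seed)
    cpnD = detect_core_periphery(netD, seed=cpn_seed)
    observed = _shared_counts(cpnH, cpnD)
    rng = np.random.default_rng(seed)
    null: list[dict[str, int]] = []
    discarded = 0
    for b in range(B):
        try:
            if fast:
                relabelled = _relabel(cpnD, rng)
                null.append(_shared_counts(cpnH, relabelled))
            else:
                H_star, D_star = permute(tableH, tableD, algorithm, seed=seed + b + 1)
                cH = detect_core_periphery(build_network(H_star, alpha=alpha), seed=cpn_seed)
                cD = detect_core_periphery(build_network(D_star, alpha=alpha), seed=cpn_seed)
                null.append(_shared_counts(cH, cD))
        except ValueError:
            discarded += 1
    B_eff = len(null)
    if B_eff == 0:
        raise RuntimeError("all permutations failed to yield a core/periphery split")
    means, p_dec, p_ris = {}, {}, {}
    for key in observed:
        vals = np.array([d[key] for d in null])
        means[key] = float(vals.mean())
        p_dec[key] = (1 + int((vals <= observed[key]).sum())) / (1 + B_eff)
        p_ris[key] = (1 + int((vals >= observed[key]).sum())) / (1 + B_eff)
    return SharedNodesResult(
        observed=observed,
        null_mean=means,
        pseudo_p_decline=p_dec,
        pseudo_p_rise=p_ris,
        B_effective=B_eff,
    )


def _relabel(cpn: CpnResult, rng: np.random.Generator) -> CpnResult:
    perm = rng.permutation(len(cpn.nodes))
    nodes = [cpn.nodes[i] for i in perm]
    return CpnResult(nodes, cpn.delta.copy(), cpn.rho_score, cpn.core_strength)


def integrate_sloan_cpn(
    table: OmuTable, cpn: CpnResult, level: float = 0.95, min_side: int = 5
) -> dict[str, tuple[SloanFit, NeutralityClassification] | None]:
    """Neutral-model fit run separately on the core and periphery OMUs.

    The table is split into a core-OMU subtable and a periphery-OMU
    subtable and the occurrence-frequency classifier runs on each,
    yielding a neutrality-by-structure cross report.  A side with fewer
    than ``min_side`` OMUs is skipped (None) with a warning.
    """
    import warnings

    out: dict[str, tuple[SloanFit, NeutralityClassification] | None] = {}
    for name, ids in (("core", cpn.core), ("periphery", cpn.periphery)):
        present = [i for i in ids if i in table.counts.index]
        if len(present) < min_side:
            warnings.warn(f"{name} side has {len(present)} OMUs (<{min_side}); skipped")
            out[name] = None
            continue
        sub = OmuTable(table.counts.loc[present], level=table.level, mode=table.mode)
        fit = estimate_m(sub)
        out[name] = (fit, classify(fit, sub, level=level))
    return out
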