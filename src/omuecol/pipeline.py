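"""End-to-end orchestration: config -> synthetic/loaded tables -> stages
-> report bundle.

One global seed fans out to per-stage substreams (stage name hashed into
the seed) so toggling one stage never perturbs another's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .motifs import find_mao, pn_ratio, trio_census
from .networks import (
    build_network,
    cpn_properties,
    detect_core_periphery,
    extract_skeleton,
    link_salience,
)
from .nsr import normalized_stochasticity_ratio
from .omu_table import OmuTable, read_omu_table
from .randomize import integrate_sloan_cpn
from .simulate import SyntheticSpec, sample_source_profile, simulate_neutral_assemblage
from .sloan import fit_and_classify

log = logging.getLogger("omuecol")


@dataclass
class RunConfig:
    """Declarative run description (loadable from YAML)."""

    table: str | None = None            # path to an OMU table TSV
    orientation: str = "rows-are-omus"
    synthetic: dict | None = None       # SyntheticSpec fields
    stages: list[str] = field(
        default_factory=lambda: ["sloan", "nsr", "network", "cpn", "hsn", "motifs"]
    )
    alpha: float = 0.05
    s_star: float = 0.9
    level: float = 0.95
    n_sims: int = 1000
    seed: int = 1
    out_dir: str = "omuecol_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if cfg.table is not None and not Path(cfg.table).exists():
            raise FileNotFoundError(f"input table not found: {cfg.table}")
        if cfg.table is None and cfg.synthetic is None:
            raise ValueError("config must give either a table path or a synthetic spec")
        return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived substream seed, stable across stage toggling (< 2**31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _load_table(config: RunConfig) -> OmuTable:
    if config.table is not None:
        return read_omu_table(config.table, orientation=config.orientation)
    spec = SyntheticSpec(seed=stage_seed(config.seed, "simulate"),
                         **(config.synthetic or {}))
    profile = sample_source_profile(spec)
    table, _ = simulate_neutral_assemblage(
        profile, spec.m, spec.I_T, spec.n_samples, spec.depth, seed=spec.seed + 1
    )
    return table


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; write the bundle.

    Returns the summary dict (also written as ``summary.json``).  Any
    stage failure raises after partial outputs are preserved.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = _load_table(config)
    table.to_tsv(out_dir / "table.tsv")
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_omu": table.n_omu,
        "n_samples": table.n_samples,
    }
    summary["config_hash"] = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]

    net = cpn = None
    if "sloan" in config.stages:
        fit, cls = fit_and_classify(table, level=config.level)
        cls.table.to_csv(out_dir / "sloan_classification.tsv", sep="\t", index=False)
        summary["sloan"] = {
            "m": fit.m, "N_T": fit.N_T, "d": fit.d, "r_squared": fit.r_squared,
            "counts": cls.counts, "percentages": cls.percentages,
        }
        log.info("sloan: m=%.4f R2=%.3f %s", fit.m, fit.r_squared, cls.counts)
    if "nsr" in config.stages:
        res = normalized_stochasticity_ratio(
            table, n_sims=config.n_sims, seed=stage_seed(config.seed, "nsr")
        )
        summary["nsr"] = {
            "SR": res.SR, "NSR": res.NSR, "n_A": res.n_A, "n_B": res.n_B,
        }
        log.info("nsr: SR=%.3f NSR=%.3f", res.SR, res.NSR)
    if "network" in config.stages:
        net = build_network(table, alpha=config.alpha)
        _write_edges(net, out_dir / "edges.tsv")
        summary["network"] = {
            "nodes": net.number_of_nodes(), "edges": net.number_of_edges(),
        }
        if net.number_of_edges() > 0:
            pr = pn_ratio(net)
            summary["network"]["pn_ratio"] = _json_num(pr.ratio)
            summary["network"]["n_positive"] = pr.n_positive
            summary["network"]["n_negative"] = pr.n_negative
    if "cpn" in config.stages and net is not None and net.number_of_edges() > 0:
        cpn = detect_core_periphery(net, seed=stage_seed(config.seed, "cpn"))
        props = cpn_properties(net, cpn)
        props["block_pn"] = {k: list(v) for k, v in props["block_pn"].items()}
        summary["cpn"] = _jsonable(props)
    if "hsn" in config.stages and net is not None and net.number_of_edges() > 0:
        hsn = extract_skeleton(net, link_salience(net), s_star=config.s_star)
        summary["hsn"] = _jsonable(
            {
                "fraction": hsn.fraction,
                "moments": hsn.moments,
                "assortativity": hsn.assortativity,
                "skeleton_edges": len(hsn.skeleton),
            }
        )
    if "motifs" in config.stages and net is not None and net.number_of_edges() > 0:
        mao = find_mao(table)
        if mao in net:
            member = trio_census(net, mao, mode="member")
            handle = trio_census(net, mao, mode="handle")
            summary["motifs"] = {
                "mao": mao,
                "member": member.counts, "member_total": member.total,
                "handle": handle.counts, "handle_total": handle.total,
            }
    if "integration" in config.stages and cpn is not None:
        integ = integrate_sloan_cpn(table, cpn, level=config.level)
        summary["integration"] = {
            side: (None if r is None else {"m": r[0].m, "counts": r[1].counts,
                                           "percentages": r[1].percentages})
            for side, r in integ.items()
        }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _write_edges(net, path: Path) -> None:
    import pandas as pd

    rows = [
        {"source": u, "target": v, **{k: d.get(k) for k in ("rho", "q", "sign")}}
        for u, v, d in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "q", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def _json_num(x):
    if isinstance(x, float) and (math.isinf(x) or math.isnan(x)):
        return str(x)
    return x


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    return _json_num(obj)
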