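"""Synthetic metagenome assemblages with known ground truth.

The generator emulates a metacommunity of local metagenome samples
assembled from one source community under the near-neutral model: local
relative abundances are beta-distributed around the source frequencies
with concentration set by the product of local community size ``I_T`` and
the immigration probability ``m``.  On top of this neutral backbone it can
plant above-/below-neutral OMUs (occurrence-frequency distortion),
correlated core/periphery blocks, redundant MG->MF annotations, and a
healthy-vs-diseased fold change — all recorded as ground truth so the
downstream classifiers, network detectors and tests can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .omu_table import AnnotationMap, OmuTable


@dataclass
class SourceCommunityProfile:
    """Relative abundances in the regional source community."""

    omu_ids: list[str]
    p: np.ndarray  # strictly positive, sums to 1

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p <= 0):
            raise ValueError("source abundances must be strictly positive")
        self.p = self.p / self.p.sum()


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic metacommunity.

    Defaults are at the functional-gene-cluster (MFGC) scale: a few
    hundred OMUs, tens of thousands of reads per sample, lognormal
    source-abundance heterogeneity spanning several orders of magnitude.
    """

    n_omu: int = 300
    n_samples: int = 100
    I_T: int = 50_000          # local community saturation size
    m: float = 0.3             # immigration probability
    depth: int = 50_000        # reads per sample
    sigma: float = 2.0         # lognormal sd of source abundances (log scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.m <= 1:
            raise ValueError("immigration probability m must be in (0, 1]")
        if self.I_T < 2:
            raise ValueError("I_T must be >= 2")
        if self.n_omu < 2:
            raise ValueError("need at least 2 OMUs")


@dataclass
class PlantedTruth:
    """Per-OMU ground-truth labels for scoring downstream inference."""

    neutrality: dict[str, str] = field(default_factory=dict)  # neutral/above/below
    structure: dict[str, str] = field(default_factory=dict)   # core/periphery/none
    treatment_affected: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(set(self.neutrality) | set(self.structure) | self.treatment_affected)
        return pd.DataFrame(
            {
                "omu_id": ids,
                "neutrality": [self.neutrality.get(i, "neutral") for i in ids],
                "structure": [self.structure.get(i, "none") for i in ids],
                "treatment_affected": [i in self.treatment_affected for i in ids],
            }
        )


def sample_source_profile(spec: SyntheticSpec) -> SourceCommunityProfile:
    """Lognormal source-community profile, normalized to sum to 1."""
    rng = np.random.default_rng(spec.seed)
    ids = [f"OMU{i:04d}" for i in range(spec.n_omu)]
    if spec.sigma == 0:
        p = np.full(spec.n_omu, 1.0 / spec.n_omu)
    else:
        p = rng.lognormal(mean=0.0, sigma=spec.sigma, size=spec.n_omu)
        p = p / p.sum()
    return SourceCommunityProfile(ids, p)


def simulate_neutral_assemblage(
    profile: SourceCommunityProfile,
    m: float,
    I_T: int,
    n_samples: int,
    depth: int,
    seed: int,
    level: str = "MFGC",
) -> tuple[OmuTable, PlantedTruth]:
    """Draw a metacommunity of neutral local communities.

    For each sample and OMU the local relative abundance is drawn from
    Beta(I_T*m*p_i, I_T*m*(1-p_i)); draws are jointly renormalized per
    sample and read counts drawn multinomially at the sequencing depth.
    """
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    a = I_T * m * profile.p
    b = I_T * m * (1.0 - profile.p)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("beta shape parameters must be positive")
    rng = np.random.default_rng(seed)
    n = len(profile.omu_ids)
    counts = np.empty((n, n_samples), dtype=float)
    for j in range(n_samples):
        phi = rng.beta(a, b)
        total = phi.sum()
        if total == 0:  # pragma: no cover - measure zero
            phi = profile.p.copy()
            total = 1.0
        counts[:, j] = rng.multinomial(depth, phi / total)
    table = OmuTable(
        pd.DataFrame(counts, index=profile.omu_ids,
                     columns=[f"S{j:03d}" for j in range(n_samples)]),
        level=level,
        mode="type2",
    )
    truth = PlantedTruth(neutrality={i: "neutral" for i in profile.omu_ids})
    return table, truth


def simulate_birth_death(
    p_i: float,
    m: float,
    I_T: int,
    n_steps: int,
    burn_in: int,
    seed: int,
    initial: int | None = None,
    thin: int = 1,
) -> np.ndarray:
    """Single-OMU neutral birth–death chain; returns post-burn-in x = I/I_T.

    At each step the OMU's abundance I increases by one with probability

        Pr(+1) = (1 - I/I_T) [m p + (1 - m) I/(I_T - 1)]

    decreases by one with

        Pr(-1) = (I/I_T) [m (1 - p) + (1 - m)(I_T - I)/(I_T - 1)]

    and stays put otherwise.  The stationary law of x approaches
    Beta(I_T m p, I_T m (1 - p)) — the diffusion-limit density used by the
    occurrence-frequency classifier — which makes this chain the
    independent oracle for that closed form.
    """
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    rng = np.random.default_rng(seed)
    I = I_T // 2 if initial is None else int(initial)
    if not 0 <= I <= I_T:
        raise ValueError("initial abundance out of range")
    out = np.empty((n_steps - burn_in + thin - 1) // thin, dtype=float)
    k = 0
    # pre-draw uniforms in blocks to keep the scalar chain fast
    block = 65536
    us = rng.random(block)
    ui = 0
    for step in range(n_steps):
        x = I / I_T
        up = (1.0 - x) * (m * p_i + (1.0 - m) * (I / (I_T - 1)))
        down = x * (m * (1.0 - p_i) + (1.0 - m) * ((I_T - I) / (I_T - 1)))
        if up < -1e-12 or down < -1e-12 or up + down > 1.0 + 1e-9:
            raise RuntimeError("transition probabilities outside [0, 1]")
        if ui == block:
            us = rng.random(block)
            ui = 0
        u = us[ui]
        ui += 1
        if u < up:
            I += 1
        elif u < up + down:
            I -= 1
        if step >= burn_in and (step - burn_in) % thin == 0:
            out[k] = I / I_T
            k += 1
    return out[:k]


def transition_probabilities(
    I: int, p_i: float, m: float, I_T: int
) -> tuple[float, float, float]:
    """(Pr(+1), Pr(-1), Pr(stay)) of the birth–death chain at abundance I."""
    x = I / I_T
    up = (1.0 - x) * (m * p_i + (1.0 - m) * (I / (I_T - 1)))
    down = x * (m * (1.0 - p_i) + (1.0 - m) * ((I_T - I) / (I_T - 1)))
    return up, down, 1.0 - up - down


def plant_selection(
    table: OmuTable,
    truth: PlantedTruth,
    above_ids: list[str],
    below_ids: list[str],
    boost: float = 0.8,
    suppress: float = 0.8,
    seed: int = 0,
) -> tuple[OmuTable, PlantedTruth]:
    """Plant above-/below-neutral OMUs by distorting occurrence frequency.

    Above-neutral OMUs get their zero cells re-seeded with a small positive
    count at rate ``boost``; below-neutral OMUs get their nonzero cells
    zeroed at rate ``suppress``, with the removed reads redistributed over
    the row's surviving cells so the row total is preserved.  Only the
    occurrence–abundance relation moves, which is the axis the
    occurrence-frequency classifier operates on.
    """
    overlap = set(above_ids) & set(below_ids)
    if overlap:
        raise ValueError(f"ids planted both above and below: {sorted(overlap)}")
    unknown = (set(above_ids) | set(below_ids)) - set(table.omu_ids)
    if unknown:
        raise ValueError(f"unknown OMU ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    counts = table.counts.copy()
    arr = counts.to_numpy()
    idx = {omu: i for i, omu in enumerate(table.omu_ids)}
    for omu in above_ids:
        row = arr[idx[omu]]
        zeros = np.flatnonzero(row == 0)
        flip = zeros[rng.random(len(zeros)) < boost]
        row[flip] = 1.0
        truth.neutrality[omu] = "above"
    for omu in below_ids:
        row = arr[idx[omu]]
        nz = np.flatnonzero(row > 0)
        drop = nz[rng.random(len(nz)) < suppress]
        removed = row[drop].sum()
        row[drop] = 0.0
        survivors = np.flatnonzero(row > 0)
        if len(survivors) > 0 and removed > 0:
            row[survivors] += removed * row[survivors] / row[survivors].sum()
        truth.neutrality[omu] = "below"
    counts.iloc[:, :] = arr
    return OmuTable(counts, level=table.level, mode=table.mode), truth


def plant_core_periphery(
    n_core: int,
    n_periphery: int,
    n_samples: int,
    loading: float = 0.9,
    noise: float = 1.0,
    seed: int = 0,
    scale: float = 100.0,
) -> tuple[OmuTable, PlantedTruth]:
    """Latent-factor table with a correlated core and satellite periphery.

    Core OMUs share one latent factor so every core pair correlates at
    ~``loading``.  Each periphery OMU couples to one (standardized) core
    OMU at the weaker strength ``0.45 * loading``; through the shared
    factor it correlates comparably with *every* core node, while
    periphery–periphery correlations scale as the square of the coupling
    (~0.16 at loading 0.9) and stay near zero.  Log-space signals are
    exponentiated to positive abundances, matching the ideal
    core/periphery pattern in significance-thresholded rank-correlation
    space: a dense core, a periphery tied to the core but not to itself.
    """
    if n_core < 3:
        raise ValueError("need at least 3 core OMUs")
    if not 0 < loading <= 1:
        raise ValueError("loading must be in (0, 1]")
    rng = np.random.default_rng(seed)
    factor = rng.standard_normal(n_samples)
    rows = []
    ids = []
    structure = {}
    core_signals = []
    for i in range(n_core):
        eps = rng.standard_normal(n_samples)
        sig = np.sqrt(loading) * factor + np.sqrt(1 - loading) * noise * eps
        core_signals.append(sig)
        ids.append(f"CORE{i:03d}")
        structure[ids[-1]] = "core"
        rows.append(sig)
    b = 0.45 * loading  # periphery->core coupling, kept below core cohesion
    for i in range(n_periphery):
        partner = core_signals[i % n_core]
        z = (partner - partner.mean()) / max(partner.std(), 1e-12)
        eps = rng.standard_normal(n_samples)
        sig = b * z + np.sqrt(1 - b * b) * noise * eps
        ids.append(f"PERI{i:03d}")
        structure[ids[-1]] = "periphery"
        rows.append(sig)
    abundances = scale * np.exp(np.vstack(rows))
    table = OmuTable(
        pd.DataFrame(abundances, index=ids,
                     columns=[f"S{j:03d}" for j in range(n_samples)]),
        level="MFGC",
        mode="type2",
    )
    return table, PlantedTruth(structure=structure)


def plant_treatment_effect(
    table: OmuTable,
    affected_ids: list[str],
    fold: float,
    seed: int = 0,
) -> tuple[OmuTable, OmuTable, PlantedTruth]:
    """Healthy/diseased pair: diseased multiplies affected rows by ``fold``
    and re-draws read counts at the original per-sample depths."""
    if fold <= 0:
        raise ValueError("fold change must be positive")
    unknown = set(affected_ids) - set(table.omu_ids)
    if unknown:
        raise ValueError(f"unknown OMU ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    healthy = table.copy()
    arr = table.counts.to_numpy(dtype=float).copy()
    idx = {omu: i for i, omu in enumerate(table.omu_ids)}
    for omu in affected_ids:
        arr[idx[omu]] *= fold
    depths = table.counts.sum(axis=0).to_numpy()
    out = np.zeros_like(arr)
    for j in range(arr.shape[1]):
        total = arr[:, j].sum()
        if total > 0 and depths[j] > 0:
            out[:, j] = rng.multinomial(int(depths[j]), arr[:, j] / total)
    diseased = OmuTable(
        pd.DataFrame(out, index=table.omu_ids, columns=table.sample_ids),
        level=table.level,
        mode=table.mode,
    )
    truth = PlantedTruth(treatment_affected=set(affected_ids))
    return healthy, diseased, truth


def plant_functional_turnover(
    table: OmuTable,
    ann: AnnotationMap,
    switching: float = 0.2,
    seed: int = 0,
) -> OmuTable:
    """Within-function competitive replacement among redundant members.

    Members of each function are paired; in every sample a pair's total
    abundance is re-split between the two members by a Beta(switching,
    switching) weight (small ``switching`` = winner-takes-most).  The
    pair totals — hence every aggregated MF/MP/MFGC row — are unchanged,
    while individual members acquire strong sample-specific presence/
    absence turnover.  This emulates functionally redundant genes
    substituting for each other across hosts: gene-level occurrence looks
    strongly selected, the functional aggregate stays neutral.
    """
    if switching <= 0:
        raise ValueError("switching must be positive")
    rng = np.random.default_rng(seed)
    counts = table.counts.copy()
    by_fun: dict[str, list[str]] = {}
    for mg in table.omu_ids:
        labels = ann.mg_to_labels.get(mg)
        if labels:
            by_fun.setdefault(sorted(labels)[0], []).append(mg)
    for members in by_fun.values():
        rng.shuffle(members)
        for i in range(0, len(members) - 1, 2):
            m1, m2 = members[i], members[i + 1]
            total = counts.loc[m1] + counts.loc[m2]
            w = rng.beta(switching, switching, size=len(total))
            first = np.round(total * w)
            counts.loc[m1] = first
            counts.loc[m2] = total - first
    return OmuTable(counts, level=table.level, mode=table.mode)


def redundant_annotation(
    mg_ids: list[str],
    n_functions: int,
    multi_label_rate: float = 0.2,
    seed: int = 0,
) -> AnnotationMap:
    """Many-to-one MG->MF map with functional redundancy.

    MGs are spread evenly over ``n_functions`` labels; a fraction also
    carries a second label, producing multi-function gene clusters.
    """
    rng = np.random.default_rng(seed)
    labels = [f"F{k:03d}" for k in range(n_functions)]
    mapping: dict[str, frozenset[str]] = {}
    for i, mg in enumerate(mg_ids):
        primary = labels[i % n_functions]
        assigned = {primary}
        if rng.random() < multi_label_rate:
            assigned.add(labels[rng.integers(n_functions)])
        mapping[mg] = frozenset(assigned)
    return AnnotationMap(mapping, label_space="custom")
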