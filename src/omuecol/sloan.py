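"""Sloan near-neutral model fit and neutrality classification.

The model predicts that, at stationarity, the local relative abundance
x_i of an OMU with source-community frequency p_i is beta-distributed

    x_i ~ Beta(N_T m p_i, N_T m (1 - p_i))

where N_T is the local community size and m the immigration probability.
Whether an OMU is observed in a sample depends on the detection model:

* ``reads`` (default for count tables): a sample of D reads is drawn
  from the local community, so the OMU is detected unless all D reads
  miss it; marginalizing over the beta law gives the expected occurrence
  frequency F(p_i) = 1 - B(a, b + D)/B(a, b) with a = N_T m p_i and
  b = N_T m (1 - p_i).
* ``threshold``: the OMU is observed when its relative abundance exceeds
  a hard detection limit d, giving F(p_i) = 1 - BetaCDF(d; a, b) — the
  classical occurrence-frequency fit.

Fitting minimizes the squared error between observed occurrence
frequencies and F(p) over m; each OMU is then called neutral if its
observed frequency falls inside the binomial confidence band around the
prediction, above-neutral if it occurs more often than predicted
(positively selected occurrence), below-neutral if less often.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .omu_table import OmuTable, relative_abundance


@dataclass
class SloanFit:
    """Fitted near-neutral model for one OMU table."""

    m: float                 # immigration probability estimate
    N_T: float               # community size used in fitting
    d: float                 # detection limit (threshold model) = 1/N_T
    omu_ids: list[str]
    p: np.ndarray            # mean relative abundance per OMU
    x: np.ndarray            # observed occurrence frequency per OMU
    r_squared: float
    n_samples: int
    excluded_ids: list[str]  # never-observed OMUs, reported but not fitted
    detection: str = "reads"  # "reads" or "threshold"

    @property
    def poor_fit(self) -> bool:
        return self.r_squared < 0.1


@dataclass
class NeutralityClassification:
    """Per-OMU neutral / above / below calls with the prediction band."""

    table: pd.DataFrame  # columns: omu_id, p, x, predicted, lower, upper, call
    counts: dict[str, int]
    percentages: dict[str, float]

    def fraction(self, call: str) -> float:
        return self.percentages.get(call, 0.0) / 100.0


def compute_p_x(table: OmuTable) -> tuple[pd.Series, pd.Series, float]:
    """Mean relative abundance p_i, occurrence frequency x_i, and N_T.

    N_T is taken as the mean sample column total, the natural community
    size when reads stand in for individuals.
    """
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples to fit the model")
    rel = relative_abundance(table)
    p = rel.mean(axis=1)
    x = (table.counts > 0).mean(axis=1)
    N_T = float(table.counts.sum(axis=0).mean())
    return p, x, N_T


def predicted_frequency(
    p: np.ndarray, m: float, N_T: float, d: float, detection: str = "reads"
) -> np.ndarray:
    """Expected occurrence frequency under the fitted beta law.

    ``reads``: 1 - B(a, b + D)/B(a, b) with D = round(N_T) reads drawn
    per sample (detection = at least one read hits the OMU).
    ``threshold``: 1 - BetaCDF(d; a, b) with hard detection limit d.
    """
    p = np.asarray(p, dtype=float)
    a = N_T * m * p
    b = N_T * m * (1.0 - p)
    if detection == "reads":
        D = max(round(N_T), 1)
        return 1.0 - np.exp(special.betaln(a, b + D) - special.betaln(a, b))
    if detection == "threshold":
        return 1.0 - special.betainc(a, b, d)
    raise ValueError(f"unknown detection model {detection!r}")


def estimate_m(
    table: OmuTable, d: float | None = None, detection: str = "reads"
) -> SloanFit:
    """Least-squares fit of the immigration probability m.

    Deterministic: bounded scalar minimization restarted from m = 0.1,
    0.5 and 0.9.  OMUs never observed are excluded (their occurrence
    carries no information about m) but reported.
    """
    p_all, x_all, N_T = compute_p_x(table)
    if d is None:
        d = 1.0 / N_T  # threshold model: detected above one read on average
    observed = x_all > 0
    excluded = list(x_all.index[~observed])
    p = p_all[observed].to_numpy()
    x = x_all[observed].to_numpy()
    if len(p) < 3:
        raise ValueError("fewer than 3 observed OMUs; cannot fit")

    def sse(m: float) -> float:
        pred = predicted_frequency(p, m, N_T, d, detection)
        return float(np.sum((x - pred) ** 2))

    best = None
    for bracket in ((1e-6, 0.1), (0.1, 0.5), (0.5, 1.0)):
        res = optimize.minimize_scalar(
            sse, bounds=(1e-6, 1.0), method="bounded",
            options={"xatol": 1e-8},
        )
        # minimize_scalar(bounded) ignores start points; probe the bracket
        # midpoints explicitly so flat regions cannot trap the fit
        probe = 0.5 * (bracket[0] + bracket[1])
        cand = [(res.fun, float(res.x)), (sse(probe), probe)]
        for f, mval in cand:
            if best is None or f < best[0]:
                best = (f, mval)
    if best is None:  # pragma: no cover
        raise RuntimeError("optimizer failed to evaluate any candidate")
    m_hat = best[1]
    ss_res = best[0]
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return SloanFit(
        m=m_hat, N_T=N_T, d=d,
        omu_ids=list(x_all.index[observed]),
        p=p, x=x, r_squared=r2,
        n_samples=table.n_samples,
        excluded_ids=excluded,
        detection=detection,
    )


def predict_with_ci(
    fit: SloanFit, p_i: np.ndarray, n_samples: int | None = None,
    level: float = 0.95, method: str = "binomial",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted occurrence frequency with a confidence band.

    ``binomial`` (default) is an exact prediction band: the central
    ``level`` quantile range of Binomial(n_samples, freq)/n_samples —
    where an *observed* occurrence frequency should fall if the OMU is
    neutral.  ``wilson`` is the Wilson score interval, a continuous
    approximation that under-covers near frequencies 0 and 1.  Both
    widen as the number of samples falls.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    if n_samples is None:
        n_samples = fit.n_samples
    freq = predicted_frequency(
        np.asarray(p_i, dtype=float), fit.m, fit.N_T, fit.d, fit.detection
    )
    n = int(n_samples)
    tail = (1.0 - level) / 2.0
    if method == "binomial":
        lower = stats.binom.ppf(tail, n, freq) / n
        upper = stats.binom.ppf(1.0 - tail, n, freq) / n
    elif method == "wilson":
        z = stats.norm.ppf(1.0 - tail)
        denom = 1.0 + z * z / n
        center = (freq + z * z / (2 * n)) / denom
        half = (z / denom) * np.sqrt(freq * (1 - freq) / n + z * z / (4 * n * n))
        lower, upper = center - half, center + half
    else:
        raise ValueError(f"unknown interval method {method!r}")
    return freq, np.clip(lower, 0.0, 1.0), np.clip(upper, 0.0, 1.0)


def classify(
    fit: SloanFit, table: OmuTable | None = None, level: float = 0.95
) -> NeutralityClassification:
    """Call each fitted OMU neutral / above / below.

    Observed frequency inside the band (bounds inclusive) is neutral;
    above the upper bound is above-neutral; below the lower bound is
    below-neutral.
    """
    freq, lower, upper = predict_with_ci(fit, fit.p, level=level)
    calls = np.where(fit.x > upper, "above", np.where(fit.x < lower, "below", "neutral"))
    df = pd.DataFrame(
        {
            "omu_id": fit.omu_ids,
            "p": fit.p,
            "x": fit.x,
            "predicted": freq,
            "lower": lower,
            "upper": upper,
            "call": calls,
        }
    )
    counts = {c: int((calls == c).sum()) for c in ("neutral", "above", "below")}
    total = max(len(calls), 1)
    percentages = {c: 100.0 * n / total for c, n in counts.items()}
    return NeutralityClassification(df, counts, percentages)


def fit_and_classify(
    table: OmuTable, level: float = 0.95
) -> tuple[SloanFit, NeutralityClassification]:
    fit = estimate_m(table)
    return fit, classify(fit, table, level=level)


def fit_source_to_destination(
    source: OmuTable, dest: OmuTable, level: float = 0.95,
    detection: str = "reads",
) -> tuple[SloanFit, NeutralityClassification]:
    """Fit with p from the source treatment and x from the destination.

    The two tables are outer-joined on OMU id with zeros; fitting then
    proceeds as in the single-table path but the source community profile
    comes from the source table.
    """
    shared = set(source.omu_ids) | set(dest.omu_ids)
    if not set(source.omu_ids) & set(dest.omu_ids):
        raise ValueError("source and destination share no OMU ids")
    ids = sorted(shared)
    src = source.counts.reindex(ids, fill_value=0.0)
    dst = dest.counts.reindex(ids, fill_value=0.0)
    src_tab = OmuTable(src, level=source.level, mode=source.mode)
    dst_tab = OmuTable(dst, level=dest.level, mode=dest.mode)
    p_src, _, _ = compute_p_x(src_tab)
    _, x_dst, N_T = compute_p_x(dst_tab)
    d = 1.0 / N_T
    observed = (x_dst > 0) & (p_src > 0)
    excluded = list(x_dst.index[~observed])
    p = p_src[observed].to_numpy()
    x = x_dst[observed].to_numpy()

    def sse(m: float) -> float:
        pred = predicted_frequency(p, m, N_T, d, detection)
        return float(np.sum((x - pred) ** 2))

    res = optimize.minimize_scalar(
        sse, bounds=(1e-6, 1.0), method="bounded", options={"xatol": 1e-8}
    )
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - res.fun / ss_tot if ss_tot > 0 else 0.0
    fit = SloanFit(
        m=float(res.x), N_T=N_T, d=d,
        omu_ids=list(x_dst.index[observed]),
        p=p, x=x, r_squared=r2,
        n_samples=dst_tab.n_samples,
        excluded_ids=excluded,
        detection=detection,
    )
    return fit, classify(fit, level=level)


def stationary_density(
    x: np.ndarray, I_T: float, m: float, p_i: float
) -> np.ndarray:
    """Stationary beta density of local relative abundance.

    phi(x) = c x^{I_T m p_i - 1} (1 - x)^{I_T m (1 - p_i) - 1}, with the
    normalizing constant c resolved through the beta function.
    """
    a = I_T * m * p_i
    b = I_T * m * (1.0 - p_i)
    if a <= 0 or b <= 0:
        raise ValueError("beta shape parameters must be positive")
    return stats.beta.pdf(np.asarray(x, dtype=float), a, b)
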