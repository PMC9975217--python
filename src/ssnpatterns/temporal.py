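"""Time-series analysis of connected-component abundances.

At each coastal time-series site the CC-by-date matrix is interrogated for:

* per-sample diversity (richness S, Shannon H in nats, Pielou evenness
  J = H/ln S);
* community *indicator* CCs, selected greedily by Escoufier's equivalent
  vectors: the subset of CC columns whose RV coefficient with the full matrix
  first reaches the chosen cumulated correlation level (default 75%);
* *rhythmic* CCs, whose Lomb-Scargle periodogram — suited to unevenly
  sampled series — peaks above PNmax > 10 (approximately p < 0.01);
* rhythmic indicators (the intersection of the two), their seasonal
  prevalence (seasons per year with at least one occurrence) and annual mean
  monthly abundance.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lombscargle as _sp_lombscargle
from scipy.stats import entropy as _sp_entropy

from .core import season_of

__all__ = [
    "CCTimeSeries",
    "PeriodogramResult",
    "DiversitySummary",
    "RVTrace",
    "diversity",
    "rv_coefficient",
    "escoufier_select",
    "lomb_scargle",
    "rhythmic_set",
    "rhythmic_indicators",
    "seasonal_prevalence",
    "annual_mean_monthly_abundance",
]


@dataclass
class CCTimeSeries:
    """One CC's abundance series at a site; dates may be unevenly spaced."""

    cc_id: str
    times: list[_dt.date]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != self.values.size:
            raise ValueError(f"{self.cc_id}: times and values differ in length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError(f"{self.cc_id}: times must be strictly increasing")
        if (self.values < 0).any():
            raise ValueError(f"{self.cc_id}: negative abundances")


@dataclass
class PeriodogramResult:
    """Peak of a normalized Lomb-Scargle periodogram for one CC."""

    cc_id: str
    pn_max: float
    period_days: float
    p_value: float
    frequency_grid: np.ndarray


@dataclass
class DiversitySummary:
    richness_S: int
    shannon_H: float
    pielou_J: float


@dataclass
class RVTrace:
    """Escoufier selection path: full ordering, cumulative RV, and the
    shortest prefix reaching the requested level."""

    order: list[str]
    cumulative_rv: list[float]
    selected: list[str]


def diversity(vector: np.ndarray) -> DiversitySummary:
    """Richness, Shannon diversity (natural log) and Pielou evenness of one
    sample."""
    v = np.asarray(vector, dtype=float)
    if (v < 0).any():
        raise ValueError("negative abundances")
    total = v.sum()
    if total <= 0:
        raise ValueError("diversity undefined for an all-zero sample")
    pos = v[v > 0]
    s = int(pos.size)
    h = float(_sp_entropy(pos / total))
    j = h / np.log(s) if s >= 2 else 0.0
    return DiversitySummary(richness_S=s, shannon_H=h, pielou_J=float(j))


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """Escoufier's RV coefficient between two column-centered matrices.

    RV = tr(XX'YY') / sqrt(tr((XX')^2) tr((YY')^2)), a matrix correlation in
    [0, 1] invariant to column rescaling of either matrix as a whole.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("matrices differ in row count")
    if X.shape[0] < 2:
        raise ValueError("need at least two rows")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = float((np.linalg.norm(Xc.T @ Xc, "fro")) ** 2) ** 0.5
    syy = float((np.linalg.norm(Yc.T @ Yc, "fro")) ** 2) ** 0.5
    if sxx == 0 or syy == 0:
        raise ValueError("zero-variance matrix")
    cross = float(np.linalg.norm(Xc.T @ Yc, "fro") ** 2)
    return cross / (sxx * syy)


def escoufier_select(
    table: pd.DataFrame,
    level: float = 0.75,
    min_occurrence: int = 5,
) -> RVTrace:
    """Greedy equivalent-vector selection of indicator CCs at one site.

    ``table`` is CC-by-date.  CCs observed on fewer than ``min_occurrence``
    dates are excluded first.  At each step the unselected CC maximizing the
    RV coefficient between the growing subset and the full matrix is added
    (ties broken by larger total abundance, then id); ``selected`` is the
    shortest prefix whose cumulative RV reaches ``level``.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError(f"level {level} outside (0, 1]")
    occ = (table > 0).sum(axis=1)
    kept = table.loc[occ[occ >= min_occurrence].index]
    if kept.empty:
        raise ValueError("no CC meets the minimum occurrence requirement")
    ids = list(kept.index)
    X = kept.to_numpy(dtype=float).T  # dates x CCs
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc
    c_full = float(np.linalg.norm(C, "fro"))
    if c_full == 0:
        raise ValueError("abundance matrix has no variance")
    totals = kept.sum(axis=1).to_numpy()

    p = len(ids)
    selected_idx: list[int] = []
    # candidate order encodes the tie-break: larger total abundance, then id
    preference = sorted(range(p), key=lambda j: (-totals[j], ids[j]))
    remaining = list(preference)
    cumulative: list[float] = []

    def rv_of(subset: list[int]) -> float:
        rows = C[subset, :]
        num = float((rows * rows).sum())
        sub = C[np.ix_(subset, subset)]
        den = float(np.linalg.norm(sub, "fro")) * c_full
        return num / den if den > 0 else 0.0

    while remaining:
        best_rv, best_j = -1.0, remaining[0]
        for j in remaining:
            cand = rv_of(selected_idx + [j])
            if cand > best_rv:
                best_rv, best_j = cand, j
        selected_idx.append(best_j)
        remaining.remove(best_j)
        cumulative.append(best_rv)

    order = [ids[j] for j in selected_idx]
    n_sel = next(
        (k + 1 for k, rv in enumerate(cumulative) if rv >= level - 1e-12), len(order)
    )
    return RVTrace(order=order, cumulative_rv=cumulative, selected=order[:n_sel])


def _to_days(times: list[_dt.date]) -> np.ndarray:
    t0 = times[0]
    return np.array([(t - t0).days for t in times], dtype=float)


def lomb_scargle(series: CCTimeSeries, ofac: int = 4) -> PeriodogramResult:
    """Classical normalized Lomb-Scargle periodogram of one CC series.

    The periodogram power is normalized by the sample variance, so PN is
    invariant to affine transforms of the values.  The frequency grid runs
    from 1/span to n/(2*span) (pseudo-Nyquist for uneven sampling) with
    oversampling factor ``ofac``.  The peak p-value uses the extreme-value
    form 1 - (1 - exp(-PNmax))^M with M = 2 * n_grid / ofac independent
    frequencies (the convention of the classical implementations).
    """
    x = series.values
    n = x.size
    if n < 8:
        raise ValueError(f"{series.cc_id}: need >= 8 observations, got {n}")
    t = _to_days(series.times)
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError(f"{series.cc_id}: zero time span")
    xc = x - x.mean()
    var = xc.var(ddof=1)
    if var == 0:
        raise ValueError(f"{series.cc_id}: constant series")
    step = 1.0 / (ofac * span)
    freqs = np.arange(1.0 / span, n / (2.0 * span) + step / 2, step)
    power = _sp_lombscargle(t, xc, 2.0 * np.pi * freqs) / var
    peak = int(np.argmax(power))
    pn_max = float(power[peak])
    m_indep = 2.0 * freqs.size / ofac
    # extreme-value tail; expm1/log1p keep precision for large PN
    p_value = float(-np.expm1(m_indep * np.log1p(-np.exp(-pn_max))))
    p_value = min(max(p_value, np.finfo(float).tiny), 1.0)
    return PeriodogramResult(
        cc_id=series.cc_id,
        pn_max=pn_max,
        period_days=float(1.0 / freqs[peak]),
        p_value=p_value,
        frequency_grid=freqs,
    )


def rhythmic_set(
    results: list[PeriodogramResult], pn_threshold: float = 10.0
) -> set[str]:
    """CC ids whose periodogram peak strictly exceeds the threshold."""
    return {r.cc_id for r in results if r.pn_max > pn_threshold}


def rhythmic_indicators(escoufier: RVTrace, rhythmic: set[str]) -> set[str]:
    """CCs that are both community indicators and rhythmic."""
    return set(escoufier.selected) & rhythmic


def seasonal_prevalence(series: CCTimeSeries, year: int) -> int:
    """Number of seasons (0-4) of a calendar year with >= 1 positive
    observation."""
    seasons = {
        season_of(t)
        for t, v in zip(series.times, series.values)
        if t.year == year and v > 0
    }
    return len(seasons)


def annual_mean_monthly_abundance(series: CCTimeSeries, year: int) -> float | None:
    """Mean over observed months of the within-month mean abundance.

    Months without samples are excluded; ``None`` when the year has no
    observations at all.
    """
    by_month: dict[int, list[float]] = {}
    for t, v in zip(series.times, series.values):
        if t.year == year:
            by_month.setdefault(t.month, []).append(float(v))
    if not by_month:
        return None
    return float(np.mean([np.mean(vals) for vals in by_month.values()]))
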