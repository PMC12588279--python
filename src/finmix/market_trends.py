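"""Incidence statistics and year-trend models for market survey data.

A sampling event is one vendor visit in which 20 fin trimmings (2 bags x 10)
are species-identified.  Incidence of a species in a year is the fraction of
vendor visits in which at least one of the 20 trimmings was that species; the
trend over years is fit with a binomial GLM (logit link, numerical year as the
only predictor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

__all__ = [
    "TRIMMINGS_PER_EVENT",
    "SurveyEvent",
    "IncidenceSeries",
    "TrendFit",
    "compute_incidence",
    "fit_trend",
    "proportional_contribution",
    "events_to_frame",
    "events_from_frame",
]

TRIMMINGS_PER_EVENT = 20  # 2 bags x 10 trimmings per vendor visit


@dataclass(frozen=True)
class SurveyEvent:
    """One vendor visit: exactly 20 species-labelled trimmings."""

    date: str  # ISO date, YYYY-MM-DD
    vendor_id: str
    species_labels: tuple[str, ...]
    bag_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.species_labels) != TRIMMINGS_PER_EVENT:
            raise ValueError(
                f"event {self.vendor_id}@{self.date} has "
                f"{len(self.species_labels)} labels, expected {TRIMMINGS_PER_EVENT}"
            )

    @property
    def year(self) -> int:
        return int(self.date[:4])

    def contains(self, species: str) -> bool:
        return species in self.species_labels


@dataclass
class IncidenceSeries:
    """Per-year vendor-visit trials and successes for one focal species."""

    species: str
    years: list[int]
    trials: np.ndarray  # k_t
    successes: np.ndarray  # y_t

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=int)
        self.successes = np.asarray(self.successes, dtype=int)
        if np.any(self.successes > self.trials) or np.any(self.successes < 0):
            raise ValueError("successes must satisfy 0 <= y_t <= k_t")

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.trials > 0, self.successes / self.trials, np.nan)

    def restrict(self, years: Iterable[int]) -> "IncidenceSeries":
        keep = [i for i, y in enumerate(self.years) if y in set(years)]
        return IncidenceSeries(
            species=self.species,
            years=[self.years[i] for i in keep],
            trials=self.trials[keep],
            successes=self.successes[keep],
        )


@dataclass
class TrendFit:
    species: str
    beta0: float  # intercept on the logit scale (centred-year parameterisation)
    beta1: float  # slope per year
    se_beta1: float
    p_wald: float
    alpha: float
    significant: bool
    separation_flag: bool
    years: list[int]
    fitted: np.ndarray  # fitted annual probabilities
    ci_low: np.ndarray
    ci_high: np.ndarray
    year_center: float


def compute_incidence(
    events: Sequence[SurveyEvent], species: str
) -> IncidenceSeries:
    """Annual incidence of ``species``: vendor visits with >= 1 matching trimming.

    Duplicate labels within an event beyond the first do not change the
    statistic; trimming order is irrelevant.
    """
    if not events:
        raise ValueError("no survey events supplied")
    trials: dict[int, int] = {}
    successes: dict[int, int] = {}
    for ev in events:
        y = ev.year
        trials[y] = trials.get(y, 0) + 1
        successes[y] = successes.get(y, 0) + int(ev.contains(species))
    years = sorted(trials)
    return IncidenceSeries(
        species=species,
        years=years,
        trials=np.array([trials[y] for y in years]),
        successes=np.array([successes[y] for y in years]),
    )


def fit_trend(
    series: IncidenceSeries,
    alpha: float = 0.05,
    years: Iterable[int] | None = None,
) -> TrendFit:
    """Binomial GLM (logit link) of incidence on numerical year.

    Year is centred before fitting for numerical stability (this affects only
    the intercept).  The Wald test on the slope decides significance at
    ``alpha``; 95% CIs on the response scale come from the delta method on the
    linear predictor.  Complete separation is flagged rather than allowed to
    diverge silently.
    """
    if years is not None:
        series = series.restrict(years)
    if len(series.years) < 2:
        raise ValueError("trend fit requires at least 2 distinct years")
    props = series.proportions
    if np.all(series.successes == 0) or np.all(series.successes == series.trials):
        raise ValueError("all-zero or all-saturated series: no trend is estimable")
    yr = np.asarray(series.years, dtype=float)
    center = yr.mean()
    X = sm.add_constant(yr - center)
    endog = np.column_stack([series.successes, series.trials - series.successes])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
    beta0, beta1 = res.params
    se1 = float(res.bse[1])
    # Perfect fit of extreme proportions -> parameters drifting to +-inf.
    separation = bool(
        not np.isfinite(se1) or se1 > 1e3 or abs(beta1) > 1e2
    )
    zval = beta1 / se1 if se1 > 0 else np.inf
    p_wald = float(2 * stats.norm.sf(abs(zval)))
    eta = X @ res.params
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, res.cov_params(), X))
    z975 = stats.norm.ppf(0.975)
    inv = special.expit
    fitted = inv(eta)
    if separation:
        warnings.warn(
            f"possible complete separation fitting trend for {series.species}",
            RuntimeWarning,
            stacklevel=2,
        )
    return TrendFit(
        species=series.species,
        beta0=float(beta0),
        beta1=float(beta1),
        se_beta1=se1,
        p_wald=p_wald,
        alpha=alpha,
        significant=bool(p_wald < alpha),
        separation_flag=separation,
        years=list(series.years),
        fitted=fitted,
        ci_low=inv(eta - z975 * se_eta),
        ci_high=inv(eta + z975 * se_eta),
        year_center=float(center),
    )


def proportional_contribution(
    events: Sequence[SurveyEvent],
    species_set: Sequence[str],
    unidentified_label: str = "unidentified",
) -> pd.DataFrame:
    """Per-year fraction of identified trimmings attributed to each species.

    Fractions are computed over identified trimmings only (labels equal to
    ``unidentified_label`` are excluded from the denominator).  Years with no
    identified trimmings report NaN fractions.  Columns: year, species,
    count, denominator, fraction.
    """
    if not events:
        raise ValueError("no survey events supplied")
    rows = []
    per_year_counts: dict[int, dict[str, int]] = {}
    per_year_denom: dict[int, int] = {}
    for ev in events:
        y = ev.year
        counts = per_year_counts.setdefault(y, {})
        for label in ev.species_labels:
            if label == unidentified_label:
                continue
            counts[label] = counts.get(label, 0) + 1
            per_year_denom[y] = per_year_denom.get(y, 0) + 1
    for y in sorted(per_year_counts):
        denom = per_year_denom.get(y, 0)
        for sp in species_set:
            c = per_year_counts[y].get(sp, 0)
            frac = c / denom if denom > 0 else np.nan
            rows.append(
                {"year": y, "species": sp, "count": c,
                 "denominator": denom, "fraction": frac}
            )
    return pd.DataFrame(rows)


def events_to_frame(events: Sequence[SurveyEvent]) -> pd.DataFrame:
    """One row per trimming: date, vendor_id, bag_id, species."""
    rows = []
    for ev in events:
        bags = ev.bag_ids or tuple(
            f"b{1 + i // 10}" for i in range(TRIMMINGS_PER_EVENT)
        )
        for bag, sp in zip(bags, ev.species_labels):
            rows.append(
                {"date": ev.date, "vendor_id": ev.vendor_id, "bag_id": bag,
                 "species": sp}
            )
    return pd.DataFrame(rows)


def events_from_frame(df: pd.DataFrame) -> list[SurveyEvent]:
    events = []
    for (date, vendor), grp in df.groupby(["date", "vendor_id"], sort=True):
        events.append(
            SurveyEvent(
                date=str(date),
                vendor_id=str(vendor),
                species_labels=tuple(grp["species"]),
                bag_ids=tuple(str(b) for b in grp["bag_id"]),
            )
        )
    return events
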