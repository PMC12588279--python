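"""Reconciliation of CITES-style trade records with customs import totals.

Implements the record-hygiene rules used for permit-ledger analysis (keep only
weight-in-kg, wild-caught, commercial-purpose fin records), partner-report
deduplication (when both importer and exporter report a shipment, the higher
volume stands), legal-share time series (reported CITES volume over total
customs fin imports), and the nation-flagging logic with its summary counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TradeRecord",
    "CustomsRecord",
    "NationProfile",
    "LegalShareSeries",
    "NationFlagReport",
    "filter_records",
    "reconcile_partner_reports",
    "legal_share",
    "market_vs_reported_ratio",
    "flag_nations",
    "load_exporter_profiles",
    "load_canonical_names",
    "canonicalize_nation",
]

_DATA_PACKAGE = "finmix.data"
EXPORTER_TABLE_RESOURCE = "hk_fin_exporters_2014_2022.csv"
CANONICAL_NAMES_RESOURCE = "nation_canonical.yaml"


@dataclass(frozen=True)
class TradeRecord:
    exporter: str
    importer: str
    year: int
    taxon: str
    term: str  # e.g. "fins"
    unit: str  # "kg" | "count" | "unknown"
    quantity: float
    source_code: str  # W = wild-caught, C = captive-bred, ...
    purpose_code: str  # T = commercial, ...
    reported_by: str = "importer"  # "importer" | "exporter"


@dataclass(frozen=True)
class CustomsRecord:
    origin_nation: str
    year: int
    kg: float

    def __post_init__(self) -> None:
        if self.kg < 0:
            raise ValueError("customs kg must be nonnegative")


@dataclass(frozen=True)
class NationProfile:
    """One exporter nation: volumes plus compliance-relevant attributes."""

    nation: str
    mean_annual_kg: float
    range_state_count: int
    fao_rfmo_catch: bool
    seizure_implicated: bool
    cites_reporting: bool

    def __post_init__(self) -> None:
        if not 0 <= self.range_state_count <= 5:
            raise ValueError("range_state_count must be in [0, 5]")


@dataclass
class LegalShareSeries:
    """Per-year CITES-reported volume, customs total, and their ratio."""

    years: list[int]
    v_cites: np.ndarray
    v_total: np.ndarray

    @property
    def share(self) -> np.ndarray:
        """Fractional share; NaN where the customs total is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.v_total > 0, self.v_cites / self.v_total, np.nan)

    @property
    def share_percent(self) -> np.ndarray:
        return self.share * 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "v_cites_kg": self.v_cites,
                "v_total_kg": self.v_total,
                "share": self.share,
                "share_percent": self.share_percent,
            }
        )


def filter_records(
    records: Iterable[TradeRecord],
    term: str = "fins",
) -> tuple[list[TradeRecord], list[tuple[TradeRecord, str]]]:
    """Partition records into kept and excluded-with-reason.

    Kept iff unit is kg, source code W, purpose code T, and the term matches.
    Filtering never raises; every exclusion carries a machine-readable reason
    (the first failing rule, checked in the order term, unit, source, purpose).
    """
    kept: list[TradeRecord] = []
    excluded: list[tuple[TradeRecord, str]] = []
    for rec in records:
        if rec.term != term:
            excluded.append((rec, f"term:{rec.term}"))
        elif rec.unit != "kg":
            excluded.append((rec, "unknown quantity"))
        elif rec.source_code != "W":
            excluded.append((rec, f"source:{rec.source_code}"))
        elif rec.purpose_code != "T":
            excluded.append((rec, f"purpose:{rec.purpose_code}"))
        else:
            kept.append(rec)
    return kept, excluded


def reconcile_partner_reports(records: Sequence[TradeRecord]) -> list[TradeRecord]:
    """Deduplicate importer/exporter double reporting by taking the maximum.

    Key: (exporter, importer, year, taxon).  When both partners report the
    same shipment with different volumes the higher one is retained; singleton
    reports pass through.  Idempotent.
    """
    best: dict[tuple[str, str, int, str], TradeRecord] = {}
    order: list[tuple[str, str, int, str]] = []
    for rec in records:
        key = (rec.exporter, rec.importer, rec.year, rec.taxon)
        cur = best.get(key)
        if cur is None:
            best[key] = rec
            order.append(key)
        elif rec.quantity > cur.quantity:
            best[key] = rec
    return [best[k] for k in order]


def legal_share(
    cites: Sequence[TradeRecord], customs: Sequence[CustomsRecord]
) -> LegalShareSeries:
    """Reported (legal) CITES volume as a share of total customs fin imports."""
    cites_by_year: dict[int, float] = {}
    for rec in cites:
        cites_by_year[rec.year] = cites_by_year.get(rec.year, 0.0) + rec.quantity
    total_by_year: dict[int, float] = {}
    for rec in customs:
        total_by_year[rec.year] = total_by_year.get(rec.year, 0.0) + rec.kg
    if not total_by_year:
        raise ValueError("no customs records supplied")
    years = sorted(total_by_year)
    v_cites = np.array([cites_by_year.get(y, 0.0) for y in years])
    v_total = np.array([total_by_year[y] for y in years])
    return LegalShareSeries(years=years, v_cites=v_cites, v_total=v_total)


def market_vs_reported_ratio(
    market_percent: float, reported_percent: float
) -> float:
    """Fold-difference between a species' market share and its reported share.

    Both arguments are percentages (e.g. 0.7 and 0.01 -> 70.0).
    """
    if reported_percent <= 0:
        raise ValueError("reported share must be positive to form a ratio")
    return market_percent / reported_percent


@dataclass
class NationFlagReport:
    table: pd.DataFrame  # profiles + "flagged" column
    n_total: int
    n_reporting: int
    n_nonreporting: int
    pct_nonreporting: float
    n_nonreporting_seizure_implicated: int
    n_catch_but_no_export: int

    def summary(self) -> dict[str, float | int]:
        return {
            "n_total": self.n_total,
            "n_reporting": self.n_reporting,
            "n_nonreporting": self.n_nonreporting,
            "pct_nonreporting": self.pct_nonreporting,
            "n_nonreporting_seizure_implicated": self.n_nonreporting_seizure_implicated,
            "n_catch_but_no_export": self.n_catch_but_no_export,
        }


def flag_nations(profiles: Sequence[NationProfile]) -> NationFlagReport:
    """Apply the three-part compliance flag and compute summary counts.

    A nation is flagged when it (1) exports unidentified fins (every profile
    row is an exporter by construction), (2) is known to catch listed species
    and/or has been implicated in fin-shipment seizures, and (3) reported no
    listed-species trade.  Summary counts include the number of non-reporting
    nations, the seizure-implicated subset, and nations reporting catches but
    no trade.
    """
    if not profiles:
        raise ValueError("no nation profiles supplied")
    names = [p.nation for p in profiles]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate nation names: {dupes}")
    rows = []
    for p in profiles:
        flagged = (p.fao_rfmo_catch or p.seizure_implicated) and not p.cites_reporting
        rows.append(
            {
                "nation": p.nation,
                "mean_annual_kg": p.mean_annual_kg,
                "range_state_count": p.range_state_count,
                "fao_rfmo_catch": p.fao_rfmo_catch,
                "seizure_implicated": p.seizure_implicated,
                "cites_reporting": p.cites_reporting,
                "flagged": flagged,
            }
        )
    df = pd.DataFrame(rows)
    n_total = len(df)
    n_reporting = int(df["cites_reporting"].sum())
    n_nonreporting = n_total - n_reporting
    return NationFlagReport(
        table=df,
        n_total=n_total,
        n_reporting=n_reporting,
        n_nonreporting=n_nonreporting,
        pct_nonreporting=100.0 * n_nonreporting / n_total,
        n_nonreporting_seizure_implicated=int(
            (df["seizure_implicated"] & ~df["cites_reporting"]).sum()
        ),
        n_catch_but_no_export=int(
            (df["fao_rfmo_catch"] & ~df["cites_reporting"]).sum()
        ),
    )


def _yes_no(value: str) -> bool:
    v = str(value).strip().lower()
    if v in {"yes", "y", "true", "1"}:
        return True
    if v in {"no", "n", "false", "0"}:
        return False
    raise ValueError(f"cannot parse yes/no value {value!r}")


def load_exporter_profiles(path: str | Path | None = None) -> list[NationProfile]:
    """Load nation profiles from CSV (default: the packaged exporter table)."""
    if path is None:
        source = resources.files(_DATA_PACKAGE).joinpath(EXPORTER_TABLE_RESOURCE)
        text = source.read_text()
    else:
        text = Path(path).read_text()
    profiles = []
    for row in csv.DictReader(text.splitlines()):
        profiles.append(
            NationProfile(
                nation=row["nation"],
                mean_annual_kg=float(row["mean_annual_kg"]),
                range_state_count=int(row["range_state_count"]),
                fao_rfmo_catch=_yes_no(row["fao_rfmo_catch"]),
                seizure_implicated=_yes_no(row["seizure_implicated"]),
                cites_reporting=_yes_no(row["cites_reporting"]),
            )
        )
    return profiles


def load_canonical_names(path: str | Path | None = None) -> dict[str, str]:
    """Alias -> canonical nation-name map from the packaged YAML config."""
    if path is None:
        text = resources.files(_DATA_PACKAGE).joinpath(
            CANONICAL_NAMES_RESOURCE
        ).read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return {str(k): str(v) for k, v in data.get("aliases", {}).items()}


def canonicalize_nation(name: str, aliases: Mapping[str, str] | None = None) -> str:
    if aliases is None:
        aliases = load_canonical_names()
    return aliases.get(name.strip(), name.strip())
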