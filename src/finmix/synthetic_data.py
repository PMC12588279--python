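"""Seeded generators for every input the pipeline consumes.

Produces baseline haplotype matrices with known ground truth, market mixture
samples, overlapping amplicon sequence sets, vendor-visit survey events, and
CITES-style trade / customs ledgers.  All generators are deterministic under a
fixed seed, conserve their specified totals exactly, and honour source
exclusivity of haplotypes, so parameter-recovery and filter tests can rely on
their structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .haplotyping import MtcrSequence
from .market_trends import TRIMMINGS_PER_EVENT, SurveyEvent
from .mixed_stock import BaselineMatrix, MixtureCounts
from .trade_reconciliation import CustomsRecord, NationProfile, TradeRecord

__all__ = [
    "SourcePopulationSpec",
    "SyntheticTruth",
    "SurveyDesignSpec",
    "DEFAULT_SOURCES",
    "default_preset",
    "biweekly_design",
    "monthly_design",
    "gen_baseline",
    "gen_mixture",
    "gen_haplotype_sequences",
    "gen_amplicon_reads",
    "gen_survey",
    "gen_trade_ledgers",
]

_BASES = np.array(list("ACGT"))

DEFAULT_SOURCES = ("SWA", "Car", "Ant", "NWA", "EAt", "IOc", "WPa", "CPa", "EPa")


@dataclass(frozen=True)
class SourcePopulationSpec:
    """Haplotype-composition blueprint for one source population."""

    name: str
    n_haplotypes: int
    exclusive_haplotypes: frozenset[str] = frozenset()
    concentration: float = 1.0
    shared_haplotypes: tuple[str, ...] | None = None  # explicit shared subset

    def __post_init__(self) -> None:
        if self.n_haplotypes < 1:
            raise ValueError(f"{self.name}: n_haplotypes must be positive")
        if self.n_haplotypes < len(self.exclusive_haplotypes):
            raise ValueError(
                f"{self.name}: n_haplotypes < number of exclusive haplotypes"
            )
        if self.concentration <= 0:
            raise ValueError(f"{self.name}: concentration must be positive")
        if self.shared_haplotypes is not None:
            want = self.n_haplotypes - len(self.exclusive_haplotypes)
            if len(self.shared_haplotypes) != want:
                raise ValueError(
                    f"{self.name}: expected {want} shared haplotypes, got "
                    f"{len(self.shared_haplotypes)}"
                )
            if set(self.shared_haplotypes) & self.exclusive_haplotypes:
                raise ValueError(
                    f"{self.name}: shared and exclusive haplotype sets overlap"
                )


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset (for recovery tests)."""

    sources: list[str]
    haplotypes: list[str]
    theta_true: np.ndarray  # (S,) simplex
    baseline_freqs: np.ndarray  # (S, H), rows simplex
    seed: int

    def __post_init__(self) -> None:
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        self.baseline_freqs = np.asarray(self.baseline_freqs, dtype=float)
        if np.any(self.theta_true < 0) or np.any(self.baseline_freqs < 0):
            raise ValueError("truth probabilities must be nonnegative")
        if abs(self.theta_true.sum() - 1.0) > 1e-12:
            raise ValueError("theta_true must sum to 1")
        rows = self.baseline_freqs.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-12):
            raise ValueError("each baseline_freqs row must sum to 1")


def default_preset() -> list[SourcePopulationSpec]:
    """Nine-source, 34-haplotype emulation preset.

    Each source carries two exclusive haplotypes (H1-H18, grouped by source)
    plus a deterministic subset of the 16 shared haplotypes H19-H34, each of
    which occurs in exactly three sources.
    """
    shared_pool = [f"H{19 + j}" for j in range(16)]
    shared_by_source: dict[int, list[str]] = {i: [] for i in range(9)}
    for j, hap in enumerate(shared_pool):
        for k in range(3):
            shared_by_source[(j + k) % 9].append(hap)
    specs = []
    for i, name in enumerate(DEFAULT_SOURCES):
        exclusive = frozenset({f"H{2 * i + 1}", f"H{2 * i + 2}"})
        shared = tuple(shared_by_source[i])
        specs.append(
            SourcePopulationSpec(
                name=name,
                n_haplotypes=len(exclusive) + len(shared),
                exclusive_haplotypes=exclusive,
                shared_haplotypes=shared,
            )
        )
    return specs


def _haplotype_universe(
    specs: Sequence[SourcePopulationSpec], rng: np.random.Generator
) -> tuple[list[str], list[list[str]]]:
    """Return the ordered haplotype universe and each source's allowed set."""
    exclusives: set[str] = set()
    for spec in specs:
        overlap = exclusives & spec.exclusive_haplotypes
        if overlap:
            raise ValueError(
                f"exclusive haplotypes claimed by multiple sources: {sorted(overlap)}"
            )
        exclusives |= spec.exclusive_haplotypes
    needs_auto = [s for s in specs if s.shared_haplotypes is None]
    auto_pool: list[str] = []
    if needs_auto:
        pool_size = max(
            s.n_haplotypes - len(s.exclusive_haplotypes) for s in needs_auto
        )
        auto_pool = [f"S{j + 1}" for j in range(pool_size)]
    universe: list[str] = []
    allowed: list[list[str]] = []
    for spec in specs:
        excl = sorted(spec.exclusive_haplotypes)
        if spec.shared_haplotypes is not None:
            shared = list(spec.shared_haplotypes)
        else:
            k = spec.n_haplotypes - len(excl)
            shared = [
                auto_pool[j]
                for j in sorted(rng.choice(len(auto_pool), size=k, replace=False))
            ]
        allowed.append(excl + shared)
        for h in excl + shared:
            if h not in universe:
                universe.append(h)
    return universe, allowed


def gen_baseline(
    specs: Sequence[SourcePopulationSpec],
    n_per_source: int,
    seed: int,
    theta_true: Sequence[float] | None = None,
) -> tuple[BaselineMatrix, SyntheticTruth]:
    """Generate a baseline count matrix plus its generating truth.

    Per-source haplotype frequencies are drawn from a symmetric Dirichlet
    (each spec's ``concentration``) restricted to that source's allowed
    haplotypes; counts are multinomial with every allowed haplotype seeded
    with one observation so no column of the matrix is empty.  Row sums equal
    ``n_per_source`` exactly and exclusive haplotypes have zero counts outside
    their source.  ``theta_true`` (the mixture ground truth carried alongside)
    defaults to a seeded Dirichlet(1) draw over the sources.
    """
    if not specs:
        raise ValueError("at least one source population spec is required")
    if n_per_source < 1:
        raise ValueError("n_per_source must be >= 1")
    rng = np.random.default_rng(seed)
    universe, allowed = _haplotype_universe(specs, rng)
    S, H = len(specs), len(universe)
    col = {h: j for j, h in enumerate(universe)}
    q_true = np.zeros((S, H))
    counts = np.zeros((S, H), dtype=np.int64)
    for i, spec in enumerate(specs):
        idx = [col[h] for h in allowed[i]]
        k = len(idx)
        if n_per_source < k:
            raise ValueError(
                f"{spec.name}: n_per_source={n_per_source} cannot cover "
                f"{k} haplotypes with at least one observation each"
            )
        freqs = rng.dirichlet(np.full(k, spec.concentration))
        q_true[i, idx] = freqs
        # One guaranteed observation per allowed haplotype, remainder multinomial.
        row = np.ones(k, dtype=np.int64)
        row += rng.multinomial(n_per_source - k, freqs)
        counts[i, idx] = row
    if theta_true is None:
        theta = rng.dirichlet(np.ones(S))
    else:
        theta = np.asarray(theta_true, dtype=float)
        if theta.shape != (S,):
            raise ValueError("theta_true length must match number of sources")
        theta = theta / theta.sum()
    baseline = BaselineMatrix(
        sources=[s.name for s in specs], haplotypes=universe, counts=counts
    )
    truth = SyntheticTruth(
        sources=[s.name for s in specs],
        haplotypes=universe,
        theta_true=theta,
        baseline_freqs=q_true,
        seed=seed,
    )
    return baseline, truth


def gen_mixture(truth: SyntheticTruth, n: int, seed: int) -> MixtureCounts:
    """Draw a market mixture of ``n`` individuals from the ground truth.

    Each individual picks a source from ``theta_true`` and then a haplotype
    from that source's ``baseline_freqs`` row; the returned counts sum to
    ``n`` exactly.
    """
    if n < 1:
        raise ValueError("mixture size n must be >= 1")
    rng = np.random.default_rng(seed)
    S, H = truth.baseline_freqs.shape
    z = rng.choice(S, size=n, p=truth.theta_true)
    counts = np.zeros(H, dtype=np.int64)
    for s, m in zip(*np.unique(z, return_counts=True)):
        counts += rng.multinomial(m, truth.baseline_freqs[s])
    return MixtureCounts(haplotypes=list(truth.haplotypes), counts=counts)


def gen_haplotype_sequences(
    haplotype_ids: Sequence[str], length: int = 535, seed: int = 0
) -> list[MtcrSequence]:
    """Random equal-length, pairwise-distinct sequences, one per haplotype ID."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out = []
    for hid in haplotype_ids:
        while True:
            bases = "".join(rng.choice(_BASES, size=length))
            if bases not in seen:
                break
        seen.add(bases)
        out.append(MtcrSequence(id=hid, bases=bases))
    return out


def gen_amplicon_reads(
    haplotype_sequences: Sequence[MtcrSequence],
    frag_lengths: tuple[int, int] = (388, 168),
    overlap: int = 21,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[MtcrSequence], list[MtcrSequence]]:
    """Split each sequence into two overlapping amplicons.

    Fragment A is the 5' ``frag_lengths[0]`` bases; fragment B starts
    ``overlap`` bases before the end of A, so merging the pair at the implied
    overlap reconstructs the source exactly when ``error_rate`` is 0.
    Substitution noise (uniform over the three alternative bases) is applied
    independently per base at ``error_rate``.
    """
    la, lb = frag_lengths
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    if overlap > min(la, lb):
        raise ValueError("overlap cannot exceed a fragment length")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    frags_a: list[MtcrSequence] = []
    frags_b: list[MtcrSequence] = []
    for seq in haplotype_sequences:
        total = la + lb - overlap
        if la > len(seq) or lb > len(seq):
            raise ValueError(
                f"{seq.id}: fragment longer than source sequence ({len(seq)} bp)"
            )
        if total != len(seq):
            raise ValueError(
                f"{seq.id}: fragments {la}+{lb} with overlap {overlap} imply "
                f"{total} bp, source is {len(seq)} bp"
            )
        a = seq.bases[:la]
        b = seq.bases[la - overlap :]
        if error_rate > 0:
            a = _mutate(a, error_rate, rng)
            b = _mutate(b, error_rate, rng)
        frags_a.append(MtcrSequence(id=seq.id, bases=a))
        frags_b.append(MtcrSequence(id=seq.id, bases=b))
    return frags_a, frags_b


def _mutate(bases: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(bases))
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alternatives[rng.integers(3)]
    return "".join(arr)


@dataclass(frozen=True)
class SurveyDesignSpec:
    """Sampling design for one survey year."""

    occasions_per_month: int  # 2 = biweekly, 1 = monthly
    vendors_per_occasion: int = 10
    bags_per_vendor: int = 2
    trimmings_per_bag: int = 10
    stocking_rate: float = 1.0  # probability a visited vendor has stock
    vendor_pool: int = 75  # vendors randomised per occasion

    def __post_init__(self) -> None:
        if self.occasions_per_month < 1:
            raise ValueError("occasions_per_month must be >= 1")
        if not 0 <= self.stocking_rate <= 1:
            raise ValueError("stocking_rate must be in [0, 1]")

    @property
    def trimmings_per_event(self) -> int:
        return self.bags_per_vendor * self.trimmings_per_bag

    @property
    def max_events_per_month(self) -> int:
        return self.occasions_per_month * self.vendors_per_occasion


def biweekly_design(**kwargs) -> SurveyDesignSpec:
    """The 2014-style design: two sampling occasions per month (up to 20 visits)."""
    return SurveyDesignSpec(occasions_per_month=2, **kwargs)


def monthly_design(**kwargs) -> SurveyDesignSpec:
    """The 2015-onward design: one occasion per month (up to 10 visits)."""
    return SurveyDesignSpec(occasions_per_month=1, **kwargs)


def gen_survey(
    years: Iterable[int],
    design: SurveyDesignSpec | Mapping[int, SurveyDesignSpec],
    species_probs: Mapping[int, Mapping[str, float]],
    seed: int = 0,
) -> list[SurveyEvent]:
    """Simulate vendor-visit survey events.

    For each month and sampling occasion, vendors from the randomised pool are
    visited in order until ``vendors_per_occasion`` stocked vendors have been
    sampled (each vendor is stocked with probability ``stocking_rate``); a
    sampled vendor contributes one event of ``bags_per_vendor x
    trimmings_per_bag`` species labels drawn from that year's composition.
    """
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    rng = np.random.default_rng(seed)
    events: list[SurveyEvent] = []
    for year in years:
        d = design[year] if isinstance(design, Mapping) else design
        if d.trimmings_per_event != TRIMMINGS_PER_EVENT:
            raise ValueError(
                f"design yields {d.trimmings_per_event} trimmings per event, "
                f"expected {TRIMMINGS_PER_EVENT}"
            )
        probs = species_probs[year]
        names = list(probs)
        p = np.array([probs[s] for s in names], dtype=float)
        if np.any(p < 0):
            raise ValueError(f"negative species probability in year {year}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"species probabilities for {year} do not sum to 1")
        for month in range(1, 13):
            for occ in range(d.occasions_per_month):
                day = 1 + occ * 14
                date = f"{year:04d}-{month:02d}-{day:02d}"
                sampled = 0
                visited = 0
                while sampled < d.vendors_per_occasion and visited < d.vendor_pool:
                    visited += 1
                    if rng.random() >= d.stocking_rate:
                        continue
                    sampled += 1
                    labels = tuple(
                        names[i]
                        for i in rng.choice(len(names), size=TRIMMINGS_PER_EVENT, p=p)
                    )
                    bag_ids = tuple(
                        f"b{1 + i // d.trimmings_per_bag}"
                        for i in range(TRIMMINGS_PER_EVENT)
                    )
                    events.append(
                        SurveyEvent(
                            date=date,
                            vendor_id=f"{date}-v{sampled:02d}",
                            species_labels=labels,
                            bag_ids=bag_ids,
                        )
                    )
    return events


def gen_trade_ledgers(
    nations: Sequence[NationProfile],
    years: Iterable[int],
    seed: int = 0,
    taxa: Sequence[str] = ("Sphyrna lewini", "Carcharhinus longimanus"),
    importer: str = "Hong Kong",
    inject_malformed: bool = True,
) -> tuple[list[TradeRecord], list[CustomsRecord]]:
    """Simulate CITES-style trade records plus customs import totals.

    Customs totals are positive for every nation-year (lognormal jitter around
    the nation's mean annual volume).  CITES records are generated only for
    nations whose reporting flag is set; when ``inject_malformed`` is on the
    ledger also carries records that the filters must reject (count-unit,
    non-wild source, non-commercial purpose) and importer/exporter double
    reports with differing volumes.
    """
    if not nations:
        raise ValueError("nations list is empty")
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    rng = np.random.default_rng(seed)
    trade: list[TradeRecord] = []
    customs: list[CustomsRecord] = []
    for nation in nations:
        for year in years:
            kg_total = float(
                max(nation.mean_annual_kg, 1.0) * rng.lognormal(0.0, 0.3)
            )
            customs.append(
                CustomsRecord(origin_nation=nation.nation, year=year, kg=kg_total)
            )
            if not nation.cites_reporting:
                continue
            for taxon in taxa:
                if rng.random() < 0.3:
                    continue  # not every taxon is traded every year
                qty = float(rng.lognormal(np.log(500.0), 0.8))
                trade.append(
                    TradeRecord(
                        exporter=nation.nation,
                        importer=importer,
                        year=year,
                        taxon=taxon,
                        term="fins",
                        unit="kg",
                        quantity=round(qty, 2),
                        source_code="W",
                        purpose_code="T",
                        reported_by="importer",
                    )
                )
                if inject_malformed and rng.random() < 0.5:
                    # partner double report with a differing volume
                    trade.append(
                        TradeRecord(
                            exporter=nation.nation,
                            importer=importer,
                            year=year,
                            taxon=taxon,
                            term="fins",
                            unit="kg",
                            quantity=round(qty * float(rng.uniform(0.6, 1.4)), 2),
                            source_code="W",
                            purpose_code="T",
                            reported_by="exporter",
                        )
                    )
            if inject_malformed:
                roll = rng.random()
                if roll < 0.15:
                    trade.append(
                        TradeRecord(
                            exporter=nation.nation, importer=importer, year=year,
                            taxon=taxa[0], term="fins", unit="count",
                            quantity=float(rng.integers(10, 500)),
                            source_code="W", purpose_code="T",
                        )
                    )
                elif roll < 0.25:
                    trade.append(
                        TradeRecord(
                            exporter=nation.nation, importer=importer, year=year,
                            taxon=taxa[0], term="fins", unit="kg",
                            quantity=round(float(rng.lognormal(np.log(100), 0.5)), 2),
                            source_code="C", purpose_code="T",
                        )
                    )
                elif roll < 0.35:
                    trade.append(
                        TradeRecord(
                            exporter=nation.nation, importer=importer, year=year,
                            taxon=taxa[0], term="fins", unit="kg",
                            quantity=round(float(rng.lognormal(np.log(100), 0.5)), 2),
                            source_code="W", purpose_code="S",
                        )
                    )
    return trade, customs
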