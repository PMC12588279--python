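"""End-to-end orchestration of the surveillance pipeline on a scenario config.

Stages: simulate -> haplotype -> structure -> msa -> trends -> reconcile.
Every run writes a manifest recording package versions, the seed, the echoed
configuration, and per-stage row counts, so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .haplotyping import merge_amplicons, assign_many, write_fasta
from .market_trends import (
    compute_incidence,
    events_to_frame,
    fit_trend,
    proportional_contribution,
)
from .mixed_stock import msa_gibbs, summarize_contributions
from .population_structure import permutation_test
from .synthetic_data import (
    biweekly_design,
    default_preset,
    gen_amplicon_reads,
    gen_baseline,
    gen_haplotype_sequences,
    gen_mixture,
    gen_survey,
    gen_trade_ledgers,
    monthly_design,
)
from .trade_reconciliation import (
    filter_records,
    flag_nations,
    legal_share,
    load_exporter_profiles,
    reconcile_partner_reports,
)

logger = logging.getLogger("finmix")

STAGES = ("simulate", "haplotype", "structure", "msa", "trends", "reconcile")


@dataclass
class ScenarioConfig:
    """Settings for one synthetic end-to-end run."""

    seed: int = 0
    out_dir: str = "finmix_run"
    # synthetic data
    n_per_source: int = 50
    mixture_n: int = 150
    survey_years: list[int] = field(default_factory=lambda: list(range(2014, 2022)))
    trade_years: list[int] = field(default_factory=lambda: list(range(2014, 2023)))
    focal_species: str = "Carcharhinus longimanus"
    focal_probability: float = 0.007
    # MSA settings
    msa_iters: int = 10_000
    msa_burn_in: int = 5_000
    msa_chains: int = 4
    alpha_theta: float | None = None
    alpha_q: float = 1.0
    # structure / trends
    structure_permutations: int = 999
    trend_alpha: float = 0.05
    trend_years: list[int] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: ScenarioConfig) -> Path:
    """Execute all six stages; returns the output directory (with manifest)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "versions": {
            "finmix": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        logger.info("running stage %s", stage)
        try:
            info = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = info
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _stage_simulate(config: ScenarioConfig, out: Path, state: dict) -> dict:
    d = out / "simulate"
    d.mkdir(exist_ok=True)
    specs = default_preset()
    baseline, truth = gen_baseline(specs, config.n_per_source, seed=config.seed)
    mixture = gen_mixture(truth, config.mixture_n, seed=config.seed + 1)
    hap_seqs = gen_haplotype_sequences(
        baseline.haplotypes, length=535, seed=config.seed + 2
    )
    frags_a, frags_b = gen_amplicon_reads(hap_seqs, seed=config.seed + 3)
    designs = {
        y: biweekly_design() if y == 2014 else monthly_design()
        for y in config.survey_years
    }
    p_focal = config.focal_probability
    comp = {
        y: {
            "Prionace glauca": 0.35,
            "Carcharhinus falciformis": 0.20,
            "Sphyrna lewini": 0.05,
            "Sphyrna zygaena": 0.03,
            "Sphyrna mokarran": 0.02,
            config.focal_species: p_focal,
            "other": 1.0 - 0.65 - p_focal,
        }
        for y in config.survey_years
    }
    events = gen_survey(config.survey_years, designs, comp, seed=config.seed + 4)
    profiles = load_exporter_profiles()
    trade, customs = gen_trade_ledgers(
        profiles, config.trade_years, seed=config.seed + 5
    )

    baseline.to_csv(d / "baseline.csv")
    mixture.to_csv(d / "mixture.csv")
    write_fasta(hap_seqs, d / "haplotypes.fasta")
    write_fasta(frags_a, d / "amplicons_a.fasta")
    write_fasta(frags_b, d / "amplicons_b.fasta")
    events_to_frame(events).to_csv(d / "survey_events.csv", index=False)
    pd.DataFrame([r.__dict__ for r in trade]).to_csv(d / "cites_trade.csv", index=False)
    pd.DataFrame([r.__dict__ for r in customs]).to_csv(d / "customs.csv", index=False)

    state.update(
        baseline=baseline, truth=truth, mixture=mixture, hap_seqs=hap_seqs,
        frags=(frags_a, frags_b), events=events, trade=trade, customs=customs,
        profiles=profiles,
    )
    return {
        "sources": baseline.n_sources,
        "haplotypes": baseline.n_haplotypes,
        "mixture_total": mixture.total,
        "survey_events": len(events),
        "trade_records": len(trade),
        "customs_records": len(customs),
    }


def _stage_haplotype(config: ScenarioConfig, out: Path, state: dict) -> dict:
    d = out / "haplotype"
    d.mkdir(exist_ok=True)
    frags_a, frags_b = state["frags"]
    merged = [
        merge_amplicons(a, b, expected_length=535)
        for a, b in zip(frags_a, frags_b)
    ]
    # baseline table keyed by the known haplotype IDs (not re-derived ones)
    from .haplotyping import HaplotypeTable

    table = HaplotypeTable()
    for s in state["hap_seqs"]:
        table.ids.append(s.id)
        table.sequences[s.id] = s.bases
        table.counts[s.id] = 1
    table.validate()
    assignments, tally = assign_many(merged, table)
    table.to_csv(d / "haplotype_table.csv")
    pd.DataFrame(
        sorted(assignments.items()), columns=["sequence_id", "haplotype_id"]
    ).to_csv(d / "assignments.csv", index=False)
    recovered = sum(1 for sid, hid in assignments.items() if hid == sid)
    info = {
        "merged": len(merged),
        "haplotypes": len(table),
        "recovered": recovered,
        **tally,
    }
    logger.info("haplotype attrition: %s", tally)
    return info


def _stage_structure(config: ScenarioConfig, out: Path, state: dict) -> dict:
    d = out / "structure"
    d.mkdir(exist_ok=True)
    truth = state["truth"]
    seq_by_hap = {s.id: s for s in state["hap_seqs"]}
    rng = np.random.default_rng(config.seed + 6)
    pops = {}
    for i, name in enumerate(truth.sources[:2]):
        draws = rng.choice(
            len(truth.haplotypes), size=20, p=truth.baseline_freqs[i]
        )
        pops[name] = [seq_by_hap[truth.haplotypes[j]] for j in draws]
    (a, seqs_a), (b, seqs_b) = pops.items()
    res = permutation_test(
        seqs_a, seqs_b,
        n_permutations=config.structure_permutations,
        seed=config.seed + 7,
        names=(a, b),
    )
    pd.DataFrame(
        [{"pop_a": a, "pop_b": b, "phi_st": res.phi_st, "p_value": res.p_value,
          "n_permutations": res.n_permutations}]
    ).to_csv(d / "pairwise_phi.csv", index=False)
    return {"pairs_tested": 1, "phi_st": res.phi_st, "p_value": res.p_value}


def _stage_msa(config: ScenarioConfig, out: Path, state: dict) -> dict:
    d = out / "msa"
    d.mkdir(exist_ok=True)
    post = msa_gibbs(
        state["baseline"],
        state["mixture"],
        n_iter=config.msa_iters,
        burn_in=config.msa_burn_in,
        n_chains=config.msa_chains,
        seed=config.seed + 8,
        alpha_theta=config.alpha_theta,
        alpha_q=config.alpha_q,
    )
    post.summary_frame().to_csv(d / "posterior_summary.csv", index=False)
    post.draws_frame().to_csv(d / "posterior_draws.csv", index=False)
    reporting = set(state["truth"].sources[:3])
    summary = summarize_contributions(post, reporting)
    summary.table.to_csv(d / "contribution_report.csv", index=False)
    state["posterior"] = post
    return {
        "chains": config.msa_chains,
        "kept_draws": int(post.draws.shape[0] * post.draws.shape[1]),
        "max_psrf": post.max_psrf(),
        "converged": post.converged,
        "detected_unreported": summary.detected_unreported,
    }


def _stage_trends(config: ScenarioConfig, out: Path, state: dict) -> dict:
    d = out / "trends"
    d.mkdir(exist_ok=True)
    events = state["events"]
    series = compute_incidence(events, config.focal_species)
    fit = fit_trend(series, alpha=config.trend_alpha, years=config.trend_years)
    pd.DataFrame(
        {"year": series.years, "trials": series.trials,
         "successes": series.successes, "incidence": series.proportions}
    ).to_csv(d / "incidence.csv", index=False)
    contrib = proportional_contribution(
        events,
        sorted({sp for ev in events for sp in ev.species_labels}),
    )
    contrib.to_csv(d / "proportional_contribution.csv", index=False)
    (d / "trend_fit.json").write_text(
        json.dumps(
            {
                "species": fit.species,
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "se_beta1": fit.se_beta1,
                "p_wald": fit.p_wald,
                "significant": fit.significant,
                "separation_flag": fit.separation_flag,
            },
            indent=2,
        )
    )
    return {
        "years": len(series.years),
        "events": int(series.trials.sum()),
        "beta1": fit.beta1,
        "p_wald": fit.p_wald,
        "significant": fit.significant,
    }


def _stage_reconcile(config: ScenarioConfig, out: Path, state: dict) -> dict:
    d = out / "reconcile"
    d.mkdir(exist_ok=True)
    kept, excluded = filter_records(state["trade"])
    deduped = reconcile_partner_reports(kept)
    shares = legal_share(deduped, state["customs"])
    report = flag_nations(state["profiles"])
    shares.to_frame().to_csv(d / "legal_share.csv", index=False)
    report.table.to_csv(d / "nation_flags.csv", index=False)
    pd.DataFrame(
        [{"exporter": r.exporter, "year": r.year, "taxon": r.taxon,
          "reason": reason} for r, reason in excluded]
    ).to_csv(d / "excluded_records.csv", index=False)
    (d / "summary.json").write_text(json.dumps(report.summary(), indent=2))
    return {
        "records_in": len(state["trade"]),
        "kept": len(kept),
        "excluded": len(excluded),
        "deduplicated": len(deduped),
        **report.summary(),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "haplotype": _stage_haplotype,
    "structure": _stage_structure,
    "msa": _stage_msa,
    "trends": _stage_trends,
    "reconcile": _stage_reconcile,
}
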