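"""Bayesian many-to-one mixed-stock analysis (MSA).

Estimates the proportional contribution ``theta[s]`` of each source population
to a mixed market sample from haplotype counts, given a baseline matrix of
haplotype counts per source.  The model is the standard conditional
Dirichlet-multinomial mixture:

* ``theta ~ Dirichlet(alpha_theta)`` — source contributions,
* ``q[s, :] ~ Dirichlet(alpha_q)`` — haplotype frequencies within source *s*,
* baseline counts ``n[s, :] ~ Multinomial(q[s, :])``,
* each mixture individual picks a source ``z_i ~ Categorical(theta)`` and a
  haplotype ``h_i ~ Categorical(q[z_i, :])``.

Inference is by Gibbs sampling over ``(z, theta, q)`` with multiple chains and
Gelman-Rubin convergence diagnostics, plus an EM conditional-MLE estimator
(baseline frequencies fixed at their MLEs) that serves as an independent
frequentist cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BaselineMatrix",
    "MixtureCounts",
    "MsaPosterior",
    "ContributionSummary",
    "msa_gibbs",
    "msa_em",
    "gelman_rubin",
    "summarize_contributions",
]

RHAT_THRESHOLD = 1.2


@dataclass
class BaselineMatrix:
    """Source-by-haplotype count matrix (the "global baseline")."""

    sources: list[str]
    haplotypes: list[str]
    counts: np.ndarray  # (S, H) nonnegative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        S, H = self.counts.shape
        if S != len(self.sources) or H != len(self.haplotypes):
            raise ValueError("counts shape does not match source/haplotype labels")
        if np.any(self.counts < 0):
            raise ValueError("baseline counts must be nonnegative")
        if np.any(self.counts.sum(axis=1) <= 0):
            bad = [self.sources[i] for i in np.flatnonzero(self.counts.sum(axis=1) <= 0)]
            raise ValueError(f"baseline sources with zero total: {bad}")
        if np.any(self.counts.sum(axis=0) <= 0):
            bad = [
                self.haplotypes[j]
                for j in np.flatnonzero(self.counts.sum(axis=0) <= 0)
            ]
            raise ValueError(f"baseline haplotypes observed nowhere: {bad}")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def frequencies(self) -> np.ndarray:
        """Row-wise MLE frequencies n[s,h] / n[s,.]."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sources, columns=self.haplotypes)

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("source").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "BaselineMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            sources=[str(s) for s in df.index],
            haplotypes=[str(h) for h in df.columns],
            counts=df.to_numpy(),
        )


@dataclass
class MixtureCounts:
    """Haplotype counts observed in one market mixture sample."""

    haplotypes: list[str]
    counts: np.ndarray  # (H,) nonnegative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.haplotypes) != self.counts.shape[0]:
            raise ValueError("counts length does not match haplotype labels")
        if np.any(self.counts < 0):
            raise ValueError("mixture counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame({"haplotype": self.haplotypes, "count": self.counts}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "MixtureCounts":
        df = pd.read_csv(path)
        return cls(
            haplotypes=[str(h) for h in df["haplotype"]],
            counts=df["count"].to_numpy(),
        )


@dataclass
class MsaPosterior:
    """Posterior draws of source contributions plus diagnostics."""

    sources: list[str]
    draws: np.ndarray  # (n_chains, n_kept, S)
    point: np.ndarray  # posterior mean, (S,)
    ci95: np.ndarray  # (S, 2) equal-tail 2.5/97.5% quantiles
    psrf: np.ndarray | None  # per-parameter R-hat, None if single chain
    converged: bool
    excluded_haplotypes: dict[str, int] = field(default_factory=dict)

    @property
    def median(self) -> np.ndarray:
        return np.median(self.draws.reshape(-1, self.draws.shape[-1]), axis=0)

    def max_psrf(self) -> float:
        if self.psrf is None:
            return float("nan")
        return float(np.max(self.psrf))

    def draws_frame(self) -> pd.DataFrame:
        """Long-format draws: chain, iter, source, theta."""
        n_chains, n_kept, S = self.draws.shape
        chain = np.repeat(np.arange(n_chains), n_kept * S)
        it = np.tile(np.repeat(np.arange(n_kept), S), n_chains)
        source = np.tile(self.sources, n_chains * n_kept)
        return pd.DataFrame(
            {"chain": chain, "iter": it, "source": source,
             "theta": self.draws.ravel()}
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": self.sources,
                "mean": self.point,
                "q2.5": self.ci95[:, 0],
                "q97.5": self.ci95[:, 1],
                "psrf": self.psrf if self.psrf is not None else np.nan,
            }
        )


def _align_mixture(
    baseline: BaselineMatrix, mixture: MixtureCounts
) -> tuple[np.ndarray, dict[str, int]]:
    """Project mixture counts onto the baseline haplotype axis.

    Haplotypes absent from the baseline cannot enter the likelihood; their
    records are excluded with a logged count (mirrors dropping incomplete /
    unmatched market sequences) and reported back to the caller.
    """
    index = {h: j for j, h in enumerate(baseline.haplotypes)}
    x = np.zeros(baseline.n_haplotypes, dtype=np.int64)
    excluded: dict[str, int] = {}
    for h, c in zip(mixture.haplotypes, np.asarray(mixture.counts)):
        c = int(c)
        if c == 0:
            continue
        j = index.get(h)
        if j is None:
            excluded[h] = excluded.get(h, 0) + c
        else:
            x[j] += c
    return x, excluded


def gelman_rubin(chains: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Classic potential scale reduction factor (PSRF, R-hat).

    ``chains`` is an (m, n) or (m, n, p) array (m chains of n draws for p
    parameters).  Returns the per-parameter R-hat::

        R = sqrt(((n - 1)/n * W + B/n) / W)

    with ``W`` the mean within-chain variance and ``B/n`` the between-chain
    variance of chain means.  When every chain has zero variance, R-hat is 1 if
    the chain means agree (degenerate but converged) and ``inf`` otherwise.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
        squeeze = True
    elif arr.ndim == 3:
        squeeze = False
    else:
        raise ValueError("chains must be an (m, n) or (m, n, p) array")
    m, n, _ = arr.shape
    if m < 2:
        raise ValueError("at least two chains are required")
    if n < 2:
        raise ValueError("chains must contain at least two draws")
    means = arr.mean(axis=1)  # (m, p)
    W = arr.var(axis=1, ddof=1).mean(axis=0)  # (p,)
    B_over_n = means.var(axis=0, ddof=1)  # (p,)
    var_plus = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    degenerate = W == 0
    if np.any(degenerate):
        rhat = np.where(degenerate & (B_over_n == 0), 1.0, rhat)
        rhat = np.where(degenerate & (B_over_n > 0), np.inf, rhat)
    result = np.asarray(rhat)
    return result[0] if squeeze else result


def msa_gibbs(
    baseline: BaselineMatrix,
    mixture: MixtureCounts,
    n_iter: int = 100_000,
    burn_in: int = 50_000,
    n_chains: int = 4,
    seed: int | None = None,
    alpha_theta: float | None = None,
    alpha_q: float = 1.0,
    rhat_threshold: float = RHAT_THRESHOLD,
) -> MsaPosterior:
    """Gibbs sampler for the Dirichlet-multinomial mixed-stock model.

    Each iteration cycles: (i) latent source labels ``z_i | theta, q``
    proportional to ``theta_s * q[s, h(i)]``; (ii) ``theta | z ~
    Dirichlet(alpha_theta + tally(z))``; (iii) ``q[s, :] | ... ~
    Dirichlet(alpha_q + baseline n[s, :] + mixture individuals assigned to
    s)``.  Draws after ``burn_in`` are retained; R-hat is computed on theta
    across chains.

    Parameters
    ----------
    n_iter
        Total iterations per chain (including burn-in).
    burn_in
        Iterations discarded from the start of each chain.
    alpha_theta
        Symmetric Dirichlet prior on contributions; defaults to ``1/S``.
    alpha_q
        Per-cell Dirichlet prior on baseline haplotype frequencies.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    S, H = baseline.n_sources, baseline.n_haplotypes
    if alpha_theta is None:
        alpha_theta = 1.0 / S
    x, excluded = _align_mixture(baseline, mixture)
    if excluded and x.sum() == 0:
        raise ValueError(
            f"no mixture haplotype is present in the baseline: {sorted(excluded)}"
        )

    n_kept = n_iter - burn_in
    rng = np.random.default_rng(seed)
    chain_seeds = rng.integers(0, 2**63 - 1, size=n_chains)
    draws = np.empty((n_chains, n_kept, S))
    base_counts = baseline.counts.astype(float)

    for c, cs in enumerate(chain_seeds):
        crng = np.random.default_rng(int(cs))
        theta = crng.dirichlet(np.full(S, alpha_theta))
        q = crng.dirichlet(np.full(H, alpha_q), size=S)
        for it in range(n_iter):
            # (i) tally latent source labels per haplotype in one vectorised
            # multinomial: p(s | h) ~ theta_s q[s, h], columns normalised.
            weights = theta[:, None] * q  # (S, H)
            col_tot = weights.sum(axis=0)
            probs = (weights / np.where(col_tot > 0, col_tot, 1.0)).T  # (H, S)
            z_tally_hs = crng.multinomial(x, probs)  # (H, S)
            z_by_source = z_tally_hs.sum(axis=0)  # (S,)
            # (ii) contributions (S=1 is degenerate: theta is exactly 1)
            if S == 1:
                theta = np.ones(1)
            else:
                theta = crng.dirichlet(alpha_theta + z_by_source)
            # (iii) baseline frequencies, informed by baseline counts plus the
            # mixture individuals currently assigned to each source
            gam = crng.standard_gamma(alpha_q + base_counts + z_tally_hs.T)
            q = gam / gam.sum(axis=1, keepdims=True)
            if it >= burn_in:
                draws[c, it - burn_in] = theta

    flat = draws.reshape(-1, S)
    point = flat.mean(axis=0)
    ci95 = np.quantile(flat, [0.025, 0.975], axis=0).T
    if n_chains >= 2:
        psrf = gelman_rubin(draws)
        converged = bool(np.max(psrf) < rhat_threshold)
    else:
        psrf = None
        converged = False
    return MsaPosterior(
        sources=list(baseline.sources),
        draws=draws,
        point=point,
        ci95=ci95,
        psrf=psrf,
        converged=converged,
        excluded_haplotypes=excluded,
    )


def mixture_log_likelihood(
    theta: np.ndarray, q: np.ndarray, x: np.ndarray
) -> float:
    """Multinomial mixture log-likelihood sum_h x[h] log(sum_s theta_s q[s,h])."""
    p = theta @ q
    mask = x > 0
    if np.any(p[mask] <= 0):
        return -np.inf
    return float(np.sum(x[mask] * np.log(p[mask])))


def msa_em(
    baseline: BaselineMatrix,
    mixture: MixtureCounts,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Conditional MLE of source contributions by EM.

    Baseline frequencies are fixed at their row MLEs; EM ascends the mixture
    log-likelihood, which is asserted monotone nondecreasing every step, and
    stops when the sup-norm change in theta drops below ``tol``.
    """
    S = baseline.n_sources
    x, excluded = _align_mixture(baseline, mixture)
    if x.sum() == 0:
        raise ValueError("mixture has no haplotypes usable against this baseline")
    q = baseline.frequencies()
    # Haplotypes observed in the mixture must have support somewhere in q.
    unsupported = np.flatnonzero((x > 0) & (q.sum(axis=0) == 0))
    if unsupported.size:
        raise ValueError(
            "mixture haplotypes with zero baseline frequency: "
            f"{[baseline.haplotypes[j] for j in unsupported]}"
        )
    theta = np.full(S, 1.0 / S)
    M = x.sum()
    ll = mixture_log_likelihood(theta, q, x)
    for _ in range(max_iter):
        # E-step responsibilities r[s,h] = theta_s q[s,h] / p[h]; M-step is the
        # expected fraction of individuals per source.
        p = theta @ q  # (H,)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = theta[:, None] * q / p[None, :]
        r = np.where(p[None, :] > 0, r, 0.0)
        new_theta = (r * x[None, :]).sum(axis=1) / M
        new_ll = mixture_log_likelihood(new_theta, q, x)
        assert new_ll >= ll - 1e-9, "EM log-likelihood decreased"
        delta = np.max(np.abs(new_theta - theta))
        theta, ll = new_theta, new_ll
        if delta < tol:
            break
    return theta


@dataclass
class ContributionSummary:
    """Per-source contribution estimates partitioned by reporting status."""

    table: pd.DataFrame  # source, mean, q2.5, q97.5, detected, reported
    detected: list[str]
    detected_reported: list[str]
    detected_unreported: list[str]


def summarize_contributions(
    post: MsaPosterior,
    reporting_sources: set[str] | Sequence[str],
    detection_floor: float = 0.0,
) -> ContributionSummary:
    """Flag detected sources and split them into reported vs unreported origins.

    A source is "detected" when its 2.5% posterior quantile exceeds
    ``detection_floor``.  Detected sources absent from ``reporting_sources``
    are flagged as unreported origins.
    """
    reporting = set(reporting_sources)
    unknown = reporting - set(post.sources)
    if unknown:
        raise ValueError(f"reporting sources not in the baseline: {sorted(unknown)}")
    detected_mask = post.ci95[:, 0] > detection_floor
    reported_mask = np.array([s in reporting for s in post.sources])
    table = pd.DataFrame(
        {
            "source": post.sources,
            "mean": post.point,
            "q2.5": post.ci95[:, 0],
            "q97.5": post.ci95[:, 1],
            "detected": detected_mask,
            "reported": reported_mask,
        }
    )
    detected = [s for s, d in zip(post.sources, detected_mask) if d]
    det_rep = [s for s in detected if s in reporting]
    det_unrep = [s for s in detected if s not in reporting]
    return ContributionSummary(
        table=table,
        detected=detected,
        detected_reported=det_rep,
        detected_unreported=det_unrep,
    )
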