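"""Pairwise population differentiation via AMOVA Phi-ST and permutation tests.

Used to decide whether a new sample set is a distinct source population or
should be folded into an existing baseline population.  The statistic is the
two-level AMOVA fixation index

    Phi_ST = sigma2_among / (sigma2_among + sigma2_within)

computed from inter-sequence distances (default: raw pairwise nucleotide
differences, no substitution-model correction).  Significance is assessed by
permuting individuals across the two groups with group sizes held fixed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .haplotyping import MtcrSequence

__all__ = [
    "StructureTestResult",
    "DelimitationResult",
    "pairwise_distance_matrix",
    "phi_st_from_distances",
    "pairwise_phi_st",
    "permutation_test",
    "delimit_population",
]


@dataclass
class StructureTestResult:
    pair: tuple[str, str]
    phi_st: float  # NaN when total variance is zero (undefined)
    p_value: float | None = None
    n_permutations: int = 0
    phi_raw: float | None = None  # unclamped statistic used for permutation ranks


def _check_pops(pop_a: Sequence[MtcrSequence], pop_b: Sequence[MtcrSequence]) -> None:
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValueError("each population needs at least 2 sequences")
    lengths = {len(s) for s in pop_a} | {len(s) for s in pop_b}
    if len(lengths) > 1:
        raise ValueError(f"sequences differ in length: {sorted(lengths)}")


def pairwise_distance_matrix(seqs: Sequence[MtcrSequence]) -> np.ndarray:
    """Raw pairwise nucleotide-difference matrix (Hamming counts)."""
    arr = np.frombuffer(
        "".join(s.bases for s in seqs).encode(), dtype="S1"
    ).reshape(len(seqs), -1)
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(float)


def phi_st_from_distances(
    d: np.ndarray, n_a: int, clamp: bool = True
) -> float:
    """Two-level AMOVA Phi_ST from a pooled distance matrix.

    The first ``n_a`` rows/columns of ``d`` are group A, the rest group B.
    Distances enter the sums of squares directly (the convention for
    pairwise-difference distances).  A negative among-group variance component
    is truncated at zero when ``clamp`` is set, so identical groups yield
    exactly 0; the raw (possibly slightly negative) value is used internally
    for permutation ranking.  Returns NaN when total variance is zero.
    """
    N = d.shape[0]
    n_b = N - n_a
    P = 2
    ssd_total = d.sum() / (2 * N)
    a = slice(0, n_a)
    b = slice(n_a, N)
    ssd_within = d[a, a].sum() / (2 * n_a) + d[b, b].sum() / (2 * n_b)
    ssd_among = ssd_total - ssd_within
    df_within = N - P
    ms_within = ssd_within / df_within
    ms_among = ssd_among / (P - 1)
    n_eff = (N - (n_a**2 + n_b**2) / N) / (P - 1)
    sigma2_w = ms_within
    sigma2_a = (ms_among - ms_within) / n_eff
    if clamp and sigma2_a < 0:
        sigma2_a = 0.0
    denom = sigma2_a + sigma2_w
    if denom == 0:
        # both components zero only possible when among is also zero -> check
        # whether there is any among-group signal at all
        return 1.0 if ssd_among > 0 else float("nan")
    return sigma2_a / denom


def pairwise_phi_st(
    pop_a: Sequence[MtcrSequence],
    pop_b: Sequence[MtcrSequence],
    names: tuple[str, str] = ("A", "B"),
) -> StructureTestResult:
    """Phi_ST between two populations (no test; see :func:`permutation_test`)."""
    _check_pops(pop_a, pop_b)
    d = pairwise_distance_matrix(list(pop_a) + list(pop_b))
    phi = phi_st_from_distances(d, len(pop_a), clamp=True)
    raw = phi_st_from_distances(d, len(pop_a), clamp=False)
    return StructureTestResult(pair=names, phi_st=phi, phi_raw=raw)


def permutation_test(
    pop_a: Sequence[MtcrSequence],
    pop_b: Sequence[MtcrSequence],
    n_permutations: int = 10_000,
    seed: int | None = None,
    names: tuple[str, str] = ("A", "B"),
    exhaustive: bool = False,
) -> StructureTestResult:
    """Permutation test of Phi_ST > 0.

    Individuals are shuffled across the two groups with sizes held fixed; the
    p-value is ``(#{permuted Phi >= observed} + 1) / (n_permutations + 1)``.
    Permutation ranking uses the unclamped statistic so ties introduced by
    truncation do not distort the null distribution.  With
    ``exhaustive=True`` all distinct splits are enumerated instead and the
    p-value is the exact fraction of splits (including the identity) whose
    statistic reaches the observed one.
    """
    _check_pops(pop_a, pop_b)
    n_a = len(pop_a)
    d = pairwise_distance_matrix(list(pop_a) + list(pop_b))
    N = d.shape[0]
    observed_raw = phi_st_from_distances(d, n_a, clamp=False)
    observed = phi_st_from_distances(d, n_a, clamp=True)
    if math.isnan(observed_raw):
        raise ValueError(
            "Phi_ST undefined: zero total variance (all sequences identical)"
        )
    if exhaustive:
        count = 0
        total = 0
        for combo in itertools.combinations(range(N), n_a):
            order = list(combo) + [i for i in range(N) if i not in combo]
            dp = d[np.ix_(order, order)]
            if phi_st_from_distances(dp, n_a, clamp=False) >= observed_raw - 1e-12:
                count += 1
            total += 1
        return StructureTestResult(
            pair=names,
            phi_st=observed,
            phi_raw=observed_raw,
            p_value=count / total,
            n_permutations=total,
        )
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(N)
    for _ in range(n_permutations):
        perm = rng.permutation(idx)
        dp = d[np.ix_(perm, perm)]
        if phi_st_from_distances(dp, n_a, clamp=False) >= observed_raw - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return StructureTestResult(
        pair=names,
        phi_st=observed,
        phi_raw=observed_raw,
        p_value=p,
        n_permutations=n_permutations,
    )


@dataclass
class DelimitationResult:
    decision: str  # "distinct" | "merged"
    merged_into: str | None
    tests: list[StructureTestResult]
    alpha: float
    corrected_alpha: float


def delimit_population(
    candidate: Sequence[MtcrSequence],
    baseline_pops: Mapping[str, Sequence[MtcrSequence]],
    alpha: float = 0.05,
    n_permutations: int = 10_000,
    seed: int | None = None,
    correction: str = "bonferroni",
) -> DelimitationResult:
    """Decide whether ``candidate`` is a distinct population.

    The candidate is tested pairwise against every baseline population.  It is
    declared distinct iff every test is significant after multiple-testing
    correction (Bonferroni by default); otherwise it is merged into the
    baseline population with the smallest nonsignificant Phi_ST.
    """
    if not baseline_pops:
        raise ValueError("baseline population map is empty")
    if len(candidate) < 2:
        raise ValueError("candidate needs at least 2 sequences")
    if correction == "bonferroni":
        corrected = alpha / len(baseline_pops)
    elif correction == "none":
        corrected = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    rng = np.random.default_rng(seed)
    tests: list[StructureTestResult] = []
    for name, seqs in baseline_pops.items():
        res = permutation_test(
            candidate,
            seqs,
            n_permutations=n_permutations,
            seed=int(rng.integers(0, 2**63 - 1)),
            names=("candidate", name),
        )
        tests.append(res)
    nonsig = [t for t in tests if t.p_value > corrected]
    if not nonsig:
        return DelimitationResult("distinct", None, tests, alpha, corrected)
    best = min(nonsig, key=lambda t: (t.phi_st, t.pair[1]))
    return DelimitationResult("merged", best.pair[1], tests, alpha, corrected)
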