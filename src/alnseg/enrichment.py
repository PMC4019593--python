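"""Annotation enrichment in segment classes.

Under the null of no enrichment, annotation instances fall into segment
classes in proportion to the fraction of the reference sequence each
class covers (plus an unassigned/background category for the uncovered
remainder).  Observed counts come from a majority-overlap assignment
rule, and departure from expectation is measured by the log-likelihood
ratio statistic

    G = 2 * sum_j O_j * log(O_j / E_j)        (0 * log 0 = 0),

whose exact tail probability under Multinomial(N, coverage) is computed
by dynamic programming (exact dictionary DP for small problems, a
quantized-grid convolution for N up to 500) or Monte Carlo beyond.
Annotation types with at most one match inside the segment classes are
not tested; Bonferroni correction is applied across the types actually
tested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb, gammaln

from .profiling import SegmentCall


def _llr_statistic(obs: np.ndarray, expected: np.ndarray) -> float:
    obs = np.asarray(obs, dtype=float)
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))


def multinomial_llr_tail(
    obs,
    p,
    *,
    method: str = "auto",
    mc_draws: int = 100_000,
    exact_states: int = 500_000,
    grid_size: int = 16384,
    seed: int = 0,
) -> float:
    """P(G >= G_obs) for the multinomial log-likelihood-ratio statistic.

    ``method`` is ``auto`` (exact DP when the composition count allows,
    grid DP for N <= 500, Monte Carlo otherwise), or one of ``exact``,
    ``grid``, ``mc``.
    """
    obs = np.asarray(obs, dtype=np.int64)
    p = np.asarray(p, dtype=float)
    if obs.shape != p.shape:
        raise ValueError("obs and p must have equal length")
    if np.any(p <= 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("p must be a strictly positive probability vector")
    N = int(obs.sum())
    if N == 0:
        return 1.0
    E = N * p
    g_obs = _llr_statistic(obs, E)
    if g_obs <= 1e-12:
        return 1.0
    J = len(p)
    if method == "auto":
        n_comp = comb(N + J - 1, J - 1)
        if n_comp <= exact_states:
            method = "exact"
        elif N <= 500:
            method = "grid"
        else:
            method = "mc"
    if method == "exact":
        return _tail_exact(N, p, g_obs)
    if method == "grid":
        return _tail_grid(N, p, g_obs, grid_size)
    if method == "mc":
        return _tail_mc(N, p, g_obs, mc_draws, seed)
    raise ValueError(f"unknown method {method!r}")


def _per_count_g(N: int, pj: float) -> np.ndarray:
    x = np.arange(N + 1, dtype=float)
    g = np.zeros(N + 1)
    g[1:] = 2.0 * x[1:] * np.log(x[1:] / (N * pj))
    return g


def _log_w(N: int, pj: float) -> np.ndarray:
    """log(pj^x / x!) for x = 0..N (the factorized multinomial weight)."""
    x = np.arange(N + 1, dtype=float)
    return x * math.log(pj) - gammaln(x + 1)


def _tail_exact(N: int, p: np.ndarray, g_obs: float, tol: float = 1e-9) -> float:
    """Exact tail by DP over categories with states (counts used,
    accumulated statistic); statistic keys rounded to 1e-12 to merge
    identical partial sums."""
    J = len(p)
    states: dict[tuple[int, float], float] = {(0, 0.0): 0.0}  # -> log weight
    for j in range(J):
        g = _per_count_g(N, p[j])
        lw = _log_w(N, p[j])
        new: dict[tuple[int, float], float] = {}
        for (m, s), w in states.items():
            xmax = N - m if j < J - 1 else N - m
            xs = range(0, xmax + 1) if j < J - 1 else (N - m,)
            for x in xs:
                key = (m + x, round(s + g[x], 12))
                val = w + lw[x]
                if key in new:
                    a, b = new[key], val
                    hi = max(a, b)
                    new[key] = hi + math.log1p(math.exp(min(a, b) - hi))
                else:
                    new[key] = val
        states = new
    logs = np.array(list(states.values()))
    stats = np.array([k[1] for k in states])
    # normalizing by the total mass (instead of multiplying by N!) keeps
    # the computation in a safe floating range
    total = np.exp(logs - logs.max()).sum()
    tail = np.exp(logs[stats >= g_obs - tol] - logs.max()).sum()
    return float(min(1.0, tail / total))


def _tail_grid(N: int, p: np.ndarray, g_obs: float, grid_size: int) -> float:
    """Quantized-statistic convolution DP: W[m, s] accumulates the
    factorized multinomial weight of using m counts with statistic in
    bin s; the final N-count slice gives the distribution of G."""
    J = len(p)
    g_max = 2.0 * N * math.log(1.0 / p.min()) + 1e-9
    eps = g_max / (grid_size - 1)
    W = np.zeros((N + 1, grid_size))
    W[0, 0] = 1.0
    for j in range(J):
        g = _per_count_g(N, p[j])
        lw = _log_w(N, p[j])
        w = np.exp(lw)
        new = np.zeros_like(W)
        for m in range(N, -1, -1):
            row = W[m]
            if not row.any():
                continue
            for x in range(0, N - m + 1):
                shift = int(round(g[x] / eps))
                if shift == 0:
                    new[m + x] += row * w[x]
                elif shift > 0:
                    new[m + x, shift:] += row[: grid_size - shift] * w[x]
                else:
                    new[m + x, :shift] += row[-shift:] * w[x]
        W = new
    dist = W[N]
    total = dist.sum()
    cut = int(math.floor((g_obs - 2 * J * eps) / eps))  # guard quantization
    tail = dist[max(cut, 0):].sum()
    return float(min(1.0, tail / total))


def _tail_mc(N: int, p: np.ndarray, g_obs: float, draws: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    draws = max(draws, 100_000)
    X = rng.multinomial(N, p, size=draws).astype(float)
    E = N * p
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(X > 0, X * np.log(X / E), 0.0)
    G = 2.0 * terms.sum(axis=1)
    hits = int(np.sum(G >= g_obs - 1e-9))
    return float((hits + 1) / (draws + 1))


@dataclass
class EnrichmentResult:
    """Per-annotation-type enrichment verdict across segment classes."""

    annotation_type: str
    n_instances: int
    observed: np.ndarray       # length K+1; last entry = unassigned/background
    expected: np.ndarray
    statistic: float           # G (LLR)
    p_value: float
    p_adjusted: float
    significant: bool
    enriched: np.ndarray       # length K bool: O_j > E_j and significant

    def to_row(self) -> dict:
        return {
            "type": self.annotation_type,
            "N": self.n_instances,
            "G": self.statistic,
            "p": self.p_value,
            "p_bonferroni": self.p_adjusted,
            "significant": self.significant,
            "enriched_classes": ",".join(map(str, np.flatnonzero(self.enriched))),
        }


def class_coverage(calls: list[SegmentCall], total_length: int, n_classes: int) -> np.ndarray:
    """Fraction of the reference sequence covered by each class's calls,
    plus the uncovered background fraction (last entry)."""
    cov = np.zeros(n_classes + 1)
    for c in calls:
        cov[c.class_index] += c.length
    cov /= total_length
    cov[-1] = max(0.0, 1.0 - cov[:-1].sum())
    return cov


def _assign_instance(start: int, end: int, chrom, calls: list[SegmentCall], n_classes: int) -> int:
    """Majority-overlap class of one annotation instance: the class
    covering > 50% of the instance; ties fall to the midpoint's class;
    mostly-uncovered instances go to the background bucket (index K)."""
    length = max(1, end - start)
    overlap = np.zeros(n_classes + 1)
    midpoint_class = n_classes
    mid = (start + end) // 2
    for c in calls:
        if chrom is not None and c.chrom is not None and c.chrom != chrom:
            continue
        ov = min(end, c.end) - max(start, c.start)
        if ov > 0:
            overlap[c.class_index] += ov
        if c.start <= mid < c.end:
            midpoint_class = c.class_index
    overlap[n_classes] = length - overlap[:n_classes].sum()
    best = int(np.argmax(overlap))
    if overlap[best] * 2 > length:
        return best
    return midpoint_class


def enrichment_test(
    calls: list[SegmentCall],
    annotations: dict[str, pd.DataFrame] | pd.DataFrame,
    total_length: int,
    n_classes: int | None = None,
    *,
    alpha: float = 0.05,
    min_matches: int = 2,
    seed: int = 0,
    mc_draws: int = 100_000,
) -> list[EnrichmentResult]:
    """Test each annotation type for enrichment across segment classes.

    ``annotations`` maps type name -> interval DataFrame (columns chrom,
    start, end), or is a single BED-like DataFrame with a ``name``
    column holding the type.  Expected counts are proportional to class
    coverage of the ``total_length`` reference sequence; types with
    fewer than ``min_matches`` instances inside the classes are skipped.
    """
    if isinstance(annotations, pd.DataFrame):
        annotations = {
            str(t): df for t, df in annotations.groupby("name", sort=True)
        }
    if n_classes is None:
        n_classes = max((c.class_index for c in calls), default=-1) + 1
    coverage = class_coverage(calls, total_length, n_classes)

    prelim = []
    for name in sorted(annotations):
        df = annotations[name]
        obs = np.zeros(n_classes + 1, dtype=np.int64)
        for row in df.itertuples(index=False):
            j = _assign_instance(
                int(row.start), int(row.end), getattr(row, "chrom", None), calls, n_classes
            )
            obs[j] += 1
        in_classes = int(obs[:n_classes].sum())
        if in_classes < min_matches:
            continue
        prelim.append((name, obs))

    n_tests = len(prelim)
    results = []
    for name, obs in prelim:
        N = int(obs.sum())
        # categories with zero coverage and zero observations carry no
        # probability mass and are excluded exactly; a zero-coverage
        # category that was nonetheless observed gets a pseudo-expected
        # floor of half a count
        cov = coverage.copy()
        observed_zero_cov = (cov == 0) & (obs > 0)
        if observed_zero_cov.any():
            warnings.warn(
                f"type {name!r}: zero-coverage category received observations; "
                "applying a pseudo-expected floor of 0.5 counts"
            )
            cov[observed_zero_cov] = 0.5 / N
        active = cov > 0
        cov_a = cov[active] / cov[active].sum()
        obs_a = obs[active]
        E = np.zeros_like(cov)
        E[active] = N * cov_a
        g = _llr_statistic(obs_a, N * cov_a)
        pval = multinomial_llr_tail(obs_a, cov_a, mc_draws=mc_draws, seed=seed)
        p_adj = min(1.0, pval * n_tests)
        sig = p_adj < alpha
        enriched = (obs[:n_classes] > E[:n_classes]) & sig
        results.append(
            EnrichmentResult(
                annotation_type=name,
                n_instances=N,
                observed=obs,
                expected=E,
                statistic=g,
                p_value=pval,
                p_adjusted=p_adj,
                significant=sig,
                enriched=enriched,
            )
        )
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
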