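"""Model selection over the number of segment classes K.

Two procedures are provided.  Procedure 1 scores each K by a deviance
information criterion computed from the sampled log-likelihood,

    DICV = -2 * mean(logL) + 2 * var(logL),

(unbiased sample variance over the post-burn-in samples; smaller is
preferred) and takes the first local minimum of the K -> DICV curve,
continuing past it only when the curve later drops clearly below
(``continue_threshold`` x curve range), and stepping K down while the
chosen model contains empty classes.  Procedure 2 keeps the largest K
for which every class is stable: a class is unstable when its
post-burn-in conservation or GC series varies too much, and empty when
its mean mixture proportion is negligible.

Label switching is controlled by :func:`relabel_trace`, which aligns the
per-iteration class frequency vectors to running reference means with an
optimal assignment; stability series and profiles use the relabelled
classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .model import SegmentationModel, SegmentationResults


def compute_dicv(results) -> float:
    """DICV = -2*mean(logL) + 2*var(logL) (unbiased variance) over the
    post-burn-in samples; accepts a results object or a raw logL array."""
    if isinstance(results, SegmentationResults):
        x = np.asarray(results.loglik_post, dtype=float)
    else:
        x = np.asarray(results, dtype=float)
    if x.size < 2:
        raise ValueError("DICV needs at least two post-burn-in samples")
    return float(-2.0 * x.mean() + 2.0 * x.var(ddof=1))


def fit_k_range(
    seq,
    k_values=range(1, 21),
    *,
    seed: int = 0,
    model_kwargs: dict | None = None,
    **fit_kwargs,
) -> dict[int, SegmentationResults]:
    """Fit the model independently for each K in ``k_values``.

    Each run gets its own seed derived deterministically from ``seed``.
    """
    k_values = sorted(int(k) for k in k_values)
    if not k_values or k_values[0] < 1:
        raise ValueError("K range must be non-empty and start at K >= 1")
    rng = np.random.default_rng(int(seed) % (2**31))
    sub_seeds = {k: int(rng.integers(2**31)) for k in k_values}
    out = {}
    for k in k_values:
        model = SegmentationModel(seq, n_classes=k, **(model_kwargs or {}))
        out[k] = model.fit(seed=sub_seeds[k], **fit_kwargs).relabel()
    return out


def dicv_curve(results_by_k: dict[int, SegmentationResults]) -> pd.Series:
    """K -> DICV as a pandas Series (index K, ascending)."""
    ks = sorted(results_by_k)
    return pd.Series([compute_dicv(results_by_k[k]) for k in ks], index=ks, name="DICV")


def dicv_standard_error(results: SegmentationResults, n_batches: int = 20) -> float:
    """Monte-Carlo standard error of the DICV estimate by contiguous
    batch means over the post-burn-in log-likelihood chain."""
    x = np.asarray(results.loglik_post, dtype=float)
    n_batches = min(n_batches, x.size // 2)
    if n_batches < 2:
        return np.inf
    bs = x.size // n_batches
    vals = [compute_dicv(x[i * bs : (i + 1) * bs]) for i in range(n_batches)]
    return float(np.std(vals, ddof=1) / np.sqrt(n_batches))


def _local_minima(values: np.ndarray) -> list[int]:
    """Indices i that are local minima; ties broken toward smaller K
    (v[i] <= v[i+1] on the right, v[i] < v[i-1] on the left)."""
    out = []
    m = len(values)
    for i in range(m):
        left_ok = i == 0 or values[i] < values[i - 1]
        right_ok = i == m - 1 or values[i] <= values[i + 1]
        if left_ok and right_ok:
            out.append(i)
    return out


def select_first_dicv_minimum(
    curve: pd.Series,
    continue_threshold: float = 0.10,
    results_by_k: dict[int, SegmentationResults] | None = None,
    empty_threshold: float = 0.005,
    noise_scale=0.0,
) -> int:
    """Procedure 1: smallest K at a local DICV minimum.

    A value counts as a minimum when the next value does not improve on
    it by more than the noise tolerance (ties and sub-noise dips break
    toward smaller K; ``noise_scale`` is either a scalar tolerance or a
    per-K map of DICV standard errors, combined as 2*sqrt(se_K^2 +
    se_{K+1}^2)).  If the curve beyond the candidate later drops below
    it by more than ``continue_threshold`` times the curve's range,
    selection continues to the next minimum.  When traces are supplied,
    K is stepped down while the chosen model contains empty classes.
    """
    if len(curve) == 0:
        raise ValueError("empty DICV curve")
    curve = curve.sort_index()
    ks = np.asarray(curve.index)
    vals = np.asarray(curve.values, dtype=float)
    m = len(vals)

    def tol(i: int) -> float:
        if np.isscalar(noise_scale):
            return float(noise_scale)
        se_i = float(noise_scale[ks[i]])
        se_j = float(noise_scale[ks[i + 1]]) if i + 1 < m else 0.0
        return 2.0 * np.hypot(se_i, se_j)

    def pair_tol(i: int, j: int) -> float:
        if np.isscalar(noise_scale):
            return float(noise_scale)
        return 2.0 * np.hypot(float(noise_scale[ks[i]]), float(noise_scale[ks[j]]))

    candidates = [
        i for i in range(m) if i == m - 1 or vals[i + 1] >= vals[i] - tol(i)
    ]
    span = float(vals.max() - vals.min())
    chosen = candidates[0]
    for i in candidates:
        chosen = i
        later = vals[i + 1 :]
        if later.size:
            j = i + 1 + int(np.argmin(later))
            drop = vals[i] - vals[j]
            # continue only past drops that are clear of both the noise
            # tolerance and the subjective-continuation threshold
            if span > 0 and drop > max(continue_threshold * span, pair_tol(i, j)):
                continue
        break
    k_sel = int(ks[chosen])
    if results_by_k is not None:
        while k_sel > 1 and k_sel in results_by_k:
            report = assess_stability(results_by_k[k_sel], empty_threshold=empty_threshold)
            if not any(f == "empty" for f in report.flags):
                break
            k_sel -= 1
    return k_sel


def select_procedure1(
    results_by_k: dict[int, SegmentationResults],
    continue_threshold: float = 0.10,
    empty_threshold: float = 0.005,
) -> int:
    """Procedure 1 straight from fitted traces: DICV curve with
    estimated Monte-Carlo noise tolerance plus the empty-class veto."""
    curve = dicv_curve(results_by_k)
    noise = {k: dicv_standard_error(r) for k, r in results_by_k.items()}
    return select_first_dicv_minimum(
        curve,
        continue_threshold=continue_threshold,
        results_by_k=results_by_k,
        empty_threshold=empty_threshold,
        noise_scale=noise,
    )


# -- convergence / stability -------------------------------------------


def convergence_series(results: SegmentationResults) -> pd.DataFrame:
    """Per-iteration, per-class conservation and GC content.

    Conservation is the within-class frequency of the match symbols
    ({a, f} for pair8, {a, v} for triple32, symbol '1' for the
    conservation-binary scheme); GC is the frequency of the symbols whose
    species-1 base is G or C.  Columns missing for a scheme (e.g. GC for
    the conservation-binary encoding) are omitted.
    """
    scheme = results.seq.scheme
    freqs = results.class_freq_series()  # (iters, K, A), canonical labels
    iters, K, _ = freqs.shape
    frames = {}
    if scheme.match_symbols:
        cons = freqs[:, :, list(scheme.match_symbols)].sum(axis=2)
        for c in range(K):
            frames[f"conservation_{c}"] = cons[:, c]
    if scheme.gc_symbols:
        gc = freqs[:, :, list(scheme.gc_symbols)].sum(axis=2)
        for c in range(K):
            frames[f"gc_{c}"] = gc[:, c]
    if not frames:
        raise ValueError(f"scheme {scheme.name!r} defines neither conservation nor GC")
    df = pd.DataFrame(frames)
    df.index.name = "iteration"
    return df


@dataclass
class StabilityReport:
    """Per-class stability diagnostics over the post-burn-in samples."""

    n_classes: int
    conservation_sd: np.ndarray
    gc_sd: np.ndarray
    mixture_proportion: np.ndarray
    variability: np.ndarray  # max of the available sd series per class
    flags: list[str] = field(default_factory=list)  # 'stable'|'unstable'|'empty'

    @property
    def all_stable(self) -> bool:
        return all(f == "stable" for f in self.flags)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": np.arange(self.n_classes),
                "mixture_proportion": self.mixture_proportion,
                "conservation_sd": self.conservation_sd,
                "gc_sd": self.gc_sd,
                "variability": self.variability,
                "flag": self.flags,
            }
        )


def assess_stability(
    results: SegmentationResults,
    var_threshold: float = 0.05,
    empty_threshold: float = 0.005,
) -> StabilityReport:
    """Flag each class stable / unstable / empty.

    A class is *empty* when its mean posterior mixture proportion falls
    below ``empty_threshold``; otherwise *unstable* when the standard
    deviation of its post-burn-in conservation or GC series exceeds
    ``var_threshold``; otherwise *stable*.
    """
    sl = results.post_slice
    if sl.start >= sl.stop:
        raise ValueError("no post-burn-in samples")
    series = convergence_series(results).iloc[sl]
    K = results.n_classes
    cons_sd = np.zeros(K)
    gc_sd = np.zeros(K)
    for c in range(K):
        if f"conservation_{c}" in series:
            cons_sd[c] = series[f"conservation_{c}"].std(ddof=1)
        if f"gc_{c}" in series:
            gc_sd[c] = series[f"gc_{c}"].std(ddof=1)
    mp = results.pi_series()[sl].mean(axis=0)
    variability = np.maximum(cons_sd, gc_sd)
    flags = []
    for c in range(K):
        if mp[c] < empty_threshold:
            flags.append("empty")
        elif variability[c] > var_threshold:
            flags.append("unstable")
        else:
            flags.append("stable")
    return StabilityReport(
        n_classes=K,
        conservation_sd=cons_sd,
        gc_sd=gc_sd,
        mixture_proportion=mp,
        variability=variability,
        flags=flags,
    )


def select_by_stability(
    results_by_k: dict[int, SegmentationResults],
    var_threshold: float = 0.05,
    empty_threshold: float = 0.005,
) -> int:
    """Procedure 2: the largest K whose classes are all stable and none
    empty; falls back to K=1 with a warning when no K qualifies."""
    for k in sorted(results_by_k, reverse=True):
        report = assess_stability(
            results_by_k[k], var_threshold=var_threshold, empty_threshold=empty_threshold
        )
        if report.all_stable:
            return int(k)
    warnings.warn("no K has all classes stable; falling back to K=1")
    return 1


def relabel_trace(results: SegmentationResults) -> np.ndarray:
    """Permutations aligning class identities across iterations.

    Classes of each iteration are matched (optimal assignment on
    Euclidean distance between class symbol-frequency vectors) to
    running reference means; returns an (iterations, K) array mapping
    raw class index -> canonical index.  Deterministic given the trace.
    """
    freqs = results.classfreq_trace
    iters, K, A = freqs.shape
    perms = np.tile(np.arange(K), (iters, 1))
    if K == 1:
        return perms
    ref = freqs[0].copy()
    count = 1
    for it in range(1, iters):
        cost = np.linalg.norm(freqs[it][:, None, :] - ref[None, :, :], axis=2)
        raw, canon = linear_sum_assignment(cost)
        perms[it, raw] = canon
        ref[canon] = (ref[canon] * count + freqs[it][raw]) / (count + 1)
        count += 1
    return perms
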