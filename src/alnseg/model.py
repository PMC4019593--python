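"""Bayesian multiple change-point model with Dirichlet-multinomial
segment classes.

Model
-----
An encoded sequence x_1..x_n over an alphabet of size A is partitioned
by change-points into segments.  Each segment is an i.i.d. multinomial
draw whose probability vector theta comes from one of K Dirichlet
"segment classes" with hyperparameters alpha_c; theta is integrated out
analytically, so a segment with symbol counts (n_1..n_A) assigned to
class c contributes the Dirichlet-multinomial marginal

    Gamma(S)/Gamma(S+N) * prod_a Gamma(alpha_ca + n_a)/Gamma(alpha_ca),

S = sum_a alpha_ca, N = sum_a n_a (the ordered-sequence marginal).
Priors: each eligible inter-position boundary is included independently
with probability rho; segment labels are categorical with weights pi ~
symmetric Dirichlet(1); each alpha component has a Gamma(shape, scale)
prior.  Fixed boundaries (block separators) are present in every
segmentation and contribute no likelihood term.

Interface
---------
``SegmentationModel(seq, n_classes).fit(...)`` returns a
:class:`SegmentationResults` carrying the MCMC trace; selection,
profiling and plotting hang off the results object.
``brute_force_posterior`` computes the exact posterior by enumeration on
tiny instances and is the correctness oracle for the sampler.
"""

from __future__ import annotations

import gzip
import itertools
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.special import gammaln, logsumexp

from . import _sampler
from .encoding import SCHEMES, EncodedSequence


def segment_log_marginal(counts, alpha) -> float:
    """Log marginal likelihood of one segment's symbol counts under a
    Dirichlet(alpha) prior on the multinomial parameter (theta
    integrated out; ordered-sequence convention, no multinomial
    coefficient)."""
    counts = np.asarray(counts)
    alpha = np.asarray(alpha, dtype=float)
    if counts.shape != alpha.shape:
        raise ValueError("counts and alpha must have the same length")
    if np.any(alpha <= 0):
        raise ValueError("all Dirichlet hyperparameters must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    S = alpha.sum()
    N = counts.sum()
    return float(
        gammaln(S) - gammaln(S + N) + np.sum(gammaln(alpha + counts) - gammaln(alpha))
    )


def log_likelihood(seq: EncodedSequence, changepoints, labels, alphas) -> float:
    """Sum of segment log-marginals for an explicit segmentation state.

    ``changepoints`` are sorted inter-position indices (including fixed
    ones); ``labels`` has one class index per segment."""
    changepoints = np.asarray(changepoints, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    alphas = np.asarray(alphas, dtype=float)
    if len(labels) != len(changepoints) + 1:
        raise ValueError("need exactly one label per segment")
    if labels.size and (labels.min() < 0 or labels.max() >= alphas.shape[0]):
        raise ValueError("segment label out of range")
    cuts = [0, *changepoints.tolist(), len(seq)]
    total = 0.0
    for s, (i, j) in enumerate(zip(cuts[:-1], cuts[1:])):
        counts = np.bincount(seq.symbols[i:j], minlength=seq.scheme.size)
        total += segment_log_marginal(counts, alphas[labels[s]])
    return total


def mc_standard_error(series) -> float:
    """Monte-Carlo standard error of a chain mean by non-overlapping
    batch means (about sqrt(T) batches)."""
    x = np.asarray(series, dtype=float)
    T = x.size
    if T < 4:
        return float(np.std(x, ddof=1) / np.sqrt(T)) if T > 1 else np.inf
    nb = max(2, int(np.sqrt(T)))
    bs = T // nb
    means = x[: nb * bs].reshape(nb, bs).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(nb))


class SegmentationModel:
    """Change-point segmentation model for one encoded sequence.

    Parameters
    ----------
    seq : EncodedSequence
        The (possibly concatenated) encoded sequence; its fixed
        boundaries are forced into every sampled segmentation.
    n_classes : int
        Number of Dirichlet segment classes K (>= 1).
    changepoint_prior : float
        Per-boundary inclusion probability rho (default 0.01).
    alpha_prior : (float, float)
        Shape and scale of the Gamma prior on each alpha component
        (default (1, 10): weakly informative, positive).
    """

    def __init__(
        self,
        seq: EncodedSequence,
        n_classes: int = 1,
        *,
        changepoint_prior: float = 0.01,
        alpha_prior: tuple[float, float] = (1.0, 10.0),
    ):
        if len(seq) < 1:
            raise ValueError("sequence must be non-empty")
        if n_classes < 1:
            raise ValueError("need at least one segment class")
        if not 0.0 < changepoint_prior < 1.0:
            raise ValueError("changepoint prior must be in (0, 1)")
        if alpha_prior[0] <= 0 or alpha_prior[1] <= 0:
            raise ValueError("alpha prior shape and scale must be positive")
        self.seq = seq
        self.n_classes = int(n_classes)
        self.changepoint_prior = float(changepoint_prior)
        self.alpha_prior = (float(alpha_prior[0]), float(alpha_prior[1]))

    @classmethod
    def from_text(cls, symbols: str, scheme, **kwargs) -> "SegmentationModel":
        """Build a model straight from a symbol string (no coordinates)."""
        if isinstance(scheme, str):
            scheme = SCHEMES[scheme]
        idx = {s: i for i, s in enumerate(scheme.alphabet)}
        seq = EncodedSequence(
            symbols=np.array([idx[c] for c in symbols], dtype=np.uint8), scheme=scheme
        )
        return cls(seq, **kwargs)

    def _prefix_counts(self) -> np.ndarray:
        A = self.seq.scheme.size
        onehot = np.zeros((len(self.seq), A), dtype=np.int64)
        onehot[np.arange(len(self.seq)), self.seq.symbols] = 1
        cum = np.zeros((len(self.seq) + 1, A), dtype=np.int64)
        np.cumsum(onehot, axis=0, out=cum[1:])
        return cum

    def fit(
        self,
        iterations: int = 20000,
        *,
        seed: int = 0,
        burn_in: float = 0.5,
        thin: int = 10,
        proposals_per_sweep: int | None = None,
        shift_fraction: float = 0.2,
        sample_alpha: bool = True,
        sample_pi: bool = True,
        alpha_init=None,
        pi_init=None,
        rw_step: float = 0.25,
        max_state_bytes: int = 512 * 1024**2,
    ) -> "SegmentationResults":
        """Run the MCMC sampler and return a results object.

        ``burn_in`` is the fraction of iterations discarded before
        posterior summaries (default 0.5).  Full states (per-position
        labels and boundary sets) are stored every ``thin`` iterations;
        per-iteration summaries are always stored.  Identical arguments
        and seed give a bitwise-identical trace.
        """
        if iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 <= burn_in < 1.0:
            raise ValueError("burn_in fraction must be in [0, 1)")
        n = len(self.seq)
        A = self.seq.scheme.size
        K = self.n_classes
        rho = self.changepoint_prior
        seed = int(seed) % (2**31)

        rng = np.random.default_rng(seed)
        if alpha_init is None:
            # start near the global composition with per-class jitter to
            # break the label symmetry
            gf = self.seq.symbol_frequencies() + 1.0 / (10.0 * A)
            gf = gf / gf.sum()
            alpha0 = gf[None, :] * A * np.exp(rng.normal(0.0, 0.5, size=(K, A)))
        else:
            alpha0 = np.broadcast_to(np.asarray(alpha_init, dtype=float), (K, A)).copy()
        if np.any(alpha0 <= 0):
            raise ValueError("initial alpha must be positive")
        pi0 = (
            np.full(K, 1.0 / K)
            if pi_init is None
            else np.asarray(pi_init, dtype=float).copy()
        )
        if pi0.shape != (K,) or np.any(pi0 <= 0):
            raise ValueError("pi_init must be a positive length-K vector")
        pi0 = pi0 / pi0.sum()

        if proposals_per_sweep is None:
            proposals_per_sweep = max(8, int(round(n * rho)))
        shift_proposals = max(1, int(round(proposals_per_sweep * shift_fraction)))

        thin = max(1, int(thin))
        n_states = (iterations + thin - 1) // thin
        if n_states * n > max_state_bytes:
            thin_eff = int(np.ceil(iterations * n / max_state_bytes))
            warnings.warn(
                f"thin={thin} would store {n_states} full states "
                f"({n_states * n / 1e6:.0f} MB); raising thin to {thin_eff}"
            )
            thin = thin_eff
            n_states = (iterations + thin - 1) // thin

        fixed = np.asarray(self.seq.fixed_boundaries, dtype=np.int64)
        bnd_cap = int(len(fixed) + max(64, 8 * proposals_per_sweep))
        cum = self._prefix_counts()

        while True:
            loglik = np.empty(iterations)
            k_free = np.empty(iterations, dtype=np.int64)
            n_seg = np.empty(iterations, dtype=np.int64)
            pi_tr = np.empty((iterations, K))
            alpha_tr = np.empty((iterations, K, A))
            freq_tr = np.empty((iterations, K, A))
            state_labels = np.zeros((n_states, n), dtype=np.int8)
            state_nb = np.zeros(n_states, dtype=np.int64)
            state_bnd = np.zeros((n_states, bnd_cap), dtype=np.int64)
            state_iters = np.zeros(n_states, dtype=np.int64)
            alpha_run = alpha0.copy()
            pi_run = pi0.copy()
            n_stored, overflow = _sampler.run_chain(
                cum,
                n,
                fixed,
                rho,
                alpha_run,
                pi_run,
                iterations,
                int(proposals_per_sweep),
                int(shift_proposals),
                sample_alpha,
                sample_pi,
                self.alpha_prior[0],
                self.alpha_prior[1],
                rw_step,
                seed,
                thin,
                n_states,
                bnd_cap,
                loglik,
                k_free,
                n_seg,
                pi_tr,
                alpha_tr,
                freq_tr,
                state_labels,
                state_nb,
                state_bnd,
                state_iters,
            )
            if not overflow:
                break
            bnd_cap *= 4  # same seed -> same chain; only the buffer grows

        return SegmentationResults(
            model=self,
            iterations=iterations,
            burn_in_index=int(np.floor(iterations * burn_in)),
            seed=seed,
            thin=thin,
            loglik=loglik,
            k_free=k_free,
            n_seg=n_seg,
            pi_trace=pi_tr,
            alpha_trace=alpha_tr,
            classfreq_trace=freq_tr,
            state_labels=state_labels[:n_stored],
            state_nb=state_nb[:n_stored],
            state_bnd=state_bnd[:n_stored],
            state_iters=state_iters[:n_stored],
        )


@dataclass
class SegmentationResults:
    """MCMC trace and posterior summaries for one (sequence, K) run."""

    model: SegmentationModel
    iterations: int
    burn_in_index: int
    seed: int
    thin: int
    loglik: np.ndarray
    k_free: np.ndarray
    n_seg: np.ndarray
    pi_trace: np.ndarray
    alpha_trace: np.ndarray
    classfreq_trace: np.ndarray
    state_labels: np.ndarray
    state_nb: np.ndarray
    state_bnd: np.ndarray
    state_iters: np.ndarray

    def __post_init__(self):
        self._perms = None

    # -- basic accessors ------------------------------------------------
    @property
    def seq(self) -> EncodedSequence:
        return self.model.seq

    @property
    def n_classes(self) -> int:
        return self.model.n_classes

    @property
    def post_slice(self) -> slice:
        return slice(self.burn_in_index, self.iterations)

    @property
    def loglik_post(self) -> np.ndarray:
        return self.loglik[self.post_slice]

    def set_burn_in(self, fraction: float) -> "SegmentationResults":
        if not 0.0 <= fraction < 1.0:
            raise ValueError("burn-in fraction must be in [0, 1)")
        self.burn_in_index = int(np.floor(self.iterations * fraction))
        return self

    # -- label-switching control ---------------------------------------
    def relabel(self) -> "SegmentationResults":
        from .selection import relabel_trace

        self._perms = relabel_trace(self)
        return self

    @property
    def permutations(self) -> np.ndarray:
        """(iterations, K) maps raw class index -> canonical index;
        identity until :meth:`relabel` is called."""
        if self._perms is None:
            return np.tile(np.arange(self.n_classes), (self.iterations, 1))
        return self._perms

    def class_freq_series(self) -> np.ndarray:
        """(iterations, K, A) per-class symbol frequencies on canonical
        class indices (post-relabel if relabel() was called)."""
        out = np.empty_like(self.classfreq_trace)
        perms = self.permutations
        it_idx = np.arange(self.iterations)[:, None]
        out[it_idx, perms, :] = self.classfreq_trace
        return out

    def pi_series(self) -> np.ndarray:
        out = np.empty_like(self.pi_trace)
        perms = self.permutations
        it_idx = np.arange(self.iterations)[:, None]
        out[it_idx, perms] = self.pi_trace
        return out

    # -- posterior summaries --------------------------------------------
    def posterior_k_and_L(self) -> tuple[float, float]:
        """Posterior mean number of free change-points k and mean segment
        length L (symbols per segment, counting fixed-boundary segments)."""
        sl = self.post_slice
        if sl.start >= sl.stop:
            raise ValueError("no post-burn-in samples")
        k = float(self.k_free[sl].mean())
        L = float((len(self.seq) / self.n_seg[sl]).mean())
        return k, L

    def dicv(self) -> float:
        from .selection import compute_dicv

        return compute_dicv(self)

    def convergence_series(self) -> pd.DataFrame:
        from .selection import convergence_series

        return convergence_series(self)

    def stability(self, var_threshold: float = 0.05, empty_threshold: float = 0.005):
        from .selection import assess_stability

        return assess_stability(
            self, var_threshold=var_threshold, empty_threshold=empty_threshold
        )

    def posterior_profile(self):
        from .profiling import posterior_profile

        return posterior_profile(self)

    def call_segments(self, threshold: float = 0.5, min_run: int = 8):
        from .profiling import call_segments

        return call_segments(self.posterior_profile(), threshold=threshold, min_run=min_run)

    def class_summary(self) -> pd.DataFrame:
        from .profiling import class_summary

        return class_summary(self)

    def plot_class_blobs(self, ax=None):
        from .plotting import plot_class_blobs

        return plot_class_blobs(self, ax=ax)

    def summary(self) -> str:
        """Human-readable fit summary in the style of statsmodels."""
        k, L = self.posterior_k_and_L()
        lines = [
            "Change-point segmentation results",
            "=" * 64,
            f"scheme: {self.seq.scheme.name:<10}  length: {len(self.seq):>10}  "
            f"fixed boundaries: {len(self.seq.fixed_boundaries)}",
            f"classes (K): {self.n_classes:<6} iterations: {self.iterations:<8} "
            f"burn-in: {self.burn_in_index}",
            f"seed: {self.seed:<12} rho: {self.model.changepoint_prior}",
            "-" * 64,
            f"posterior mean change-points k: {k:.2f}",
            f"posterior mean segment length L: {L:.2f}",
            f"mean log-likelihood: {self.loglik_post.mean():.2f}   "
            f"DICV: {self.dicv():.2f}",
            "-" * 64,
        ]
        summ = self.class_summary()
        lines.append(summ.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------
    def save(self, directory) -> None:
        """Serialize the trace: per-iteration summaries as TSV, thinned
        states as text, config as YAML."""
        os.makedirs(directory, exist_ok=True)
        K, A = self.n_classes, self.seq.scheme.size
        summ = pd.DataFrame(
            {"iteration": np.arange(self.iterations), "loglik": self.loglik,
             "k_free": self.k_free, "n_seg": self.n_seg}
        )
        for c in range(K):
            summ[f"pi_{c}"] = self.pi_trace[:, c]
        for c in range(K):
            for a in range(A):
                summ[f"alpha_{c}_{a}"] = self.alpha_trace[:, c, a]
                summ[f"freq_{c}_{a}"] = self.classfreq_trace[:, c, a]
        summ.to_csv(os.path.join(directory, "summaries.tsv"), sep="\t", index=False)
        with gzip.open(os.path.join(directory, "states.txt.gz"), "wt") as fh:
            for st in range(len(self.state_iters)):
                nb = self.state_nb[st]
                bnds = ",".join(map(str, self.state_bnd[st, :nb]))
                labs = ",".join(map(str, self.state_labels[st]))
                fh.write(f"{self.state_iters[st]}\t{bnds}\t{labs}\n")
        cfg = {
            "n_classes": K,
            "iterations": int(self.iterations),
            "burn_in_index": int(self.burn_in_index),
            "seed": int(self.seed),
            "thin": int(self.thin),
            "changepoint_prior": self.model.changepoint_prior,
            "alpha_prior": list(self.model.alpha_prior),
            "scheme": self.seq.scheme.name,
            "length": len(self.seq),
            "n_fixed": int(len(self.seq.fixed_boundaries)),
        }
        with open(os.path.join(directory, "config.yaml"), "w") as fh:
            yaml.safe_dump(cfg, fh)

    @classmethod
    def load(cls, directory, seq: EncodedSequence) -> "SegmentationResults":
        """Reload a trace saved by :meth:`save` (the encoded sequence is
        supplied separately; only its length and scheme must match)."""
        with open(os.path.join(directory, "config.yaml")) as fh:
            cfg = yaml.safe_load(fh)
        if cfg["length"] != len(seq) or cfg["scheme"] != seq.scheme.name:
            raise ValueError("sequence does not match the saved trace")
        model = SegmentationModel(
            seq,
            n_classes=cfg["n_classes"],
            changepoint_prior=cfg["changepoint_prior"],
            alpha_prior=tuple(cfg["alpha_prior"]),
        )
        summ = pd.read_csv(os.path.join(directory, "summaries.tsv"), sep="\t")
        K, A = cfg["n_classes"], seq.scheme.size
        iters = cfg["iterations"]
        pi_tr = summ[[f"pi_{c}" for c in range(K)]].to_numpy()
        alpha_tr = np.empty((iters, K, A))
        freq_tr = np.empty((iters, K, A))
        for c in range(K):
            for a in range(A):
                alpha_tr[:, c, a] = summ[f"alpha_{c}_{a}"]
                freq_tr[:, c, a] = summ[f"freq_{c}_{a}"]
        st_iters, st_nb, st_bnd, st_labels = [], [], [], []
        with gzip.open(os.path.join(directory, "states.txt.gz"), "rt") as fh:
            for line in fh:
                it_s, bnds, labs = line.rstrip("\n").split("\t")
                st_iters.append(int(it_s))
                b = np.array(
                    [int(x) for x in bnds.split(",")] if bnds else [], dtype=np.int64
                )
                st_nb.append(len(b))
                st_bnd.append(b)
                st_labels.append([int(x) for x in labs.split(",")])
        n_states = len(st_iters)
        cap = max((len(b) for b in st_bnd), default=1) or 1
        bnd_arr = np.zeros((n_states, cap), dtype=np.int64)
        for i, b in enumerate(st_bnd):
            bnd_arr[i, : len(b)] = b
        return cls(
            model=model,
            iterations=iters,
            burn_in_index=cfg["burn_in_index"],
            seed=cfg["seed"],
            thin=cfg["thin"],
            loglik=summ["loglik"].to_numpy(),
            k_free=summ["k_free"].to_numpy(),
            n_seg=summ["n_seg"].to_numpy(),
            pi_trace=pi_tr,
            alpha_trace=alpha_tr,
            classfreq_trace=freq_tr,
            state_labels=np.asarray(st_labels, dtype=np.int8),
            state_nb=np.asarray(st_nb, dtype=np.int64),
            state_bnd=bnd_arr,
            state_iters=np.asarray(st_iters, dtype=np.int64),
        )


def brute_force_posterior(
    seq: EncodedSequence,
    alpha,
    pi=None,
    changepoint_prior: float = 0.01,
    max_free: int = 20,
) -> dict:
    """Exact posterior marginals by exhaustive enumeration (test oracle).

    Enumerates every subset of the eligible (non-fixed) boundaries with
    alpha and pi held fixed, summing segment Dirichlet-multinomial
    marginals with labels integrated out.  Returns per-boundary inclusion
    probabilities, per-position class probabilities and the posterior
    mean free change-point count.
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    K = alpha.shape[0]
    pi = np.full(K, 1.0 / K) if pi is None else np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    n = len(seq)
    fixed = set(map(int, seq.fixed_boundaries))
    eligible = [b for b in range(1, n) if b not in fixed]
    if len(eligible) > max_free:
        raise ValueError(
            f"{len(eligible)} eligible boundaries exceed enumeration cap {max_free}"
        )
    rho = changepoint_prior
    logpi = np.log(pi)
    log_rho, log_1mrho = np.log(rho), np.log(1.0 - rho)

    # cache collapsed segment scores and per-class posteriors
    counts_cum = np.zeros((n + 1, seq.scheme.size), dtype=np.int64)
    onehot = np.zeros((n, seq.scheme.size), dtype=np.int64)
    onehot[np.arange(n), seq.symbols] = 1
    np.cumsum(onehot, axis=0, out=counts_cum[1:])

    seg_logmarg: dict[tuple[int, int], np.ndarray] = {}

    def seg_scores(i: int, j: int) -> np.ndarray:
        key = (i, j)
        if key not in seg_logmarg:
            cts = counts_cum[j] - counts_cum[i]
            seg_logmarg[key] = np.array(
                [logpi[c] + segment_log_marginal(cts, alpha[c]) for c in range(K)]
            )
        return seg_logmarg[key]

    log_weights = []
    configs = []
    incl = np.zeros(n - 1) if n > 1 else np.zeros(0)
    class_prob = np.zeros((n, K))
    k_mean_num = 0.0

    for mask in itertools.product((0, 1), repeat=len(eligible)):
        free = [b for b, m in zip(eligible, mask) if m]
        cuts = sorted(set(free) | fixed)
        bounds = [0, *cuts, n]
        lw = sum(mask) * log_rho + (len(eligible) - sum(mask)) * log_1mrho
        seg_post = []
        for i, j in zip(bounds[:-1], bounds[1:]):
            sc = seg_scores(i, j)
            lw += logsumexp(sc)
            seg_post.append((i, j, np.exp(sc - logsumexp(sc))))
        log_weights.append(lw)
        configs.append((free, seg_post))

    log_weights = np.asarray(log_weights)
    logZ = logsumexp(log_weights)
    w = np.exp(log_weights - logZ)
    for wi, (free, seg_post) in zip(w, configs):
        for b in free:
            incl[b - 1] += wi
        for b in fixed:
            incl[b - 1] += wi
        for i, j, post in seg_post:
            class_prob[i:j] += wi * post
        k_mean_num += wi * len(free)

    return {
        "boundary_prob": incl,
        "class_prob": class_prob,
        "k_mean": k_mean_num,
        "log_evidence": float(logZ),
    }
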