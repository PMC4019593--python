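"""Posterior class profiles, segment calling and export.

A position's class-membership probability is the fraction of stored
post-burn-in states whose segment covering that position carries the
class (after relabelling).  Segment calls are maximal runs of at least
``min_run`` positions whose probability for one class reaches the
threshold; runs never cross fixed boundaries or reference-coordinate
discontinuities.  Calls are exported as BED6 and, given a reference
FASTA, as per-class FASTA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass

from .encoding import EncodedSequence
from .model import SegmentationResults


@dataclass
class PosteriorProfile:
    """Per-position class-membership probabilities plus posterior mean
    change-point count and segment length."""

    probs: np.ndarray  # (n, K), rows sum to 1
    k_mean: float
    length_mean: float
    seq: EncodedSequence

    def __post_init__(self):
        rows = self.probs.sum(axis=1)
        if self.probs.size and not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("profile rows must sum to 1")


@dataclass
class SegmentCall:
    """One called segment (0-based half-open; sequence-space indices are
    always present, genomic coordinates when the sequence has them)."""

    class_index: int
    chrom: str | None
    start: int
    end: int
    mean_prob: float
    seq_start: int
    seq_end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


def posterior_profile(results: SegmentationResults) -> PosteriorProfile:
    """Empirical per-position class probabilities from the stored
    (relabelled) post-burn-in states."""
    n = len(results.seq)
    K = results.n_classes
    perms = results.permutations
    keep = results.state_iters >= results.burn_in_index
    if not keep.any():
        raise ValueError("no stored post-burn-in states; lower thin or burn-in")
    counts = np.zeros((n, K))
    pos = np.arange(n)
    for st in np.flatnonzero(keep):
        lab = perms[results.state_iters[st]][results.state_labels[st]]
        counts[pos, lab] += 1.0
    probs = counts / counts.sum(axis=1, keepdims=True)
    k_mean, L_mean = results.posterior_k_and_L()
    return PosteriorProfile(probs=probs, k_mean=k_mean, length_mean=L_mean, seq=results.seq)


def _break_indices(seq: EncodedSequence) -> np.ndarray:
    """Positions p where a run may not continue from p-1 to p: fixed
    boundaries plus reference-coordinate discontinuities."""
    n = len(seq)
    breaks = set(map(int, seq.fixed_boundaries))
    if seq.coords is not None and n > 1:
        pos = seq.coords["pos"].to_numpy()
        chrom = seq.coords["chrom"].to_numpy()
        jump = (pos[1:] != pos[:-1] + 1) | (chrom[1:] != chrom[:-1])
        breaks.update((np.flatnonzero(jump) + 1).tolist())
    return np.asarray(sorted(breaks), dtype=np.int64)


def call_segments(
    profile: PosteriorProfile, threshold: float = 0.5, min_run: int = 8
) -> list[SegmentCall]:
    """Maximal runs of length >= ``min_run`` where one class's posterior
    probability is >= ``threshold`` (inclusive).

    A position belongs to its most probable class only (ties to the
    lower class index), so calls are disjoint; runs are split at fixed
    boundaries and coordinate gaps.
    """
    probs = profile.probs
    n = len(profile.seq)
    if n == 0:
        return []
    best = np.argmax(probs, axis=1)
    best_p = probs[np.arange(n), best]
    active = best_p >= threshold
    breaks = set(_break_indices(profile.seq).tolist())
    coords = profile.seq.coords

    out: list[SegmentCall] = []
    p = 0
    while p < n:
        if not active[p]:
            p += 1
            continue
        q = p + 1
        while (
            q < n
            and active[q]
            and best[q] == best[p]
            and q not in breaks
        ):
            q += 1
        if q - p >= min_run:
            if coords is not None:
                chrom = str(coords["chrom"].iloc[p])
                gstart = int(coords["pos"].iloc[p])
                gend = int(coords["pos"].iloc[q - 1]) + 1
                strand = str(coords["strand"].iloc[p])
            else:
                chrom, gstart, gend, strand = None, p, q, "+"
            out.append(
                SegmentCall(
                    class_index=int(best[p]),
                    chrom=chrom,
                    start=gstart,
                    end=gend,
                    mean_prob=float(best_p[p:q].mean()),
                    seq_start=p,
                    seq_end=q,
                    strand=strand,
                )
            )
        p = q
    return out


def class_summary(results: SegmentationResults) -> pd.DataFrame:
    """Per-class posterior means: mixture proportion (MP), conservation,
    GC content and (pair8 only) transition/transversion ratio.

    T/T is the ratio of mean transition-symbol frequency to mean
    transversion-symbol frequency; with no transversions it is inf, and
    with neither it is NaN.
    """
    scheme = results.seq.scheme
    sl = results.post_slice
    freqs = results.class_freq_series()[sl]
    mp = results.pi_series()[sl].mean(axis=0)
    K = results.n_classes
    data = {"class": np.arange(K), "MP": mp}
    if scheme.match_symbols:
        data["conservation"] = freqs[:, :, list(scheme.match_symbols)].sum(axis=2).mean(axis=0)
    if scheme.gc_symbols:
        data["GC"] = freqs[:, :, list(scheme.gc_symbols)].sum(axis=2).mean(axis=0)
    if scheme.transition_symbols and scheme.transversion_symbols:
        ts = freqs[:, :, list(scheme.transition_symbols)].sum(axis=2).mean(axis=0)
        tv = freqs[:, :, list(scheme.transversion_symbols)].sum(axis=2).mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            data["Ts/Tv"] = np.where(tv > 0, ts / np.where(tv > 0, tv, 1.0),
                                     np.where(ts > 0, np.inf, np.nan))
    return pd.DataFrame(data)


def summarize_counts(counts, scheme) -> dict:
    """Conservation / GC / Ts-Tv ratio of a raw symbol count vector
    (direct recomputation used to cross-check the trace summaries)."""
    counts = np.asarray(counts, dtype=float)
    tot = counts.sum()
    f = counts / tot if tot else counts
    out = {}
    if scheme.match_symbols:
        out["conservation"] = float(f[list(scheme.match_symbols)].sum())
    if scheme.gc_symbols:
        out["GC"] = float(f[list(scheme.gc_symbols)].sum())
    if scheme.transition_symbols and scheme.transversion_symbols:
        ts = f[list(scheme.transition_symbols)].sum()
        tv = f[list(scheme.transversion_symbols)].sum()
        out["Ts/Tv"] = float(ts / tv) if tv > 0 else (np.inf if ts > 0 else np.nan)
    return out


def fixed_boundary_report(seq: EncodedSequence) -> int:
    """Number of fixed change-points (alignment-block boundaries)."""
    return int(len(seq.fixed_boundaries))


def export_bed(calls: list[SegmentCall], path) -> None:
    """Write calls as BED6: name = class_<k>, score = 1000 * mean
    posterior probability."""
    with open(path, "w") as fh:
        for c in calls:
            chrom = c.chrom if c.chrom is not None else "seq"
            score = int(round(1000 * c.mean_prob))
            fh.write(
                f"{chrom}\t{c.start}\t{c.end}\tclass_{c.class_index}\t{score}\t{c.strand}\n"
            )


def read_calls_bed(path) -> list[SegmentCall]:
    """Inverse of :func:`export_bed` (sequence-space fields mirror the
    genomic ones on read)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            out.append(
                SegmentCall(
                    class_index=int(name.removeprefix("class_")),
                    chrom=None if chrom == "seq" else chrom,
                    start=int(start),
                    end=int(end),
                    mean_prob=int(score) / 1000.0,
                    seq_start=int(start),
                    seq_end=int(end),
                    strand=strand,
                )
            )
    return out


def export_class_fasta(calls: list[SegmentCall], reference, path) -> None:
    """Extract the reference-species sequence of each call as FASTA.

    ``reference`` is a pyfaidx.Fasta, a dict of contig -> sequence
    string, or a path to an (uncompressed) FASTA file.  Records are
    named ``chrom:start-end|class_<k>``.
    """
    if isinstance(reference, (str,)) or hasattr(reference, "__fspath__"):
        from pyfaidx import Fasta

        reference = Fasta(str(reference))
    with open(path, "w") as fh:
        for c in calls:
            if c.chrom is None:
                raise ValueError("calls lack genomic coordinates; cannot extract FASTA")
            try:
                contig = reference[c.chrom]
            except KeyError as exc:
                raise KeyError(f"contig {c.chrom!r} missing from reference") from exc
            seq = str(contig[c.start : c.end])
            fh.write(f">{c.chrom}:{c.start}-{c.end}|class_{c.class_index}\n{seq}\n")
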