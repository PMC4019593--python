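"""Seeded generators for control sequences and planted-truth benchmarks.

``single_class_control`` reproduces the single-class control
construction: a sequence of the same length and fixed-boundary layout
as a template, in which every segment's multinomial parameter is drawn
from *one* Dirichlet distribution centred on the template's character
frequencies — so any structure a segmentation finds beyond one class is
spurious.  ``multiclass`` generalizes this to K planted classes with
known change-points for recovery benchmarks; ``alignment_pair``
produces a raw two-species alignment whose pair8 encoding has planted
classes; ``motif_control_classes`` regenerates observed segment classes
with identical length multisets and matched base composition, for
motif-discovery null controls.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import PAIR8, EncodedSequence, EncodingScheme

#: Realistic pair8 symbol frequencies for a 3' UTR alignment of closely
#: related Drosophila species: conservation ~0.95, species-1 GC ~0.38,
#: transition/transversion ratio ~1.2.
DROSOPHILA_UTR_PAIR8_FREQS = np.array(
    [0.5930, 0.0064, 0.0140, 0.0064, 0.0050, 0.3570, 0.0050, 0.0130]
)
DROSOPHILA_UTR_PAIR8_FREQS = DROSOPHILA_UTR_PAIR8_FREQS / DROSOPHILA_UTR_PAIR8_FREQS.sum()


@dataclass
class PlantedTruth:
    """Ground truth of a simulated sequence."""

    changepoints: np.ndarray       # planted (free) inter-position boundaries
    labels: np.ndarray             # class per planted segment
    class_freqs: np.ndarray        # (K, A)
    weights: np.ndarray            # (K,)
    scheme: EncodingScheme
    seed: int

    def position_labels(self, n: int) -> np.ndarray:
        """True class of every position."""
        lengths = np.diff([0, *self.changepoints.tolist(), n])
        return np.repeat(self.labels, lengths)


def _segment_bounds(length: int, boundaries) -> list[tuple[int, int]]:
    cuts = [0, *sorted(int(b) for b in boundaries), length]
    return list(zip(cuts[:-1], cuts[1:]))


def single_class_control(
    frequencies=None,
    length: int | None = None,
    boundaries=None,
    template: EncodedSequence | None = None,
    *,
    concentration: float = 100.0,
    seed: int = 0,
    scheme: EncodingScheme = PAIR8,
) -> EncodedSequence:
    """Single-segment-class control sequence.

    Either pass a ``template`` (its length, fixed boundaries, scheme and
    empirical frequencies are reused) or ``frequencies`` + ``length`` (+
    optional ``boundaries``).  Each segment draws its own multinomial
    parameter from Dirichlet(concentration * frequencies) and emits
    symbols i.i.d. from it.
    """
    if template is not None:
        scheme = template.scheme
        length = len(template)
        boundaries = template.fixed_boundaries
        if frequencies is None:
            frequencies = template.symbol_frequencies()
    if frequencies is None or length is None:
        raise ValueError("need a template, or frequencies and length")
    freqs = np.asarray(frequencies, dtype=float)
    if np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0, atol=1e-6):
        raise ValueError("frequencies must be non-negative and sum to 1")
    freqs = freqs / freqs.sum()
    if len(freqs) != scheme.size:
        raise ValueError("frequency vector length must match the scheme alphabet")
    boundaries = np.asarray(boundaries if boundaries is not None else [], dtype=np.int64)
    rng = np.random.default_rng(seed)
    symbols = np.empty(length, dtype=np.uint8)
    alpha = np.where(freqs > 0, concentration * freqs, 1e-6)
    for i, j in _segment_bounds(length, boundaries):
        theta = rng.dirichlet(alpha)
        symbols[i:j] = rng.choice(scheme.size, size=j - i, p=theta)
    return EncodedSequence(symbols=symbols, scheme=scheme, fixed_boundaries=boundaries)


def evenly_spaced_boundaries(length: int, mean_spacing: float, seed: int = 0) -> np.ndarray:
    """Fixed-boundary layout with approximately geometric spacing around
    ``mean_spacing`` (emulating concatenated UTR blocks of varying size)."""
    rng = np.random.default_rng(seed)
    cuts = []
    p = 0
    while True:
        p += max(1, int(rng.geometric(1.0 / mean_spacing)))
        if p >= length:
            break
        cuts.append(p)
    return np.asarray(cuts, dtype=np.int64)


def multiclass(
    class_freqs,
    weights=None,
    *,
    boundary_rate: float = 0.01,
    length: int = 10000,
    scheme: EncodingScheme | None = None,
    seed: int = 0,
) -> tuple[EncodedSequence, PlantedTruth]:
    """Planted K-class sequence: change-points are i.i.d. Bernoulli per
    inter-position boundary, segment labels i.i.d. from ``weights`` and
    symbols i.i.d. within each segment from its class frequency vector.

    Planted boundaries are *free* (not fixed), so recovery benchmarks
    must find them.  Adjacent segments may share a label; the planted
    truth keeps them distinct.
    """
    class_freqs = np.atleast_2d(np.asarray(class_freqs, dtype=float))
    K, A = class_freqs.shape
    if np.any(class_freqs < 0) or not np.allclose(class_freqs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("class frequency vectors must lie on the simplex")
    class_freqs = class_freqs / class_freqs.sum(axis=1, keepdims=True)
    weights = (
        np.full(K, 1.0 / K) if weights is None else np.asarray(weights, dtype=float)
    )
    weights = weights / weights.sum()
    if scheme is None:
        scheme = PAIR8 if A == 8 else _generic_scheme(A)
    if scheme.size != A:
        raise ValueError("scheme alphabet size must match class vectors")
    rng = np.random.default_rng(seed)
    if boundary_rate > 0 and length > 1:
        mask = rng.random(length - 1) < boundary_rate
        changepoints = np.flatnonzero(mask) + 1
    else:
        changepoints = np.empty(0, dtype=np.int64)
    bounds = _segment_bounds(length, changepoints)
    labels = rng.choice(K, size=len(bounds), p=weights)
    symbols = np.empty(length, dtype=np.uint8)
    for (i, j), lab in zip(bounds, labels):
        symbols[i:j] = rng.choice(A, size=j - i, p=class_freqs[lab])
    seq = EncodedSequence(symbols=symbols, scheme=scheme)
    truth = PlantedTruth(
        changepoints=np.asarray(changepoints, dtype=np.int64),
        labels=np.asarray(labels, dtype=np.int64),
        class_freqs=class_freqs,
        weights=weights,
        scheme=scheme,
        seed=seed,
    )
    return seq, truth


def _generic_scheme(A: int) -> EncodingScheme:
    """Ad-hoc scheme for arbitrary alphabet sizes (simulation only)."""
    glyphs = "0123456789abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if A > len(glyphs):
        raise ValueError("alphabet too large for the generic scheme")
    return EncodingScheme(
        name=f"generic{A}", alphabet=glyphs[:A], arity=1,
        column_map={(g,): i for i, g in enumerate(glyphs[:A])},
    )


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


def alignment_pair(
    segments: list[dict],
    *,
    seed: int = 0,
) -> tuple[str, str, PlantedTruth]:
    """Two aligned sequences with planted compositional classes.

    ``segments`` is a list of dicts with keys ``length``, ``gc``
    (species-1 GC fraction), ``match`` (per-base identity probability)
    and ``kappa`` (transition:transversion odds; each of the two possible
    transversions is half-weighted), plus optional ``label``.
    """
    rng = np.random.default_rng(seed)
    s1 = []
    s2 = []
    cps = []
    labels = []
    pos = 0
    for si, spec in enumerate(segments):
        L = int(spec["length"])
        gc = float(spec["gc"])
        match = float(spec["match"])
        kappa = float(spec.get("kappa", 1.0))
        labels.append(int(spec.get("label", si)))
        p1 = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
        bases = "ACGT"
        for _ in range(L):
            b1 = bases[rng.choice(4, p=p1)]
            if rng.random() < match:
                b2 = b1
            elif rng.random() < kappa / (kappa + 1.0):
                b2 = _TRANSITION[b1]
            else:
                b2 = _TRANSVERSIONS[b1][int(rng.random() < 0.5)]
            s1.append(b1)
            s2.append(b2)
        pos += L
        if si < len(segments) - 1:
            cps.append(pos)
    truth = PlantedTruth(
        changepoints=np.asarray(cps, dtype=np.int64),
        labels=np.asarray(labels, dtype=np.int64),
        class_freqs=np.empty((0, 8)),
        weights=np.empty(0),
        scheme=PAIR8,
        seed=seed,
    )
    return "".join(s1), "".join(s2), truth


def motif_control_classes(
    lengths,
    base_freqs,
    replicates: int = 100,
    seed: int = 0,
) -> list[list[tuple[str, str]]]:
    """Null control classes for motif discovery.

    Each replicate contains one random sequence per observed segment —
    the length multiset matches the observed class exactly and bases are
    i.i.d. from the observed base frequencies.  Returns a list of
    replicates, each a list of (record name, sequence).
    """
    lengths = [int(x) for x in lengths]
    if not lengths:
        raise ValueError("observed class has no segments")
    p = np.asarray(base_freqs, dtype=float)
    if p.shape != (4,) or np.any(p < 0):
        raise ValueError("base_freqs must be 4 non-negative values (A, C, G, T)")
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out = []
    for r in range(replicates):
        recs = []
        for i, L in enumerate(lengths):
            seq = "".join(bases[rng.choice(4, size=L, p=p)])
            recs.append((f"control_{r}_{i}", seq))
        out.append(recs)
    return out


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
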