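"""Symbol encodings of alignment columns.

A pairwise alignment column (two aligned bases) is mapped to one of 8
symbols ``a``–``h``; a three-way column to one of 32 symbols
``a``–``z``, ``U``–``Z``.  Both encodings are *non-directional*: a column
and its reverse complement receive the same symbol, so the encoded
sequence is invariant to which strand was aligned.  Two binary encodings
are also provided: GC content of a single sequence (``1`` = G/C) and
conservation of a pairwise alignment (``1`` = match).

Columns containing an indel or an ambiguous base (N or any other IUPAC
ambiguity code) are excluded from the encoded sequence; the coordinate
map records, for every retained symbol, the reference-species position
it came from.  Block boundaries (for example between concatenated
3' UTRs) are represented structurally as *fixed boundaries* — indices
between symbol positions that every segmentation must cut at — rather
than as emitted separator symbols.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
GAP_CHARS = frozenset("-.")
AMBIGUOUS_CHARS = frozenset("NRYSWKMBDHV")
NUCLEOTIDES = frozenset("ACGT")


def complement_column(column: tuple[str, ...]) -> tuple[str, ...]:
    """Base-complement every entry of a column (not reversed: a single
    column has no 5'/3' extent)."""
    return tuple(COMPLEMENT[b] for b in column)


@dataclass(frozen=True)
class EncodingScheme:
    """A total map from ungapped, unambiguous alignment columns to symbols.

    Attributes
    ----------
    name : str
        ``pair8``, ``triple32``, ``gc2`` or ``cons2``.
    alphabet : str
        Ordered symbol list; its length is the alphabet size A.
    arity : int
        Number of species per column (1 for ``gc2``).
    column_map : dict
        Column tuple -> symbol index.  Total on all ``4**arity`` ungapped
        columns; complementary columns share an index.
    match_symbols : tuple of int
        Symbol indices representing a conserved (matching) column, or
        ``()`` when conservation is undefined for the scheme.
    gc_symbols : tuple of int
        Symbol indices whose species-1 base is G or C, or ``()``.
    transition_symbols, transversion_symbols : tuple of int
        Mismatch symbol indices split by substitution type (pair8 only).
    """

    name: str
    alphabet: str
    arity: int
    column_map: dict = field(repr=False)
    match_symbols: tuple = ()
    gc_symbols: tuple = ()
    transition_symbols: tuple = ()
    transversion_symbols: tuple = ()

    @property
    def size(self) -> int:
        return len(self.alphabet)

    def symbol_index(self, column) -> int:
        return self.column_map[tuple(column)]

    def indices_of(self, symbols: str) -> tuple:
        return tuple(self.alphabet.index(s) for s in symbols)


def _build_map(species_rows: list[str], symbols: str, alphabet: str) -> dict:
    """Build a total column map from a printed half-table by filling the
    remaining columns through complementation."""
    arity = len(species_rows)
    cmap: dict = {}
    for i, sym in enumerate(symbols):
        col = tuple(row[i] for row in species_rows)
        cmap[col] = alphabet.index(sym)
    for col in itertools.product("ACGT", repeat=arity):
        if col not in cmap:
            cmap[col] = cmap[complement_column(col)]
    # non-directionality is structural: verify once at import
    for col, idx in cmap.items():
        assert cmap[complement_column(col)] == idx
    return cmap


_PAIR8_SP1 = "ATATATATCGCGCGCG"
_PAIR8_SP2 = "ATCGGCTAATCGGCTA"
_PAIR8_SYM = "aabbccddeeffgghh"

PAIR8 = EncodingScheme(
    name="pair8",
    alphabet="abcdefgh",
    arity=2,
    column_map=_build_map([_PAIR8_SP1, _PAIR8_SP2], _PAIR8_SYM, "abcdefgh"),
    match_symbols=(0, 5),          # a, f
    gc_symbols=(4, 5, 6, 7),       # e, f, g, h  (species-1 base is G/C)
    transition_symbols=(2, 7),     # c, h  (A<->G, C<->T)
    transversion_symbols=(1, 3, 4, 6),  # b, d, e, g
)

_TRIPLE32_SP1 = "A" * 16 + "C" * 16
_TRIPLE32_SP2 = "AAAACCCCGGGGTTTT" * 2
_TRIPLE32_SP3 = "ACGT" * 8
_TRIPLE32_SYM = "abcdefghijklmnopqrstuvwxyzUVWXYZ"

TRIPLE32 = EncodingScheme(
    name="triple32",
    alphabet=_TRIPLE32_SYM,
    arity=3,
    column_map=_build_map(
        [_TRIPLE32_SP1, _TRIPLE32_SP2, _TRIPLE32_SP3], _TRIPLE32_SYM, _TRIPLE32_SYM
    ),
    match_symbols=(0, 21),                    # a (AAA/TTT), v (CCC/GGG)
    gc_symbols=tuple(range(16, 32)),          # species-1 base C (or its complement G)
)

GC2 = EncodingScheme(
    name="gc2",
    alphabet="01",
    arity=1,
    column_map={("A",): 0, ("T",): 0, ("G",): 1, ("C",): 1},
    gc_symbols=(1,),
)

CONS2 = EncodingScheme(
    name="cons2",
    alphabet="01",
    arity=2,
    column_map={
        col: int(col[0] == col[1]) for col in itertools.product("ACGT", repeat=2)
    },
    match_symbols=(1,),
)

SCHEMES = {s.name: s for s in (PAIR8, TRIPLE32, GC2, CONS2)}


@dataclass
class EncodedSequence:
    """A symbol sequence over a scheme alphabet with fixed boundaries and
    an optional reference-coordinate map.

    ``symbols`` stores alphabet indices (uint8); ``text()`` renders the
    glyphs.  ``fixed_boundaries`` are inter-position indices b (1 <= b <
    len) meaning "a segment boundary is forced between positions b-1 and
    b".  ``coords`` (optional) is a DataFrame with one row per symbol and
    columns ``chrom``, ``pos``, ``strand`` giving the species-1 position
    each retained column came from.
    """

    symbols: np.ndarray
    scheme: EncodingScheme
    fixed_boundaries: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )
    coords: pd.DataFrame | None = None

    def __post_init__(self):
        self.symbols = np.asarray(self.symbols, dtype=np.uint8)
        self.fixed_boundaries = np.asarray(
            np.sort(np.unique(self.fixed_boundaries)), dtype=np.int64
        )
        n = len(self.symbols)
        if n and self.fixed_boundaries.size:
            if self.fixed_boundaries[0] < 1 or self.fixed_boundaries[-1] >= n:
                raise ValueError("fixed boundaries must lie strictly inside the sequence")
        elif self.fixed_boundaries.size and n == 0:
            raise ValueError("empty sequence cannot carry fixed boundaries")
        if self.coords is not None and len(self.coords) != n:
            raise ValueError("coordinate map length must equal symbol count")

    def __len__(self) -> int:
        return len(self.symbols)

    def text(self) -> str:
        alpha = np.frombuffer(self.scheme.alphabet.encode(), dtype=np.uint8)
        return alpha[self.symbols].tobytes().decode()

    def blocks(self) -> list[np.ndarray]:
        """Symbol arrays of the chunks delimited by fixed boundaries."""
        return np.split(self.symbols, self.fixed_boundaries)

    def symbol_counts(self) -> np.ndarray:
        return np.bincount(self.symbols, minlength=self.scheme.size).astype(np.int64)

    def symbol_frequencies(self) -> np.ndarray:
        c = self.symbol_counts()
        return c / max(1, c.sum())

    def conservation(self) -> float:
        """Fraction of match symbols among retained columns."""
        f = self.symbol_frequencies()
        return float(f[list(self.scheme.match_symbols)].sum())

    def gc_fraction(self) -> float:
        f = self.symbol_frequencies()
        return float(f[list(self.scheme.gc_symbols)].sum())


def _classify_column(column: tuple[str, ...], position: int) -> str:
    """Return 'keep', 'skip', or raise for an invalid character."""
    for base in column:
        if base in GAP_CHARS or base in AMBIGUOUS_CHARS:
            return "skip"
        if base not in NUCLEOTIDES:
            raise ValueError(
                f"invalid character {base!r} in alignment column {position}"
            )
    return "keep"


def encode_columns(
    columns,
    scheme: EncodingScheme,
    *,
    chrom: str | None = None,
    positions=None,
    strand: str = "+",
) -> EncodedSequence:
    """Encode an iterable of alignment columns under ``scheme``.

    Gapped/ambiguous columns are dropped (the coordinate map skips them).
    ``positions``, if given, holds the species-1 reference coordinate of
    every *input* column; retained columns keep theirs.
    """
    codes: list[int] = []
    kept_pos: list[int] = []
    for i, col in enumerate(columns):
        col = tuple(str(b).upper() for b in col)
        if len(col) != scheme.arity:
            raise ValueError(
                f"column {i} has {len(col)} entries; scheme {scheme.name!r} "
                f"expects {scheme.arity}"
            )
        if _classify_column(col, i) == "skip":
            continue
        codes.append(scheme.column_map[col])
        if positions is not None:
            kept_pos.append(positions[i])
    coords = None
    if positions is not None:
        coords = pd.DataFrame(
            {
                "chrom": chrom if chrom is not None else ".",
                "pos": np.asarray(kept_pos, dtype=np.int64),
                "strand": strand,
            }
        )
    return EncodedSequence(
        symbols=np.asarray(codes, dtype=np.uint8), scheme=scheme, coords=coords
    )


def encode_pairwise(columns, **coord_kwargs) -> EncodedSequence:
    """Encode two-species columns with the 8-symbol non-directional scheme."""
    return encode_columns(columns, PAIR8, **coord_kwargs)


def encode_threeway(columns, **coord_kwargs) -> EncodedSequence:
    """Encode three-species columns with the 32-symbol non-directional scheme."""
    return encode_columns(columns, TRIPLE32, **coord_kwargs)


def encode_binary(data, mode: str, **coord_kwargs) -> EncodedSequence:
    """Binary encodings: ``mode='gc'`` takes one nucleotide sequence
    (1 for G/C, 0 for A/T); ``mode='conservation'`` takes pairwise
    columns (1 for a match, 0 for a mismatch; indels excluded)."""
    if mode == "gc":
        columns = [(b,) for b in data]
        return encode_columns(columns, GC2, **coord_kwargs)
    if mode == "conservation":
        return encode_columns(data, CONS2, **coord_kwargs)
    raise ValueError(f"unknown binary mode {mode!r}; use 'gc' or 'conservation'")


def concatenate_blocks(blocks: list[EncodedSequence]) -> EncodedSequence:
    """Concatenate encoded blocks, inserting a fixed boundary between
    consecutive non-empty blocks and preserving internal boundaries."""
    blocks = [b for b in blocks if len(b) > 0]
    if not blocks:
        return EncodedSequence(np.empty(0, dtype=np.uint8), scheme=PAIR8)
    scheme = blocks[0].scheme
    for b in blocks[1:]:
        if b.scheme.name != scheme.name:
            raise ValueError(
                f"cannot concatenate blocks with schemes "
                f"{scheme.name!r} and {b.scheme.name!r}"
            )
    if len(blocks) == 1:
        return blocks[0]
    symbols = np.concatenate([b.symbols for b in blocks])
    boundaries: list[int] = []
    offset = 0
    for i, b in enumerate(blocks):
        if i > 0:
            boundaries.append(offset)
        boundaries.extend(int(x) + offset for x in b.fixed_boundaries)
        offset += len(b)
    coords = None
    if all(b.coords is not None for b in blocks):
        coords = pd.concat([b.coords for b in blocks], ignore_index=True)
    return EncodedSequence(
        symbols=symbols,
        scheme=scheme,
        fixed_boundaries=np.asarray(boundaries, dtype=np.int64),
        coords=coords,
    )


def reverse_complement_check(columns, scheme: EncodingScheme | None = None) -> bool:
    """True iff encoding the columns equals encoding their complements —
    holds for every column set by scheme construction."""
    columns = [tuple(str(b).upper() for b in c) for c in columns]
    if scheme is None:
        arity = len(columns[0]) if columns else 2
        scheme = {1: GC2, 2: PAIR8, 3: TRIPLE32}[arity]
    comp = [
        tuple(COMPLEMENT.get(b, b) for b in col)  # gaps/ambiguity pass through
        for col in columns
    ]
    fwd = encode_columns(columns, scheme)
    rev = encode_columns(comp, scheme)
    return np.array_equal(fwd.symbols, rev.symbols)
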