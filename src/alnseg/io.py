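"""Alignment and interval I/O.

Readers wrap Biopython's AlignIO (MAF, aligned FASTA) and pandas (BED,
GFF3).  Coordinates are 0-based half-open throughout, BED-compatible;
GFF3 input is converted on read.  The encoded-sequence writer emits one
line of symbols per block (blocks are the chunks between fixed
boundaries) plus an optional sidecar TSV coordinate map, and the reader
inverts this exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .encoding import (
    EncodedSequence,
    EncodingScheme,
    GAP_CHARS,
    PAIR8,
    SCHEMES,
    TRIPLE32,
    encode_columns,
)


@dataclass
class AlignmentBlock:
    """One gapless-coordinate alignment block: equal-length rows, one per
    species, with species-1 (the reference, first row) genomic placement."""

    rows: list[str]
    species: list[str] = field(default_factory=list)
    chrom: str | None = None
    start: int = 0
    strand: str = "+"

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if not self.species:
            self.species = [f"species{i + 1}" for i in range(len(self.rows))]

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def columns(self):
        return list(zip(*self.rows))

    def ref_positions(self) -> np.ndarray:
        """Species-1 coordinate of each column; -1 where species 1 is gapped."""
        pos = np.full(self.ncol, -1, dtype=np.int64)
        p = self.start
        for i, b in enumerate(self.rows[0]):
            if b not in GAP_CHARS:
                pos[i] = p
                p += 1
        return pos

    def select_species(self, which: tuple[int, ...]) -> "AlignmentBlock":
        """Project onto a subset of rows (species 1 must stay first for
        coordinates to remain meaningful)."""
        return AlignmentBlock(
            rows=[self.rows[i] for i in which],
            species=[self.species[i] for i in which],
            chrom=self.chrom,
            start=self.start,
            strand=self.strand,
        )


def read_fasta_alignment(path, species: list[str] | None = None) -> AlignmentBlock:
    """Read an aligned FASTA (one record per species, equal lengths)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        bad = max(records, key=lambda r: len(r.seq))
        raise ValueError(
            f"ragged alignment in {path}: record {bad.id!r} has length "
            f"{len(bad.seq)}"
        )
    names = species or [r.id for r in records]
    return AlignmentBlock(rows=[str(r.seq).upper() for r in records], species=names)


def read_maf(path, species: list[str] | None = None) -> list[AlignmentBlock]:
    """Read a MAF file into a list of alignment blocks.

    Record ids of the form ``db.chrom`` give the chromosome; the first
    record of each block (or the first listed species) is the reference
    whose ``start`` is kept.
    """
    blocks = []
    for msa in AlignIO.parse(str(path), "maf"):
        recs = list(msa)
        if species:
            order = []
            for sp in species:
                match = [r for r in recs if r.id == sp or r.id.split(".")[0] == sp]
                if not match:
                    raise ValueError(f"species {sp!r} missing from MAF block")
                order.append(match[0])
            recs = order
        ref = recs[0]
        chrom = ref.id.split(".", 1)[1] if "." in ref.id else ref.id
        blocks.append(
            AlignmentBlock(
                rows=[str(r.seq).upper() for r in recs],
                species=[r.id for r in recs],
                chrom=chrom,
                start=int(ref.annotations.get("start", 0)),
                strand="+" if ref.annotations.get("strand", 1) in (1, "+") else "-",
            )
        )
    return blocks


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ into a DataFrame with 0-based half-open intervals."""
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#", dtype=str)
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = _BED_COLS[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def read_gff3(path, feature: str | None = None) -> pd.DataFrame:
    """Read GFF3 intervals, converting 1-based closed to 0-based half-open."""
    names = [
        "chrom", "source", "feature", "start", "end",
        "score", "strand", "frame", "attributes",
    ]
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#", names=names)
    if feature is not None:
        df = df[df["feature"] == feature].reset_index(drop=True)
    out = df[["chrom", "start", "end", "feature", "score", "strand"]].copy()
    out["start"] = out["start"].astype(np.int64) - 1
    out["end"] = out["end"].astype(np.int64)
    return out.rename(columns={"feature": "name"})


def slice_by_annotation(block: AlignmentBlock, intervals: pd.DataFrame) -> list[AlignmentBlock]:
    """Slice an alignment block into sub-blocks, one per interval, keeping
    the columns whose species-1 position falls in [start, end).

    Intervals extending beyond the aligned extent are clipped with a
    warning; intervals on other chromosomes yield empty blocks that are
    dropped.
    """
    ref_pos = block.ref_positions()
    covered = ref_pos >= 0
    lo = int(ref_pos[covered].min()) if covered.any() else block.start
    hi = int(ref_pos[covered].max()) + 1 if covered.any() else block.start
    out = []
    for row in intervals.itertuples(index=False):
        if block.chrom is not None and getattr(row, "chrom", block.chrom) != block.chrom:
            continue
        start, end = int(row.start), int(row.end)
        if start < lo or end > hi:
            warnings.warn(
                f"interval {getattr(row, 'chrom', '?')}:{start}-{end} extends "
                f"beyond alignment extent [{lo}, {hi}); clipping"
            )
            start, end = max(start, lo), min(end, hi)
        mask = (ref_pos >= start) & (ref_pos < end)
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        sub_rows = ["".join(r[i] for i in idx) for r in block.rows]
        out.append(
            AlignmentBlock(
                rows=sub_rows,
                species=list(block.species),
                chrom=block.chrom,
                start=int(ref_pos[idx[0]]),
                strand=block.strand,
            )
        )
    return out


def encode_block(
    block: AlignmentBlock,
    scheme: EncodingScheme | str = PAIR8,
    species: tuple[int, ...] | None = None,
) -> EncodedSequence:
    """Encode one alignment block, carrying species-1 coordinates through.

    For a pair scheme applied to a deeper alignment, ``species`` selects
    which two rows to project out (default: the first ``arity`` rows);
    columns gapped in either projected species are dropped by the encoder.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    if species is None:
        species = tuple(range(scheme.arity))
    if len(species) != scheme.arity:
        raise ValueError(
            f"scheme {scheme.name!r} needs {scheme.arity} species, got {len(species)}"
        )
    sub = block.select_species(species)
    return encode_columns(
        sub.columns(),
        scheme,
        chrom=block.chrom,
        positions=block.ref_positions(),
        strand=block.strand,
    )


def write_encoded(seq: EncodedSequence, path, coords_path=None) -> None:
    """Write symbols as plain text, one line per block (fixed boundaries
    become line breaks), with an optional sidecar coordinate TSV."""
    text = seq.text()
    cuts = [0, *map(int, seq.fixed_boundaries), len(seq)]
    with open(path, "w") as fh:
        for a, b in zip(cuts[:-1], cuts[1:]):
            fh.write(text[a:b] + "\n")
    if coords_path is not None:
        if seq.coords is None:
            raise ValueError("sequence has no coordinate map to write")
        df = seq.coords.copy()
        df.insert(0, "index", np.arange(len(df)))
        df.to_csv(coords_path, sep="\t", index=False)


def read_encoded(path, scheme: EncodingScheme | str, coords_path=None) -> EncodedSequence:
    """Inverse of :func:`write_encoded`."""
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    sym_index = {s: i for i, s in enumerate(scheme.alphabet)}
    codes: list[int] = []
    boundaries: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if codes:
                boundaries.append(len(codes))
            codes.extend(sym_index[c] for c in line)
    coords = None
    if coords_path is not None:
        coords = pd.read_csv(coords_path, sep="\t").drop(columns=["index"])
    return EncodedSequence(
        symbols=np.asarray(codes, dtype=np.uint8),
        scheme=scheme,
        fixed_boundaries=np.asarray(boundaries, dtype=np.int64),
        coords=coords,
    )
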