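"""Per-column conservation statistics and sequence-logo data.

Given a pre-computed ortholog alignment of the region surrounding a GC
center, this module computes per-column residue counts, Shannon entropy and
information content (IC), plus the per-letter stack heights used by logo
renderers:

    H_j  = - sum_a f_aj log2 f_aj            (over non-gap residues)
    e_n  = 19 / (2 ln 2 * n_j)               (small-sample correction)
    IC_j = max(0, log2 20 - H_j - e_n)
    height(a, j) = f_aj * IC_j

Gaps are excluded from the frequency denominator and reported separately as
a gap fraction, the convention of standard logo tools.  Alignment
computation itself is out of scope: input is aligned FASTA or Clustal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .pattern import ANY, CANONICAL_AA, ResiduePattern

GAP_CHARS = "-."
LOG2_20 = math.log2(20.0)


@dataclass(frozen=True)
class AlignmentBlock:
    """An in-memory multiple alignment: equal-length rows plus their ids."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no sequences")
        width = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(
                    f"ragged alignment: row {sid!r} has length {len(row)}, "
                    f"expected {width}"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, index: int) -> str:
        """Residues of a 1-based column."""
        return "".join(row[index - 1] for row in self.rows)


@dataclass(frozen=True)
class ColumnProfile:
    """Conservation statistics for one alignment column (1-based index)."""

    column: int
    counts: dict[str, int]
    gap_count: int
    frequencies: dict[str, float]
    entropy_bits: float
    small_sample_correction: float
    information_content: float
    stack_heights: dict[str, float]
    all_gap: bool = False

    @property
    def gap_fraction(self) -> float:
        total = self.gap_count + sum(self.counts.values())
        return self.gap_count / total if total else 0.0


def read_alignment(path: str | Path, format: str = "afa") -> AlignmentBlock:
    """Read a multiple alignment from aligned FASTA (``afa``) or ``clustal``.

    Rows are validated equal-length; sequence ids are preserved in file
    order.  Ragged input raises a ``ValueError`` naming the offending id.
    """
    fmt = {"afa": "fasta", "fasta": "fasta", "clustal": "clustal"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown alignment format {format!r}")
    if fmt == "fasta":
        # Read leniently so ragged rows can be reported by id.
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
    else:
        aln = AlignIO.read(str(path), fmt)
        ids = [rec.id for rec in aln]
        rows = [str(rec.seq).upper() for rec in aln]
    if not rows:
        raise ValueError(f"no sequences found in {path}")
    return AlignmentBlock(tuple(ids), tuple(rows))


def column_profiles(
    block: AlignmentBlock, correction: bool = True
) -> list[ColumnProfile]:
    """Compute a :class:`ColumnProfile` for every column of ``block``.

    ``correction`` toggles the small-sample entropy correction
    ``e_n = 19 / (2 ln2 n)`` (n = non-gap count in the column).  An all-gap
    column is flagged and reported with zero information content.
    """
    profiles: list[ColumnProfile] = []
    for col in range(1, block.n_columns + 1):
        residues = block.column(col).upper()
        counts: dict[str, int] = {}
        gap_count = 0
        for ch in residues:
            if ch in GAP_CHARS:
                gap_count += 1
            else:
                counts[ch] = counts.get(ch, 0) + 1
        n_nongap = sum(counts.values())
        if n_nongap == 0:
            profiles.append(
                ColumnProfile(col, {}, gap_count, {}, 0.0, 0.0, 0.0, {}, all_gap=True)
            )
            continue
        freqs = {aa: c / n_nongap for aa, c in counts.items()}
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        e_n = 19.0 / (2.0 * math.log(2.0) * n_nongap) if correction else 0.0
        ic = max(0.0, LOG2_20 - entropy - e_n)
        heights = {aa: f * ic for aa, f in freqs.items()}
        profiles.append(
            ColumnProfile(col, counts, gap_count, freqs, entropy, e_n, ic, heights)
        )
    return profiles


def profiles_table(profiles: Sequence[ColumnProfile]) -> pd.DataFrame:
    """Per-column summary table (counts, gap fraction, entropy, IC)."""
    rows = []
    for p in profiles:
        row = {
            "column": p.column,
            "n_nongap": sum(p.counts.values()),
            "gap_fraction": p.gap_fraction,
            "entropy_bits": p.entropy_bits,
            "small_sample_correction": p.small_sample_correction,
            "ic_bits": p.information_content,
            "all_gap": p.all_gap,
        }
        for aa in CANONICAL_AA:
            row[f"count_{aa}"] = p.counts.get(aa, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def stack_height_matrix(profiles: Sequence[ColumnProfile]) -> pd.DataFrame:
    """Columns x residues matrix of logo stack heights (bits).

    Consumable by standard logo renderers; each row sums to the column's
    information content.
    """
    data = np.zeros((len(profiles), len(CANONICAL_AA)))
    index = []
    for i, p in enumerate(profiles):
        index.append(p.column)
        for j, aa in enumerate(CANONICAL_AA):
            data[i, j] = p.stack_heights.get(aa, 0.0)
    return pd.DataFrame(data, index=pd.Index(index, name="column"), columns=list(CANONICAL_AA))


def center_conservation_report(
    block: AlignmentBlock,
    pattern: ResiduePattern,
    center_columns: dict[int, int],
) -> pd.DataFrame:
    """Fraction of sequences conforming to each motif position.

    ``center_columns`` maps each of the pattern's fixed positions (1-based,
    1..span) to a distinct alignment column.  A residue conforms when it
    satisfies the motif element governing that position; wildcard positions
    count every non-gap residue as conforming; gaps never conform.
    """
    span = pattern.fixed_span
    if span is None:
        raise ValueError("center conservation requires a fixed-span pattern")
    # Expand elements to per-position constraints.
    per_position = []
    for el in pattern.elements:
        per_position.extend([el] * el.min_repeat)
    if sorted(center_columns) != list(range(1, span + 1)):
        raise ValueError(f"center_columns must map positions 1..{span}")
    cols = list(center_columns.values())
    if len(set(cols)) != len(cols):
        raise ValueError("center_columns must map to distinct columns")
    for c in cols:
        if not 1 <= c <= block.n_columns:
            raise ValueError(f"column {c} outside alignment (1..{block.n_columns})")
    rows = []
    for pos in range(1, span + 1):
        col = center_columns[pos]
        el = per_position[pos - 1]
        residues = block.column(col).upper()
        if el.kind == ANY:
            conforming = sum(1 for ch in residues if ch not in GAP_CHARS)
        else:
            conforming = sum(
                1 for ch in residues if ch not in GAP_CHARS and el.matches(ch)
            )
        rows.append(
            {
                "motif_position": pos,
                "alignment_column": col,
                "n_conforming": conforming,
                "conforming_fraction": conforming / block.n_sequences,
            }
        )
    return pd.DataFrame(rows)
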