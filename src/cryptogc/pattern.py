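"""PROSITE-dialect motif parsing and protein-sequence scanning.

The central query of the package is the guanylate-cyclase (GC) diagnostic
motif ``[RKS]-[YFW]-[GCTH]-[VIL]-[FV]-x(3)-[VIL]-x(4)-[KR]``: a 14-residue
pattern whose positions 1, 3 and 14 carry the functionally assigned catalytic
residues of nucleotide cyclases.  This module parses that notation (and the
general PROSITE pattern dialect around it) and scans protein sequences for
every occurrence.

Coordinates are 1-based inclusive throughout, matching the residue-position
language used in the literature ("position 14" is the last residue of the
motif window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity / non-standard codes tolerated in input sequences.  They satisfy
#: wildcard positions but never certify membership of a residue class.
AMBIGUOUS_AA = "XBZU"
_ALLOWED = set(CANONICAL_AA) | set(AMBIGUOUS_AA)

#: Default name for the GC diagnostic motif used in reports.
GC_MOTIF = "[RKS]-[YFW]-[GCTH]-[VIL]-[FV]-x(3)-[VIL]-x(4)-[KR]"

CLASS = "class"
NOT_CLASS = "not_class"
ANY = "any"


class PatternSyntaxError(ValueError):
    """Raised when a motif string cannot be parsed; names the bad element."""


@dataclass(frozen=True)
class PatternElement:
    """One hyphen-separated element of a PROSITE pattern.

    ``kind`` is ``"class"`` (``[RKS]``), ``"not_class"`` (``{P}``) or
    ``"any"`` (``x``).  ``residues`` is the member set for class elements and
    ``None`` for wildcards.  ``min_repeat``/``max_repeat`` encode ``(n)`` and
    ``(n,m)`` suffixes; plain elements have both equal to 1.
    """

    kind: str
    residues: frozenset[str] | None
    min_repeat: int = 1
    max_repeat: int = 1

    @property
    def fixed(self) -> bool:
        return self.min_repeat == self.max_repeat

    def matches(self, residue: str) -> bool:
        """Whether a single residue satisfies one repeat of this element."""
        if self.kind == ANY:
            return residue in _ALLOWED
        if residue in AMBIGUOUS_AA:
            # An ambiguity code cannot certify (or rule out) class membership.
            return False
        if self.kind == CLASS:
            return residue in self.residues
        return residue not in self.residues


@dataclass(frozen=True)
class ResiduePattern:
    """A parsed PROSITE-dialect motif.

    Attributes
    ----------
    source_text : str
        The verbatim motif string.
    elements : tuple of PatternElement
        Ordered elements.
    n_anchored, c_anchored : bool
        Whether the pattern carries the ``<`` / ``>`` terminal anchors.
    """

    source_text: str
    elements: tuple[PatternElement, ...]
    n_anchored: bool = False
    c_anchored: bool = False

    @property
    def fixed_span(self) -> int | None:
        """Total residue span, or ``None`` when variable repeats make it so."""
        if any(not e.fixed for e in self.elements):
            return None
        return sum(e.min_repeat for e in self.elements)

    @property
    def min_span(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max_repeat for e in self.elements)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its FASTA identity."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - _ALLOWED
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residue letters {sorted(bad)}"
            )


@dataclass(frozen=True)
class MotifMatch:
    """A located motif occurrence; ``start``/``end`` are 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    matched_seq: str

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _parse_repeat(suffix: str, idx: int, token: str) -> tuple[int, int]:
    body = suffix[1:-1]
    parts = body.split(",")
    try:
        if len(parts) == 1:
            lo = hi = int(parts[0])
        elif len(parts) == 2:
            lo, hi = int(parts[0]), int(parts[1])
        else:
            raise ValueError
    except ValueError:
        raise PatternSyntaxError(
            f"element {idx}: malformed repeat {suffix!r} in {token!r}"
        ) from None
    if lo < 1 or lo > hi:
        raise PatternSyntaxError(
            f"element {idx}: repeat must satisfy 1 <= min <= max in {token!r}"
        )
    return lo, hi


def _check_residues(letters: str, idx: int, token: str) -> frozenset[str]:
    if not letters:
        raise PatternSyntaxError(f"element {idx}: empty residue class in {token!r}")
    bad = set(letters) - set(CANONICAL_AA)
    if bad:
        raise PatternSyntaxError(
            f"element {idx}: unknown residue letters {sorted(bad)} in {token!r}"
        )
    return frozenset(letters)


def parse_pattern(text: str) -> ResiduePattern:
    """Parse a PROSITE-dialect motif string into a :class:`ResiduePattern`.

    Supported dialect: hyphen-separated elements; ``[..]`` residue classes;
    ``{..}`` negated classes; ``x`` wildcards; single residue letters;
    optional ``(n)`` / ``(n,m)`` repeat suffixes on any element; the
    terminal anchors ``<`` and ``>``.  A trailing ``.`` (full PROSITE
    syntax) is tolerated.  Parsing is case-insensitive.

    >>> parse_pattern("[RKS]-[YFW]-[GCTH]-[VIL]-[FV]-x(3)-[VIL]-x(4)-[KR]").fixed_span
    14
    """
    if not isinstance(text, str) or not text.strip():
        raise PatternSyntaxError("empty motif string")
    work = text.strip().rstrip(".")
    n_anchored = work.startswith("<")
    if n_anchored:
        work = work[1:]
    c_anchored = work.endswith(">")
    if c_anchored:
        work = work[:-1]
    tokens = [t.strip() for t in work.split("-")]
    elements: list[PatternElement] = []
    for idx, token in enumerate(tokens, start=1):
        if not token:
            raise PatternSyntaxError(f"element {idx}: empty element in {text!r}")
        up = token.upper()
        lo, hi = 1, 1
        if up.endswith(")"):
            cut = up.rfind("(")
            if cut == -1:
                raise PatternSyntaxError(
                    f"element {idx}: unmatched ')' in {token!r}"
                )
            lo, hi = _parse_repeat(up[cut:], idx, token)
            up = up[:cut]
        if up.startswith("["):
            if not up.endswith("]"):
                raise PatternSyntaxError(
                    f"element {idx}: unterminated '[' in {token!r}"
                )
            residues = _check_residues(up[1:-1], idx, token)
            elements.append(PatternElement(CLASS, residues, lo, hi))
        elif up.startswith("{"):
            if not up.endswith("}"):
                raise PatternSyntaxError(
                    f"element {idx}: unterminated '{{' in {token!r}"
                )
            residues = _check_residues(up[1:-1], idx, token)
            if len(residues) >= len(CANONICAL_AA):
                raise PatternSyntaxError(
                    f"element {idx}: negated class excludes every residue"
                )
            elements.append(PatternElement(NOT_CLASS, residues, lo, hi))
        elif up == "X":
            elements.append(PatternElement(ANY, None, lo, hi))
        elif len(up) == 1 and up in CANONICAL_AA:
            elements.append(PatternElement(CLASS, frozenset(up), lo, hi))
        else:
            raise PatternSyntaxError(
                f"element {idx}: unrecognized element {token!r}"
            )
    return ResiduePattern(text, tuple(elements), n_anchored, c_anchored)


def _position_tables(pattern: ResiduePattern) -> np.ndarray:
    """Per-position byte lookup tables for a fixed-span pattern."""
    span = pattern.fixed_span
    assert span is not None
    tables = np.zeros((span, 256), dtype=bool)
    pos = 0
    for el in pattern.elements:
        allowed = np.zeros(256, dtype=bool)
        for aa in CANONICAL_AA:
            allowed[ord(aa)] = el.matches(aa)
        for aa in AMBIGUOUS_AA:
            allowed[ord(aa)] = el.matches(aa)
        for _ in range(el.min_repeat):
            tables[pos] = allowed
            pos += 1
    return tables


def _scan_fixed(pattern: ResiduePattern, seq_upper: str) -> list[tuple[int, int]]:
    span = pattern.fixed_span
    n = len(seq_upper)
    if n < span:
        return []
    arr = np.frombuffer(seq_upper.encode("ascii"), dtype=np.uint8)
    tables = _position_tables(pattern)
    ok = np.ones(n - span + 1, dtype=bool)
    for off in range(span):
        ok &= tables[off][arr[off : off + n - span + 1]]
    starts = np.flatnonzero(ok)
    return [(int(s), int(s) + span) for s in starts]


def _match_from(
    elements: Sequence[PatternElement], seq: str, pos: int, ei: int
) -> int | None:
    """Greedy backtracking match; returns the end offset (exclusive) or None."""
    if ei == len(elements):
        return pos
    el = elements[ei]
    # Count how many repeats are satisfiable from pos.
    max_here = 0
    while (
        max_here < el.max_repeat
        and pos + max_here < len(seq)
        and el.matches(seq[pos + max_here])
    ):
        max_here += 1
    for take in range(max_here, el.min_repeat - 1, -1):
        end = _match_from(elements, seq, pos + take, ei + 1)
        if end is not None:
            return end
    return None


def scan_sequence(pattern: ResiduePattern, record: ProteinRecord) -> list[MotifMatch]:
    """Find every occurrence of ``pattern`` in ``record``.

    All match start positions are reported (overlaps allowed), sorted by
    start; one match per start (the longest, for variable-span patterns).
    Matching is case-insensitive; ambiguity codes X/B/Z/U satisfy wildcard
    positions but never a residue class.
    """
    seq = record.sequence
    seq_upper = seq.upper()
    spans: list[tuple[int, int]]
    if pattern.fixed_span is not None and not pattern.n_anchored and not pattern.c_anchored:
        spans = _scan_fixed(pattern, seq_upper)
    else:
        starts: Iterable[int]
        if pattern.n_anchored:
            starts = (0,)
        else:
            starts = range(len(seq_upper) - pattern.min_span + 1)
        spans = []
        for s in starts:
            end = _match_from(pattern.elements, seq_upper, s, 0)
            if end is None:
                continue
            if pattern.c_anchored:
                # Retry demanding the match consume the full tail.
                if end != len(seq_upper):
                    end = _anchored_tail(pattern.elements, seq_upper, s)
                    if end is None:
                        continue
            spans.append((s, end))
    return [
        MotifMatch(record.id, s + 1, e, seq[s:e]) for s, e in spans
    ]


def _anchored_tail(
    elements: Sequence[PatternElement], seq: str, start: int
) -> int | None:
    """Match requiring consumption up to the sequence end (C-terminal anchor)."""

    def rec(pos: int, ei: int) -> int | None:
        if ei == len(elements):
            return pos if pos == len(seq) else None
        el = elements[ei]
        max_here = 0
        while (
            max_here < el.max_repeat
            and pos + max_here < len(seq)
            and el.matches(seq[pos + max_here])
        ):
            max_here += 1
        for take in range(max_here, el.min_repeat - 1, -1):
            out = rec(pos + take, ei + 1)
            if out is not None:
                return out
        return None

    return rec(start, 0)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Load protein records from a FASTA file.

    Stop codons ``*`` and gap characters ``-``/``.`` are stripped with a
    logged warning.  An unreadable or empty file raises ``OSError`` /
    ``ValueError``.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        cleaned = seq.replace("*", "").replace("-", "").replace(".", "")
        if cleaned != seq:
            logger.warning(
                "protein %s: stripped %d stop/gap characters on load",
                rec.id,
                len(seq) - len(cleaned),
            )
        records.append(ProteinRecord(rec.id, rec.description, cleaned))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def scan_fasta(
    fasta_path: str | Path,
    pattern: ResiduePattern,
    pattern_name: str = "GC_diagnostic",
) -> pd.DataFrame:
    """Scan every record of a FASTA file; one row per match.

    Rows are ordered by file order then match start.  Columns:
    ``protein_id, start, end, matched_seq, pattern_name``.
    """
    rows = []
    for record in read_fasta(fasta_path):
        for m in scan_sequence(pattern, record):
            rows.append(
                {
                    "protein_id": m.protein_id,
                    "start": m.start,
                    "end": m.end,
                    "matched_seq": m.matched_seq,
                    "pattern_name": pattern_name,
                }
            )
    return pd.DataFrame(
        rows, columns=["protein_id", "start", "end", "matched_seq", "pattern_name"]
    )


def match_probability(
    pattern: ResiduePattern,
    background: Mapping[str, float] | Sequence[float],
) -> float:
    """Per-start-position probability of a match under an i.i.d. background.

    ``background`` maps the 20 canonical residues to frequencies (or is a
    vector in :data:`CANONICAL_AA` order) summing to 1.  Each class position
    contributes the summed frequency of its members, each negated class the
    complement, and each wildcard position 1.  Only fixed-span patterns are
    supported (the quantity is otherwise not per-position).
    """
    if pattern.fixed_span is None:
        raise ValueError("match_probability requires a fixed-span pattern")
    if isinstance(background, Mapping):
        freqs = {aa.upper(): float(v) for aa, v in background.items()}
    else:
        vec = list(background)
        if len(vec) != len(CANONICAL_AA):
            raise ValueError("background vector must have 20 entries")
        freqs = dict(zip(CANONICAL_AA, map(float, vec)))
    total = sum(freqs.get(aa, 0.0) for aa in CANONICAL_AA)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"background frequencies sum to {total}, not 1")
    prob = 1.0
    for el in pattern.elements:
        if el.kind == ANY:
            contrib = 1.0
        elif el.kind == CLASS:
            contrib = sum(freqs.get(aa, 0.0) for aa in el.residues)
        else:
            contrib = 1.0 - sum(freqs.get(aa, 0.0) for aa in el.residues)
        prob *= contrib**el.min_repeat
    return prob


#: Uniform background over the canonical residues, for quick estimates.
UNIFORM_BACKGROUND = {aa: 1.0 / 20.0 for aa in CANONICAL_AA}
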