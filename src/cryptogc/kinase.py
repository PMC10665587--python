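"""Kinase-domain context classification for GC-center hits.

A crypto (moonlighting) GC is a catalytic center embedded inside a kinase
domain.  Rather than full domain calling, this module looks for the three
classic protein-kinase anchor motifs near a hit:

* the glycine-rich phosphate-binding **G-loop** (``G-x-G-x-x-[GSA]``),
* the β3-strand **VAIK** lysine motif (``[VAIL]-A-[ILVF]-K``),
* the catalytic-loop **HRD** triad (``H-R-D``).

A hit is called embedded when at least two distinct anchor types occur
within a configurable window around it.  The anchor patterns, threshold
and window are all overridable; reports record the patterns used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .pattern import MotifMatch, ProteinRecord, ResiduePattern, parse_pattern, scan_sequence

DEFAULT_ANCHOR_PATTERNS: dict[str, str] = {
    "G-loop": "G-x-G-x-x-[GSA]",
    "VAIK": "[VAIL]-[A]-[ILVF]-K",
    "HRD": "H-R-D",
}

#: Half-width (residues) of the region searched around a center.  Kinase
#: domains span ~250-300 residues, so +/-150 from the center covers the
#: N-lobe G-loop/VAIK and the catalytic loop wherever the center sits.
DEFAULT_WINDOW = 150

#: Minimum number of distinct anchor types required to call a hit embedded.
DEFAULT_MIN_ANCHORS = 2


@dataclass(frozen=True)
class AnchorHit:
    anchor_name: str
    start: int  # 1-based inclusive
    end: int
    matched_seq: str


@dataclass
class KinaseAnchorSet:
    """Anchor patterns in force plus every anchor occurrence in a region."""

    patterns: dict[str, ResiduePattern]
    region: tuple[int, int]  # 1-based inclusive interval searched
    found_anchors: list[AnchorHit] = field(default_factory=list)

    @property
    def anchor_types_found(self) -> set[str]:
        return {a.anchor_name for a in self.found_anchors}


@dataclass(frozen=True)
class ContextClassification:
    """Embedded-in-kinase verdict for one GC-center hit."""

    protein_id: str
    center_start: int
    embedded_in_kinase: bool
    anchors_found: tuple[str, ...]
    distances: dict[str, int]  # anchor name -> signed offset (anchor - center)
    window: int


def compile_anchor_patterns(
    patterns: dict[str, str] | None = None,
) -> dict[str, ResiduePattern]:
    """Parse anchor motif strings (defaults: G-loop, VAIK, HRD)."""
    source = patterns if patterns is not None else DEFAULT_ANCHOR_PATTERNS
    return {name: parse_pattern(text) for name, text in source.items()}


def locate_kinase_anchors(
    record: ProteinRecord,
    region: tuple[int, int],
    patterns: dict[str, ResiduePattern] | None = None,
) -> KinaseAnchorSet:
    """Find all kinase anchor motifs inside ``region`` (1-based inclusive).

    The interval is clipped to the protein; an inverted interval raises.
    Every anchor occurrence is reported, tagged with its anchor name and
    absolute coordinates in the protein.
    """
    lo, hi = region
    if lo > hi:
        raise ValueError(f"inverted interval ({lo}, {hi})")
    lo = max(1, lo)
    hi = min(len(record.sequence), hi)
    compiled = patterns if patterns is not None else compile_anchor_patterns()
    if lo > hi:  # region falls entirely outside the protein
        return KinaseAnchorSet(compiled, (lo, hi), [])
    sub = ProteinRecord(record.id, record.description, record.sequence[lo - 1 : hi])
    found: list[AnchorHit] = []
    for name, pat in compiled.items():
        for m in scan_sequence(pat, sub):
            found.append(
                AnchorHit(name, m.start + lo - 1, m.end + lo - 1, m.matched_seq)
            )
    found.sort(key=lambda a: (a.start, a.anchor_name))
    return KinaseAnchorSet(compiled, (lo, hi), found)


def classify_context(
    match: MotifMatch,
    anchors: KinaseAnchorSet,
    window: int = DEFAULT_WINDOW,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
) -> ContextClassification:
    """Call a center embedded when >= ``min_anchors`` distinct anchor types
    lie within ``window`` residues of it.

    ``distances`` reports, per anchor type found, the signed offset from the
    center start to the nearest occurrence's start (negative = upstream).
    """
    in_window: dict[str, int] = {}
    for hit in anchors.found_anchors:
        if hit.start < match.start - window or hit.start > match.end + window:
            continue
        offset = hit.start - match.start
        prev = in_window.get(hit.anchor_name)
        if prev is None or abs(offset) < abs(prev):
            in_window[hit.anchor_name] = offset
    names = tuple(sorted(in_window))
    return ContextClassification(
        protein_id=match.protein_id,
        center_start=match.start,
        embedded_in_kinase=len(names) >= min_anchors,
        anchors_found=names,
        distances=dict(in_window),
        window=window,
    )


def classify_match(
    record: ProteinRecord,
    match: MotifMatch,
    window: int = DEFAULT_WINDOW,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    patterns: dict[str, ResiduePattern] | None = None,
) -> ContextClassification:
    """Convenience wrapper: locate anchors around ``match`` then classify."""
    region = (match.start - window, match.end + window)
    anchors = locate_kinase_anchors(record, region, patterns)
    return classify_context(match, anchors, window, min_anchors)
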