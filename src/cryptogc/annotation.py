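"""Functional annotation of guanylate-cyclase center matches.

Within the 14-residue GC diagnostic window three positions carry assigned
catalytic roles: position 1 hydrogen-bonds the guanine moiety of the GTP
substrate, position 3 confers substrate specificity (guanine vs adenine),
and the positively charged position 14 stabilizes the transition from GTP
to cGMP.  This module projects those assignments onto a located match.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pattern import MotifMatch

GC_SPAN = 14

POS1_ROLE = "hydrogen bond with guanine moiety"
POS3_ROLE = "substrate specificity"
POS14_ROLE = "transition-state stabilization"

#: Canonical receptor and soluble GC catalytic centers catalogued in humans
#: all open with this pentapeptide; the label is descriptive only.
CANONICAL_PREFIX = "RYCLF"

CANONICAL_CYCLASE_LIKE = "canonical_cyclase_like"
KINASE_EMBEDDED_LIKE = "kinase_embedded_like"
OTHER = "other"

_POS1_ALLOWED = set("RKS")
_POS3_ALLOWED = set("GCTH")
_POS14_ALLOWED = set("KR")


@dataclass(frozen=True)
class GcCenterAnnotation:
    """The functional triad of a GC-center match plus a descriptive class."""

    match: MotifMatch
    pos1_residue: str
    pos3_residue: str
    pos14_residue: str
    center_class: str
    pos1_role: str = POS1_ROLE
    pos3_role: str = POS3_ROLE
    pos14_role: str = POS14_ROLE


def annotate_center(match: MotifMatch) -> GcCenterAnnotation:
    """Extract the functional triad (positions 1, 3, 14) of a GC-center match.

    The match must span exactly 14 residues and satisfy the diagnostic
    motif's class constraints at the triad positions.  ``center_class`` is
    ``canonical_cyclase_like`` when the center opens with ``RYCLF`` (shared
    by the catalogued receptor and soluble GCs), otherwise ``other``; the
    kinase-context stage upgrades embedded hits to ``kinase_embedded_like``.
    """
    if match.span != GC_SPAN:
        raise ValueError(
            f"GC-center annotation requires a {GC_SPAN}-residue match, "
            f"got span {match.span}"
        )
    seq = match.matched_seq.upper()
    pos1, pos3, pos14 = seq[0], seq[2], seq[13]
    if pos1 not in _POS1_ALLOWED:
        raise ValueError(f"position 1 residue {pos1!r} outside class [RKS]")
    if pos3 not in _POS3_ALLOWED:
        raise ValueError(f"position 3 residue {pos3!r} outside class [GCTH]")
    if pos14 not in _POS14_ALLOWED:
        raise ValueError(f"position 14 residue {pos14!r} outside class [KR]")
    center_class = CANONICAL_CYCLASE_LIKE if seq.startswith(CANONICAL_PREFIX) else OTHER
    return GcCenterAnnotation(match, pos1, pos3, pos14, center_class)
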