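"""cryptogc: discovery and characterization of crypto guanylate-cyclase
centers moonlighting inside kinase domains.

The pipeline scans proteomes with the 14-residue GC diagnostic motif,
annotates each hit's catalytic triad, decides whether the hit is embedded
in a kinase domain via the G-loop/VAIK/HRD anchor motifs, quantifies
per-column conservation of the center across ortholog alignments, and
analyzes reporter and EIA activity assays (exact Wilcoxon signed-rank;
ANOVA with Tukey-Kramer comparisons).
"""

from importlib import resources

from .annotation import GcCenterAnnotation, annotate_center
from .conservation import (
    AlignmentBlock,
    ColumnProfile,
    center_conservation_report,
    column_profiles,
    profiles_table,
    read_alignment,
    stack_height_matrix,
)
from .kinase import (
    ContextClassification,
    KinaseAnchorSet,
    classify_context,
    classify_match,
    compile_anchor_patterns,
    locate_kinase_anchors,
)
from .pattern import (
    GC_MOTIF,
    MotifMatch,
    PatternSyntaxError,
    ProteinRecord,
    ResiduePattern,
    match_probability,
    parse_pattern,
    read_fasta,
    scan_fasta,
    scan_sequence,
)
from .simulate import (
    SyntheticAssaySpec,
    SyntheticProteomeSpec,
    generate_assay,
    generate_ortholog_family,
    generate_proteome,
    write_fasta,
)
from .stats import (
    AnovaTukeyResult,
    ReporterAssay,
    WilcoxonResult,
    normalize_reporter,
    one_way_anova,
    tukey_kramer,
    wilcoxon_exact,
)

__version__ = "0.1.0"


def table1_centers_path():
    """Path to the packaged FASTA of the 18 predicted human GC centers."""
    return resources.files("cryptogc").joinpath("data/table1_centers.fasta")


__all__ = [
    "GC_MOTIF",
    "AlignmentBlock",
    "AnovaTukeyResult",
    "ColumnProfile",
    "ContextClassification",
    "GcCenterAnnotation",
    "KinaseAnchorSet",
    "MotifMatch",
    "PatternSyntaxError",
    "ProteinRecord",
    "ReporterAssay",
    "ResiduePattern",
    "SyntheticAssaySpec",
    "SyntheticProteomeSpec",
    "WilcoxonResult",
    "annotate_center",
    "center_conservation_report",
    "classify_context",
    "classify_match",
    "column_profiles",
    "compile_anchor_patterns",
    "generate_assay",
    "generate_ortholog_family",
    "generate_proteome",
    "locate_kinase_anchors",
    "match_probability",
    "normalize_reporter",
    "one_way_anova",
    "parse_pattern",
    "profiles_table",
    "read_alignment",
    "read_fasta",
    "scan_fasta",
    "scan_sequence",
    "stack_height_matrix",
    "table1_centers_path",
    "tukey_kramer",
    "wilcoxon_exact",
    "write_fasta",
]
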