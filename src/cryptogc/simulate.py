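"""Seeded synthetic data with the structure each pipeline stage assumes.

Three generators are provided, each a pure function of its spec and seed
(identical seeds give byte-identical output):

* :func:`generate_proteome` — random proteomes with GC-motif centers
  planted either inside a kinase-like scaffold (all three anchor motifs
  within the context window) or in plain random background, plus a
  plant-truth table;
* :func:`generate_ortholog_family` — an ortholog-family alignment with
  invariant center columns and independently mutated flanks, emulating the
  deep vertebrate ortholog alignments used for sequence logos;
* :func:`generate_assay` — a reporter screen (induced vs control
  luminescence/OD pairs) and an EIA table (cGMP per cofactor group).

All randomness flows from the single spec seed through NumPy's
``SeedSequence``/``default_rng`` (PCG64), with one spawned child stream per
emitted table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .conservation import AlignmentBlock
from .kinase import DEFAULT_ANCHOR_PATTERNS, DEFAULT_WINDOW, compile_anchor_patterns
from .pattern import (
    ANY,
    CANONICAL_AA,
    CLASS,
    GC_MOTIF,
    ProteinRecord,
    ResiduePattern,
    parse_pattern,
    scan_sequence,
)

_AA = np.array(list(CANONICAL_AA))


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Study conditions for a planted-motif proteome benchmark."""

    n_proteins: int = 200
    length_min: int = 400
    length_max: int = 800
    background: tuple[float, ...] = tuple([1.0 / 20.0] * 20)
    n_embedded_plants: int = 100
    n_background_plants: int = 100
    motif: str = GC_MOTIF
    anchor_patterns: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ANCHOR_PATTERNS)
    )
    window: int = DEFAULT_WINDOW
    clean_background: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_embedded_plants + self.n_background_plants > self.n_proteins:
            raise ValueError("more plants than proteins")
        pat = parse_pattern(self.motif)
        span = pat.fixed_span
        if span is None:
            raise ValueError("planted motif must have a fixed span")
        if self.length_min < span + 2 * self.window:
            raise ValueError(
                f"length_min={self.length_min} too small for span {span} "
                f"plus 2x window {self.window}"
            )
        if self.length_min > self.length_max:
            raise ValueError("length_min > length_max")
        if abs(sum(self.background) - 1.0) > 1e-9 or len(self.background) != 20:
            raise ValueError("background must be 20 frequencies summing to 1")


@dataclass(frozen=True)
class SyntheticAssaySpec:
    """Study conditions for the reporter screen and EIA quantification.

    Defaults mirror the assay design: two transformants with n = 8
    biological replicates each in the reporter screen, and triplicate EIA
    measurements per cofactor condition with a strong Mn2+ preference
    (Mn2+ mean exceeding the Mg2+ mean by over 100 fmol cGMP per ug).
    """

    transformants: tuple[str, ...] = ("NTRK1", "PSKR1")
    n_replicates: int = 8
    fold_change: float = 3.0
    reporter_noise_sd: float = 0.1  # lognormal sigma on luminescence
    eia_group_means: dict[str, float] = field(
        default_factory=lambda: {"Mn2+": 120.0, "Mg2+": 10.0, "no_protein": 2.0}
    )
    eia_noise_sd: float = 5.0
    eia_n_per_group: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1 or self.eia_n_per_group < 2:
            raise ValueError("need >=1 reporter replicate and >=2 EIA replicates")
        if self.fold_change <= 0 or self.reporter_noise_sd <= 0:
            raise ValueError("fold change and noise sd must be positive")
        if any(m <= 0 for m in self.eia_group_means.values()) or self.eia_noise_sd <= 0:
            raise ValueError("EIA means and sd must be positive")


def _sample_background(rng: np.random.Generator, n: int, probs: Sequence[float]) -> np.ndarray:
    return rng.choice(_AA, size=n, p=np.asarray(probs))


def sample_pattern_instance(
    pattern: ResiduePattern, rng: np.random.Generator, background: Sequence[float]
) -> str:
    """Draw one fixed-span sequence satisfying ``pattern``: uniform within
    each residue class, background-distributed at wildcard positions."""
    if pattern.fixed_span is None:
        raise ValueError("can only sample instances of fixed-span patterns")
    out: list[str] = []
    for el in pattern.elements:
        for _ in range(el.min_repeat):
            if el.kind == ANY:
                out.append(str(rng.choice(_AA, p=np.asarray(background))))
            elif el.kind == CLASS:
                out.append(str(rng.choice(sorted(el.residues))))
            else:
                allowed = sorted(set(CANONICAL_AA) - el.residues)
                out.append(str(rng.choice(allowed)))
    return "".join(out)


def _count_anchor_types_near(
    record: ProteinRecord,
    center_start: int,
    center_end: int,
    compiled: dict[str, ResiduePattern],
    window: int,
) -> int:
    types = 0
    for pat in compiled.values():
        hit = any(
            center_start - window <= m.start <= center_end + window
            for m in scan_sequence(pat, record)
        )
        types += int(hit)
    return types


def generate_proteome(
    spec: SyntheticProteomeSpec,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a proteome with planted GC centers plus its truth table.

    Proteins come in three kinds: *embedded* plants (center plus one
    instance of each kinase anchor within the window), *background* plants
    (center in plain random sequence), and pure background.  With
    ``clean_background`` (the default) sequences are redrawn until chance
    alone produces no unplanned motif hit and no spurious kinase context
    around a background plant, so the truth table is exhaustive; switch it
    off to measure spontaneous hit rates.

    Returns ``(records, truth)`` where truth has one row per protein:
    ``protein_id, kind, center_start, embedded, gloop_start, vaik_start,
    hrd_start``.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    motif = parse_pattern(spec.motif)
    span = motif.fixed_span
    compiled = compile_anchor_patterns(spec.anchor_patterns)
    kinds = (
        ["embedded"] * spec.n_embedded_plants
        + ["background_plant"] * spec.n_background_plants
        + ["background"]
        * (spec.n_proteins - spec.n_embedded_plants - spec.n_background_plants)
    )
    records: list[ProteinRecord] = []
    truth_rows = []
    for i, kind in enumerate(kinds):
        pid = f"SYN{i + 1:05d}_{kind}"
        for _attempt in range(1000):
            length = int(rng.integers(spec.length_min, spec.length_max + 1))
            seq = _sample_background(rng, length, spec.background)
            row: dict[str, object] = {
                "protein_id": pid,
                "kind": kind,
                "center_start": pd.NA,
                "embedded": False,
                "gloop_start": pd.NA,
                "vaik_start": pd.NA,
                "hrd_start": pd.NA,
            }
            if kind != "background":
                center = sample_pattern_instance(motif, rng, spec.background)
                # Leave room for the window on both sides.
                cstart = int(
                    rng.integers(spec.window + 1, length - span - spec.window + 2)
                )
                seq[cstart - 1 : cstart - 1 + span] = list(center)
                row["center_start"] = cstart
            if kind == "embedded":
                row["embedded"] = True
                offsets = {
                    "G-loop": int(rng.integers(-140, -90)),
                    "VAIK": int(rng.integers(-85, -40)),
                    "HRD": int(rng.integers(20, 80)),
                }
                for name, off in offsets.items():
                    inst = sample_pattern_instance(
                        compiled[name], rng, spec.background
                    )
                    astart = cstart + off
                    seq[astart - 1 : astart - 1 + len(inst)] = list(inst)
                    key = {"G-loop": "gloop_start", "VAIK": "vaik_start", "HRD": "hrd_start"}[name]
                    row[key] = astart
            record = ProteinRecord(pid, pid, "".join(seq))
            if not spec.clean_background:
                break
            hits = scan_sequence(motif, record)
            hit_starts = {m.start for m in hits}
            expected = {row["center_start"]} if kind != "background" else set()
            expected = {s for s in expected if s is not pd.NA}
            if hit_starts != expected:
                continue  # spontaneous motif occurrence: redraw
            if kind == "background_plant":
                n_types = _count_anchor_types_near(
                    record, cstart, cstart + span - 1, compiled, spec.window
                )
                if n_types >= 2:
                    continue  # chance kinase context: redraw
            break
        else:
            raise RuntimeError(f"could not realize protein {pid} under spec")
        records.append(record)
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return records, truth


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (deterministic byte layout)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def generate_ortholog_family(
    reference_center: str,
    n_sequences: int = 217,
    flank_length: int = 20,
    substitution_rate: float = 0.5,
    conserved_columns: Sequence[int] | None = None,
    background: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[AlignmentBlock, dict]:
    """Simulate an ortholog-family alignment around a GC center.

    The reference row is ``flank + reference_center + flank`` with flanks
    drawn from the background.  Center columns (or an explicit
    ``conserved_columns`` set) are invariant across the family; every other
    column is mutated independently per sequence at ``substitution_rate``
    (replacement drawn from the background, so a "mutation" may silently
    restore the original residue).

    Returns the alignment plus a truth dict with the reference row and the
    1-based ``center_columns`` mapping motif positions to columns.
    """
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution_rate must lie in [0, 1]")
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    probs = np.asarray(background if background is not None else [1 / 20] * 20)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    center = reference_center.upper()
    left = "".join(_sample_background(rng, flank_length, probs))
    right = "".join(_sample_background(rng, flank_length, probs))
    reference = left + center + right
    n_cols = len(reference)
    center_cols = list(range(flank_length + 1, flank_length + len(center) + 1))
    conserved = set(conserved_columns) if conserved_columns is not None else set(center_cols)
    if any(c < 1 or c > n_cols for c in conserved):
        raise ValueError("conserved columns outside alignment")
    ref_arr = np.array(list(reference))
    mutable = np.array([c - 1 for c in range(1, n_cols + 1) if c not in conserved], dtype=int)
    rows = []
    for _ in range(n_sequences):
        row = ref_arr.copy()
        if mutable.size:
            mask = rng.random(mutable.size) < substitution_rate
            idx = mutable[mask]
            row[idx] = _sample_background(rng, idx.size, probs)
        rows.append("".join(row))
    ids = tuple(f"ortholog_{i + 1:03d}" for i in range(n_sequences))
    block = AlignmentBlock(ids, tuple(rows))
    truth = {
        "reference": reference,
        "center_columns": {pos: col for pos, col in enumerate(center_cols, start=1)},
        "conserved_columns": sorted(conserved),
    }
    return block, truth


def generate_assay(
    spec: SyntheticAssaySpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a reporter-screen table, an EIA table and their truth.

    Reporter: per transformant and replicate, a control culture with
    baseline luminescence/OD and an induced culture whose OD-normalized
    luminescence is ``fold_change`` times the control's up to lognormal
    noise — so with fold change well above the noise sd every induced
    ratio exceeds 1.  EIA: per cofactor group, normal draws at the declared
    mean (fmol cGMP per ug protein).
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    rep_rng, eia_rng = (np.random.default_rng(s) for s in root.spawn(2))
    rows = []
    for transformant in spec.transformants:
        for rep in range(1, spec.n_replicates + 1):
            control_od = float(rep_rng.uniform(0.4, 0.6))
            induced_od = float(rep_rng.uniform(0.4, 0.6))
            base = 1000.0 * float(
                rep_rng.lognormal(mean=0.0, sigma=spec.reporter_noise_sd)
            )
            noise = float(rep_rng.lognormal(mean=0.0, sigma=spec.reporter_noise_sd))
            control_lum = base * control_od
            induced_lum = spec.fold_change * noise * base * induced_od
            rows.append((transformant, f"r{rep}", "control", control_lum, control_od))
            rows.append((transformant, f"r{rep}", "induced", induced_lum, induced_od))
    reporter = pd.DataFrame(
        rows, columns=["transformant", "replicate", "condition", "luminescence", "od600"]
    )
    eia_rows = []
    for group, mean in spec.eia_group_means.items():
        draws = eia_rng.normal(mean, spec.eia_noise_sd, size=spec.eia_n_per_group)
        for rep, val in enumerate(draws, start=1):
            eia_rows.append((group, f"r{rep}", float(val)))
    eia = pd.DataFrame(eia_rows, columns=["condition", "replicate", "cgmp_fmol_per_ug"])
    truth = {
        "fold_change": spec.fold_change,
        "eia_group_means": dict(spec.eia_group_means),
    }
    return reporter, eia, truth
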