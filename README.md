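# cryptogc

Tools for discovering and characterizing **crypto (moonlighting) guanylate
cyclases** — low-activity GC catalytic centers hidden inside kinase domains.
Canonical guanylate cyclases convert GTP to the second messenger cGMP; a
growing class of receptor kinases (the plant phytosulfokine receptor PSKR1,
human IRAK3, and the neurotrophic receptor tyrosine kinase NTRK1/TrkA) carry
a functional GC center embedded in their kinase domain.  `cryptogc` is aimed
at sequence analysts who want to scan proteomes for such centers,
contextualize and rank the hits, and analyze the activity assays used to
validate them.

## What it computes

**Motif scanning.**  Candidate centers are found with the 14-position GC
diagnostic motif, written in PROSITE notation:

```
[RKS]-[YFW]-[GCTH]-[VIL]-[FV]-x(3)-[VIL]-x(4)-[KR]
```

Position 1 hydrogen-bonds the guanine moiety of GTP, position 3 confers
substrate (guanine vs adenine) specificity, and the basic residue at
position 14 stabilizes the GTP→cGMP transition state.  The scanner reports
every occurrence with 1-based inclusive coordinates.

**Kinase context.**  A hit is called *embedded in a kinase domain* when at
least two of the three classic kinase anchor motifs — the glycine-rich
G-loop (`G-x-G-x-x-[GSA]`), the β3 VAIK lysine motif (`[VAIL]-A-[ILVF]-K`)
and the catalytic-loop HRD triad — occur within ±150 residues of the
center (patterns, threshold and window all configurable).

**Conservation logos.**  For a pre-computed ortholog alignment of the
region around a center, per-column information content is computed as
`IC_j = max(0, log2 20 − H_j − e_n)` with Shannon entropy `H_j` over
non-gap residues and the small-sample correction `e_n = 19/(2 ln2 · n)`,
plus the per-letter stack heights (`f_aj · IC_j`) consumed by logo
renderers, and the fraction of sequences conforming to each motif position.

**Assay statistics.**  Reporter-screen luminescence is normalized to OD600
and to each transformant's uninduced control; the one-sample **exact
Wilcoxon signed-rank test** (null enumerated over all 2^n sign
assignments) tests the ratios against 1.  In-vitro cGMP quantities per
cofactor group are compared by one-way ANOVA followed by the
**Tukey–Kramer** studentized-range test.

A seeded synthetic-data module generates proteomes with planted centers
(embedded or background), ortholog families with conserved center columns,
and assay tables — each with a ground-truth table, so every pipeline stage
is testable closed-loop.

## Worked example

The package ships a FASTA of the 18 predicted human GC-center sequences
(`cryptogc.table1_centers_path()`).  Scanning it:

```
$ cryptogc scan --fasta src/cryptogc/data/table1_centers.fasta --out scan_out
scanned 18 proteins: 18 candidate proteins, 18 motif matches
```

Every catalogued center — e.g. NTRK1's `SFGVVlweIftygK` (triad S/G/K) and
the natriuretic peptide receptor's `RYCLFgdtVntasR` (triad R/C/R) — is a
full-length motif match; `scan_out/candidates.tsv` lists coordinates,
triads and kinase context per hit.

Simulated assays, analyzed end to end:

```
$ cryptogc simulate --kind assay --seed 4 --out sim
$ cryptogc stats --reporter sim/reporter.tsv --eia sim/eia.tsv --out stats_out
```

prints (abridged) for the NTRK1 reporter arm:

```
"NTRK1": {"n": 8, "W_plus": 36.0, "p_value": 0.0078125, "exact_null": true}
```

— with all 8 induced/control ratios above 1, the positive-rank sum takes
its maximal value 36 and the exact two-sided p is 2/2⁸ = 0.0078125
(reported as P = 0.0078).  The EIA arm gives F = 749.2 (p = 6.3e−08) with
Tukey–Kramer calling Mn²⁺ vs Mg²⁺ significant (mean difference
117.1 fmol cGMP/µg, adjusted p = 1.5e−07) and Mg²⁺ vs no-protein not
significant (adjusted p = 0.093) — the Mn²⁺-preference structure the
generator plants.

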