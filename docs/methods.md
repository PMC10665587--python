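# Methods

## Motif model and scanner

The scanner implements the PROSITE pattern dialect needed for GC-center
and kinase-anchor motifs: residue classes `[..]`, negated classes `{..}`,
wildcards `x` with `(n)`/`(n,m)` repeats, single-letter elements, and the
terminal anchors `<`/`>` (parsed and honored, though no default motif uses
them).  Full PROSITE profiles (PSSMs) and nucleotide patterns are out of
scope.

Matching semantics, chosen where the notation itself is silent:

* **Coordinates** are 1-based inclusive in every report, matching the
  field's residue-position language ("position 14").
* **All overlapping matches** are reported, one per start position;
  completeness is the safer default for a discovery screen.  For
  variable-span patterns the longest match per start is reported (greedy
  semantics, identical to a regular-expression translation with greedy
  quantifiers — the oracle used in the tests).
* **Ambiguity codes** X/B/Z/U satisfy wildcard positions but never a
  residue class, positive or negated: an undetermined residue cannot
  certify a catalytic assignment.
* Matching is **case-insensitive** (published center sequences are printed
  in mixed case); matched subsequences are reported in the original case.
* Stop codons `*` and gap characters are stripped at FASTA load with a
  logged warning.

Fixed-span patterns are scanned by vectorized per-position lookup tables;
variable-span patterns by greedy backtracking.  Both paths are checked
against an independent regex-translation oracle on random pattern/sequence
pairs.

`match_probability` gives the per-start-position match probability under
an i.i.d. residue background (product over positions of summed class
frequencies; wildcards contribute 1).  For the GC diagnostic motif under a
uniform background this is 1296/20⁷ ≈ 1.01×10⁻⁶, the analytic rate the
synthetic-benchmark tests compare against.

## Center annotation

Positions 1, 3 and 14 of each 14-residue match are extracted as the
functional triad (guanine hydrogen bonding; substrate specificity;
transition-state stabilization).  `center_class` is a descriptive,
package-internal label: `canonical_cyclase_like` for centers opening with
`RYCLF` (shared by all catalogued human receptor and soluble GCs),
`kinase_embedded_like` for other centers classified as kinase-embedded,
`other` otherwise.  It carries no functional claim — catalytic activity is
an experimental question.

## Kinase-context classification

The anchor motifs are named in the kinase literature but have no single
canonical pattern; the defaults are deliberately loose consensus forms
(G-loop `G-x-G-x-x-[GSA]`, VAIK `[VAIL]-[A]-[ILVF]-K`, HRD `H-R-D`) and
are user-overridable, with the patterns used recorded in every report's
provenance block.  The decision rule — at least 2 of the 3 anchor types
within ±150 residues of the center — balances sensitivity (degenerate
G-loops are common) against false context calls; a kinase domain spans
roughly 250–300 residues, so a ±150 window covers the N-lobe anchors and
the catalytic loop from anywhere inside the domain.  No ordering among
anchors is enforced.  Enlarging the window can only add anchors, so the
embedded call is monotone in the window, a property the tests check.  No
HMM-based domain calling or structural superposition is attempted.

## Conservation profiles

Frequencies are computed over non-gap residues only, with the gap fraction
reported separately (the convention of standard logo tools).  The
small-sample correction `e_n = 19/(2 ln2 · n)` is on by default and
switchable off for exact analytic tests; at n = 217 sequences it is
≈0.063 bits.  Information content is clipped at 0.  An all-gap column is
flagged and reported with IC 0 rather than NaN.  Alignment computation is
not reimplemented — pre-aligned FASTA or Clustal input is the contract.
Per-column stack heights (frequency × IC) are emitted as a TSV matrix for
any logo renderer; no image rendering is bundled.

## Assay statistics

**Reporter normalization.**  Each replicate's ratio is
(induced lum/OD) / (control lum/OD).  Replicates with nonpositive OD are
dropped with a logged reason; a replicate missing either condition is an
error naming the orphan.

**Exact Wilcoxon signed-rank.**  Differences equal to the null value are
dropped (Wilcoxon's original procedure); tied absolute differences receive
mid-ranks.  The null distribution of W⁺ is enumerated over all 2^n sign
assignments of the realized ranks — implemented as a polynomial product
over doubled (hence integer) ranks, which is arithmetically identical to
full enumeration — for n ≤ 20 by default.  The two-sided p doubles the
smaller tail, capped at 1; with a symmetric null this equals two-tailed
summation.  Beyond n = 20 an Edgeworth-corrected normal tail is used: the
cumulants of W⁺ = Σ rᵢBᵢ (Bᵢ i.i.d. Bernoulli(½)) follow from the realized
ranks, and the kurtosis term repairs the O(1/n) error of the plain
continuity-corrected normal approximation — worst observed disagreement
with the exact p is ~2×10⁻⁴ for n in 25–40, versus ~5×10⁻³ uncorrected.
The Hodges–Lehmann pseudo-median (median of all Walsh averages of the
differences) accompanies the test as its natural location estimate.

**ANOVA / Tukey–Kramer.**  Standard between/within decomposition; the
degenerate all-identical case is reported as F = 0, p = 1.  Pairwise
statistics use the Kramer standard error
`sqrt((MSE/2)(1/nᵢ + 1/nⱼ))`, valid for unequal group sizes, with adjusted
p from scipy's studentized-range distribution at (k, df_within).  The
k = 2 equal-n case collapses to the pooled t-test (q = |t|·√2), checked to
1e−6 in the tests, and a seeded null simulation checks familywise type-I
error calibration at α = 0.05.

EIA absorbance→concentration conversion via a kit standard curve is out of
scope; the module consumes cGMP amounts (fmol/µg) directly.

## Synthetic data

All generators are pure functions of (spec, seed), drawing from NumPy's
PCG64 via a single `SeedSequence` with one spawned child stream per
emitted table; identical seeds give byte-identical outputs.

*Proteomes.*  Default benchmark: 200 proteins of 400–800 residues with a
uniform residue background, 100 *embedded* plants (center plus one
instance of each anchor at randomized offsets inside the ±150 window) and
100 *background* plants (center in plain random sequence).  Planted
centers are sampled uniformly within each residue class and from the
background at wildcard positions.  With `clean_background` (default) a
protein is redrawn if chance alone produced an unplanned motif hit
(≈10⁻⁶/position) or gave a background plant a spurious 2-anchor kinase
context (≈1% of draws): the generator's contract is that the truth table
is exhaustive, and rejection enforces it; switch it off to measure raw
spontaneous hit rates against the analytic probability.  Real proteome
composition (non-uniform residue usage, domain structure, homology) is
deliberately not emulated — passing closed-loop tests demonstrates
correctness of the machinery, not discovery performance on real proteomes.

*Ortholog families.*  Default 217 sequences (the scale of a deep
vertebrate ortholog alignment), 20-residue flanks, invariant center
columns, i.i.d. per-column substitution elsewhere with replacement drawn
from the background.  Indels, phylogenetic correlation and rate
heterogeneity are not modeled.

*Assays.*  Reporter defaults: 2 transformants × 8 replicates, fold change
3.0 with lognormal noise σ = 0.1 — an effect far above noise, so all
induced ratios exceed 1 and the exact p attains 2/2⁸.  EIA defaults: group
means Mn²⁺ = 120, Mg²⁺ = 10, no-protein = 2 fmol cGMP/µg with normal
σ = 5, n = 3 per group — chosen to echo the qualitative Mn²⁺ ≫ Mg²⁺
preference (>100 fmol/µg difference) of characterized crypto GCs without
asserting unpublished raw values.

## Numerical choices and limitations

* Background-frequency validation tolerance 1e−9; ANOVA sum-of-squares
  identities hold to 1e−9 relative; studentized-range p values rely on
  scipy's quadrature of the range CDF.
* Problem sizes in the test suite (e.g. 3,000 background proteins ≈ 2×10⁶
  scanned positions for the hit-rate calibration; 4,000 null simulations
  for familywise error) were chosen as the smallest giving statistically
  meaningful intervals; all checks are seeded and deterministic.
* The per-start match probability assumes an i.i.d. background; real
  proteomes are compositionally biased, so analytic rates are
  calibration tools, not proteome-wide expectations.
* The discovery pipeline ranks sequence context only.  Ortholog curation
  (e.g. removing sequences with large indels before alignment), domain
  prediction, structural modeling and any activity prediction are outside
  the package.
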