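"""Statistics for the reporter screen and in-vitro cGMP assays.

Two analyses are provided, mirroring how crypto-GC activity data are
evaluated:

* a one-sample **exact Wilcoxon signed-rank test** on OD-normalized
  reporter ratios against the no-change value 1 — the null distribution of
  the positive-rank sum W+ is built by enumerating all 2^n sign
  assignments of the ranked absolute differences, so with n = 8 replicates
  all shifted the same way the two-sided p is exactly 2/2^8 = 0.0078125;
* **one-way ANOVA followed by the Tukey-Kramer test** (studentized-range
  distribution, valid for unequal group sizes) on cGMP amounts per
  cofactor condition.

EIA absorbance-to-concentration conversion is upstream of this module; it
consumes cGMP amounts (fmol per microgram protein) directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Largest n for which the exact null is enumerated by default.
EXACT_N_LIMIT = 20


@dataclass(frozen=True)
class ReporterAssay:
    """One replicate of the cGMP-reporter screen, induced vs control."""

    transformant: str
    replicate: str
    induced_lum: float
    induced_od: float
    control_lum: float
    control_od: float

    @property
    def normalized_ratio(self) -> float:
        """(induced lum/OD) / (control lum/OD)."""
        return (self.induced_lum / self.induced_od) / (
            self.control_lum / self.control_od
        )


@dataclass(frozen=True)
class WilcoxonResult:
    n_input: int
    n_effective: int
    w_plus: float
    p_value: float
    hl_estimate: float
    exact_null: bool


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_difference: float
    q_statistic: float
    adjusted_p: float
    significant: bool


@dataclass(frozen=True)
class AnovaTukeyResult:
    group_labels: tuple[str, ...]
    group_n: dict[str, int]
    group_mean: dict[str, float]
    group_sd: dict[str, float]
    f_statistic: float
    df_between: int
    df_within: int
    anova_p: float
    alpha: float
    comparisons: tuple[PairwiseComparison, ...]


def normalize_reporter(raw: pd.DataFrame) -> list[ReporterAssay]:
    """Pair induced/control rows per (transformant, replicate) and compute
    OD-normalized luminescence ratios.

    ``raw`` needs columns ``transformant, replicate, condition,
    luminescence, od600`` with condition in {"induced", "control"}.
    Replicates with a nonpositive OD reading are dropped with a logged
    reason; a replicate missing either condition raises, naming the orphan.
    """
    required = {"transformant", "replicate", "condition", "luminescence", "od600"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"reporter table missing columns: {sorted(missing)}")
    out: list[ReporterAssay] = []
    for (transformant, replicate), grp in raw.groupby(
        ["transformant", "replicate"], sort=False
    ):
        conditions = dict(zip(grp["condition"], grp.index))
        if "induced" not in conditions or "control" not in conditions:
            have = sorted(conditions)
            raise ValueError(
                f"unmatched replicate: transformant={transformant!r} "
                f"replicate={replicate!r} has only conditions {have}"
            )
        ind = grp[grp["condition"] == "induced"].iloc[0]
        con = grp[grp["condition"] == "control"].iloc[0]
        if ind["od600"] <= 0 or con["od600"] <= 0:
            logger.warning(
                "dropping transformant=%s replicate=%s: nonpositive OD600",
                transformant,
                replicate,
            )
            continue
        out.append(
            ReporterAssay(
                str(transformant),
                str(replicate),
                float(ind["luminescence"]),
                float(ind["od600"]),
                float(con["luminescence"]),
                float(con["od600"]),
            )
        )
    return out


def _exact_null_counts(scaled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign vectors per value of the doubled positive-rank sum.

    Mid-ranks are half-integer, so ranks are doubled to index an integer
    array.  The polynomial product over (1 + x^(2 r_i)) enumerates all 2^n
    sign assignments.
    """
    total = int(scaled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in scaled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    return counts


def _midranks(abs_diffs: np.ndarray) -> np.ndarray:
    return sps.rankdata(abs_diffs, method="average")


def wilcoxon_exact(
    values: Sequence[float], mu0: float = 1.0, method: str = "auto"
) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test of location against ``mu0``.

    Differences equal to ``mu0`` are dropped before ranking; ties among
    absolute differences receive mid-ranks.  With ``method="auto"`` the null
    is enumerated exactly over all sign assignments for n_effective <= 20
    and a tie-corrected, continuity-corrected normal approximation is used
    beyond; ``"exact"``/``"approx"`` force either route.  The two-sided p
    doubles the smaller exact tail, capped at 1.

    ``hl_estimate`` is the Hodges-Lehmann pseudo-median of the differences
    (median of all Walsh averages), the natural location estimate to
    accompany the test.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("no values supplied")
    diffs = vals - mu0
    diffs = diffs[diffs != 0.0]
    n_eff = diffs.size
    if n_eff == 0:
        raise ValueError("all values equal mu0: no information")
    ranks = _midranks(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    walsh = [
        (diffs[i] + diffs[j]) / 2.0 for i in range(n_eff) for j in range(i, n_eff)
    ]
    hl = float(np.median(walsh))
    use_exact = method == "exact" or (method == "auto" and n_eff <= EXACT_N_LIMIT)
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    if use_exact:
        scaled = np.rint(2.0 * ranks).astype(np.int64)
        counts = _exact_null_counts(scaled)
        total = float(2**n_eff)
        w_scaled = int(round(2.0 * w_plus))
        lower = counts[: w_scaled + 1].sum() / total
        upper = counts[w_scaled:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        exact = True
    else:
        # Edgeworth-corrected normal tail: W+ = sum r_i B_i with B_i iid
        # Bernoulli(1/2), so the null cumulants follow from the realized
        # (mid-)ranks directly; the kurtosis term repairs the O(1/n) error
        # of the plain normal approximation.
        mean = float(ranks.sum()) / 2.0
        var = float((ranks**2).sum()) / 4.0
        k4 = -float((ranks**4).sum()) / 8.0
        if var <= 0:
            raise ValueError("degenerate null variance")
        sd = math.sqrt(var)
        edge = k4 / (24.0 * var**2)

        def tail_ge(w: float) -> float:
            z = (w - 0.5 - mean) / sd
            return sps.norm.sf(z) + sps.norm.pdf(z) * edge * (z**3 - 3 * z)

        def tail_le(w: float) -> float:
            z = (w + 0.5 - mean) / sd
            return sps.norm.cdf(z) - sps.norm.pdf(z) * edge * (z**3 - 3 * z)

        p = min(1.0, 2.0 * max(0.0, min(tail_le(w_plus), tail_ge(w_plus))))
        exact = False
    return WilcoxonResult(int(vals.size), int(n_eff), w_plus, float(p), hl, exact)


def _group_arrays(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} has n={arr.size} < 2")
        arrays[str(label)] = arr
    return arrays


def one_way_anova(
    groups: Mapping[str, Sequence[float]],
) -> tuple[float, tuple[int, int], float]:
    """Standard one-way fixed-effects ANOVA.

    Returns ``(F, (df_between, df_within), p)``.  Degenerate cases: zero
    between- and within-group variation gives F = 0, p = 1; zero within-
    group variation with distinct means gives F = inf, p = 0.
    """
    arrays = _group_arrays(groups)
    k = len(arrays)
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between = k - 1
    df_within = all_vals.size - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, (df_between, df_within), 1.0
        return math.inf, (df_between, df_within), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), (df_between, df_within), p


def tukey_kramer(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaTukeyResult:
    """All-pairs Tukey-Kramer comparisons after one-way ANOVA.

    For groups i, j the studentized-range statistic is

        q_ij = |mean_i - mean_j| / sqrt( (MSE/2) (1/n_i + 1/n_j) )

    with the adjusted p from the studentized-range distribution at
    (k, df_within); the Kramer form of the standard error makes the test
    valid for unequal group sizes.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    arrays = _group_arrays(groups)
    labels = tuple(arrays)
    k = len(labels)
    f, (df_b, df_w), anova_p = one_way_anova(groups)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    mse = ss_within / df_w
    comparisons = []
    for la, lb in combinations(labels, 2):
        a, b = arrays[la], arrays[lb]
        diff = a.mean() - b.mean()
        se = math.sqrt((mse / 2.0) * (1.0 / a.size + 1.0 / b.size))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else math.inf
            p_adj = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_w))
            p_adj = min(1.0, max(0.0, p_adj))
        comparisons.append(
            PairwiseComparison(la, lb, float(diff), float(q), p_adj, p_adj < alpha)
        )
    return AnovaTukeyResult(
        group_labels=labels,
        group_n={l: int(a.size) for l, a in arrays.items()},
        group_mean={l: float(a.mean()) for l, a in arrays.items()},
        group_sd={l: float(a.std(ddof=1)) for l, a in arrays.items()},
        f_statistic=f,
        df_between=df_b,
        df_within=df_w,
        anova_p=anova_p,
        alpha=alpha,
        comparisons=tuple(comparisons),
    )


def comparisons_table(result: AnovaTukeyResult) -> pd.DataFrame:
    """Human-readable table of the Tukey-Kramer comparisons."""
    return pd.DataFrame(
        [
            {
                "group_a": c.group_a,
                "group_b": c.group_b,
                "mean_difference": c.mean_difference,
                "q": c.q_statistic,
                "adjusted_p": c.adjusted_p,
                "significant": c.significant,
            }
            for c in result.comparisons
        ]
    )
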