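"""Reporter normalization, exact Wilcoxon, ANOVA and Tukey-Kramer."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cryptogc import (
    generate_assay,
    normalize_reporter,
    one_way_anova,
    tukey_kramer,
    wilcoxon_exact,
)
from cryptogc.simulate import SyntheticAssaySpec
from cryptogc.stats import _exact_null_counts, _midranks


def brute_force_wilcoxon_p(values, mu0):
    """Independent oracle: full enumeration over all 2^n sign vectors."""
    diffs = [v - mu0 for v in values if v != mu0]
    n = len(diffs)
    ranks = _midranks(np.abs(np.asarray(diffs)))
    w_obs = sum(r for r, d in zip(ranks, diffs) if d > 0)
    le = ge = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        le += w <= w_obs + 1e-9
        ge += w >= w_obs - 1e-9
    total = 2**n
    return min(1.0, 2.0 * min(le / total, ge / total))


class TestReporter:
    def make_table(self):
        return pd.DataFrame(
            [
                ("NTRK1", "r1", "induced", 2000.0, 0.5),
                ("NTRK1", "r1", "control", 500.0, 0.5),
                ("NTRK1", "r2", "induced", 900.0, 0.45),
                ("NTRK1", "r2", "control", 900.0, 0.45),
            ],
            columns=["transformant", "replicate", "condition", "luminescence", "od600"],
        )

    def test_forced_ratios(self):
        a, b = normalize_reporter(self.make_table())
        assert a.normalized_ratio == pytest.approx(4.0)
        assert b.normalized_ratio == pytest.approx(1.0)

    def test_orphan_replicate_rejected(self):
        table = self.make_table().iloc[:3]
        with pytest.raises(ValueError, match="r2"):
            normalize_reporter(table)

    def test_nonpositive_od_dropped_with_log(self, caplog):
        table = self.make_table()
        table.loc[0, "od600"] = 0.0
        with caplog.at_level("WARNING"):
            out = normalize_reporter(table)
        assert len(out) == 1 and out[0].replicate == "r2"
        assert "nonpositive OD600" in caplog.text

    def test_ratios_match_spreadsheet_recomputation(self):
        reporter, _, _ = generate_assay(SyntheticAssaySpec(seed=21))
        assays = normalize_reporter(reporter)
        wide = reporter.pivot_table(
            index=["transformant", "replicate"],
            columns="condition",
            values=["luminescence", "od600"],
        )
        for a in assays:
            row = wide.loc[(a.transformant, a.replicate)]
            expected = (row["luminescence"]["induced"] / row["od600"]["induced"]) / (
                row["luminescence"]["control"] / row["od600"]["control"]
            )
            assert a.normalized_ratio == pytest.approx(expected, rel=1e-12)


class TestWilcoxon:
    def test_eight_positive_replicates_give_printed_p(self):
        values = [1.2, 1.5, 1.9, 2.2, 2.8, 3.1, 3.6, 4.0]
        res = wilcoxon_exact(values, mu0=1.0)
        assert res.p_value == 2.0 / 2.0**8 == 0.0078125
        assert round(res.p_value, 4) == 0.0078
        assert res.n_effective == 8 and res.exact_null
        assert res.w_plus == 36.0

    def test_single_effective_value(self):
        res = wilcoxon_exact([2.0, 1.0], mu0=1.0)
        assert res.n_effective == 1 and res.p_value == 1.0

    def test_all_values_at_null_rejected(self):
        with pytest.raises(ValueError, match="no information"):
            wilcoxon_exact([1.0, 1.0], mu0=1.0)

    def test_matches_brute_force_enumeration(self):
        rng = random.Random(1234)
        for _ in range(25):
            n = rng.randint(2, 12)
            # Mix of continuous and tied magnitudes to exercise mid-ranks.
            vals = [round(rng.uniform(-2, 3), rng.choice([1, 2])) for _ in range(n)]
            if all(v == 0 for v in vals):
                continue
            res = wilcoxon_exact(vals, mu0=0.0)
            assert res.p_value == pytest.approx(
                brute_force_wilcoxon_p(vals, 0.0), abs=1e-12
            )

    def test_exact_null_symmetric_and_sums_to_one(self):
        for n in (3, 5, 8, 12):
            ranks = np.arange(1, n + 1, dtype=float)
            counts = _exact_null_counts((2 * ranks).astype(np.int64))
            assert counts.sum() == 2**n
            assert np.array_equal(counts, counts[::-1])  # symmetric about n(n+1)/4

    def test_normal_approximation_close_for_large_n(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            vals = rng.normal(0.15, 1.0, size=30)
            exact = wilcoxon_exact(vals, 0.0, method="exact")
            approx = wilcoxon_exact(vals, 0.0, method="approx")
            assert exact.exact_null and not approx.exact_null
            assert abs(exact.p_value - approx.p_value) < 0.005

    def test_hl_estimate_is_walsh_median(self):
        vals = [1.0, 2.0, 4.0]
        res = wilcoxon_exact(vals, mu0=0.0)
        walsh = sorted(
            (a + b) / 2 for i, a in enumerate(vals) for b in vals[i:]
        )
        assert res.hl_estimate == np.median(walsh)


class TestAnova:
    def test_identical_groups(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        f, (dfb, dfw), p = one_way_anova(g)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert (dfb, dfw) == (2, 6) and p == pytest.approx(1.0)

    def test_two_groups_equal_squared_t(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        f, _, p_f = one_way_anova({"a": a, "b": b})
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-12)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n=1"):
            one_way_anova({"a": [1.0], "b": [1.0, 2.0]})

    def test_matches_independent_recomputation(self):
        _, eia, _ = generate_assay(SyntheticAssaySpec(seed=33))
        groups = {
            str(g): list(s["cgmp_fmol_per_ug"])
            for g, s in eia.groupby("condition", sort=False)
        }
        f, _, p = one_way_anova(groups)
        f_ref, p_ref = sps.f_oneway(*groups.values())
        assert f == pytest.approx(f_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_total_ss_decomposition(self):
        rng = np.random.default_rng(17)
        groups = {f"g{i}": rng.normal(i, 2.0, rng.integers(3, 9)) for i in range(4)}
        all_vals = np.concatenate(list(groups.values()))
        ss_total = ((all_vals - all_vals.mean()) ** 2).sum()
        grand = all_vals.mean()
        ssb = sum(a.size * (a.mean() - grand) ** 2 for a in groups.values())
        ssw = sum(((a - a.mean()) ** 2).sum() for a in groups.values())
        assert ssb + ssw == pytest.approx(ss_total, rel=1e-9)
        f, (dfb, dfw), _ = one_way_anova(groups)
        assert f == pytest.approx((ssb / dfb) / (ssw / dfw), rel=1e-12)


class TestTukeyKramer:
    def test_identical_groups_no_flags(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        res = tukey_kramer(g)
        for c in res.comparisons:
            assert c.adjusted_p == pytest.approx(1.0, abs=1e-9)
            assert not c.significant

    def test_two_groups_reduce_to_pooled_t(self):
        """For k = 2 equal-n groups, q = |t| sqrt(2) and the p values agree."""
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        res = tukey_kramer({"a": a, "b": b})
        (cmp,) = res.comparisons
        t, p_t = sps.ttest_ind(a, b)
        assert cmp.q_statistic == pytest.approx(abs(t) * math.sqrt(2), rel=1e-10)
        assert cmp.adjusted_p == pytest.approx(p_t, abs=1e-6)

    def test_matches_statsmodels_reference(self):
        """Cross-check adjusted p values against an independent implementation."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(12)
        groups = {f"g{i}": rng.normal(i * 0.8, 1.0, 6) for i in range(3)}
        res = tukey_kramer(groups)
        data = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        ref = pairwise_tukeyhsd(data, labels)
        ours = {frozenset((c.group_a, c.group_b)): c.adjusted_p for c in res.comparisons}
        for (la, lb), p_ref in zip(
            itertools.combinations(ref.groupsunique, 2), ref.pvalues
        ):
            assert ours[frozenset((la, lb))] == pytest.approx(p_ref, abs=1e-6)

    def test_familywise_error_calibrated_under_null(self):
        """Seeded null simulation: familywise type-I error ~ alpha = 0.05."""
        rng = np.random.default_rng(2024)
        reps, k, n = 4000, 4, 3
        x = rng.normal(0.0, 1.0, size=(reps, k, n))
        means = x.mean(axis=2)
        ssw = ((x - means[:, :, None]) ** 2).sum(axis=(1, 2))
        df_w = k * (n - 1)
        mse = ssw / df_w
        crit = sps.studentized_range.ppf(0.95, k, df_w)
        qmax = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(mse / n)
        rate = float((qmax > crit).mean())
        lo = sps.binom.ppf(0.005, reps, 0.05) / reps
        hi = sps.binom.ppf(0.995, reps, 0.05) / reps
        assert lo <= rate <= hi

    def test_eia_structure_flags_mn_vs_mg(self):
        _, eia, _ = generate_assay(SyntheticAssaySpec(seed=9))
        groups = {
            str(g): list(s["cgmp_fmol_per_ug"])
            for g, s in eia.groupby("condition", sort=False)
        }
        res = tukey_kramer(groups, alpha=0.05)
        flags = {frozenset((c.group_a, c.group_b)): c.significant for c in res.comparisons}
        assert flags[frozenset(("Mn2+", "Mg2+"))]
        assert flags[frozenset(("Mn2+", "no_protein"))]
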