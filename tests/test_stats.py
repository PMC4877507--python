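"""Group statistics against independent from-scratch oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import tiny_exp1
from rhythmtag.pipeline import analyze_cohort
from rhythmtag.stats import (
    build_report,
    mixed_anova_gg,
    paired_t_bonferroni,
    pearson_r,
)


def paired_t_oracle(a, b):
    """Textbook paired t: mean difference over its standard error."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    from scipy.stats import t as tdist

    return t, 2 * tdist.sf(abs(t), n - 1)


def mixed_anova_oracle(df, dv="y", within="level", subject="subject_id", between="group"):
    """Balanced mixed-design ANOVA from explicit sums of squares, plus the
    Greenhouse-Geisser epsilon from the double-centred covariance."""
    wide = df.pivot(index=subject, columns=within, values=dv)
    groups = df.drop_duplicates(subject).set_index(subject)[between]
    X = wide.to_numpy()
    glabs = groups.loc[wide.index].to_numpy()
    N, k = X.shape
    M = X.mean()
    lev = X.mean(axis=0)
    gnames = sorted(set(glabs))
    G = len(gnames)
    ssb = sssub = ssint = sserr = 0.0
    for g in gnames:
        sel = glabs == g
        ng = sel.sum()
        Mg = X[sel].mean()
        ssb += k * ng * (Mg - M) ** 2
        sssub += k * ((X[sel].mean(axis=1) - Mg) ** 2).sum()
        Mgs = X[sel].mean(axis=0)
        ssint += ng * ((Mgs - Mg - lev + M) ** 2).sum()
        resid = X[sel] - X[sel].mean(axis=1, keepdims=True) - Mgs + Mg
        sserr += (resid**2).sum()
    ssw = N * ((lev - M) ** 2).sum()
    Fb = (ssb / (G - 1)) / (sssub / (N - G))
    Fw = (ssw / (k - 1)) / (sserr / ((N - G) * (k - 1)))
    Fi = (ssint / ((G - 1) * (k - 1))) / (sserr / ((N - G) * (k - 1)))
    S = np.cov(X, rowvar=False, ddof=1)
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    eps = np.trace(Sc) ** 2 / ((k - 1) * np.sum(Sc**2))
    return Fb, Fw, Fi, eps


def make_long(rng, n_per_group=5, k=4, effect=0.5):
    rows = []
    for g in ("a", "b"):
        for i in range(n_per_group):
            base = rng.normal(0, 1)
            for s in range(k):
                rows.append(
                    {
                        "subject_id": f"{g}{i}",
                        "group": g,
                        "level": f"L{s}",
                        "y": base + rng.normal(0, 1) + (effect * s if g == "a" else 0),
                    }
                )
    return pd.DataFrame(rows)


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_t_bonferroni([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p_raw == 1.0

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1, 0.2, 10)
        b = rng.normal(0, 0.2, 10)
        r1 = paired_t_bonferroni(a, b, 1)
        r5 = paired_t_bonferroni(a, b, 5)
        assert r5.p_adjusted == pytest.approx(min(1.0, 5 * r1.p_raw))

    def test_matches_formula_oracle(self):
        a = [2.1, 1.8, 2.5, 3.0, 2.2, 1.9]
        b = [1.7, 1.9, 2.0, 2.4, 2.1, 1.5]
        res = paired_t_bonferroni(a, b)
        t_o, p_o = paired_t_oracle(a, b)
        assert res.t == pytest.approx(t_o, abs=1e-10)
        assert res.p_raw == pytest.approx(p_o, abs=1e-10)
        assert res.df == 5

    def test_adjusted_p_bounds_property(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.standard_normal(6)
            b = rng.standard_normal(6)
            m = int(rng.integers(1, 10))
            res = paired_t_bonferroni(a, b, m)
            assert res.p_raw <= res.p_adjusted <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t_bonferroni([1, 2, 3], [1, 2])


class TestMixedAnova:
    def test_matches_sums_of_squares_oracle(self):
        df = make_long(np.random.default_rng(123))
        res = mixed_anova_gg(df, "y", "level", "subject_id", "group")
        Fb, Fw, Fi, eps = mixed_anova_oracle(df)
        assert res.between.F == pytest.approx(Fb, abs=1e-8)
        assert res.within.F == pytest.approx(Fw, abs=1e-8)
        assert res.interaction.F == pytest.approx(Fi, abs=1e-8)
        assert res.gg_epsilon == pytest.approx(eps, abs=1e-8)
        # corrected dfs scale by epsilon
        assert res.interaction.df1 == pytest.approx((2 - 1) * (4 - 1) * eps)

    def test_two_within_levels_epsilon_is_one(self):
        df = make_long(np.random.default_rng(5), k=2)
        res = mixed_anova_gg(df, "y", "level", "subject_id", "group")
        assert res.gg_epsilon == 1.0

    def test_compound_symmetry_epsilon_near_one(self):
        rng = np.random.default_rng(7)
        rows = []
        for g in ("a", "b"):
            for i in range(100):
                base = rng.normal(0, 2)  # shared subject effect -> CS
                for s in range(4):
                    rows.append(
                        {"subject_id": f"{g}{i}", "group": g, "level": f"L{s}",
                         "y": base + rng.normal(0, 1)}
                    )
        res = mixed_anova_gg(pd.DataFrame(rows), "y", "level", "subject_id", "group")
        assert res.gg_epsilon > 0.95

    def test_epsilon_lower_bound(self):
        df = make_long(np.random.default_rng(9), k=5)
        res = mixed_anova_gg(df, "y", "level", "subject_id", "group")
        assert 1 / (5 - 1) <= res.gg_epsilon <= 1.0

    def test_degenerate_design_rejected(self):
        df = make_long(np.random.default_rng(0), k=1)
        with pytest.raises(ValueError):
            mixed_anova_gg(df, "y", "level", "subject_id", "group")


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, 2 * x)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(10)
        y = 0.5 * x + rng.standard_normal(10)
        r, p = pearson_r(x, y)
        r_o = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(r_o, abs=1e-10)
        from scipy.stats import t as tdist

        t_o = r_o * np.sqrt(8 / (1 - r_o**2))
        assert p == pytest.approx(2 * tdist.sf(abs(t_o), 8), abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBuildReport:
    def test_duple_boost_cohort_flags_interaction_and_duple_bin(self, tmp_path):
        # transient response kept small so its pattern harmonics do not
        # mask the steady-state contrast at the shared bins
        cfg = tiny_exp1(
            seed=42,
            n_subjects={"music": 10, "no_music": 10},
            ssep_sd_frac=0.08,
            boost_factor=3.0,
            erp_amp_uv=1.0,
            erp_amp_sd_uv=0.3,
        )
        res = analyze_cohort(cfg, out_dir=tmp_path)
        aov = res["report"]["group_by_frequency_anova"].set_index("effect")
        assert aov.loc["interaction", "p"] < 0.05
        post = res["report"]["posthoc_group_by_frequency"].set_index("frequency_hz")
        assert post.loc[1.5, "significant"]
        assert (tmp_path / "report" / "exclusions.txt").exists()

    def test_report_tables_written(self, tmp_path):
        cfg = tiny_exp1(seed=3, n_subjects={"music": 4, "no_music": 4})
        res = analyze_cohort(cfg, out_dir=tmp_path)
        for name in (
            "ssep_vs_noise_floor",
            "related_vs_unrelated",
            "group_by_frequency_anova",
            "posthoc_group_by_frequency",
            "erp_anova",
            "correlations",
        ):
            assert (tmp_path / "report" / f"{name}.csv").exists()
            assert name in res["report"]

    def test_missing_columns_rejected(self, tmp_path):
        df = pd.DataFrame({"subject_id": ["a", "b", "c"], "group": list("xyz")})
        with pytest.raises(ValueError):
            build_report(df, tmp_path, [1.0], [1.0], [1.0])
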