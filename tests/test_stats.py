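import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

import rsdelta as rd
from rsdelta.stats import grubbs_critical


def regional_frame(rng, ns=(6, 5, 4), effect=None, bands=rd.BAND_NAMES,
                   rois=("frontal", "central", "parietal", "occipital",
                         "temporal"), subject_sd=0.5, noise_sd=0.3):
    """Tidy regional-activity frame with subject random effects."""
    rows = []
    groups = ("Nold", "noADMCI-noEEA", "noADMCI-EEA")
    for g, n in zip(groups, ns):
        for i in range(n):
            sid = f"{g}-{i}"
            base = rng.normal(0, subject_sd)
            for b in bands:
                for r in rois:
                    mu = base
                    if effect and (g, b, r) in effect:
                        mu += effect[(g, b, r)]
                    rows.append({
                        "subject_id": sid, "group": g, "band": b, "roi": r,
                        "value": 10 ** (mu + rng.normal(0, noise_sd)),
                    })
    return pd.DataFrame(rows)


class TestLog10AndCheck:
    def test_unit_values_become_zero(self):
        df = pd.DataFrame({"subject_id": ["a", "b", "c", "d"],
                           "group": ["G"] * 4, "band": ["delta"] * 4,
                           "roi": ["temporal"] * 4, "value": [1.0] * 4})
        out, report = rd.log10_and_check(df)
        assert np.allclose(out["log10_value"], 0.0)

    def test_nonpositive_rejected_with_cell_info(self):
        df = pd.DataFrame({"subject_id": ["a", "b", "c"], "group": ["G"] * 3,
                           "band": ["delta"] * 3, "roi": ["temporal"] * 3,
                           "value": [1.0, 0.0, 2.0]})
        with pytest.raises(ValueError, match="delta"):
            rd.log10_and_check(df)

    def test_lognormal_cells_pass_normality(self):
        """After log10, lognormal samples are rarely rejected (Monte
        Carlo)."""
        rng = np.random.default_rng(8)
        ok = 0
        n_rep = 60
        for _ in range(n_rep):
            df = pd.DataFrame({
                "subject_id": [f"s{i}" for i in range(200)],
                "group": ["G"] * 200, "band": ["delta"] * 200,
                "roi": ["temporal"] * 200,
                "value": 10 ** rng.normal(0, 0.4, 200)})
            _, rep = rd.log10_and_check(df)
            ok += not rep["non_normal"].iloc[0]
        assert ok / n_rep >= 0.9


class TestMixedAnova:
    def test_location_invariance(self):
        rng = np.random.default_rng(1)
        df = regional_frame(rng)
        df, _ = rd.log10_and_check(df)
        res1 = {r.effect: r.F for r in rd.mixed_anova(df)}
        df2 = df.copy()
        df2["log10_value"] = df2["log10_value"] + 7.7
        res2 = {r.effect: r.F for r in rd.mixed_anova(df2)}
        for eff in ("Group x Band", "Group x ROI", "Band x ROI",
                    "Group x Band x ROI"):
            assert res1[eff] == pytest.approx(res2[eff], rel=1e-9)

    def test_degenerate_design_equals_oneway_anova(self):
        """Two groups and a single within cell reduce to the classical
        one-way F (scipy oracle, 1e-8)."""
        rng = np.random.default_rng(2)
        rows = []
        for g, n in (("A", 9), ("B", 12)):
            for i in range(n):
                rows.append({"subject_id": f"{g}{i}", "group": g,
                             "band": "delta", "roi": "temporal",
                             "log10_value": rng.normal(0.3 if g == "A"
                                                       else 0.0, 1.0)})
        df = pd.DataFrame(rows)
        res = rd.mixed_anova(df, bands=("delta",), rois=("temporal",))
        a = df[df.group == "A"].log10_value
        b = df[df.group == "B"].log10_value
        oracle = sst.f_oneway(a, b)
        assert res[0].F == pytest.approx(oracle.statistic, abs=1e-8)
        assert res[0].p == pytest.approx(oracle.pvalue, abs=1e-8)

    def test_matches_pingouin_single_within_factor(self):
        """One between + one within factor agrees with an independent
        mixed-ANOVA implementation."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        rows = []
        for g, n in (("A", 9), ("B", 7)):
            for i in range(n):
                base = rng.normal(0, 1)
                for j, band in enumerate(rd.BAND_NAMES):
                    rows.append({"subject_id": f"{g}{i}", "group": g,
                                 "band": band, "roi": "temporal",
                                 "log10_value": base + rng.normal(
                                     0.1 * j if g == "A" else 0, 1)})
        df = pd.DataFrame(rows)
        mine = {r.effect: r for r in rd.mixed_anova(df, rois=("temporal",))}
        ref = pg.mixed_anova(data=df, dv="log10_value", within="band",
                             subject="subject_id", between="group")
        for eff, src in (("Group", "group"), ("Band", "band"),
                         ("Group x Band", "Interaction")):
            row = ref[ref.Source == src].iloc[0]
            assert mine[eff].F == pytest.approx(row["F"], rel=1e-9)
            assert mine[eff].p == pytest.approx(row["p_unc"], rel=1e-9)

    def test_null_rejection_rate_nominal(self):
        """Group x Band x ROI rejects at about 5% under the null (Monte
        Carlo, 200 replicates)."""
        rng = np.random.default_rng(4)
        rej = 0
        n_rep = 200
        for _ in range(n_rep):
            df = regional_frame(rng, ns=(6, 6, 6))
            df, _ = rd.log10_and_check(df)
            res = {r.effect: r for r in rd.mixed_anova(df)}
            rej += res["Group x Band x ROI"].p < 0.05
        assert 2 <= rej <= 19, f"{rej}/{n_rep}"

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(5)
        df = regional_frame(rng)
        df, _ = rd.log10_and_check(df)
        with pytest.raises(ValueError, match="missing cell"):
            rd.mixed_anova(df.iloc[:-1])


class TestDuncan:
    def test_identical_means_nothing_significant(self):
        means = {"A": 1.0, "B": 1.0, "C": 1.0}
        ns = {"A": 10, "B": 10, "C": 10}
        ps = rd.duncan_pairwise(means, ns, ms_error=0.5, df_error=27)
        assert all(p > 0.9 for p in ps.values())

    def test_two_group_case_equals_studentized_range_r2(self):
        """For two groups the Duncan p equals the r=2 studentized-range
        tail, which in turn equals the two-sided t probability with
        q = sqrt(2)|t| (t-distribution oracle)."""
        means = {"A": 0.0, "B": 0.8}
        ns = {"A": 12, "B": 9}
        ms, df = 0.9, 19
        p = rd.duncan_pairwise(means, ns, ms, df)[("A", "B")]
        nh = 2 / (1 / 12 + 1 / 9)
        q = 0.8 / np.sqrt(ms / nh)
        t = q / np.sqrt(2)
        oracle = 2 * sst.t.sf(t, df)
        assert p == pytest.approx(oracle, rel=1e-4)

    def test_family_threshold_is_two_permil(self):
        rng = np.random.default_rng(6)
        df = regional_frame(rng)
        df, _ = rd.log10_and_check(df)
        ph = rd.duncan_posthoc(df)
        assert (ph["significant"] == (ph["p"] < 0.05 / 25)).all()

    def test_bonferroni_thresholds(self):
        assert rd.bonferroni_threshold(0.05, 25) == pytest.approx(0.002)
        assert rd.bonferroni_threshold(0.05, 8) == pytest.approx(0.00625)
        assert rd.bonferroni_threshold(0.05, 13) == pytest.approx(0.0038,
                                                                  abs=5e-5)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(7)
        effect = {("noADMCI-EEA", "delta", "temporal"): 1.2}
        df = regional_frame(rng, ns=(10, 19, 13), effect=effect,
                            noise_sd=0.2, subject_sd=0.2)
        df, _ = rd.log10_and_check(df)
        ph = rd.duncan_posthoc(df)
        cell = ph[(ph.band == "delta") & (ph.roi == "temporal")
                  & (ph.group_a != "Nold") & (ph.group_b != "Nold")]
        assert cell["significant"].iloc[0]


class TestGrubbs:
    def test_all_equal_no_outliers(self):
        assert rd.grubbs_iterative(np.ones(10)) == []

    def test_gross_outlier_flagged_first(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(20)
        x = np.append(x, 10.0)
        removed = rd.grubbs_iterative(x, alpha=0.001)
        assert removed[0] == 20

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        x = np.append(rng.standard_normal(15), [8.0, -9.0])
        removed = set(rd.grubbs_iterative(x))
        perm = rng.permutation(len(x))
        assert {int(perm[j]) for j in rd.grubbs_iterative(x[perm])} == removed

    def test_critical_value_matches_published_table(self):
        # classical two-sided Grubbs critical value, n=10, alpha=0.05
        assert grubbs_critical(10, 0.05) == pytest.approx(2.290, abs=0.001)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rd.grubbs_iterative(np.array([1.0, 2.0]))


class TestExactTests:
    def test_gender_table_reproduces_published_p(self):
        p = rd.fisher_freeman_halton([[6, 24], [6, 13], [0, 13]])
        assert round(p, 2) == 0.07

    def test_fisher_matches_scipy_on_small_margins(self):
        """2x2 enumeration agrees with the hypergeometric oracle for all
        tables with margins <= 8."""
        for a in range(5):
            for b in range(5):
                for c in range(5):
                    for d in range(5):
                        if (a + b) == 0 or (c + d) == 0 \
                                or (a + c) == 0 or (b + d) == 0:
                            continue
                        mine = rd.fisher_freeman_halton([[a, b], [c, d]])
                        oracle = sst.fisher_exact([[a, b], [c, d]]).pvalue
                        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_freeman_halton_against_bruteforce(self):
        """2x3 enumeration agrees with an independent direct enumeration."""
        from math import comb

        def brute(table):
            t = np.asarray(table)
            cols = t.sum(axis=0)
            r0 = t.sum(axis=1)[0]
            n = t.sum()

            def prob(cells):
                num = 1.0
                for cj, vj in zip(cols, cells):
                    num *= comb(cj, vj)
                return num / comb(n, r0)

            p_obs = prob(t[0])
            p = 0.0
            for v0 in range(cols[0] + 1):
                for v1 in range(cols[1] + 1):
                    v2 = r0 - v0 - v1
                    if 0 <= v2 <= cols[2]:
                        pr = prob([v0, v1, v2])
                        if pr <= p_obs * (1 + 1e-9):
                            p += pr
            return p

        rng = np.random.default_rng(10)
        for _ in range(10):
            t = rng.integers(0, 7, (2, 3))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert rd.fisher_freeman_halton(t) == \
                pytest.approx(brute(t), abs=1e-10)


class TestMarkerBattery:
    def test_family_thresholds_and_schema(self):
        rng = np.random.default_rng(11)
        subjects = pd.DataFrame({
            "group": ["A"] * 19 + ["B"] * 13,
            "age": rng.normal(69, 5, 32),
            "mmse": rng.normal(27, 1.5, 32),
        })
        family = [
            {"marker": "age", "test": "ttest"},
            {"marker": "mmse", "test": "kruskal"},
            {"marker": "gender", "test": "freeman_halton",
             "table": [[6, 24], [6, 13], [0, 13]]},
        ] + [{"marker": f"m{i}", "test": "fisher",
              "table": [[3, 7], [5, 2]]} for i in range(10)]
        out = rd.marker_battery(subjects, family)
        assert len(out) == 13
        assert np.allclose(out["threshold"], 0.05 / 13)
        assert out["threshold"].iloc[0] == pytest.approx(0.0038, abs=5e-5)

    def test_non_numeric_marker_rejected(self):
        subjects = pd.DataFrame({"group": ["A", "A", "B", "B"],
                                 "colour": ["red", "blue", "red", "green"]})
        with pytest.raises(ValueError, match="not numeric"):
            rd.marker_battery(subjects,
                              [{"marker": "colour", "test": "ttest"}])


class TestRoc:
    def test_perfect_separation(self):
        r = rd.roc_classify([1, 2, 3, 10, 11, 12],
                            ["c", "c", "c", "p", "p", "p"], positive="p")
        assert r.auroc == 1.0
        assert r.sensitivity == 1.0
        assert r.specificity == 1.0

    def test_auroc_equals_pairwise_oracle(self):
        """Trapezoidal AUROC equals (concordant + 0.5 ties) over all
        case-control pairs."""
        rng = np.random.default_rng(12)
        scores = np.round(rng.normal(0, 1, 40), 1)   # force some ties
        labels = ["p" if rng.uniform() < 0.4 else "c" for _ in scores]
        if len(set(labels)) < 2:
            labels[0] = "p" if labels[0] == "c" else "c"
        r = rd.roc_classify(scores, labels, positive="p")
        cases = scores[[i for i, l in enumerate(labels) if l == "p"]]
        ctrls = scores[[i for i, l in enumerate(labels) if l == "c"]]
        conc = ties = 0
        for x in cases:
            for y in ctrls:
                conc += x > y
                ties += x == y
        oracle = (conc + 0.5 * ties) / (len(cases) * len(ctrls))
        assert r.auroc == pytest.approx(oracle, abs=1e-10)

    def test_weighted_accuracy_definition(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(0, 1, 50) + np.array(
            [1.0 if i < 15 else 0.0 for i in range(50)])
        labels = ["p"] * 15 + ["c"] * 35
        r = rd.roc_classify(scores, labels, positive="p")
        assert r.accuracy == pytest.approx(
            (r.sensitivity * 15 + r.specificity * 35) / 50)

    def test_auroc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(0, 1, 30)
        labels = ["p"] * 12 + ["c"] * 18
        r1 = rd.roc_classify(scores, labels, positive="p")
        r2 = rd.roc_classify(np.exp(3 * scores), labels, positive="p")
        assert r1.auroc == pytest.approx(r2.auroc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rd.roc_classify([1, 2, 3], ["p", "p", "p"], positive="p")
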