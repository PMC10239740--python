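"""Stratification, annotation, volcano statistics."""
import numpy as np
import pandas as pd
import pytest

import seminalomics as so
from seminalomics.study import ADDUCT_MASSES

from conftest import make_table


@pytest.fixture(scope="module")
def cohort():
    return so.generate_cohort(2731, seed=1)


class TestStratification:
    def test_four_by_fifty_gives_200(self, cohort):
        design = so.stratify_extremes(cohort, n_per_group=50)
        assert design.n_selected == 200
        counts = design.table["group"].value_counts()
        assert set(counts.index) == {"G1", "G2", "G3", "G4"}
        assert (counts == 50).all()

    def test_groups_disjoint(self, cohort):
        design = so.stratify_extremes(cohort, n_per_group=50)
        assert design.table.index.is_unique

    def test_deterministic_reruns(self, cohort):
        a = so.stratify_extremes(cohort, n_per_group=50)
        b = so.stratify_extremes(cohort, n_per_group=50)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_extremes_actually_selected(self, cohort):
        """Low-TS groups sit below the cohort TS median, high above."""
        design = so.stratify_extremes(cohort, n_per_group=50)
        med = cohort["TS"].median()
        low = design.table.index[design.table["ts_class"] == "low"]
        high = design.table.index[design.table["ts_class"] == "high"]
        assert cohort.loc[low, "TS"].max() < med
        assert cohort.loc[high, "TS"].min() > med

    def test_small_cohort_rejected(self):
        small = so.generate_cohort(100, seed=0)
        with pytest.raises(ValueError):
            so.stratify_extremes(small, n_per_group=50)

    def test_contingency_five_percent_gives_210(self, cohort):
        design = so.stratify_extremes(cohort, n_per_group=50)
        extended = so.add_contingency(design, fraction=0.05)
        assert extended.n_selected == 210
        assert extended.table["contingency"].sum() == 10

    def test_zero_fraction_unchanged(self, cohort):
        design = so.stratify_extremes(cohort, n_per_group=50)
        assert so.add_contingency(design, fraction=0.0) is design

    def test_contingency_spread_evenly(self, cohort):
        design = so.stratify_extremes(cohort, n_per_group=50)
        extended = so.add_contingency(design, fraction=0.05)
        extra = extended.table[extended.table["contingency"]]
        counts = extra["group"].value_counts()
        assert counts.min() >= 2 and counts.max() <= 3

    def test_rounding_half_away_from_zero(self, cohort):
        design = so.stratify_extremes(cohort, n_per_group=50)
        # 0.0125 * 200 = 2.5 -> 3 extras
        extended = so.add_contingency(design, fraction=0.0125)
        assert extended.n_selected == 203


def library_frame(rows):
    return pd.DataFrame(rows, columns=["compound", "mass", "rt", "library"])


class TestAnnotation:
    def test_protonated_hit_with_small_ppm_error(self):
        lib = library_frame([("cpd", 288.2089, 9.0, "steroid")])
        feats = pd.DataFrame({"mz": [289.2161], "rt": [9.02]}, index=["f1"])
        hits = so.annotate_features(feats, lib, ppm_tol=5, rt_tol=0.2)
        assert len(hits) == 1
        assert hits.loc[0, "adduct"] == "[M+H]+"
        assert abs(hits.loc[0, "ppm_error"]) < 0.5

    def test_rt_gate_blocks_mass_match(self):
        lib = library_frame([("cpd", 288.2089, 9.0, "steroid")])
        feats = pd.DataFrame({"mz": [289.2161], "rt": [9.02]}, index=["f1"])
        hits = so.annotate_features(feats, lib, ppm_tol=5, rt_tol=0.01)
        assert len(hits) == 0

    def test_sodiated_exact_match(self):
        mass = 300.1
        lib = library_frame([("cpd", mass, 5.0, "MSMLS")])
        feats = pd.DataFrame(
            {"mz": [mass + ADDUCT_MASSES["[M+Na]+"]], "rt": [5.0]}, index=["f1"]
        )
        hits = so.annotate_features(feats, lib)
        assert hits.loc[0, "adduct"] == "[M+Na]+"
        assert hits.loc[0, "ppm_error"] == pytest.approx(0.0, abs=1e-9)

    def test_engineered_panel_hits_and_misses(self):
        """10 features built on library adduct masses hit; 5 far-off
        features do not."""
        rng = np.random.default_rng(0)
        masses = rng.uniform(150, 600, 10)
        lib = library_frame(
            [(f"c{i}", m, 2.0 + i, "MSMLS") for i, m in enumerate(masses)]
        )
        adducts = list(ADDUCT_MASSES.values())
        feats = pd.DataFrame(
            {
                "mz": [m + adducts[i % 4] for i, m in enumerate(masses)]
                + list(rng.uniform(700, 900, 5)),
                "rt": [2.0 + i for i in range(10)] + [20.0] * 5,
            },
            index=[f"f{i}" for i in range(15)],
        )
        hits = so.annotate_features(feats, lib, ppm_tol=5, rt_tol=0.1)
        assert hits["feature_id"].nunique() == 10
        assert set(hits["feature_id"]) == {f"f{i}" for i in range(10)}

    def test_empty_library_rejected(self):
        feats = pd.DataFrame({"mz": [100.0], "rt": [1.0]}, index=["f1"])
        with pytest.raises(ValueError, match="library"):
            so.annotate_features(feats, library_frame([]))


class TestVolcano:
    def make_intensities(self, n_per=10, n_feat=30, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.lognormal(10, 0.3, (2 * n_per, n_feat))
        idx = pd.Index(range(2 * n_per), name="injection_order")
        intens = pd.DataFrame(X, index=idx,
                              columns=[f"f{i}" for i in range(n_feat)])
        labels = pd.Series(["low"] * n_per + ["high"] * n_per, index=idx)
        return intens, labels

    def test_identical_groups_fc_zero(self):
        intens, labels = self.make_intensities()
        intens.iloc[10:] = intens.iloc[:10].to_numpy()
        res = so.volcano(intens, labels)
        assert np.allclose(res["log2_fc"], 0.0)
        assert (res["p_value"] == 1.0).all()

    def test_planted_doubling_gives_plus_one(self):
        intens, labels = self.make_intensities()
        intens.iloc[10:] = intens.iloc[:10].to_numpy()
        intens.iloc[10:, 0] *= 2.0  # high group doubled
        res = so.volcano(intens, labels)
        assert res["log2_fc"].iloc[0] == pytest.approx(1.0)

    def test_welch_oracle(self):
        """P-values equal an independently coded Welch statistic with the
        t tail, feature by feature."""
        from scipy import stats as sps
        intens, labels = self.make_intensities(n_per=12, n_feat=100, seed=4)
        res = so.volcano(intens, labels)
        hi = intens.iloc[12:].to_numpy()
        lo = intens.iloc[:12].to_numpy()
        for j in range(100):
            m1, m2 = hi[:, j].mean(), lo[:, j].mean()
            v1, v2 = hi[:, j].var(ddof=1), lo[:, j].var(ddof=1)
            n1 = n2 = 12
            t = (m1 - m2) / np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
            p = 2 * sps.t.sf(abs(t), df)
            assert res["p_value"].iloc[j] == pytest.approx(p, rel=1e-10)

    def test_label_swap_antisymmetry(self):
        intens, labels = self.make_intensities(seed=5)
        res = so.volcano(intens, labels)
        flipped = labels.map({"low": "high", "high": "low"})
        res2 = so.volcano(intens, flipped)
        assert np.allclose(res["log2_fc"], -res2["log2_fc"], atol=1e-12)
        assert np.allclose(res["p_value"], res2["p_value"], atol=1e-12)

    def test_q_values_dominate_p_values(self):
        intens, labels = self.make_intensities(seed=6)
        res = so.volcano(intens, labels)
        assert (res["q_value"] >= res["p_value"] - 1e-15).all()

    def test_tiny_class_rejected(self):
        intens, labels = self.make_intensities()
        labels.iloc[:] = "high"
        labels.iloc[0] = "low"
        with pytest.raises(ValueError):
            so.volcano(intens, labels)

    def test_planted_table_effect_detected_end_to_end(self):
        table, truth = make_table(n_discriminant=4, effect_log2=1.0,
                                  noise_cv=0.05, seed=21)
        mask = table.role_mask("study").to_numpy()
        res = so.volcano(
            table.intensities.loc[mask],
            table.sample_meta.loc[mask, "ts_class"],
        )
        planted = list(truth.discriminant_features)
        assert (res.loc[planted, "q_value"] < 0.01).all()
        assert res.loc[planted, "log2_fc"].min() > 0.8
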