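"""Factorial ANOVA routing, Tukey letters, Cochran/Shapiro checks, Pearson bands."""

import itertools

import numpy as np
import pandas as pd
import pytest

from canopytherm.stats import (
    FactorialAnova,
    cochran_c,
    compact_letters,
    factorial_analysis,
    interpret_r,
    oneway_tukey,
    pearson_report,
)


def _design_frame(rng, genotype_means, treatment_offset, interaction=None, sd=0.5, n=5):
    """Balanced 2 x G data set from programmed cell means."""
    rows = []
    for g, mu in genotype_means.items():
        for t in ("control", "drought"):
            cell = mu + (treatment_offset if t == "drought" else 0.0)
            if interaction and t == "drought":
                cell += interaction.get(g, 0.0)
            for r in range(n):
                rows.append(
                    {
                        "genotype": g,
                        "treatment": t,
                        "replicate": r + 1,
                        "y": cell + rng.normal(0, sd),
                    }
                )
    return pd.DataFrame(rows)


class TestCochranC:
    def test_homogeneous_variances_not_flagged(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(0, 1, 10) for _ in range(5)]
        c, p = cochran_c(groups)
        assert 0 < c < 0.5 and p > 0.05

    def test_one_inflated_variance_flagged(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 0.2, 10) for _ in range(4)] + [rng.normal(0, 5, 10)]
        c, p = cochran_c(groups)
        assert c > 0.9 and p < 0.01

    def test_all_constant_groups(self):
        c, p = cochran_c([np.full(5, 2.0), np.full(5, 3.0)])
        assert (c, p) == (0.0, 1.0)


def _letters_valid(letters: dict, pmat: pd.DataFrame, alpha: float) -> bool:
    """Validity oracle: share a letter <=> pairwise p > alpha, every group lettered."""
    for g in pmat.index:
        if not letters[g]:
            return False
    for a, b in itertools.combinations(list(pmat.index), 2):
        share = bool(set(letters[a]) & set(letters[b]))
        if share != (pmat.loc[a, b] > alpha):
            return False
    return True


class TestCompactLetters:
    def _pmat(self, names, sig_pairs, alpha=0.05):
        k = len(names)
        m = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
        for a, b in sig_pairs:
            m.loc[a, b] = m.loc[b, a] = alpha / 2
        return m

    def test_all_pairs_significant_gives_distinct_letters(self):
        m = self._pmat(list("XYZ"), [("X", "Y"), ("X", "Z"), ("Y", "Z")])
        assert compact_letters(m) == {"X": "a", "Y": "b", "Z": "c"}

    def test_no_pair_significant_shares_one_letter(self):
        m = self._pmat(list("XYZ"), [])
        assert compact_letters(m) == {"X": "a", "Y": "a", "Z": "a"}

    def test_chain_pattern_a_ab_b(self):
        # only the extreme pair differs: the middle group bridges both
        m = self._pmat(list("XYZ"), [("X", "Z")])
        assert compact_letters(m) == {"X": "a", "Y": "ab", "Z": "b"}

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_random_pmatrices_satisfy_sharing_iff_rule(self, k):
        rng = np.random.default_rng(k)
        names = [f"g{i}" for i in range(k)]
        for _ in range(60):
            tri = rng.random((k, k))
            m = pd.DataFrame(np.triu(tri, 1) + np.triu(tri, 1).T + np.eye(k),
                             index=names, columns=names)
            letters = compact_letters(m, alpha=0.5)  # dense significance mix
            assert _letters_valid(letters, m, 0.5)

    def test_asymmetric_matrix_rejected(self):
        m = pd.DataFrame([[1.0, 0.1], [0.9, 1.0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError, match="symmetric"):
            compact_letters(m)


class TestFactorialRouting:
    def test_interaction_routes_within_treatment(self):
        rng = np.random.default_rng(10)
        means = {"G1": 28.0, "G2": 28.0, "G3": 28.0, "G4": 28.0}
        inter = {"G1": 5.0, "G2": 3.0, "G3": 1.0, "G4": 1.0}
        df = _design_frame(rng, means, treatment_offset=0.0, interaction=inter, sd=0.3)
        res = factorial_analysis(df, "y")
        assert res.routing == "compare_within_treatment"
        assert res.interaction_p <= 0.05
        assert set(res.letters) == {"control", "drought"}

    def test_pure_treatment_effect_routes_between_treatments(self):
        rng = np.random.default_rng(11)
        means = {g: 28.0 for g in ("G1", "G2", "G3", "G4")}
        df = _design_frame(rng, means, treatment_offset=2.0, sd=0.5)
        res = factorial_analysis(df, "y")
        assert res.routing == "compare_between_treatments"
        assert res.treatment_p <= 0.05
        # each genotype family compares its two treatments
        assert set(res.letters) == {"G1", "G2", "G3", "G4"}
        for fam in res.letters.values():
            assert fam["control"] != fam["drought"]

    def test_treatment_effect_power(self):
        # programmed effect ~4 sd/sqrt(n): detected in >= 95% of simulations
        rng = np.random.default_rng(12)
        sd, n = 0.5, 5
        effect = 4 * sd / np.sqrt(n)
        means = {g: 28.0 for g in ("G1", "G2", "G3", "G4")}
        hits = routed = 0
        B = 100
        for _ in range(B):
            df = _design_frame(rng, means, treatment_offset=effect, sd=sd, n=n)
            res = factorial_analysis(df, "y")
            hits += res.treatment_p <= 0.05
            routed += res.routing == "compare_between_treatments"
        assert hits / B >= 0.95
        assert routed / B >= 0.90  # interaction is null: rarely flagged

    def test_constant_cells_share_single_letter(self):
        rows = [
            {"genotype": g, "treatment": t, "replicate": r, "y": 30.0}
            for g in ("G1", "G2")
            for t in ("control", "drought")
            for r in (1, 2, 3)
        ]
        res = factorial_analysis(pd.DataFrame(rows), "y")
        assert res.routing == "compare_between_treatments"
        for fam in res.letters.values():
            assert fam["control"] == fam["drought"] == "a"

    def test_empty_and_underfilled_cells_rejected(self):
        rng = np.random.default_rng(13)
        df = _design_frame(rng, {"G1": 28.0, "G2": 29.0}, 1.0, n=3)
        with pytest.raises(ValueError, match="empty design cell"):
            factorial_analysis(df[~((df.genotype == "G2") & (df.treatment == "drought"))], "y")
        drop_one = df.drop(df[(df.genotype == "G2") & (df.treatment == "drought")].index[:2])
        with pytest.raises(ValueError, match="need >= 2"):
            factorial_analysis(drop_one, "y")

    def test_model_object_api(self):
        rng = np.random.default_rng(14)
        df = _design_frame(rng, {"G1": 28.0, "G2": 30.0}, 1.0)
        res = FactorialAnova(df, "y", alpha=0.05).fit()
        text = res.summary()
        assert "Routing" in text and "Cochran" in text


class TestOnewayTukey:
    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        groups = {
            "A": rng.normal(5.0, 0.3, 5),
            "B": rng.normal(3.0, 0.3, 5),
            "C": rng.normal(1.0, 0.3, 5),
            "D": rng.normal(1.0, 0.3, 5),
        }
        _, pmat, letters = oneway_tukey(groups)
        assert letters["A"] == "a" and letters["B"] == "b"
        assert letters["C"] == letters["D"] == "c"
        assert _letters_valid(letters, pmat, 0.05)


class TestPearson:
    def _frame(self, x, y):
        return pd.DataFrame({"x": x, "y": y})

    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        rep = pearson_report(self._frame(x, 2 * x), ["x", "y"])
        assert rep.r_matrix.loc["x", "y"] == pytest.approx(1.0)
        assert rep.interpretation_matrix.loc["x", "y"] == "very high positive"

    @pytest.mark.parametrize(
        "r,band",
        [
            (0.1, "negligible"), (0.3, "low"), (0.45, "low"), (0.5, "moderate"),
            (0.6, "moderate"), (0.7, "high"), (0.89, "high"), (0.9, "very high"),
            (1.0, "very high"), (-0.6, "moderate"),
        ],
    )
    def test_interpretation_bands(self, r, band):
        out = interpret_r(r)
        assert out.band == band
        if r < 0:
            assert out.direction == "negative"

    def test_small_sample_bias_region_monte_carlo(self):
        rng = np.random.default_rng(20)
        rho, n = 0.8, 40
        rs, labels = [], []
        for _ in range(500):
            x = rng.normal(0, 1, n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
            rep = pearson_report(self._frame(x, y), ["x", "y"])
            r = rep.r_matrix.loc["x", "y"]
            rs.append(r)
            labels.append(interpret_r(r).band)
        assert abs(np.mean(rs) - 0.79) <= 0.05
        assert labels.count("high") / len(labels) > 0.5

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0, 1, 30)
        y = 0.7 * x + rng.normal(0, 0.5, 30)
        base = pearson_report(self._frame(x, y), ["x", "y"]).r_matrix.loc["x", "y"]
        scaled = pearson_report(self._frame(3 * x + 7, 0.1 * y - 2), ["x", "y"])
        flipped = pearson_report(self._frame(x, -y), ["x", "y"])
        assert scaled.r_matrix.loc["x", "y"] == pytest.approx(base, abs=1e-12)
        assert flipped.r_matrix.loc["x", "y"] == pytest.approx(-base, abs=1e-12)

    def test_zero_variance_reported_na_with_warning(self):
        df = self._frame(np.arange(5.0), np.full(5, 2.0))
        with pytest.warns(UserWarning, match="zero variance"):
            rep = pearson_report(df, ["x", "y"])
        assert np.isnan(rep.r_matrix.loc["x", "y"])
        assert rep.interpretation_matrix.loc["x", "y"] == "NA"

    def test_too_few_observations_rejected(self):
        df = self._frame([1.0, 2.0], [2.0, 4.0])
        with pytest.raises(ValueError, match=">= 3"):
            pearson_report(df, ["x", "y"])
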