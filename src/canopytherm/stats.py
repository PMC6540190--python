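"""Factorial statistics for the genotype x treatment experiment.

The experimental design is a completely randomized two-factor layout:
treatment (control, drought) crossed with genotype, n replicate pots per
cell. For each response the module runs variance-homogeneity (Cochran's C)
and residual-normality (Shapiro-Wilk) checks as non-blocking warnings, a
two-way fixed-effects ANOVA, and then routes the mean comparisons the way a
factorial analysis should:

* interaction significant  -> genotypes are compared *within* each treatment;
* only main effects        -> treatments are compared per genotype.

Pairwise comparisons use Tukey's studentized-range test at the error degrees
of freedom of the full two-way model, and the outcome is condensed into a
compact letter display: groups sharing a letter are not significantly
different. Pearson correlations between responses are reported with the
conventional interpretation bands (|r| < 0.30 negligible, then low, moderate,
high, very high in 0.20-wide steps up to 0.90-1.00).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AnalysisResult",
    "FactorialAnova",
    "factorial_analysis",
    "oneway_tukey",
    "compact_letters",
    "cochran_c",
    "CorrelationReport",
    "pearson_report",
    "interpret_r",
]


def cochran_c(groups: list[np.ndarray]) -> tuple[float, float]:
    """Cochran's C test of variance homogeneity across groups.

    C is the largest group variance over the sum of group variances. The
    p-value uses the standard Bonferroni bound through the F distribution:
    with k groups of (average) size n, F = (k-1) C / (1 - C) follows
    F(n-1, (k-1)(n-1)) under the null for the maximal variance.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    variances = np.array([g.var(ddof=1) for g in groups])
    total = variances.sum()
    if total == 0:
        return 0.0, 1.0
    k = len(groups)
    c = float(variances.max() / total)
    n_bar = np.mean([len(g) for g in groups])
    if c >= 1.0:
        return c, 0.0
    f = (k - 1) * c / (1.0 - c)
    p = min(1.0, k * sps.f.sf(f, n_bar - 1, (k - 1) * (n_bar - 1)))
    return c, float(p)


# ---------------------------------------------------------------------------
# Compact letter display


def compact_letters(pairwise_p: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Assign letters so groups share a letter iff their pairwise p > alpha.

    Insert-and-absorb: start from one letter column holding all groups; for
    every significant pair, split each column containing both members into
    two columns (one without each member); absorb columns that became subsets
    of another. Letters are assigned to the surviving columns in order of
    their first group.

    Parameters
    ----------
    pairwise_p : DataFrame
        Symmetric matrix of adjusted p-values, index == columns == group names.
    """
    if not pairwise_p.index.equals(pairwise_p.columns):
        raise ValueError("pairwise_p must be square with matching index/columns")
    groups = list(pairwise_p.index)
    vals = pairwise_p.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, equal_nan=True):
        raise ValueError("pairwise_p must be symmetric")

    columns: list[set[int]] = [set(range(len(groups)))]
    for i, j in itertools.combinations(range(len(groups)), 2):
        if vals[i, j] > alpha:
            continue  # not significant: may share
        new_cols: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                new_cols.append(col - {i})
                new_cols.append(col - {j})
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another (keeps maximal sets)
        columns = []
        for col in new_cols:
            if any(col < other or (col == other and col in columns) for other in new_cols):
                continue
            if col not in columns:
                columns.append(col)

    columns.sort(key=lambda col: (min(col), sorted(col)))
    if len(columns) > 52:
        raise ValueError("more letter columns than available letters")
    alphabet = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for idx in sorted(col):
            out[groups[idx]] += letter
    return out


# ---------------------------------------------------------------------------
# Two-way factorial analysis


@dataclass
class AnalysisResult:
    """Outcome of the factorial analysis of one response variable."""

    response: str
    alpha: float
    homogeneity_c: float
    homogeneity_p: float
    normality_p: float
    anova_table: pd.DataFrame
    routing: str  # "compare_within_treatment" | "compare_between_treatments"
    tukey_pairs: dict[str, pd.DataFrame]
    pairwise_p: dict[str, pd.DataFrame]
    letters: dict[str, dict[str, str]]
    notes: list[str] = field(default_factory=list)

    @property
    def interaction_p(self) -> float:
        return float(self.anova_table.loc["treatment:genotype", "PR(>F)"])

    @property
    def treatment_p(self) -> float:
        return float(self.anova_table.loc["treatment", "PR(>F)"])

    @property
    def genotype_p(self) -> float:
        return float(self.anova_table.loc["genotype", "PR(>F)"])

    def summary(self) -> str:
        lines = [
            f"Factorial analysis of {self.response} (alpha={self.alpha})",
            "=" * 60,
            f"Cochran C = {self.homogeneity_c:.3f} (p = {self.homogeneity_p:.4f}); "
            f"Shapiro-Wilk residual p = {self.normality_p:.4f}",
            "",
            self.anova_table.to_string(),
            "",
            f"Routing: {self.routing}",
        ]
        for family, letters in self.letters.items():
            pretty = ", ".join(f"{g}: {v}" for g, v in letters.items())
            lines.append(f"  [{family}] {pretty}")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def _check_design(data: pd.DataFrame, response: str) -> pd.DataFrame:
    for col in ("treatment", "genotype", response):
        if col not in data.columns:
            raise ValueError(f"records lack required column '{col}'")
    data = data.dropna(subset=[response])
    counts = data.groupby(["treatment", "genotype"], observed=True)[response].count()
    treatments = data["treatment"].unique()
    genotypes = data["genotype"].unique()
    for t in treatments:
        for g in genotypes:
            n = counts.get((t, g), 0)
            if n == 0:
                raise ValueError(f"empty design cell: treatment={t}, genotype={g}")
            if n < 2:
                raise ValueError(
                    f"cell treatment={t}, genotype={g} has {n} replicate(s); need >= 2"
                )
    return data


def _tukey_table(
    means: pd.Series, ns: pd.Series, mse: float, df_resid: float, k_family: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Tukey(-Kramer) comparisons among the groups in `means`."""
    names = list(means.index)
    rows = []
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        diff = means[a] - means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0:
            q = np.inf if diff != 0 else 0.0
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k_family, df_resid))
        rows.append({"group1": a, "group2": b, "diff": diff, "q": q, "p_adj": p})
        pmat.loc[a, b] = pmat.loc[b, a] = p
    return pd.DataFrame(rows), pmat


class FactorialAnova:
    """Two-way fixed-effects model for one response, statsmodels-style.

    ``FactorialAnova(records, "CT").fit()`` returns an
    :class:`AnalysisResult` carrying the ANOVA table, assumption checks,
    interaction-dependent Tukey comparisons, and compact letter displays.
    """

    def __init__(self, data: pd.DataFrame, response: str, alpha: float = 0.05):
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.data = _check_design(data.copy(), response)
        self.response = response
        self.alpha = alpha

    def fit(self) -> AnalysisResult:
        data = self.data.rename(columns={self.response: "_y"})
        model = ols("_y ~ C(treatment) * C(genotype)", data=data).fit()
        table = anova_lm(model, typ=2)
        table = table.rename(
            index={
                "C(treatment)": "treatment",
                "C(genotype)": "genotype",
                "C(treatment):C(genotype)": "treatment:genotype",
            }
        )
        notes: list[str] = []

        cells = [g.to_numpy() for _, g in data.groupby(["treatment", "genotype"], observed=True)["_y"]]
        c_stat, c_p = cochran_c(cells)
        if c_p <= self.alpha:
            notes.append(
                f"variance homogeneity questionable (Cochran C p = {c_p:.4f}); "
                "analysis proceeds"
            )
        resid = model.resid.to_numpy()
        if np.allclose(resid, resid[0]):
            sw_p = 1.0  # constant residuals: normality test undefined, treat as pass
        else:
            sw_p = float(sps.shapiro(resid).pvalue)
        if sw_p <= self.alpha:
            notes.append(
                f"residual normality questionable (Shapiro-Wilk p = {sw_p:.4f}); "
                "analysis proceeds"
            )

        mse = float(model.mse_resid)
        df_resid = float(model.df_resid)
        inter_p = float(table.loc["treatment:genotype", "PR(>F)"])

        tukey_pairs: dict[str, pd.DataFrame] = {}
        pairwise: dict[str, pd.DataFrame] = {}
        letters: dict[str, dict[str, str]] = {}
        if inter_p <= self.alpha:
            routing = "compare_within_treatment"
            genotypes = list(pd.unique(data["genotype"]))
            for t, sub in data.groupby("treatment", observed=True):
                means = sub.groupby("genotype", observed=True)["_y"].mean().reindex(genotypes)
                ns = sub.groupby("genotype", observed=True)["_y"].count().reindex(genotypes)
                tab, pmat = _tukey_table(means, ns, mse, df_resid, len(genotypes))
                tukey_pairs[str(t)] = tab
                pairwise[str(t)] = pmat
                letters[str(t)] = compact_letters(pmat, self.alpha)
        else:
            routing = "compare_between_treatments"
            for g, sub in data.groupby("genotype", observed=True):
                means = sub.groupby("treatment", observed=True)["_y"].mean()
                ns = sub.groupby("treatment", observed=True)["_y"].count()
                tab, pmat = _tukey_table(means, ns, mse, df_resid, 2)
                tukey_pairs[str(g)] = tab
                pairwise[str(g)] = pmat
                letters[str(g)] = compact_letters(pmat, self.alpha)

        return AnalysisResult(
            response=self.response,
            alpha=self.alpha,
            homogeneity_c=c_stat,
            homogeneity_p=c_p,
            normality_p=sw_p,
            anova_table=table,
            routing=routing,
            tukey_pairs=tukey_pairs,
            pairwise_p=pairwise,
            letters=letters,
            notes=notes,
        )


def factorial_analysis(
    records: pd.DataFrame, response: str, alpha: float = 0.05
) -> AnalysisResult:
    """Convenience wrapper: ``FactorialAnova(records, response, alpha).fit()``."""
    return FactorialAnova(records, response, alpha).fit()


def oneway_tukey(
    values_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """One-way Tukey HSD across groups (used for genotype deltaCT contrasts).

    Returns the pairwise comparison table, the symmetric adjusted-p matrix,
    and the compact letter display.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in values_by_group.items()}
    if any(len(a) < 2 for a in arrays.values()):
        raise ValueError("every group needs at least two observations")
    n_total = sum(len(a) for a in arrays.values())
    df_resid = n_total - len(names)
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    mse = sse / df_resid
    means = pd.Series({k: a.mean() for k, a in arrays.items()})
    ns = pd.Series({k: len(a) for k, a in arrays.items()})
    tab, pmat = _tukey_table(means, ns, mse, df_resid, len(names))
    return tab, pmat, compact_letters(pmat, alpha)


# ---------------------------------------------------------------------------
# Pearson correlation with interpretation bands


class InterpretedR(NamedTuple):
    band: str
    direction: str
    label: str


_BANDS = [
    (0.30, "negligible"),
    (0.50, "low"),
    (0.70, "moderate"),
    (0.90, "high"),
    (np.inf, "very high"),
]


def interpret_r(r: float) -> InterpretedR:
    """Interpretation band for a Pearson coefficient.

    |r| in [0, 0.30) is negligible; [0.30, 0.50) low; [0.50, 0.70) moderate;
    [0.70, 0.90) high; [0.90, 1.00] very high. Boundaries belong to the upper
    band. The direction (positive/negative) qualifies the label whenever
    r != 0.
    """
    if np.isnan(r):
        return InterpretedR("NA", "", "NA")
    if abs(r) > 1 + 1e-12:
        raise ValueError(f"|r| must be <= 1, got {r}")
    mag = abs(r)
    for bound, band in _BANDS:
        if mag < bound:
            break
    direction = "positive" if r > 0 else "negative" if r < 0 else ""
    label = f"{band} {direction}".strip()
    return InterpretedR(band, direction, label)


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations with banded interpretation."""

    variables: list[str]
    r_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    n_matrix: pd.DataFrame
    interpretation_matrix: pd.DataFrame

    def summary(self) -> str:
        lines = ["Pearson correlation report", "=" * 40, self.r_matrix.round(3).to_string()]
        return "\n".join(lines)


def pearson_report(records: pd.DataFrame, variables: list[str]) -> CorrelationReport:
    """Pairwise Pearson r, two-sided p, and interpretation for chosen variables.

    Pairs with fewer than 3 complete observations or a zero-variance member
    are reported as NA with a warning.
    """
    missing = [v for v in variables if v not in records.columns]
    if missing:
        raise ValueError(f"variables not in records: {missing}")
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=variables, columns=variables)
    for v in variables:
        n.loc[v, v] = records[v].notna().sum()
    for a, b in itertools.combinations(variables, 2):
        sub = records[[a, b]].dropna()
        n.loc[a, b] = n.loc[b, a] = len(sub)
        if len(sub) < 3:
            raise ValueError(f"pair ({a}, {b}) has {len(sub)} complete observations; need >= 3")
        if sub[a].var() == 0 or sub[b].var() == 0:
            warnings.warn(
                f"zero variance in pair ({a}, {b}); correlation undefined (NA)",
                stacklevel=2,
            )
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        res = sps.pearsonr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
    interp = r.map(lambda v: interpret_r(v).label)
    for v in variables:
        interp.loc[v, v] = "—"
    return CorrelationReport(
        variables=list(variables),
        r_matrix=r,
        p_matrix=p,
        n_matrix=n,
        interpretation_matrix=interp,
    )
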