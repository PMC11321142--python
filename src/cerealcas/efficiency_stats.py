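"""Editing-efficiency statistics: binomial GLMs, crossed ANOVA, summaries.

Mutagenesis outcomes come in two modes.  In Sanger mode each T0 plant is
scored mutated / not mutated per gene; proportions of mutated plants are
compared between constructs with a binomial GLM (logit link) and nested
models are tested with chi-squared likelihood-ratio tests.  In Illumina
mode each plant carries a percentage of mutant alleles per locus; those
percentages are analysed by crossed analysis of variance (sequential,
type-I sums of squares, e.g. Gene * CDS).

Aggregation conventions:

* per-gene efficiency = 100 * k / n mutated plants;
* a construct's mean efficiency is the unweighted mean over its genes and
  the quoted standard error is sd(per-gene %) / sqrt(#genes);
* the all-targets rate is the percentage of plants mutated in every gene
  the construct targets — with nested outcomes (active plants edit every
  accessible target) it equals the lowest per-gene efficiency;
* display percentages round to the nearest integer, raw values are kept.

The synergy decomposition quantifies whether two enhancements (e.g. the
D156R temperature-tolerance mutation and intron-mediated enhancement of a
Cas12a coding sequence) combine super-additively: with efficiencies for
the base CDS, each single enhancement and the combination,
``synergy = combined - base - delta_a - delta_b``.  When the base activity
is indistinguishable from the assay's wild-type artifact floor the
relevant figure is ``enhancement_gain = combined - delta_a - delta_b``,
the gain of the combination over the summed single enhancements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "T0Outcome",
    "outcomes_frame",
    "binarize",
    "proportion_table",
    "BinomialGLMFit",
    "fit_binomial_glm",
    "LRTResult",
    "lrt",
    "AnovaTable",
    "anova_crossed",
    "EfficiencySummary",
    "summarize",
    "aggregate_per_gene",
    "SynergyDecomposition",
    "synergy",
    "plot_construct_means",
]

#: mutant-allele percentage above which a plant counts as mutated when
#: binary summaries are requested from Illumina-mode data (set above the
#: few-percent wild-type artifact floor of amplicon assays)
DEFAULT_BINARY_THRESHOLD = 10.0


@dataclass(frozen=True)
class T0Outcome:
    """One plant x gene record; exactly one of ``mutated`` (Sanger mode)
    and ``pct_mutant_alleles`` (Illumina mode) is present."""

    plant_id: str
    construct: str
    gene: str
    mutated: bool | None = None
    pct_mutant_alleles: float | None = None

    def __post_init__(self) -> None:
        if (self.mutated is None) == (self.pct_mutant_alleles is None):
            raise ValueError("exactly one of mutated / pct_mutant_alleles required")
        if self.pct_mutant_alleles is not None and not (
                0.0 <= self.pct_mutant_alleles <= 100.0):
            raise ValueError("pct_mutant_alleles must be in [0, 100]")


def outcomes_frame(outcomes) -> pd.DataFrame:
    """List of T0Outcome -> tidy DataFrame (passes DataFrames through)."""
    if isinstance(outcomes, pd.DataFrame):
        return outcomes
    return pd.DataFrame([vars(o) for o in outcomes])


def binarize(df: pd.DataFrame,
             threshold: float = DEFAULT_BINARY_THRESHOLD) -> pd.DataFrame:
    """Illumina-mode table -> Sanger-mode table via a mutant-allele
    percentage threshold."""
    out = df.copy()
    out["mutated"] = out["pct_mutant_alleles"] > threshold
    return out.drop(columns=["pct_mutant_alleles"])


def proportion_table(df: pd.DataFrame,
                     by=("construct", "gene")) -> pd.DataFrame:
    """(construct, gene) -> (k mutated, n plants)."""
    df = outcomes_frame(df)
    grouped = df.groupby(list(by))["mutated"].agg(k="sum", n="count").reset_index()
    grouped["k"] = grouped["k"].astype(int)
    return grouped


@dataclass(frozen=True)
class LRTResult:
    term: str
    chi2: float
    df: int
    p: float


@dataclass
class BinomialGLMFit:
    """Sequence of nested binomial-logit fits, one per added term.

    ``models[i]`` is the statsmodels result after adding ``terms[:i]``
    (``models[0]`` is the intercept-only fit).
    """

    terms: tuple
    models: list
    formulas: list

    @property
    def deviance(self) -> float:
        return float(self.models[-1].deviance)

    @property
    def result(self):
        return self.models[-1]

    def term_tests(self) -> list[LRTResult]:
        """Sequential likelihood-ratio chi-squared test for each term."""
        out = []
        for i, term in enumerate(self.terms):
            null, full = self.models[i], self.models[i + 1]
            chi2 = max(0.0, float(null.deviance - full.deviance))
            df = int(full.df_model - null.df_model)
            out.append(LRTResult(term, chi2, df,
                                 float(sps.chi2.sf(chi2, df)) if df else 1.0))
        return out


def _fit_one(endog, formula: str, data: pd.DataFrame):
    X = patsy.dmatrix(formula, data, return_type="dataframe")
    model = sm.GLM(endog, np.asarray(X), family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    return res


def fit_binomial_glm(table: pd.DataFrame, terms) -> BinomialGLMFit:
    """Fit a binomial GLM (logit link) to a (k, n) proportion table.

    ``terms`` is the ordered list of factor columns, e.g. ["gene",
    "construct"]; nested fits are kept so sequential likelihood-ratio
    tests can be read off.  Quasi-complete separation (all-0 or all-n
    cells) is handled by a half-count continuity adjustment with a
    warning.
    """
    terms = tuple(terms)
    for t in terms:
        if table[t].nunique() < 2:
            raise ValueError(f"factor {t!r} needs >= 2 levels")
    k = table["k"].to_numpy(float)
    n = table["n"].to_numpy(float)
    if np.any(k < 0) or np.any(k > n) or np.any(n < 1):
        raise ValueError("need 0 <= k <= n and n >= 1 in the proportion table")
    endog = np.column_stack([k, n - k])
    separated = bool(np.any((k == 0) | (k == n)))
    if separated:
        warnings.warn(
            "complete/quasi-complete separation in the proportion table; "
            "applying a half-count continuity adjustment",
            stacklevel=2,
        )
        endog = np.column_stack([k + 0.5, n - k + 0.5])

    formulas = ["1"]
    for i in range(len(terms)):
        formulas.append(" + ".join(["1"] + [f"C({t})" for t in terms[:i + 1]]))
    models = []
    for f in formulas:
        res = _fit_one(endog, f, table)
        if not res.converged:
            raise RuntimeError(
                f"binomial GLM failed to converge for formula {f!r}: "
                f"{res.mle_retvals if hasattr(res, 'mle_retvals') else res}"
            )
        models.append(res)
    return BinomialGLMFit(terms, models, formulas)


def lrt(null, full, term: str = "model") -> LRTResult:
    """Likelihood-ratio chi-squared test between two nested binomial fits.

    Accepts :class:`BinomialGLMFit` objects or raw statsmodels results;
    the null's terms must be a prefix/subset of the full model's.
    """
    def _dev_df(fit):
        if isinstance(fit, BinomialGLMFit):
            return float(fit.deviance), int(fit.result.df_model), set(fit.terms)
        return float(fit.deviance), int(fit.df_model), None

    dev0, df0, t0 = _dev_df(null)
    dev1, df1, t1 = _dev_df(full)
    if t0 is not None and t1 is not None and not t0 <= t1:
        raise ValueError(f"models are not nested: {t0} vs {t1}")
    df = df1 - df0
    if df < 0:
        raise ValueError("null model has more parameters than the full model")
    chi2 = max(0.0, dev0 - dev1)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(term, chi2, df, p)


@dataclass(frozen=True)
class AnovaTable:
    """Sequential (type-I) ANOVA: (term, F, ndf, ddf, p) rows plus the
    sums of squares needed to verify the decomposition."""

    terms: tuple                        # ((name, F, ndf, ddf, p), ...)
    ss: tuple                           # per-term SS, same order
    ss_residual: float
    ss_total: float


def anova_crossed(df: pd.DataFrame, response: str = "pct_mutant_alleles",
                  factors: tuple[str, str] = ("gene", "construct")) -> AnovaTable:
    """Crossed two-factor ANOVA (A * B) on per-plant percentages with
    sequential sums of squares; every cell must be non-empty."""
    df = outcomes_frame(df)
    a, b = factors
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    cells = df.groupby([a, b]).size()
    full_index = pd.MultiIndex.from_product([df[a].unique(), df[b].unique()])
    missing = [c for c in full_index if c not in cells.index]
    if missing:
        raise ValueError(f"empty design cells: {missing}")
    data = df.rename(columns={response: "_y", a: "_a", b: "_b"})
    model = sm.formula.ols("_y ~ C(_a) * C(_b)", data=data).fit()
    tab = sm.stats.anova_lm(model, typ=1)
    ddf = int(tab.loc["Residual", "df"])
    names = {"C(_a)": a, "C(_b)": b, "C(_a):C(_b)": f"{a}:{b}"}
    rows, ss = [], []
    for idx, row in tab.iterrows():
        if idx == "Residual":
            continue
        rows.append((names[idx], float(row["F"]), int(row["df"]), ddf,
                     float(row["PR(>F)"])))
        ss.append(float(row["sum_sq"]))
    ss_res = float(tab.loc["Residual", "sum_sq"])
    y = data["_y"].to_numpy(float)
    ss_total = float(((y - y.mean()) ** 2).sum())
    return AnovaTable(tuple(rows), tuple(ss), ss_res, ss_total)


@dataclass(frozen=True)
class EfficiencySummary:
    per_gene: dict                      # (construct, gene) -> percentage
    mean_over_genes: dict               # construct -> percentage
    se_over_genes: dict                 # construct -> SE of the gene means
    all_targets: dict                   # construct -> % plants hit everywhere
    n_plants: dict                      # construct -> plants counted

    def rounded(self, which: str = "mean_over_genes") -> dict:
        """Display rounding to the nearest integer percent."""
        return {k: round(v) for k, v in getattr(self, which).items()}


def aggregate_per_gene(per_gene: dict) -> tuple[dict, dict]:
    """Mean and SE over genes from (construct, gene) -> percentage."""
    by_construct: dict[str, list[float]] = {}
    for (construct, _gene), pct in per_gene.items():
        by_construct.setdefault(construct, []).append(float(pct))
    means = {c: float(np.mean(v)) for c, v in by_construct.items()}
    ses = {
        c: (float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else float("nan"))
        for c, v in by_construct.items()
    }
    return means, ses


def summarize(outcomes) -> EfficiencySummary:
    """Per-construct efficiency summary from Sanger-mode outcomes.

    Plants lacking a record for one of the construct's genes are excluded
    from the all-targets rate (with a warning), not from per-gene rates.
    """
    df = outcomes_frame(outcomes)
    if df.empty:
        raise ValueError("no outcomes to summarise")
    table = proportion_table(df)
    per_gene = {
        (r.construct, r.gene): 100.0 * r.k / r.n for r in table.itertuples()
    }
    means, ses = aggregate_per_gene(per_gene)

    all_targets: dict[str, float] = {}
    n_plants: dict[str, int] = {}
    for construct, sub in df.groupby("construct"):
        genes = set(sub["gene"].unique())
        wide = sub.pivot_table(index="plant_id", columns="gene",
                               values="mutated", aggfunc="first")
        complete = wide.dropna()
        dropped = len(wide) - len(complete)
        if dropped:
            warnings.warn(
                f"{construct}: {dropped} plant(s) missing a gene record, "
                f"excluded from the all-targets rate",
                stacklevel=2,
            )
        n = len(complete)
        n_plants[construct] = n
        if n == 0:
            all_targets[construct] = float("nan")
        else:
            hit_all = complete[sorted(genes)].all(axis=1).sum()
            all_targets[construct] = 100.0 * float(hit_all) / n
    return EfficiencySummary(per_gene, means, ses, all_targets, n_plants)


@dataclass(frozen=True)
class SynergyDecomposition:
    base: float
    delta_a: float
    delta_b: float
    combined: float
    expected_additive: float
    synergy: float
    saturated: bool

    @property
    def enhancement_gain(self) -> float:
        """Gain of the combination over the summed single enhancements
        (= synergy + base); the relevant figure when the base efficiency
        sits at the assay's artifact floor."""
        return self.combined - self.delta_a - self.delta_b


def synergy(base: float, with_a: float, with_b: float,
            with_both: float) -> SynergyDecomposition:
    """Decompose the combined effect of two enhancements.

    All four inputs are efficiencies in [0, 100]: the base construct, each
    single enhancement, and the combination.  ``saturated`` flags designs
    whose additive expectation exceeds 100% — there the synergy cannot be
    measured because the single effects already hit the ceiling.
    """
    for v in (base, with_a, with_b, with_both):
        if not 0.0 <= v <= 100.0:
            raise ValueError("efficiencies must be percentages in [0, 100]")
    delta_a = with_a - base
    delta_b = with_b - base
    expected = base + delta_a + delta_b
    return SynergyDecomposition(
        base=base, delta_a=delta_a, delta_b=delta_b, combined=with_both,
        expected_additive=expected,
        synergy=with_both - base - delta_a - delta_b,
        saturated=expected > 100.0,
    )


def plot_construct_means(summary: EfficiencySummary, path=None):
    """Bar plot of per-construct mean efficiency with SE error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    constructs = sorted(summary.mean_over_genes)
    means = [summary.mean_over_genes[c] for c in constructs]
    ses = [summary.se_over_genes.get(c, float("nan")) for c in constructs]
    fig, ax = plt.subplots(figsize=(1.2 * len(constructs) + 2, 4))
    ax.bar(constructs, means, yerr=ses, capsize=4, color="#4c72b0")
    ax.set_ylabel("mean T0 mutagenesis efficiency (%)")
    ax.set_ylim(0, 105)
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
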