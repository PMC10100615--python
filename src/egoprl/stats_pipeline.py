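"""Questionnaire scoring, grouping, clustering and the regression suite.

All group comparisons use the unpaired two-sample Wilcoxon rank-sum test
and all correlations are Spearman, two-tailed at alpha = 0.05, matching
the non-normal score distributions typical of these instruments.  The two
headline regressions are ordinary least squares on the printed reduced
structures: a 7-predictor model of the psychopathology composite
(size, ties, kinship, belief and three two-way interactions) and a
13-predictor model of the initial volatility belief mu3_0 that includes
the paranoia x ties x belief three-way term.  Backward stepwise selection
under AIC, respecting marginality, reduces the corresponding full models.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "StatResult",
    "RegressionFit",
    "paranoia_group",
    "score_general",
    "score_covid",
    "psychopathology_composite",
    "mean_split",
    "elbow_kmeans",
    "pca_scores",
    "Term",
    "backward_stepwise",
    "fit_ols_terms",
    "fit_reduced_model_psych",
    "fit_reduced_model_mu30",
    "PSYCH_REDUCED_TERMS",
    "MU30_REDUCED_TERMS",
    "wilcoxon_rank_sum",
    "spearman",
    "bayes_factor_two_sample",
    "FEATURE_COLUMNS",
    "build_cohort_table",
    "analyze_cohort",
]

ALPHA = 0.05

#: the seven network features entering clustering and PCA
FEATURE_COLUMNS = ["size", "strong_ties", "density", "centralization",
                   "constraint", "kinship", "asb"]

Term = Tuple[str, ...]


@dataclass
class StatResult:
    statistic: float
    p_value: float
    name: str
    n: Tuple[int, ...] = ()


@dataclass
class RegressionFit:
    terms: List[Term]
    params: pd.Series
    pvalues: pd.Series
    fvalue: float
    f_pvalue: float
    df_model: int
    df_resid: int
    rsquared: float
    aic: float
    results: object = field(repr=False, default=None)

    def coef(self, term: Term) -> float:
        return float(self.params[_term_name(term)])


# ---------------------------------------------------------------- scoring

def paranoia_group(rgpts_b: float) -> str:
    """'high' iff the R-GPTS persecution (part B) score meets the clinical
    cutoff of 11."""
    return "high" if rgpts_b >= 11 else "low"


def score_general(items: Sequence[float]) -> float:
    """Sum of the five general-conspiracy items (each 1-5; range 5-25)."""
    items = np.asarray(items, dtype=float)
    if items.size != 5 or np.any(items < 1) or np.any(items > 5):
        raise ValueError("general-conspiracy scale takes five 1-5 responses")
    return float(items.sum())


def score_covid(items: Sequence[float]) -> float:
    """Sum of the five COVID-vaccine conspiracy items (each 1-7; range 5-35)."""
    items = np.asarray(items, dtype=float)
    if items.size != 5 or np.any(items < 1) or np.any(items > 7):
        raise ValueError("COVID-conspiracy scale takes five 1-7 responses")
    return float(items.sum())


def psychopathology_composite(bai: Sequence[float], bdi: Sequence[float],
                              paranoia: Sequence[float]) -> np.ndarray:
    """Mean of the within-cohort z-scores of anxiety, depression, paranoia."""
    arrs = [np.asarray(a, dtype=float) for a in (bai, bdi, paranoia)]
    zs = [stats.zscore(a) for a in arrs]
    return np.mean(zs, axis=0)


def mean_split(values: Sequence[float]) -> np.ndarray:
    """Label each value 'high' iff strictly above the mean (ties -> 'low')."""
    v = np.asarray(values, dtype=float)
    return np.where(v > v.mean(), "high", "low")


# ------------------------------------------------------- clustering / PCA

def elbow_kmeans(features: np.ndarray, k_range: Sequence[int] = range(1, 11),
                 n_init: int = 10, seed: int = 0):
    """Seeded k-means over ``k_range`` with automated elbow selection.

    The elbow is the k whose point on the (k, WCSS) curve lies farthest
    from the chord joining the curve's endpoints (a kneedle-style rule for
    "the bend in the plot").  Degenerate input (all rows identical) gives
    k* = 1.  Returns ``(k_star, labels, wcss_curve)``.
    """
    X = np.asarray(features, dtype=float)
    k_range = [k for k in k_range if 1 <= k < X.shape[0]]
    if not k_range:
        raise ValueError("k_range must contain at least one k in [1, n)")
    wcss = []
    labels_by_k = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        wcss.append(float(km.inertia_))
        labels_by_k[k] = km.labels_
    wcss = np.asarray(wcss)
    if wcss[0] <= 1e-12:           # all points identical
        k_star = 1 if 1 in labels_by_k else k_range[0]
        return k_star, labels_by_k[k_star], pd.Series(wcss, index=k_range, name="wcss")

    ks = np.asarray(k_range, dtype=float)
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    y = (wcss - wcss[-1]) / (wcss[0] - wcss[-1])
    # distance below the chord y = 1 - x, up to the constant 1/sqrt(2)
    dist = (1.0 - x) - y
    k_star = k_range[int(np.argmax(dist))]
    return k_star, labels_by_k[k_star], pd.Series(wcss, index=k_range, name="wcss")


def pca_scores(features: np.ndarray, standardize: bool = True):
    """Centered (optionally standardized) PCA of the feature matrix.

    Returns ``(loadings, scores, explained_variance_ratio)`` with loadings
    of shape (n_features, n_components), components orthonormal and
    explained variance nonincreasing.
    """
    X = np.asarray(features, dtype=float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    p = PCA()
    scores = p.fit_transform(X)
    return p.components_.T, scores, p.explained_variance_ratio_


# ------------------------------------------------------------ regression

def _term_name(term: Term) -> str:
    return ":".join(term)


def _design_matrix(data: pd.DataFrame, terms: Sequence[Term]) -> pd.DataFrame:
    cols = {}
    for term in terms:
        col = np.ones(len(data))
        for f in term:
            col = col * data[f].to_numpy(dtype=float)
        cols[_term_name(term)] = col
    X = pd.DataFrame(cols, index=data.index)
    X.insert(0, "Intercept", 1.0)
    return X


def fit_ols_terms(data: pd.DataFrame, response: str,
                  terms: Sequence[Term]) -> RegressionFit:
    """OLS fit of ``response`` on product terms of columns of ``data``."""
    terms = [tuple(t) for t in terms]
    X = _design_matrix(data, terms)
    if len(data) <= X.shape[1]:
        raise ValueError(
            f"n = {len(data)} observations cannot identify {X.shape[1]} parameters"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X.to_numpy())
        bad = [X.columns[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    res = sm.OLS(data[response].to_numpy(dtype=float), X).fit()
    return RegressionFit(
        terms=list(terms), params=res.params, pvalues=res.pvalues,
        fvalue=float(res.fvalue), f_pvalue=float(res.f_pvalue),
        df_model=int(res.df_model), df_resid=int(res.df_resid),
        rsquared=float(res.rsquared), aic=float(res.aic), results=res,
    )


def _droppable(terms: Sequence[Term]) -> List[Term]:
    """Terms not strictly contained in any other remaining term (marginality)."""
    out = []
    for t in terms:
        if not any(set(t) < set(u) for u in terms if u != t):
            out.append(t)
    return out


def check_marginality(terms: Sequence[Term]) -> None:
    terms = [tuple(t) for t in terms]
    have = {t for t in terms}
    for t in terms:
        if len(t) > 1:
            for sub_len in range(1, len(t)):
                for sub in itertools.combinations(t, sub_len):
                    if tuple(sub) not in have and not any(
                        set(sub) <= set(u) and len(u) < len(t) for u in have
                    ):
                        raise ValueError(
                            f"term {t} lacks marginal term {sub} in the full model"
                        )


def backward_stepwise(data: pd.DataFrame, response: str,
                      full_terms: Sequence[Term],
                      criterion: str = "aic") -> RegressionFit:
    """Backward elimination under an information criterion.

    Starting from the full model, repeatedly drop the single term whose
    removal most improves (lowers) the criterion, never dropping a main
    effect or lower-order interaction while a higher-order term containing
    it remains; stop when no removal improves.  Criterion is AIC by
    default ('bic' is also accepted).
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    terms = [tuple(t) for t in full_terms]
    check_marginality(terms)

    def crit(fit: RegressionFit) -> float:
        return fit.aic if criterion == "aic" else float(fit.results.bic)

    current = fit_ols_terms(data, response, terms)
    while True:
        best_fit, best_terms = None, None
        for t in _droppable(current.terms):
            cand_terms = [u for u in current.terms if u != t]
            cand = fit_ols_terms(data, response, cand_terms)
            if best_fit is None or crit(cand) < crit(best_fit):
                best_fit, best_terms = cand, cand_terms
        if best_fit is not None and crit(best_fit) < crit(current):
            current = best_fit
        else:
            return current


PSYCH_REDUCED_TERMS: List[Term] = [
    ("SIZE",), ("TIES",), ("KIN",), ("BELIEF",),
    ("SIZE", "TIES"), ("TIES", "KIN"), ("SIZE", "BELIEF"),
]

MU30_REDUCED_TERMS: List[Term] = [
    ("PARANOIA",), ("SIZE",), ("TIES",), ("KIN",), ("BELIEF",),
    ("PARANOIA", "SIZE"), ("PARANOIA", "TIES"), ("PARANOIA", "KIN"),
    ("PARANOIA", "BELIEF"), ("TIES", "BELIEF"), ("KIN", "BELIEF"),
    ("PARANOIA", "TIES", "BELIEF"), ("PARANOIA", "KIN", "BELIEF"),
]


def fit_reduced_model_psych(data: pd.DataFrame,
                            response: str = "psychopathology") -> RegressionFit:
    """The 7-predictor reduced psychopathology model.

    ``y ~ SIZE + TIES + KIN + BELIEF + SIZE:TIES + TIES:KIN + SIZE:BELIEF``.
    The SIZE:BELIEF coefficient is the protective size-by-assumed-shared-
    belief interaction of interest.
    """
    return fit_ols_terms(data, response, PSYCH_REDUCED_TERMS)


def fit_reduced_model_mu30(data: pd.DataFrame,
                           response: str = "mu30") -> RegressionFit:
    """The 13-predictor reduced volatility-prior model, including the
    PARANOIA:TIES:BELIEF three-way interaction."""
    return fit_ols_terms(data, response, MU30_REDUCED_TERMS)


# --------------------------------------------------------- simple tests

def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Unpaired two-sample Wilcoxon rank-sum test (midranks for ties),
    two-sided.  The statistic is the Mann-Whitney W for the first sample,
    as printed by R's ``wilcox.test``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return StatResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      name="wilcoxon_rank_sum", n=(x.size, y.size))


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation with two-sided p."""
    rho, p = stats.spearmanr(x, y)
    return StatResult(statistic=float(rho), p_value=float(p),
                      name="spearman", n=(len(x),))


def bayes_factor_two_sample(x: Sequence[float], y: Sequence[float],
                            r_scale: float = math.sqrt(2) / 2) -> float:
    """JZS default-prior Bayes factor (BF10) for a two-sample comparison.

    Cauchy prior with scale ``sqrt(2)/2`` on the standardized effect;
    BF10 < 1 favours the null of no group difference.
    """
    from pingouin import bayesfactor_ttest

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, _ = stats.ttest_ind(x, y)
    return float(bayesfactor_ttest(t, x.size, y.size, paired=False, r=r_scale))


# ------------------------------------------------------------- pipeline

def build_cohort_table(cohort_df: pd.DataFrame, features_df: pd.DataFrame,
                       fits_df: pd.DataFrame,
                       behavior_df: pd.DataFrame) -> pd.DataFrame:
    """Merge the per-ego products into the analysis table.

    Inputs are the questionnaire table (``cohort.csv``), the network
    feature table (``features.csv``), the HGF fit table (one row per
    ego x half with a ``mu3_0`` column) and the behavioural-rate table.
    The merged table adds the psychopathology composite and the analysis
    aliases SIZE/TIES/KIN/BELIEF/PARANOIA (z-scored features), with
    ``mu30`` taken from the first-half fit.
    """
    fits_first = fits_df[fits_df["half"] == "first"][["ego_id", "mu3_0"]].rename(
        columns={"mu3_0": "mu30_first"})
    fits_second = fits_df[fits_df["half"] == "second"][["ego_id", "mu3_0"]].rename(
        columns={"mu3_0": "mu30_second"})
    tab = (cohort_df
           .merge(features_df, on="ego_id", how="inner")
           .merge(fits_first, on="ego_id", how="left")
           .merge(fits_second, on="ego_id", how="left")
           .merge(behavior_df, on="ego_id", how="left"))
    tab["mu30"] = tab["mu30_first"]
    tab["psychopathology"] = psychopathology_composite(
        tab["bai"], tab["bdi"], tab["rgpts_total"])

    def z(col: str) -> np.ndarray:
        v = tab[col].to_numpy(dtype=float)
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    tab["SIZE"] = z("size")
    tab["TIES"] = z("strong_ties")
    tab["KIN"] = z("kinship")
    tab["BELIEF"] = z("asb")
    tab["PARANOIA"] = z("rgpts_total")
    return tab


def analyze_cohort(table: pd.DataFrame, seed: int = 0) -> Dict[str, object]:
    """Run the headline analysis suite on a merged cohort table.

    Group contrasts (high vs low paranoia) on mu3_0, win-switch and
    lose-stay; Spearman correlations of paranoia/conspiracy scores with
    mu3_0; k-means + elbow clustering of the seven network features with
    PCA; mean-split Bayes factors for assumed shared belief; and the two
    reduced regression models.  Returns a JSON-serialisable dict.
    """
    out: Dict[str, object] = {}
    hi = table[table["paranoia_group"] == "high"]
    lo = table[table["paranoia_group"] == "low"]

    for col in ("mu30", "win_switch", "lose_stay"):
        x, y = hi[col].dropna(), lo[col].dropna()
        r = wilcoxon_rank_sum(x, y)
        out[f"{col}_group"] = {
            "W": r.statistic, "p": r.p_value,
            "mean_high": float(x.mean()), "mean_low": float(y.mean()),
        }

    for label, a, b in [
        ("paranoia_mu30", "rgpts_total", "mu30"),
        ("paranoia_general", "rgpts_total", "general_score"),
        ("paranoia_covid", "rgpts_total", "covid_score"),
        ("paranoia_qanon", "rgpts_total", "qanon"),
        ("general_mu30", "general_score", "mu30"),
        ("covid_mu30", "covid_score", "mu30"),
        ("qanon_mu30", "qanon", "mu30"),
    ]:
        sub = table[[a, b]].dropna()
        r = spearman(sub[a], sub[b])
        out[f"rho_{label}"] = {"rho": r.statistic, "p": r.p_value}

    feats = table[FEATURE_COLUMNS].dropna()
    X = stats.zscore(feats.to_numpy(dtype=float), axis=0)
    k_star, labels, wcss = elbow_kmeans(X, seed=seed)
    _, _, evr = pca_scores(feats.to_numpy(dtype=float))
    out["clustering"] = {"k_star": int(k_star),
                         "wcss": {int(k): float(v) for k, v in wcss.items()},
                         "pc_variance_explained": [float(v) for v in evr[:2]]}

    split = mean_split(table["asb"].to_numpy(dtype=float))
    hi_b, lo_b = table[split == "high"], table[split == "low"]
    sub_hi, sub_lo = hi_b["mu30"].dropna(), lo_b["mu30"].dropna()
    out["bf10_asb_split_mu30"] = bayes_factor_two_sample(sub_hi, sub_lo)
    out["bf10_asb_split_psych"] = bayes_factor_two_sample(
        hi_b["psychopathology"].dropna(), lo_b["psychopathology"].dropna())

    psych = fit_reduced_model_psych(table.dropna(subset=["psychopathology"]))
    out["psych_model"] = {
        "F": psych.fvalue, "df": [psych.df_model, psych.df_resid],
        "p": psych.f_pvalue, "r2": psych.rsquared,
        "beta_size_belief": psych.coef(("SIZE", "BELIEF")),
    }
    mu_tab = table.dropna(subset=["mu30"])
    mu30 = fit_reduced_model_mu30(mu_tab)
    out["mu30_model"] = {
        "F": mu30.fvalue, "df": [mu30.df_model, mu30.df_resid],
        "p": mu30.f_pvalue, "r2": mu30.rsquared,
        "beta_paranoia_ties_belief": mu30.coef(("PARANOIA", "TIES", "BELIEF")),
    }
    return out
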