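"""Statistical comparisons across sex and social status.

Thin, reproducible contracts over established fitting routines:

* a linear mixed model on the square root of the pairwise Jaro values, with
  the nine-level dyad factor (distance type x sexes x status) as the fixed
  effect and dyad identity as a random intercept, tested against the
  random-only null by likelihood ratio (df = levels - 1);
* a linear mixed model on log normalized diversity with the three-level
  singer category as the fixed effect and crossed random intercepts for
  singer identity and song;
* an RBF-kernel SVM classifying singer categories from each contribution's
  profile of Jaro similarities to a training reference set, with (C, sigma)
  tuned by 10-fold cross-validation on a stratified 70% training split;
* a Kruskal-Wallis test of entropy rates across categories and the Spearman
  correlation of dominant-male vs dominant-female entropy rates by group.

Mixed models are fit with statsmodels' MixedLM.  Kenward-Roger denominator
degrees of freedom are not available in this backend; post-hoc (Tukey
adjusted, studentized-range) contrasts use a large-sample residual df
instead, and every report records the method actually used.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelFitReport",
    "ClassificationReport",
    "EntropyTestReport",
    "fit_distance_lmm",
    "fit_diversity_lmm",
    "svm_classify_categories",
    "entropy_group_tests",
]


@dataclasses.dataclass
class ModelFitReport:
    """Omnibus likelihood-ratio test and post-hoc contrasts for one LMM."""

    model_label: str
    response: str
    fixed_factor: str
    levels: tuple[str, ...]
    random_structure: str
    lrt_chi2: float
    lrt_df: int
    p_value: float
    posthoc: pd.DataFrame | None
    df_method: str
    converged: bool


def _tukey_posthoc(
    level_means: dict[str, float],
    cov: pd.DataFrame,
    coef_for_level: dict[str, np.ndarray],
    df_resid: float,
) -> pd.DataFrame:
    """All-pairs contrasts with studentized-range (Tukey) adjusted p-values."""
    levels = list(level_means)
    k = len(levels)
    rows = []
    C = cov.to_numpy()
    for a, b in itertools.combinations(levels, 2):
        L = coef_for_level[a] - coef_for_level[b]
        est = level_means[a] - level_means[b]
        se = float(np.sqrt(L @ C @ L))
        t = est / se if se > 0 else np.inf
        p_raw = 2.0 * stats.t.sf(abs(t), df_resid)
        p_adj = float(stats.studentized_range.sf(np.sqrt(2.0) * abs(t), k, df_resid))
        rows.append(
            {
                "contrast": f"{a} - {b}",
                "estimate": est,
                "se": se,
                "df": df_resid,
                "t": t,
                "p_raw": min(p_raw, 1.0),
                "p_adj": min(max(p_adj, p_raw), 1.0),
            }
        )
    return pd.DataFrame(rows)


def _fit_ml(model) -> object:
    """ML fit with an optimizer cascade.

    Powell avoids the costly analytic score evaluations and usually reaches
    the same optimum, but can wander into singular variance configurations
    or stop early; any failed or unconverged attempt falls through to the
    default (gradient) optimizer and the fit with the best log-likelihood
    wins.  An under-converged null fit would silently inflate the
    likelihood-ratio statistic, so convergence is not taken on trust.
    """
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for kwargs in ({"method": "powell", "maxiter": 2000}, {}):
            try:
                res = model.fit(reml=False, **kwargs)
            except Exception:
                continue
            if best is None or res.llf > best.llf:
                best = res
            if best.converged:
                break
    if best is None:
        raise RuntimeError("mixed-model fit failed with every optimizer")
    return best


def _posthoc_from_fit(result, factor: str, levels: list[str],
                      df_resid: float) -> pd.DataFrame:
    fe = result.fe_params
    names = list(fe.index)
    cov = result.cov_params().loc[names, names]
    coef_for_level: dict[str, np.ndarray] = {}
    level_means: dict[str, float] = {}
    for lev in levels:
        v = np.zeros(len(names))
        v[names.index("Intercept")] = 1.0
        term = f"C({factor})[T.{lev}]"
        if term in names:
            v[names.index(term)] = 1.0
        coef_for_level[lev] = v
        level_means[lev] = float(v @ fe.to_numpy())
    return _tukey_posthoc(level_means, cov, coef_for_level, df_resid)


def _distance_design(data: pd.DataFrame):
    """Fixed design + variance-component spec for the distance model."""
    from patsy import dmatrix
    from statsmodels.regression.mixed_linear_model import VCSpec

    n = len(data)
    dyad_codes = pd.Categorical(data["dyad_id"]).codes
    n_dyads = int(dyad_codes.max()) + 1
    Zd = np.zeros((n, n_dyads))
    Zd[np.arange(n), dyad_codes] = 1.0
    # multiple-membership indicator: each record loads on both of its
    # contributions with a shared variance parameter
    ia, ib = data["idx_a"].to_numpy(), data["idx_b"].to_numpy()
    n_contrib = int(max(ia.max(), ib.max())) + 1
    Zc = np.zeros((n, n_contrib))
    Zc[np.arange(n), ia] += 1.0
    Zc[np.arange(n), ib] += 1.0
    vcs = VCSpec(
        ["dyad", "contribution"],
        [[[f"dyad{i}" for i in range(n_dyads)]],
         [[f"contrib{i}" for i in range(n_contrib)]]],
        [[Zd], [Zc]],
    )
    Xf = dmatrix("C(category_factor)", data, return_type="dataframe")
    return Xf, vcs


def fit_distance_lmm(
    records: pd.DataFrame,
    posthoc: bool = True,
    contribution_re: bool = True,
) -> ModelFitReport:
    """Mixed model of sqrt(Jaro) on the nine-level dyad factor.

    ``records`` is the output of :func:`indriflex.jaro.build_dyad_dataset`.
    The model always carries a random intercept per dyad (unordered singer
    pair).  Because every contribution appears in many records, records
    sharing a contribution are correlated across dyads as well; by default a
    second, multiple-membership variance component over contributions
    absorbs that sharing (without it the likelihood-ratio test is grossly
    anticonservative — pseudo-replication grows with the number of records
    per dyad).  ``contribution_re=False`` fits the dyad-only structure.

    The likelihood-ratio test compares against a null with the same random
    structure and only an intercept; with all nine levels present its df
    is 8.
    """
    data = records.copy()
    data["category_factor"] = data["category_factor"].astype(str)
    levels = sorted(data["category_factor"].unique())
    if len(levels) < 2:
        raise ValueError("the dyad factor needs at least two observed levels")
    if data["dyad_id"].nunique() < 2:
        raise ValueError("need at least two dyads to identify the random effect")

    if contribution_re:
        Xf, vcs = _distance_design(data)
        y = data["jd_sqrt"].to_numpy()
        groups = np.zeros(len(data))
        full = sm.MixedLM(y, Xf, groups, exog_vc=vcs)
        null = sm.MixedLM(
            y, pd.DataFrame({"Intercept": np.ones(len(data))}), groups,
            exog_vc=vcs,
        )
        random_structure = "(1 | dyad_id) + (1 | contribution, both members)"
    else:
        full = sm.MixedLM.from_formula(
            "jd_sqrt ~ C(category_factor)", groups="dyad_id", data=data
        )
        null = sm.MixedLM.from_formula("jd_sqrt ~ 1", groups="dyad_id", data=data)
        random_structure = "~1 | dyad_id"

    r_full, r_null = _fit_ml(full), _fit_ml(null)
    chi2 = max(2.0 * (r_full.llf - r_null.llf), 0.0)
    df = len(levels) - 1
    p = float(stats.chi2.sf(chi2, df))
    # contrasts compare dyad-level means; use a dyad-level residual df
    df_resid = float(max(records["dyad_id"].nunique() - len(levels), 2))
    table = (
        _posthoc_from_fit(r_full, "category_factor", levels, df_resid)
        if posthoc
        else None
    )
    return ModelFitReport(
        model_label="distance_lmm",
        response="sqrt(jd)",
        fixed_factor="category_factor",
        levels=tuple(levels),
        random_structure=random_structure,
        lrt_chi2=float(chi2),
        lrt_df=df,
        p_value=p,
        posthoc=table,
        df_method="dyad-level residual df (Kenward-Roger unavailable in backend)",
        converged=bool(r_full.converged and r_null.converged),
    )


def fit_diversity_lmm(
    records: pd.DataFrame,
    posthoc: bool = True,
) -> ModelFitReport:
    """Mixed model of log normalized diversity on singer category.

    ``records`` is the output of :func:`indriflex.diversity.diversity_table`.
    Random structure: crossed random intercepts for singer identity and for
    song (variance components over one population group).
    """
    data = records.copy()
    levels = sorted(data["category"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two singer categories")
    if data["singer_id"].nunique() < 2 or data["song_id"].nunique() < 2:
        raise ValueError("need at least two singers and two songs")
    data["_pop"] = 1
    vc = {"singer": "0 + C(singer_id)", "song": "0 + C(song_id)"}
    full = sm.MixedLM.from_formula(
        "log_nd ~ C(category)", groups="_pop", vc_formula=vc, re_formula="0",
        data=data,
    )
    null = sm.MixedLM.from_formula(
        "log_nd ~ 1", groups="_pop", vc_formula=vc, re_formula="0", data=data
    )
    r_full, r_null = _fit_ml(full), _fit_ml(null)
    chi2 = max(2.0 * (r_full.llf - r_null.llf), 0.0)
    df = len(levels) - 1
    p = float(stats.chi2.sf(chi2, df))
    # conservative denominator df: one observation unit per singer
    df_resid = float(max(data["singer_id"].nunique() - len(levels), 2))
    table = (
        _posthoc_from_fit(r_full, "category", levels, df_resid)
        if posthoc
        else None
    )
    return ModelFitReport(
        model_label="diversity_lmm",
        response="log(nd)",
        fixed_factor="category",
        levels=tuple(levels),
        random_structure="(1 | singer_id) + (1 | song_id), crossed",
        lrt_chi2=float(chi2),
        lrt_df=df,
        p_value=p,
        posthoc=table,
        df_method="singer-level residual df (Kenward-Roger unavailable in backend)",
        converged=bool(r_full.converged and r_null.converged),
    )


@dataclasses.dataclass
class ClassificationReport:
    """Tuned RBF-SVM classification of categories from Jaro profiles."""

    classes: tuple[str, ...]
    best_C: float
    best_sigma: float
    cv_folds: int
    train_fraction: float
    cv_accuracy: float
    train_accuracy: float
    test_accuracy: float
    per_class_recall: dict[str, float]
    confusion: pd.DataFrame
    seed: int


#: Default (C, sigma) grids: powers of four spanning the usual RBF ranges.
DEFAULT_C_GRID = tuple(float(2.0**e) for e in range(-5, 16, 4))
DEFAULT_SIGMA_GRID = tuple(float(2.0**e) for e in range(-15, 4, 4))


def svm_classify_categories(
    matrix: np.ndarray,
    labels,
    seed: int = 0,
    C_grid=DEFAULT_C_GRID,
    sigma_grid=DEFAULT_SIGMA_GRID,
    train_fraction: float = 0.7,
    cv_folds: int = 10,
    min_class_size: int = 10,
    precomputed_kernel: bool = False,
) -> ClassificationReport:
    """Classify contributions into singer categories from Jaro similarities.

    The feature vector of contribution *i* is its row of pairwise Jaro
    similarities restricted to the training reference set (the kernel-matrix
    -as-features reading); ``precomputed_kernel=True`` instead feeds the
    similarity matrix to the SVM as a precomputed kernel.  (C, sigma) are
    chosen by ``cv_folds``-fold stratified cross-validated accuracy on a
    stratified ``train_fraction`` split, then the tuned model is refit on the
    training split and scored on the held-out remainder.
    """
    labels = np.asarray(labels)
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if matrix.shape != (n, n):
        raise ValueError("matrix must be square and match labels")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < min_class_size:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} < {min_class_size} strings"
        )

    idx = np.arange(n)
    idx_tr, idx_te = train_test_split(
        idx, train_size=train_fraction, stratify=labels, random_state=seed
    )
    y_tr, y_te = labels[idx_tr], labels[idx_te]
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)

    if precomputed_kernel:
        K_tr = matrix[np.ix_(idx_tr, idx_tr)]
        K_te = matrix[np.ix_(idx_te, idx_tr)]
        search = GridSearchCV(
            SVC(kernel="precomputed"),
            {"C": list(C_grid)},
            cv=cv,
            scoring="accuracy",
            n_jobs=1,
        )
        search.fit(K_tr, y_tr)
        best = search.best_estimator_
        best_sigma = float("nan")
        train_pred, test_pred = best.predict(K_tr), best.predict(K_te)
    else:
        X_tr = matrix[np.ix_(idx_tr, idx_tr)]
        X_te = matrix[np.ix_(idx_te, idx_tr)]
        param_grid = {
            "C": list(C_grid),
            "gamma": [1.0 / (2.0 * s**2) for s in sigma_grid],
        }
        search = GridSearchCV(
            SVC(kernel="rbf"), param_grid, cv=cv, scoring="accuracy", n_jobs=1
        )
        search.fit(X_tr, y_tr)
        best = search.best_estimator_
        best_sigma = float(np.sqrt(1.0 / (2.0 * best.gamma)))
        train_pred, test_pred = best.predict(X_tr), best.predict(X_te)

    conf = confusion_matrix(y_te, test_pred, labels=classes)
    recall = {
        str(c): float(conf[i, i] / conf[i].sum()) if conf[i].sum() else float("nan")
        for i, c in enumerate(classes)
    }
    return ClassificationReport(
        classes=tuple(str(c) for c in classes),
        best_C=float(best.C),
        best_sigma=best_sigma,
        cv_folds=cv_folds,
        train_fraction=train_fraction,
        cv_accuracy=float(search.best_score_),
        train_accuracy=float(np.mean(train_pred == y_tr)),
        test_accuracy=float(np.mean(test_pred == y_te)),
        per_class_recall=recall,
        confusion=pd.DataFrame(conf, index=classes, columns=classes),
        seed=seed,
    )


@dataclasses.dataclass
class EntropyTestReport:
    """Kruskal-Wallis across categories + male/female Spearman by group."""

    kw_chi2: float
    kw_df: int
    kw_p: float
    categories: tuple[str, ...]
    spearman_rho: float
    spearman_n: int
    spearman_p: float
    spearman_tested: bool


def entropy_group_tests(
    entropy: pd.DataFrame,
    min_groups: int = 3,
) -> EntropyTestReport:
    """Compare entropy rates across categories and between duetting dominants.

    ``entropy`` is the output of :func:`indriflex.markov.entropy_table`.
    Singers with undefined entropy (NaN) are excluded.  The Spearman
    correlation pairs, per group, the dominant female's and dominant male's
    entropy rates; with fewer than ``min_groups`` complete pairs it is
    reported untested.
    """
    df = entropy.dropna(subset=["entropy_rate"])
    cats = sorted(df["category"].unique())
    samples = [df.loc[df["category"] == c, "entropy_rate"].to_numpy() for c in cats]
    if len(cats) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 categories with >= 2 singers each")
    kw = stats.kruskal(*samples)

    dom = df[df["category"].isin(["dominant_female", "dominant_male"])]
    wide = dom.pivot_table(index="group_id", columns="category",
                           values="entropy_rate", aggfunc="mean")
    wide = wide.dropna()
    tested = (
        {"dominant_female", "dominant_male"} <= set(wide.columns)
        and len(wide) >= min_groups
    )
    if tested:
        rho, p = stats.spearmanr(wide["dominant_female"], wide["dominant_male"])
        rho, p, n_pairs = float(rho), float(p), len(wide)
    else:
        rho, p, n_pairs = float("nan"), float("nan"), len(wide)
    return EntropyTestReport(
        kw_chi2=float(kw.statistic),
        kw_df=len(cats) - 1,
        kw_p=float(kw.pvalue),
        categories=tuple(cats),
        spearman_rho=rho,
        spearman_n=n_pairs,
        spearman_p=p,
        spearman_tested=bool(tested),
    )
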