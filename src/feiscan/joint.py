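"""Joint logistic odds-ratio models, interaction selection and summaries.

The top SNP of each associated gene plus race enter a multivariate logistic
model; odds ratios are reported with Wald 95% CIs. Whether race acts partly
through genotype is probed by exhaustive BIC comparison over all subsets of
race x SNP interaction terms (BIC as a Bayes-factor approximation). Fisher's
method combines independent chi-square p-values; ``cohort_summary``
reproduces the descriptive table: per-race counts/percentages of inhibitor
status and mutation categories with a 2x2 Pearson chi-square for
status-by-race.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import MUTATION_CATEGORIES, CohortTable, MutationTable

logger = logging.getLogger(__name__)


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with an odds-ratio table."""

    or_table: pd.DataFrame  # term, beta, se, OR, ci95_low, ci95_high, p_wald
    loglik: float
    k: int
    n: int
    fitted: np.ndarray

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * np.log(self.n)


@dataclass
class ModelSelectionResult:
    """Exhaustive BIC comparison over interaction-term subsets."""

    table: pd.DataFrame  # model, terms, loglik, k, n, bic, excluded
    best_model: str
    best_terms: tuple
    best_fit: LogisticFit


_SEPARATION_BETA = 15.0


def fit_logistic(y, x: pd.DataFrame, add_intercept: bool = True) -> LogisticFit:
    """Logistic regression by IRLS with Wald 95% CIs exponentiated to ORs.

    Raises on perfect separation (diverging coefficient, named) and on a
    rank-deficient design.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not isinstance(x, pd.DataFrame):
        x = pd.DataFrame(np.atleast_2d(np.asarray(x, dtype=float)))
        if x.shape[0] != len(y):
            x = x.T
        x.columns = [f"x{j}" for j in range(x.shape[1])]
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype has no variation")
    design = sm.add_constant(x, has_constant="add") if add_intercept else x.copy()
    if np.linalg.matrix_rank(design.to_numpy(dtype=float)) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need n > number of parameters")
    model = sm.GLM(y, design.astype(float), family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    params = np.asarray(res.params)
    if np.abs(params).max() > _SEPARATION_BETA:
        term = design.columns[int(np.abs(params).argmax())]
        raise ValueError(f"perfect separation: coefficient of {term!r} diverges")
    se = np.asarray(res.bse)
    zcrit = stats.norm.isf(0.025)
    table = pd.DataFrame(
        {
            "term": design.columns,
            "beta": params,
            "se": se,
            "OR": np.exp(params),
            "ci95_low": np.exp(params - zcrit * se),
            "ci95_high": np.exp(params + zcrit * se),
            "p_wald": 2.0 * stats.norm.sf(np.abs(params / se)),
        }
    )
    return LogisticFit(
        or_table=table,
        loglik=float(res.llf),
        k=design.shape[1],
        n=len(y),
        fitted=np.asarray(res.fittedvalues),
    )


def select_interaction_model(
    y, base: pd.DataFrame, snps: pd.DataFrame, race
) -> ModelSelectionResult:
    """Exhaustive BIC selection over race x SNP interaction subsets.

    The base model (covariates in ``base``, all SNP main effects and race)
    is always retained; every subset of race x SNP product terms is added in
    turn and the minimum-BIC model wins. Models with separation are flagged
    and excluded with a warning.
    """
    if snps.shape[1] > 12:
        raise ValueError("interaction enumeration limited to 12 candidate SNPs")
    race = np.asarray(race, dtype=float).ravel()
    main = pd.concat([base.reset_index(drop=True), snps.reset_index(drop=True)], axis=1)
    main["race"] = race
    rows = []
    fits = {}
    for subset in itertools.chain.from_iterable(
        itertools.combinations(snps.columns, r) for r in range(snps.shape[1] + 1)
    ):
        design = main.copy()
        for s in subset:
            design[f"race:{s}"] = race * snps[s].to_numpy(dtype=float)
        name = "+".join(subset) if subset else "(no interactions)"
        try:
            fit = fit_logistic(y, design)
        except ValueError as exc:
            logger.warning("model %s excluded: %s", name, exc)
            rows.append(
                {"model": name, "terms": subset, "loglik": np.nan, "k": np.nan,
                 "n": len(y), "bic": np.nan, "excluded": True}
            )
            continue
        fits[name] = fit
        rows.append(
            {"model": name, "terms": subset, "loglik": fit.loglik, "k": fit.k,
             "n": fit.n, "bic": fit.bic, "excluded": False}
        )
    table = pd.DataFrame(rows)
    ok = table[~table["excluded"]]
    if ok.empty:
        raise ValueError("every candidate model was excluded (separation)")
    best_row = ok.loc[ok["bic"].idxmin()]
    return ModelSelectionResult(
        table=table,
        best_model=str(best_row["model"]),
        best_terms=tuple(best_row["terms"]),
        best_fit=fits[str(best_row["model"])],
    )


def fishers_method(pvals) -> float:
    """Fisher's combined probability: -2 sum(ln p) ~ chi2 with 2k df."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    stat, combined = stats.combine_pvalues(p, method="fisher")
    return float(combined)


def cohort_summary(cohort: CohortTable, mutations: MutationTable) -> pd.DataFrame:
    """Descriptive statistics: status and mutation spectrum by race.

    Counts and percentages (1 decimal) per race and overall for baseline
    (and, when present, historical) inhibitor status and each mutation
    category, plus the fraction with any identified causative lesion; the
    status-by-race association is a 2x2 Pearson chi-square without
    continuity correction.
    """
    ct = cohort.table
    if ct.empty:
        raise ValueError("empty cohort")
    mt = mutations.table.set_index("subject_id")
    missing = set(ct["subject_id"]) - set(mt.index)
    if missing:
        raise KeyError(f"subjects missing from mutation table: {sorted(missing)[:5]}")
    mt = mt.loc[ct["subject_id"]]

    groups = {"ALL": np.ones(len(ct), dtype=bool)}
    for r in ("BA", "WE"):
        groups[r] = (ct["race"] == r).to_numpy()

    rows = []

    def add(stat, values: pd.Series):
        for gname, mask in groups.items():
            n_grp = int(mask.sum())
            count = int(values[mask].sum())
            rows.append(
                {
                    "statistic": stat,
                    "group": gname,
                    "count": count,
                    "denominator": n_grp,
                    "percent": round(100.0 * count / n_grp, 1) if n_grp else np.nan,
                }
            )

    add("baseline_status", ct["baseline_status"].astype(bool))
    if "historical_status" in ct.columns and ct["historical_status"].notna().all():
        add("historical_status", ct["historical_status"].astype(bool))
    add("mutation_identified", (mt["category"] != "not_identified").reset_index(drop=True))
    for cat in MUTATION_CATEGORIES:
        add(f"category:{cat}", (mt["category"] == cat).reset_index(drop=True))

    summary = pd.DataFrame(rows)
    tab = pd.crosstab(ct["race"], ct["baseline_status"])
    if tab.shape == (2, 2) and (tab.to_numpy() > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    else:
        chi2, p = np.nan, np.nan
    summary.attrs["chi2_status_by_race"] = float(chi2)
    summary.attrs["chi2_p_status_by_race"] = float(p)
    return summary
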