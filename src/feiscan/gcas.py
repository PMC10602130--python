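"""Gene-centric association scan (GCAS).

Each QC-passed SNP is tested as a fixed effect in the mixed model while the
structured random effects (kinship K, mutation sharing M) absorb the
non-independence in the cohort. Multiple testing is Bonferroni-corrected
twice: per candidate gene (over that gene's assigned SNPs) and chip-wide
(over every analyzed SNP). Thresholds are reported on the -log10(p) scale;
a SNP sitting exactly on a threshold is NOT significant (strict inequality).
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .io import MISSING, GenotypeMatrix
from .varcomp import VCFit, _ml_loglik, fit_vc

logger = logging.getLogger(__name__)


def assign_snps_to_genes(markers: pd.DataFrame, gene_map: pd.DataFrame) -> pd.Series:
    """Map marker id -> gene symbol; unmapped markers stay unassigned.

    Assignment must be a function: a marker mapped to two different genes is
    an error. Gene-map rows referencing unknown markers are ignored with a
    logged count (they are assignments for markers that failed QC).
    """
    gm = gene_map.drop_duplicates()
    dup = gm["marker_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"marker {gm['marker_id'][dup].iloc[0]!r} assigned to more than one gene"
        )
    known = gm["marker_id"].isin(markers["id"])
    if (~known).any():
        logger.info("%d gene-map rows reference markers not in the panel", (~known).sum())
    mapping = gm[known].set_index("marker_id")["gene"]
    return markers["id"].map(mapping).rename("gene")


def gene_snp_counts(assignment: pd.Series) -> dict:
    """Per-gene counts of assigned (QC-passed) SNPs."""
    return assignment.dropna().value_counts().to_dict()


def bonferroni_neglog10(alpha: float, n_tests: int) -> float:
    """-log10(alpha / n_tests), the Bonferroni threshold on the -log10 scale."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(np.log10(n_tests) - np.log10(alpha))


def round_threshold(value: float, ndigits: int = 2) -> float:
    """Half-up rounding for reported thresholds (e.g. 6.44, 3.76)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _maf(dosage: np.ndarray) -> float:
    d = dosage[dosage != MISSING]
    if d.size == 0:
        return np.nan
    p = d.mean() / 2.0
    return float(min(p, 1.0 - p))


def scan(
    y,
    x,
    genotypes: GenotypeMatrix,
    components,
    assignment: pd.Series | None = None,
    race: np.ndarray | None = None,
    mode: str = "wald_fixed_V",
    null_fit: VCFit | None = None,
) -> pd.DataFrame:
    """Per-SNP association tests within the mixed model.

    mode="wald_fixed_V" (default): the covariance V is fixed at the null
    REML estimates and each SNP enters by GLS; p comes from the Wald z of
    its coefficient. mode="full_lrt": the variance components are
    re-estimated by ML with and without the SNP and p comes from chi2_1 on
    twice the log-likelihood difference. Covariates ``x`` (including the
    intercept) are always retained; the counted allele is re-oriented to the
    minor allele in the combined sample. Monomorphic or covariate-collinear
    SNPs are skipped with a logged reason.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    n = len(y)
    if genotypes.n_subjects != n:
        raise ValueError("genotypes not aligned to phenotype")
    if mode not in ("wald_fixed_V", "full_lrt"):
        raise ValueError(f"unknown scan mode {mode!r}")
    if null_fit is None:
        null_fit = fit_vc(y, x, components)
    mats = [c.matrix if hasattr(c, "matrix") else np.asarray(c) for c in components]

    theta = np.array(
        [null_fit.variances[nm] for nm in null_fit.component_names]
        + [null_fit.variances["e"]]
    )
    v = theta[-1] * np.eye(n)
    for t, m in zip(theta[:-1], mats):
        v = v + t * m
    c, low = cho_factor(v, lower=True)
    vi_y = cho_solve((c, low), y)
    vi_x = cho_solve((c, low), x)

    rows = []
    for j in range(genotypes.n_markers):
        marker = genotypes.markers.iloc[j]
        d = genotypes.dosages[:, j].astype(float)
        miss = genotypes.dosages[:, j] == MISSING
        maf_all = _maf(genotypes.dosages[:, j])
        if miss.any():
            d[miss] = d[~miss].mean() if (~miss).any() else 0.0
        counted = marker["counted_allele"]
        if np.nanmean(d) / 2.0 > 0.5:
            d = 2.0 - d  # flip to count the minor allele
            counted = marker["other_allele"]
        row = {
            "marker_id": marker["id"],
            "gene": assignment.iloc[j] if assignment is not None else marker.get("gene"),
            "chrom": marker["chrom"],
            "pos": marker["pos"],
            "counted_allele": counted,
            "maf": maf_all,
        }
        if race is not None:
            race = np.asarray(race)
            for grp in np.unique(race):
                row[f"maf_{grp}"] = _maf(genotypes.dosages[race == grp, j])
        if np.var(d) == 0:
            logger.info("skipping %s: monomorphic", marker["id"])
            row.update(skip_reason="monomorphic")
            rows.append(row)
            continue
        xg = np.column_stack([x, d])
        if np.linalg.matrix_rank(xg) <= x.shape[1]:
            logger.info("skipping %s: collinear with covariates", marker["id"])
            row.update(skip_reason="collinear")
            rows.append(row)
            continue
        if mode == "wald_fixed_V":
            vi_d = cho_solve((c, low), d)
            xt = np.column_stack([vi_x, vi_d])
            xtvix = xg.T @ xt
            cov = np.linalg.inv(xtvix)
            beta = cov @ (xg.T @ vi_y)
            se = np.sqrt(cov[-1, -1])
            zstat = beta[-1] / se
            p = 2.0 * stats.norm.sf(abs(zstat))
            row.update(beta=float(beta[-1]), se=float(se), p_value=float(p))
        else:
            fit1 = fit_vc(y, xg, components)
            theta1 = np.array(
                [fit1.variances[nm] for nm in fit1.component_names]
                + [fit1.variances["e"]]
            )
            ll1 = _ml_loglik(theta1, mats, y, xg)
            ll0 = null_fit.loglik_ml
            lam = max(0.0, 2.0 * (ll1 - ll0))
            p = stats.chi2.sf(lam, df=1)
            row.update(
                beta=float(fit1.betas[-1]),
                se=float(fit1.beta_se[-1]),
                p_value=float(p),
            )
        row["neglog10_p"] = float(-np.log10(max(row["p_value"], 1e-300)))
        rows.append(row)
    table = pd.DataFrame(rows)
    if "skip_reason" not in table.columns:
        table["skip_reason"] = pd.NA
    return table


def flag_significant(
    table: pd.DataFrame,
    alpha: float = 0.05,
    n_chipwide: int | None = None,
    per_gene_counts: dict | None = None,
) -> pd.DataFrame:
    """Attach Bonferroni thresholds and significance flags to a scan table.

    Gene-level: neglog10_p strictly above -log10(alpha / n_gene) for the
    SNP's assigned gene; chip-wide analogous with n_chipwide (default: the
    number of tested SNPs in the table). Boundary equality is not
    significant. SNPs without a gene get no gene-level flag.
    """
    out = table.copy()
    tested = out["p_value"].notna()
    if n_chipwide is None:
        n_chipwide = int(tested.sum())
    chip_thr = bonferroni_neglog10(alpha, n_chipwide)
    out["chipwide_threshold_neglog10"] = chip_thr
    out["significant_chipwide"] = tested & (out["neglog10_p"] > chip_thr)
    if per_gene_counts is None:
        per_gene_counts = out.loc[tested, "gene"].dropna().value_counts().to_dict()
    gene_thr = out["gene"].map(
        {g: bonferroni_neglog10(alpha, n) for g, n in per_gene_counts.items()}
    )
    out["gene_threshold_neglog10"] = gene_thr
    sig_gene = tested & gene_thr.notna() & (out["neglog10_p"] > gene_thr)
    out["significant_gene_level"] = sig_gene.where(gene_thr.notna(), other=pd.NA)
    return out
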