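"""Synthetic hemophilia-A cohorts for end-to-end pipeline testing.

The generator reproduces the statistical structure the analysis assumes: a
two-ancestry cohort of ~450 males recruited through treatment centres (so a
sizeable minority have a close relative in-sample), race-stratified marker
frequencies including ancestry-restricted variants, a heterogeneous
spectrum of causative F8 lesions dominated by intron-22 inversions and
missense substitutions, and a binary inhibitor phenotype thresholded from a
Gaussian liability with additive-polygenic, mutation-shared and residual
components. Family members share the familial F8 lesion; the intron-22 and
intron-1 inversions are recurrent (one shared allele each) while missense
carriers draw from a pool of distinct alleles and unresolved lesions get
per-subject unique tokens.

Everything is deterministic given (params, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import io as fio
from .io import CohortTable, GenotypeMatrix, MutationTable
from .relatedness import StructuredCovariance, mutation_sharing_matrix, pedigree_kinship

_OTHER_CATEGORIES = (
    "nonsense",
    "small_indel",
    "intron1_inv",
    "splice_site",
    "large_del_multi_exon",
    "large_del_le_1_exon",
    "multiple",
)

#: Recurrent lesions: every carrier shares one allele identifier.
_RECURRENT_ALLELES = {"intron22_inv": "I22INV", "intron1_inv": "I1INV"}


def _default_mutation_freqs() -> dict:
    # Intron-22 inversions 41.6%, missense 21.6%, unresolved 9.8%; the
    # remaining mass is spread uniformly over the other seven categories.
    freqs = {"intron22_inv": 0.416, "missense": 0.216, "not_identified": 0.098}
    rest = 1.0 - sum(freqs.values())
    for cat in _OTHER_CATEGORIES:
        freqs[cat] = rest / len(_OTHER_CATEGORIES)
    return freqs


@dataclass
class SimulationParams:
    """Cohort-generator settings; defaults are the study conditions."""

    n_subjects: int = 450
    race_props: dict = field(default_factory=lambda: {"BA": 206 / 450, "WE": 244 / 450})
    # subject fractions by family type; sib pairs + avuncular pairs put
    # ~31% of subjects in a family with another sampled subject
    frac_sib_pair: float = 0.21
    frac_avuncular: float = 0.10
    n_genes: int = 10
    snps_per_gene: int = 30
    maf_range: tuple = (0.05, 0.5)
    rare_maf_range: tuple = (0.001, 0.01)
    ancestry_restricted_fraction: float = 0.10
    mutation_freqs: dict = field(default_factory=_default_mutation_freqs)
    n_missense_alleles: int = 61
    sigma2_g: float = 0.47
    sigma2_m: float = 0.08
    sigma2_e: float = 0.45
    intercept: float = 0.0
    race_beta: float = 0.21  # liability shift for BA vs WE ancestry
    prevalence: float = 0.185
    historical_prevalence: float = 0.305
    causal_snp_betas: dict = field(default_factory=dict)  # marker_id -> liability beta

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if abs(sum(self.race_props.values()) - 1.0) > 1e-9:
            raise ValueError("race proportions must sum to 1")
        if not 0.0 <= self.frac_sib_pair + self.frac_avuncular <= 1.0:
            raise ValueError("family-type fractions must lie in [0, 1]")
        if abs(sum(self.mutation_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("mutation category frequencies must sum to 1")
        if min(self.sigma2_g, self.sigma2_m, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.mutation_freqs.get("missense", 0) > 0 and self.n_missense_alleles < 1:
            raise ValueError("need at least one distinct missense allele")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# pedigrees


def simulate_pedigrees(params: SimulationParams, seed):
    """Draw family units and race labels.

    Returns (ped, samples): ``ped`` is the full pedigree table (id, sire,
    dam, sex, 0 = founder) including unsampled connecting parents; ``samples``
    lists the cohort subjects with family id, family type and race. Family
    counts are fixed by the params; only race assignment and downstream
    draws vary with the seed.
    """
    rng = _rng(seed)
    n = params.n_subjects
    n_sib = int(round(n * params.frac_sib_pair / 2))
    n_av = int(round(n * params.frac_avuncular / 2))
    n_single = n - 2 * (n_sib + n_av)
    if n_single < 0:  # pair rounding overshot; shrink the last unit type
        n_av += n_single // 2
        n_single = n - 2 * (n_sib + n_av)
    races = list(params.race_props)
    probs = np.array([params.race_props[r] for r in races])

    ped_rows, sample_rows = [], []
    fam = 0

    def founder(iid, sex):
        ped_rows.append({"id": iid, "sire": "0", "dam": "0", "sex": sex})

    def child(iid, sire, dam, sex="M"):
        ped_rows.append({"id": iid, "sire": sire, "dam": dam, "sex": sex})

    def sample(iid, ftype, race):
        sample_rows.append(
            {"subject_id": iid, "family": f"F{fam:04d}", "family_type": ftype, "race": race}
        )

    for ftype, count in (("sib_pair", n_sib), ("avuncular", n_av), ("singleton", n_single)):
        for _ in range(count):
            fam += 1
            race = races[int(rng.choice(len(races), p=probs))]
            pre = f"F{fam:04d}"
            if ftype == "singleton":
                founder(f"{pre}_S1", "M")
                sample(f"{pre}_S1", ftype, race)
            elif ftype == "sib_pair":
                founder(f"{pre}_FA", "M")
                founder(f"{pre}_MO", "F")
                for k in (1, 2):
                    child(f"{pre}_S{k}", f"{pre}_FA", f"{pre}_MO")
                    sample(f"{pre}_S{k}", ftype, race)
            else:  # avuncular: uncle U and his brother's son N are sampled
                founder(f"{pre}_GF", "M")
                founder(f"{pre}_GM", "F")
                child(f"{pre}_U", f"{pre}_GF", f"{pre}_GM")
                child(f"{pre}_P", f"{pre}_GF", f"{pre}_GM")
                founder(f"{pre}_W", "F")
                child(f"{pre}_N", f"{pre}_P", f"{pre}_W")
                sample(f"{pre}_U", ftype, race)
                sample(f"{pre}_N", ftype, race)
    ped = pd.DataFrame(ped_rows)
    samples = pd.DataFrame(sample_rows)
    # race of every pedigree member = race of its family (founders marry in)
    fam_race = samples.drop_duplicates("family").set_index("family")["race"]
    ped["family"] = ped["id"].str.split("_").str[0]
    ped["race"] = ped["family"].map(fam_race)
    return ped, samples


# ---------------------------------------------------------------------------
# genotypes


def _draw_marker_frequencies(params: SimulationParams, rng) -> pd.DataFrame:
    m = params.n_genes * params.snps_per_gene
    lo, hi = params.maf_range
    p_ba = rng.uniform(lo, hi, size=m)
    p_we = rng.uniform(lo, hi, size=m)
    n_restricted = int(round(params.ancestry_restricted_fraction * m))
    if n_restricted:
        idx = rng.choice(m, size=n_restricted, replace=False)
        rare = rng.uniform(*params.rare_maf_range, size=n_restricted)
        which = rng.random(n_restricted) < 0.5  # which ancestry keeps it common
        p_ba[idx] = np.where(which, p_ba[idx], rare)
        p_we[idx] = np.where(which, rare, p_we[idx])
    genes = [f"GENE{g + 1:02d}" for g in range(params.n_genes)]
    return pd.DataFrame(
        {
            "id": [f"rs{j + 1:06d}" for j in range(m)],
            "chrom": [str(g % 22 + 1) for g in np.repeat(np.arange(params.n_genes), params.snps_per_gene)],
            "pos": np.tile(np.arange(params.snps_per_gene), params.n_genes) * 1000 + 10_000,
            "counted_allele": "A",
            "other_allele": "G",
            "gene": np.repeat(genes, params.snps_per_gene),
            "p_BA": p_ba,
            "p_WE": p_we,
        }
    )


def drop_genotypes(
    ped: pd.DataFrame,
    samples: pd.DataFrame,
    params: SimulationParams,
    seed,
    return_all: bool = False,
):
    """Founder draws plus Mendelian gene-dropping through the pedigree.

    Founders receive Binomial(2, p_race) dosages; each non-founder inherits
    one allele per parent, transmitted with probability dosage/2. Returns
    the GenotypeMatrix restricted to sampled subjects and the marker truth
    table (including per-race frequencies and gene assignments); with
    ``return_all`` the per-individual dosage dict over the whole pedigree is
    appended (for Mendelian-consistency checks).
    """
    rng = _rng(seed)
    markers = _draw_marker_frequencies(params, rng)
    for col in ("p_BA", "p_WE"):
        bad = (markers[col] <= 0) | (markers[col] > 0.5)
        if bad.any():
            raise ValueError(
                f"marker {markers['id'][bad].iloc[0]} has {col} outside (0, 0.5]"
            )
    m = len(markers)
    freq = {"BA": markers["p_BA"].to_numpy(), "WE": markers["p_WE"].to_numpy()}
    dosage: dict[str, np.ndarray] = {}
    for _, row in ped.iterrows():  # pedigree rows are parents-first by construction
        if row["sire"] == "0":
            dosage[row["id"]] = rng.binomial(2, freq[row["race"]]).astype(np.int8)
        else:
            d_s, d_d = dosage[row["sire"]], dosage[row["dam"]]
            a1 = rng.random(m) < d_s / 2.0
            a2 = rng.random(m) < d_d / 2.0
            dosage[row["id"]] = (a1.astype(np.int8) + a2.astype(np.int8))
    ids = samples["subject_id"].to_numpy(dtype=object)
    mat = np.vstack([dosage[s] for s in ids])
    g = GenotypeMatrix(
        subject_ids=ids,
        dosages=mat,
        markers=markers[["id", "chrom", "pos", "counted_allele", "other_allele", "gene"]],
    )
    if return_all:
        return g, markers, dosage
    return g, markers


# ---------------------------------------------------------------------------
# mutations


def assign_mutations(samples: pd.DataFrame, params: SimulationParams, seed) -> MutationTable:
    """Assign a causative F8 lesion per family; relatives share it.

    Recurrent inversions map to one shared allele id; missense families
    draw from the configured pool of distinct alleles; other categories get
    a family-unique lesion label; unresolved lesions get per-subject unique
    tokens (no sharing implied even within a family).
    """
    rng = _rng(seed)
    cats = list(params.mutation_freqs)
    probs = np.array([params.mutation_freqs[c] for c in cats])
    rows = []
    for fam, grp in samples.groupby("family", sort=True):
        cat = cats[int(rng.choice(len(cats), p=probs))]
        if cat in _RECURRENT_ALLELES:
            allele = _RECURRENT_ALLELES[cat]
        elif cat == "missense":
            allele = f"MS{int(rng.integers(params.n_missense_alleles)) + 1:03d}"
        elif cat == "not_identified":
            allele = None  # per subject below
        else:
            allele = f"{cat.upper()}_{fam}"
        for sid in grp["subject_id"]:
            rows.append(
                {
                    "subject_id": sid,
                    "category": cat,
                    "allele_id": allele if allele is not None else f"NI_{sid}",
                }
            )
    order = {s: i for i, s in enumerate(samples["subject_id"])}
    rows.sort(key=lambda r: order[r["subject_id"]])
    return MutationTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# phenotype


def _liability_threshold(params: SimulationParams, prevalence: float) -> float:
    """Quantile of the theoretical marginal liability mixture.

    Within each ancestry the liability is Gaussian with its own mean
    (intercept + race effect) and common variance s2_g + s2_m + s2_e; the
    threshold solves the mixture tail probability = prevalence.
    """
    sd = np.sqrt(params.sigma2_g + params.sigma2_m + params.sigma2_e)
    means = {
        r: params.intercept + (params.race_beta if r == "BA" else 0.0)
        for r in params.race_props
    }
    w = params.race_props
    if sd == 0.0:
        # degenerate point-mass mixture: quantile over the race means
        vals = sorted(means.values())
        cum = 0.0
        for v in vals:
            cum += sum(w[r] for r in w if means[r] == v)
            if cum >= 1.0 - prevalence:
                return float(v)
        return float(vals[-1])

    def tail(t):
        return sum(w[r] * stats.norm.sf((t - means[r]) / sd) for r in w) - prevalence

    lo = min(means.values()) - 10 * sd
    hi = max(means.values()) + 10 * sd
    return float(optimize.brentq(tail, lo, hi))


def simulate_phenotype(
    k_ped: StructuredCovariance,
    m: StructuredCovariance,
    samples: pd.DataFrame,
    mutations: MutationTable,
    params: SimulationParams,
    seed,
    genotypes: GenotypeMatrix | None = None,
):
    """Threshold a Gaussian liability into the binary inhibitor phenotype.

    g ~ N(0, s2_g K) via Cholesky; the mutation effect draws one
    N(0, s2_m) deviate per distinct allele id and assigns it to carriers,
    so cov(m) = s2_m M exactly; e ~ N(0, s2_e I). Baseline status is
    liability > t with t the upper-prevalence quantile of the theoretical
    marginal distribution; historical status uses the (lower) threshold for
    the historical prevalence, so baseline-positive implies
    historical-positive.

    Returns (CohortTable, liabilities).
    """
    rng = _rng(seed)
    ids = samples["subject_id"].to_numpy(dtype=object)
    n = len(ids)
    kmat = k_ped.align(ids).matrix
    draws = rng.standard_normal(n)
    if np.count_nonzero(kmat - np.diag(np.diag(kmat))) == 0:
        g = np.sqrt(params.sigma2_g * np.diag(kmat)) * draws  # unrelated cohort
    else:
        try:
            chol = np.linalg.cholesky(kmat + 1e-10 * np.eye(n))
        except np.linalg.LinAlgError:
            raise ValueError("pedigree kinship matrix is not PSD") from None
        g = np.sqrt(params.sigma2_g) * (chol @ draws)

    alleles = mutations.table.set_index("subject_id").loc[ids, "allele_id"]
    uniq = alleles.unique()
    effects = dict(zip(uniq, np.sqrt(params.sigma2_m) * rng.standard_normal(len(uniq))))
    m_eff = alleles.map(effects).to_numpy(dtype=float)

    e = np.sqrt(params.sigma2_e) * rng.standard_normal(n)
    race_ind = (samples["race"] == "BA").to_numpy(dtype=float)
    liab = params.intercept + params.race_beta * race_ind + g + m_eff + e

    if params.causal_snp_betas:
        if genotypes is None:
            raise ValueError("causal SNP effects require genotypes")
        gsub = genotypes.subset_subjects(ids)
        for mk, beta in params.causal_snp_betas.items():
            j = gsub.markers.index[gsub.markers["id"] == mk]
            if len(j) != 1:
                raise KeyError(f"causal marker {mk!r} not in genotype panel")
            d = gsub.dosages[:, j[0]].astype(float)
            liab += beta * (d - d.mean())  # centered so the threshold stays calibrated

    t_base = _liability_threshold(params, params.prevalence)
    t_hist = _liability_threshold(params, params.historical_prevalence)
    cohort = CohortTable(
        pd.DataFrame(
            {
                "subject_id": ids,
                "baseline_status": (liab > t_base).astype(int),
                "historical_status": (liab > t_hist).astype(int),
                "race": samples["race"].to_numpy(),
            }
        )
    )
    return cohort, liab


# ---------------------------------------------------------------------------
# bundle


def simulate(params: SimulationParams, seed: int, outdir=None) -> dict:
    """Generate a full synthetic input bundle.

    Independent sub-streams are spawned from the seed for each stage, so
    the bundle is fully reproducible. When ``outdir`` is given, writes
    genotypes (dosage TSV), cohort, mutations, gene map, pedigree, the two
    covariance matrices and the true generating parameters.
    """
    root = np.random.default_rng(seed)
    s_ped, s_geno, s_mut, s_phen = root.spawn(4)
    ped, samples = simulate_pedigrees(params, s_ped)
    genotypes, marker_truth = drop_genotypes(ped, samples, params, s_geno)
    mutations = assign_mutations(samples, params, s_mut)
    ids = samples["subject_id"].to_numpy(dtype=object)
    k_ped = pedigree_kinship(ped[["id", "sire", "dam", "sex"]], subject_ids=ids)
    m = mutation_sharing_matrix(mutations, subject_ids=ids, granularity="allele")
    cohort, liab = simulate_phenotype(
        k_ped, m, samples, mutations, params, s_phen, genotypes=genotypes
    )
    gene_map = marker_truth[["id", "gene"]].rename(columns={"id": "marker_id"})
    bundle = {
        "params": params,
        "seed": seed,
        "pedigree": ped,
        "samples": samples,
        "genotypes": genotypes,
        "marker_truth": marker_truth,
        "mutations": mutations,
        "cohort": cohort,
        "gene_map": gene_map,
        "K_ped": k_ped,
        "M": m,
        "liability": liab,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fio.write_dosage_tsv(genotypes, outdir / "genotypes.tsv")
        fio.write_cohort(cohort, outdir / "cohort.tsv")
        fio.write_mutations(mutations, outdir / "mutations.tsv")
        fio.write_gene_map(gene_map, outdir / "gene_map.tsv")
        ped.to_csv(outdir / "pedigree.tsv", sep="\t", index=False)
        fio.write_matrix(k_ped.matrix, ids, outdir / "kinship_pedigree.tsv")
        fio.write_matrix(m.matrix, ids, outdir / "mutation_sharing.tsv")
        truth = asdict(params)
        truth["seed"] = seed
        (outdir / "true_params.json").write_text(json.dumps(truth, indent=2, default=str) + "\n")
    return bundle
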