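"""Readers and writers for cohort, genotype, mutation and result tables.

All tabular formats are plain TSV; genotypes may additionally come from a
VCF (GT field only, biallelic sites). Coordinates are 1-based as in VCF.
Missing dosages use the out-of-band sentinel :data:`MISSING`, never 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Out-of-band sentinel for a missing genotype dosage.
MISSING: int = -1

#: Valid causative-mutation categories (eight lesion classes plus the
#: "multiple distinct lesions" and "lesion not identified" bookkeeping ones).
MUTATION_CATEGORIES: tuple[str, ...] = (
    "nonsense",
    "missense",
    "small_indel",
    "intron1_inv",
    "splice_site",
    "intron22_inv",
    "large_del_multi_exon",
    "large_del_le_1_exon",
    "multiple",
    "not_identified",
)

RACES: tuple[str, ...] = ("BA", "WE")

_MARKER_COLUMNS = ["id", "chrom", "pos", "counted_allele", "other_allele", "gene"]


@dataclass
class GenotypeMatrix:
    """Subjects x markers matrix of counted-allele dosages.

    ``dosages`` holds integers in {0, 1, 2} or :data:`MISSING`; ``markers``
    is a DataFrame with columns id, chrom, pos (1-based), counted_allele,
    other_allele and an optional gene symbol per marker.
    """

    subject_ids: np.ndarray
    dosages: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.subject_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage for subject {self.subject_ids[i]!r}, marker "
                f"{self.markers['id'].iloc[j]!r} is {self.dosages[i, j]!r}; "
                "expected 0, 1, 2 or missing"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids in genotype matrix")
        if self.markers["id"].duplicated().any():
            dup = self.markers["id"][self.markers["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        if (self.markers["pos"] < 1).any():
            raise ValueError("marker positions must be 1-based (>= 1)")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_subjects(self, ids) -> "GenotypeMatrix":
        """Reorder/subset rows to ``ids`` (all must be present)."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as exc:
            raise KeyError(f"subject {exc.args[0]!r} not in genotype matrix") from None
        return GenotypeMatrix(
            subject_ids=np.asarray(list(ids), dtype=object),
            dosages=self.dosages[rows],
            markers=self.markers.reset_index(drop=True),
        )


@dataclass
class CohortTable:
    """Per-subject phenotype and covariates.

    ``baseline_status`` is 1 when any-titer FVIII inhibitors were present at
    study entry. ``race`` is the self-reported ancestry group, BA or WE.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"subject_id", "baseline_status", "race"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if t["subject_id"].duplicated().any():
            dup = t["subject_id"][t["subject_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate subject {dup!r} in cohort table")
        if not t["baseline_status"].isin([0, 1]).all():
            raise ValueError("baseline_status must be 0/1")
        bad_race = ~t["race"].isin(RACES)
        if bad_race.any():
            raise ValueError(
                f"unknown race value {t['race'][bad_race].iloc[0]!r}; "
                f"expected one of {RACES}"
            )
        self.table = t.reset_index(drop=True)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy(dtype=object)

    @property
    def baseline_status(self) -> np.ndarray:
        return self.table["baseline_status"].to_numpy(dtype=float)

    @property
    def race(self) -> pd.Series:
        return self.table["race"]

    def race_indicator(self) -> np.ndarray:
        """1.0 for BA subjects, 0.0 for WE (the modelling code for race)."""
        return (self.table["race"] == "BA").to_numpy(dtype=float)


@dataclass
class MutationTable:
    """Per-subject causative F8 lesion: category plus exact-allele label.

    ``allele_id`` names the precise lesion (e.g. "I22INV", "p.R1966Q"); for
    unresolved lesions (category ``not_identified``) it is a per-subject
    unique token so that no sharing is implied.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"subject_id", "category", "allele_id"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"mutation table missing columns: {sorted(missing)}")
        if t["subject_id"].duplicated().any():
            dup = t["subject_id"][t["subject_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate subject {dup!r} in mutation table")
        bad = ~t["category"].isin(MUTATION_CATEGORIES)
        if bad.any():
            raise ValueError(
                f"unknown mutation category {t['category'][bad].iloc[0]!r}; "
                f"valid categories: {list(MUTATION_CATEGORIES)}"
            )
        if (t["allele_id"].astype(str).str.len() == 0).any() or t["allele_id"].isna().any():
            raise ValueError("allele_id must be non-empty")
        ni = t.loc[t["category"] == "not_identified", "allele_id"]
        if ni.duplicated().any():
            raise ValueError(
                "not_identified subjects must carry per-subject unique allele tokens"
            )
        self.table = t.reset_index(drop=True)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy(dtype=object)


# ---------------------------------------------------------------------------
# readers


def read_genotypes(path, format: str = "dosage_tsv") -> GenotypeMatrix:
    """Read genotype dosages from a dosage TSV or a VCF.

    The dosage TSV has a header row of marker ids and a first column of
    subject ids; entries are 0/1/2 or NA. VCF records must be biallelic with
    a GT field; multi-allelic records are skipped with a logged warning and
    the ALT allele is the counted allele.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosages = np.full(df.shape, MISSING, dtype=np.int8)
    values = df.to_numpy()
    for j in range(df.shape[1]):
        col = values[:, j]
        for i, v in enumerate(col):
            if pd.isna(v):
                continue
            fv = float(v)
            if fv not in (0.0, 1.0, 2.0):
                raise ValueError(
                    f"non-{{0,1,2}} dosage {v!r} at subject {df.index[i]!r}, "
                    f"marker {df.columns[j]!r}"
                )
            dosages[i, j] = int(fv)
    markers = pd.DataFrame(
        {
            "id": df.columns,
            "chrom": "NA",
            "pos": np.arange(1, df.shape[1] + 1),
            "counted_allele": "NA",
            "other_allele": "NA",
            "gene": pd.Series([pd.NA] * df.shape[1], dtype=object),
        }
    )
    return GenotypeMatrix(
        subject_ids=df.index.to_numpy(dtype=object),
        dosages=dosages,
        markers=markers,
    )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    subjects = np.asarray(vcf.samples, dtype=object)
    cols: list[np.ndarray] = []
    records: list[dict] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            logger.warning(
                "skipping multi-allelic record %s:%d (%s)", var.CHROM, var.POS, var.ID
            )
            continue
        # gts012: 0/1/2 ALT-allele counts, 3 = unknown
        d = var.gt_types.astype(np.int8)
        d[d == 3] = MISSING
        cols.append(d)
        records.append(
            {
                "id": var.ID if var.ID else f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "counted_allele": var.ALT[0],
                "other_allele": var.REF,
                "gene": pd.NA,
            }
        )
    vcf.close()
    if n_skipped:
        logger.info("skipped %d multi-allelic records", n_skipped)
    markers = pd.DataFrame(records, columns=_MARKER_COLUMNS)
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(subjects), 0), dtype=np.int8)
    )
    return GenotypeMatrix(subject_ids=subjects, dosages=dosages, markers=markers)


def read_cohort(path) -> CohortTable:
    """Read the subject phenotype/covariate TSV."""
    df = pd.read_csv(Path(path), sep="\t", dtype={"subject_id": str})
    return CohortTable(df)


def read_mutations(path) -> MutationTable:
    """Read the causative-mutation TSV (subject_id, category, allele_id)."""
    df = pd.read_csv(
        Path(path), sep="\t", dtype={"subject_id": str, "allele_id": str}
    )
    return MutationTable(df)


def read_gene_map(path) -> pd.DataFrame:
    """Read the marker -> gene assignment TSV (columns marker_id, gene)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    required = {"marker_id", "gene"}
    if missing := required - set(df.columns):
        raise ValueError(f"gene map missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# writers


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosages, index=g.subject_ids, columns=g.markers["id"])
    df = df.astype(object).where(df != MISSING, other=pd.NA)
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


def write_mutations(muts: MutationTable, path) -> None:
    muts.table.to_csv(path, sep="\t", index=False)


def write_gene_map(gene_map: pd.DataFrame, path) -> None:
    gene_map.to_csv(path, sep="\t", index=False)


def write_association_table(table: pd.DataFrame, path) -> None:
    """Write a per-SNP association table as TSV.

    Column order is deterministic; p-values are in scientific notation and
    floats carry 12 significant digits so the table round-trips.
    """
    if table.empty:
        logger.warning("association table is empty; writing header only")
    out = table.copy()
    for col in out.columns:
        if col == "p_value":
            out[col] = out[col].map(lambda v: f"{v:.12e}" if pd.notna(v) else "NA")
        elif pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.12g}" if pd.notna(v) else "NA")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_association_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_report(fit, path) -> None:
    """Serialize a variance-component fit (and optional partition) as JSON."""
    payload = fit.to_dict() if hasattr(fit, "to_dict") else dict(fit)
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer, np.bool_)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_matrix(matrix: np.ndarray, subject_ids, path) -> None:
    """Write a subjects x subjects covariance matrix as TSV with id header."""
    df = pd.DataFrame(matrix, index=list(subject_ids), columns=list(subject_ids))
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), df.index.to_numpy(dtype=object)


def align_subjects(
    cohort: CohortTable,
    genotypes: GenotypeMatrix | None = None,
    mutations: MutationTable | None = None,
) -> np.ndarray:
    """Return cohort subject order; log subjects dropped from genotypes.

    The cohort table defines the modeling population and row order. Subjects
    present in the genotypes but absent from the cohort are dropped with a
    logged count; a cohort subject missing from the genotypes or mutation
    table is an error.
    """
    ids = cohort.subject_ids
    idset = set(ids)
    if genotypes is not None:
        extra = [s for s in genotypes.subject_ids if s not in idset]
        if extra:
            logger.info("dropping %d genotyped subjects absent from cohort", len(extra))
        missing = idset - set(genotypes.subject_ids)
        if missing:
            raise KeyError(f"cohort subjects missing from genotypes: {sorted(missing)[:5]}")
    if mutations is not None:
        missing = idset - set(mutations.subject_ids)
        if missing:
            raise KeyError(f"cohort subjects missing from mutation table: {sorted(missing)[:5]}")
    return ids
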