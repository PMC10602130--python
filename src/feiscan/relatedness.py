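"""Structured covariance matrices over subjects.

Two random-effect structures enter the mixed model: an empirical kinship /
genomic relationship matrix (GRM) estimated from SNP dosages, and an
indicator matrix of shared causative-F8-mutation identity. A pedigree-based
numerator relationship matrix is also provided as simulation ground truth —
known and marker-inferred relationships lie on the same relatedness
continuum, so the empirical GRM should converge to it as markers accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, MutationTable

PSD_TOL = 1e-8


def _is_psd(matrix: np.ndarray, tol: float = PSD_TOL) -> bool:
    """PSD up to tolerance via Cholesky of the jittered matrix (O(n^3/3),
    much cheaper than a full eigendecomposition for large cohorts)."""
    scale = max(1.0, float(np.abs(np.diag(matrix)).max()))
    shifted = matrix + (tol * scale) * np.eye(matrix.shape[0])
    try:
        np.linalg.cholesky(shifted)
        return True
    except np.linalg.LinAlgError:
        return False


@dataclass
class StructuredCovariance:
    """Symmetric PSD covariance over subjects with a provenance tag."""

    matrix: np.ndarray
    kind: str  # grm | mutation_sharing | pedigree_kinship
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        n = len(self.subject_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({n}, {n})")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")
        if (np.diag(self.matrix) <= 0).any():
            raise ValueError("covariance diagonal must be positive")
        if not _is_psd(self.matrix):
            w_min = np.linalg.eigvalsh(self.matrix).min()
            raise ValueError(f"matrix not PSD (min eigenvalue {w_min:.3g})")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def align(self, ids) -> "StructuredCovariance":
        """Reorder to the given subject order (all ids must be present)."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            rows = np.asarray([index[s] for s in ids])
        except KeyError as exc:
            raise KeyError(f"subject {exc.args[0]!r} not in {self.kind} matrix") from None
        return StructuredCovariance(
            matrix=self.matrix[np.ix_(rows, rows)],
            kind=self.kind,
            subject_ids=np.asarray(list(ids), dtype=object),
        )


def compute_grm(
    g: GenotypeMatrix, maf_min: float = 0.01, max_missing: float = 0.05
) -> StructuredCovariance:
    """GCTA-style per-marker-standardized genomic relationship matrix.

    K_ij = (1/L) sum_l (g_il - 2 p_l)(g_jl - 2 p_l) / (2 p_l (1 - p_l))
    over the L markers surviving the call-rate and MAF filters, with p_l the
    sample counted-allele frequency and missing dosages mean-imputed to
    2 p_l. Centering makes K invariant to swapping which allele is counted.
    """
    if g.n_subjects < 2:
        raise ValueError("GRM requires at least 2 subjects")
    d = g.dosages.astype(float)
    d[g.dosages == MISSING] = np.nan
    call = 1.0 - np.isnan(d).mean(axis=0)
    p = np.nanmean(d, axis=0) / 2.0
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    keep = (call >= 1.0 - max_missing) & (maf >= maf_min) & (maf > 0)
    if not keep.any():
        raise ValueError("no informative markers after filtering")
    d = d[:, keep]
    p = p[keep]
    d = np.where(np.isnan(d), 2.0 * p, d)
    z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    k = (z @ z.T) / z.shape[1]
    k = (k + k.T) / 2.0
    return StructuredCovariance(matrix=k, kind="grm", subject_ids=g.subject_ids)


def mutation_sharing_matrix(
    muts: MutationTable, subject_ids=None, granularity: str = "allele"
) -> StructuredCovariance:
    """Indicator covariance of shared causative-F8-mutation identity.

    M_ij = 1 iff subjects i and j carry the same exact lesion
    (granularity="allele") or the same lesion category
    (granularity="category"); the diagonal is 1. Subjects whose lesion was
    not identified share with no one under either granularity — unknown
    lesions are almost surely distinct. A union of disjoint blocks of ones,
    so M is PSD with eigenvalues equal to the block sizes plus zeros.
    """
    if granularity not in ("allele", "category"):
        raise ValueError(f"granularity must be 'allele' or 'category', got {granularity!r}")
    t = muts.table
    if subject_ids is None:
        subject_ids = muts.subject_ids
    t = t.set_index("subject_id")
    missing = [s for s in subject_ids if s not in t.index]
    if missing:
        raise KeyError(f"subject {missing[0]!r} has no mutation record")
    t = t.loc[list(subject_ids)]
    key = t["allele_id"] if granularity == "allele" else t["category"]
    key = key.to_numpy(dtype=object).copy()
    unidentified = (t["category"] == "not_identified").to_numpy()
    # unique singleton tokens regardless of granularity
    key[unidentified] = [f"__ni_{s}" for s in np.asarray(subject_ids)[unidentified]]
    codes = np.unique(key.astype(str), return_inverse=True)[1]
    m = (codes[:, None] == codes[None, :]).astype(float)
    return StructuredCovariance(
        matrix=m, kind="mutation_sharing", subject_ids=np.asarray(subject_ids, dtype=object)
    )


def pedigree_kinship(ped: pd.DataFrame, subject_ids=None) -> StructuredCovariance:
    """Numerator relationship matrix (2 x kinship) by the recursive tabular method.

    ``ped`` has columns id, sire, dam (0 or empty = founder); entries follow
    A_ii = 1 + A(sire,dam)/2 and A_ij = (A(j,sire) + A(j,dam))/2 after
    sorting parents before offspring. Full sibs get 0.5, avuncular and
    grandparent-grandchild pairs 0.25.
    """
    ids = ped["id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual in pedigree")
    parent = {}
    for _, row in ped.iterrows():
        s, d = str(row["sire"]), str(row["dam"])
        parent[str(row["id"])] = (
            s if s not in ("0", "", "nan", "NA") else None,
            d if d not in ("0", "", "nan", "NA") else None,
        )
    for iid, (s, d) in parent.items():
        for p in (s, d):
            if p is not None and p not in parent:
                raise ValueError(f"parent {p!r} of {iid!r} not in pedigree")
    order = _topological_order(parent)
    idx = {iid: i for i, iid in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for i, iid in enumerate(order):
        s, d = parent[iid]
        si = idx[s] if s is not None else None
        di = idx[d] if d is not None else None
        a[i, i] = 1.0 + (0.5 * a[si, di] if si is not None and di is not None else 0.0)
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * a[:i, si]
        if di is not None:
            row += 0.5 * a[:i, di]
        a[i, :i] = a[:i, i] = row
    if subject_ids is None:
        subject_ids = np.asarray(order, dtype=object)
    rows = np.asarray([idx[str(s)] for s in subject_ids])
    return StructuredCovariance(
        matrix=a[np.ix_(rows, rows)],
        kind="pedigree_kinship",
        subject_ids=np.asarray(subject_ids, dtype=object),
    )


def _topological_order(parent: dict) -> list:
    """Parents-before-offspring ordering; detects ancestry cycles."""
    order: list = []
    state: dict = {}  # 0 visiting, 1 done

    def visit(iid, stack):
        if state.get(iid) == 1:
            return
        if state.get(iid) == 0:
            raise ValueError(f"pedigree cycle: {iid!r} is its own ancestor")
        state[iid] = 0
        for p in parent[iid]:
            if p is not None:
                visit(p, stack + [iid])
        state[iid] = 1
        order.append(iid)

    for iid in parent:
        visit(iid, [])
    return order
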