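"""Direct genomic values for validation animals and accuracy testing.

A validation animal's DGV is ``mu_hat + w_k' g_hat (+ a_hat_k)`` with the
marker row standardized on the *reference* population's allele frequencies.
Accuracy is the Pearson correlation between DGV and the (pseudo-)phenotype.
Two prediction methods validated on the same animals give dependent
accuracies sharing one variable; their difference is tested with the
Hotelling-Williams t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_prep import RelationshipMatrix, StandardizedGenotypes
from .io_formats import PhenotypeTable

__all__ = [
    "DGVTable",
    "ValidationResult",
    "predict_dgv",
    "accuracy",
    "hotelling_williams",
    "compare_runs",
    "chain_stability",
]


@dataclass
class DGVTable:
    """Predicted direct genomic values with their additive breakdown."""

    df: pd.DataFrame  # sample_id, dgv, mu_hat, marker_term, polygenic_term

    def __post_init__(self):
        need = {"sample_id", "dgv"}
        if not need.issubset(self.df.columns):
            raise ValueError("DGV table needs sample_id and dgv columns")
        if self.df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in DGV table")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy(dtype=object)

    @property
    def dgv(self) -> np.ndarray:
        return self.df["dgv"].to_numpy(dtype=float)


@dataclass
class ValidationResult:
    r: float
    n_validation: int
    t: float | None = None
    df: int | None = None
    p_two_sided: float | None = None


def predict_dgv(
    summary,
    W_val: StandardizedGenotypes,
    polygenic_mode: str = "none",
    A: RelationshipMatrix | None = None,
    reference_ids=None,
    validation_ids=None,
) -> DGVTable:
    """DGV_k = mu_hat + w_k' g_hat + a_hat_k for each validation animal.

    ``polygenic_mode="none"`` (default) gives the marker-only DGV. With
    ``"pedigree"``, the polygenic term is projected onto validation animals
    through the relationship matrix: ``a_val = A_vr A_rr^{-1} a_ref_hat``;
    an animal unrelated to every reference animal gets exactly zero.
    """
    if list(W_val.source_map.marker_id) != list(summary.map.marker_id):
        raise ValueError("marker panel of W_val does not match the fitted effects")
    ids = validation_ids
    if ids is None:
        raise ValueError("validation_ids (sample ids matching W_val rows) required")
    ids = np.asarray(ids, dtype=object)
    if len(ids) != W_val.n_samples:
        raise ValueError("validation_ids length does not match W_val rows")
    marker_term = W_val.W @ summary.g_mean
    poly = np.zeros(W_val.n_samples)
    if polygenic_mode == "pedigree":
        if summary.a_mean is None:
            raise ValueError("summary has no polygenic estimates")
        if A is None or reference_ids is None:
            raise ValueError("pedigree mode needs A and reference_ids")
        pos = {s: i for i, s in enumerate(A.ids)}
        ridx = np.array([pos[s] for s in reference_ids])
        vidx = np.array([pos[s] for s in ids])
        A_rr = A.A[np.ix_(ridx, ridx)]
        A_vr = A.A[np.ix_(vidx, ridx)]
        poly = A_vr @ np.linalg.solve(A_rr, summary.a_mean)
    elif polygenic_mode != "none":
        raise ValueError("polygenic_mode must be 'none' or 'pedigree'")
    df = pd.DataFrame(
        {
            "sample_id": ids,
            "dgv": summary.mu_mean + marker_term + poly,
            "mu_hat": summary.mu_mean,
            "marker_term": marker_term,
            "polygenic_term": poly,
        }
    )
    return DGVTable(df)


def accuracy(dgv: DGVTable, pheno: PhenotypeTable, trait: str) -> ValidationResult:
    """Pearson correlation r(DGV, phenotype) over the shared animals."""
    sub = pheno.for_trait(trait).set_index("sample_id")
    common = [s for s in dgv.sample_ids if s in sub.index]
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping animals")
    d = dgv.df.set_index("sample_id").loc[common, "dgv"].to_numpy(dtype=float)
    y = sub.loc[common, "value"].to_numpy(dtype=float)
    if d.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in DGV or phenotype")
    return ValidationResult(r=float(np.corrcoef(d, y)[0, 1]), n_validation=len(common))


def hotelling_williams(r12: float, r13: float, r23: float, n: int):
    """Test equality of two dependent correlations sharing variable 1.

    Variable 1 is the shared phenotype; 2 and 3 are the two DGV sets.
    With ``|R| = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23`` and
    ``rbar = (r12 + r13)/2``,

        t = (r12 - r13) * sqrt( (n-1)(1+r23) /
              ( 2 |R| (n-1)/(n-3) + rbar^2 (1-r23)^3 ) )

    on n - 3 degrees of freedom; p is two-sided.
    """
    if n < 4:
        raise ValueError("need n >= 4 validation animals")
    for r in (r12, r13, r23):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    if detR < -1e-10:
        raise ValueError("incoherent correlation triple (negative determinant)")
    detR = max(detR, 0.0)
    rbar = 0.5 * (r12 + r13)
    df = n - 3
    denom = 2.0 * detR * (n - 1) / df + rbar**2 * (1.0 - r23) ** 3
    if denom <= 0:
        raise ValueError("degenerate correlation triple")
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def compare_runs(
    dgv_a: DGVTable, dgv_b: DGVTable, pheno: PhenotypeTable, trait: str
) -> tuple[ValidationResult, ValidationResult]:
    """Accuracies of two DGV sets on the same animals plus their HW test.

    Returns (result_a, result_b); result_a carries the t, df and two-sided p
    for the difference r(pheno, a) - r(pheno, b).
    """
    ids_a = set(dgv_a.sample_ids)
    ids_b = set(dgv_b.sample_ids)
    if ids_a != ids_b:
        raise ValueError("DGV tables cover different validation animals")
    sub = pheno.for_trait(trait).set_index("sample_id")
    common = [s for s in dgv_a.sample_ids if s in sub.index]
    if len(common) < 4:
        raise ValueError("need at least 4 overlapping animals for the test")
    y = sub.loc[common, "value"].to_numpy(dtype=float)
    a = dgv_a.df.set_index("sample_id").loc[common, "dgv"].to_numpy(dtype=float)
    b = dgv_b.df.set_index("sample_id").loc[common, "dgv"].to_numpy(dtype=float)
    r12 = float(np.corrcoef(y, a)[0, 1])
    r13 = float(np.corrcoef(y, b)[0, 1])
    r23 = float(np.corrcoef(a, b)[0, 1])
    if r12 == r13:
        t, df, p = 0.0, len(common) - 3, 1.0
    else:
        t, df, p = hotelling_williams(r12, r13, r23, len(common))
    res_a = ValidationResult(r=r12, n_validation=len(common), t=t, df=df, p_two_sided=p)
    res_b = ValidationResult(r=r13, n_validation=len(common))
    return res_a, res_b


def chain_stability(summaries) -> float:
    """Mean pairwise correlation of segment-variance profiles across runs.

    The conventional chain-length diagnostic: consecutive independent runs
    of an adequately long chain give near-identical segment-variance maps.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries")
    first = summaries[0].report_partition
    vecs = []
    for s in summaries:
        if not s.report_partition.same_layout(first):
            raise ValueError("summaries use different reporting partitions")
        vecs.append(np.asarray(s.segment_variances.variances, dtype=float))
    cors = []
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            cors.append(float(np.corrcoef(vecs[i], vecs[j])[0, 1]))
    return float(np.mean(cors))
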