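"""Genomic (VanRaden) and pedigree relationship matrices.

The genomic relationship matrix is VanRaden method 1:

    G = M M' / (2 sum_j p_j (1 - p_j))

where row entries of M are (2 - 2p_j), (1 - 2p_j) and (-2p_j) for counted-
allele dosages 2, 1 and 0, and p_j is the observed frequency of the counted
allele.  Columns of M sum to zero under observed frequencies, so all entries
of G sum to zero — the identity behind the scale diagnostics (mean diagonal
~ 1, mean off-diagonal ~ 0) used to check comparability of A and G.

The pedigree numerator relationship matrix A uses the tabular method:
A_ii = 1 + 0.5 A(sire, dam), A_ij = 0.5 (A_j,sire(i) + A_j,dam(i)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ovinepred.containers import GenotypeMatrix, Pedigree

__all__ = [
    "RelationshipMatrix",
    "ScaleDiagnostics",
    "RelatednessGroups",
    "compute_grm",
    "compute_nrm",
    "classify_relatedness",
    "scale_diagnostics",
    "centered_coding",
]


@dataclass
class RelationshipMatrix:
    """Dense symmetric relationship matrix with provenance."""

    ids: np.ndarray
    values: np.ndarray
    source: str  # "markers" | "pedigree"
    panel_label: str = ""
    freq_source: str = ""

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.ids.size
        if self.values.shape != (n, n):
            raise ValueError("values must be n x n for n ids")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValueError("relationship matrix must be symmetric within 1e-10")
        if self.source == "markers" and (np.diag(self.values) < 0).any():
            raise ValueError("marker-based relationship diagonal must be nonnegative")
        if self.source == "pedigree" and (np.diag(self.values) < 1 - 1e-12).any():
            raise ValueError("pedigree relationship diagonal must be >= 1")

    @property
    def n(self) -> int:
        return self.ids.size

    def index_of(self, wanted_ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[w] for w in wanted_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in relationship matrix") from exc

    def submatrix(self, wanted_ids) -> "RelationshipMatrix":
        idx = self.index_of(wanted_ids)
        return RelationshipMatrix(
            ids=self.ids[idx],
            values=self.values[np.ix_(idx, idx)],
            source=self.source,
            panel_label=self.panel_label,
            freq_source=self.freq_source,
        )


@dataclass
class ScaleDiagnostics:
    mean_diagonal: float
    mean_offdiagonal: float


@dataclass
class RelatednessGroups:
    """Partition of candidates by genomic relatedness to a reference set.

    high: mean of the k_top largest relationships to the reference >= high
    threshold; low: no relationship to the reference above the low
    threshold; neither: the rest.
    """

    high: list
    low: list
    neither: list
    k_top: int = 30
    high_threshold: float = 0.20
    low_threshold: float = 0.10

    def label_of(self) -> dict:
        out = {}
        for lab, ids in (("high", self.high), ("low", self.low), ("neither", self.neither)):
            for i in ids:
                out[i] = lab
        return out


def centered_coding(geno: GenotypeMatrix, freqs: np.ndarray | None = None):
    """VanRaden M matrix (dosage - 2p) and the frequencies used.

    Missing genotypes are mean-imputed (their centered entry is 0, adding no
    spurious relationship).
    """
    d = geno.dosage()
    if freqs is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            freqs = np.nanmean(d, axis=0) / 2.0
    freqs = np.where(np.isnan(freqs), 0.0, freqs)
    M = d - 2.0 * freqs[None, :]
    M[np.isnan(M)] = 0.0
    return M, freqs


def compute_grm(
    geno: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    panel_label: str = "",
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix.

    Allele frequencies default to the observed frequencies in the supplied
    individuals (pass ``freqs`` to use e.g. reference-only frequencies).
    Monomorphic SNPs contribute nothing to numerator or denominator.
    """
    M, p = centered_coding(geno, freqs)
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all SNPs monomorphic: GRM denominator is zero")
    Mp = np.ascontiguousarray(M[:, poly])
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = (Mp @ Mp.T) / denom
    G = 0.5 * (G + G.T)  # enforce exact symmetry against rounding
    return RelationshipMatrix(
        ids=geno.ids.copy(),
        values=G,
        source="markers",
        panel_label=panel_label,
        freq_source="supplied" if freqs is not None else "observed",
    )


def compute_nrm(ped: Pedigree) -> RelationshipMatrix:
    """Pedigree numerator relationship matrix by the tabular method."""
    t = ped.table
    ids = t["id"].to_numpy(dtype=object)
    idx = {v: i for i, v in enumerate(ids)}
    n = ids.size
    sires = np.array([idx.get(s, -1) for s in t["sire"]], dtype=np.int64)
    dams = np.array([idx.get(d, -1) for d in t["dam"]], dtype=np.int64)
    if ((sires >= np.arange(n)) & (sires >= 0)).any() or (
        (dams >= np.arange(n)) & (dams >= 0)
    ).any():
        raise ValueError("pedigree not topologically ordered (cycle or forward reference)")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sires[i], dams[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix(ids=ids, values=A, source="pedigree")


def classify_relatedness(
    grm: RelationshipMatrix,
    reference,
    candidates,
    k_top: int = 30,
    high_threshold: float = 0.20,
    low_threshold: float = 0.10,
) -> RelatednessGroups:
    """Split candidates into high / low / neither relatedness to a reference.

    high: mean of the candidate's ``k_top`` largest genomic relationships to
    the reference at or above ``high_threshold``; low: maximum relationship
    to any reference individual at or below ``low_threshold``.  Ties at the
    k_top boundary are handled by the sorted top-k (equal values interchange
    freely, so the mean is unaffected).
    """
    reference = list(reference)
    candidates = list(candidates)
    if set(reference) & set(candidates):
        raise ValueError("reference and candidate sets must be disjoint")
    ref_idx = grm.index_of(reference)
    cand_idx = grm.index_of(candidates)
    if len(reference) < k_top:
        warnings.warn(
            f"only {len(reference)} reference animals for k_top={k_top}; using all",
            stacklevel=2,
        )
    k = min(k_top, len(reference))
    rel = grm.values[np.ix_(cand_idx, ref_idx)]
    top_mean = np.sort(rel, axis=1)[:, -k:].mean(axis=1)
    max_rel = rel.max(axis=1)
    high, low, neither = [], [], []
    for cid, tm, mx in zip(candidates, top_mean, max_rel):
        if tm >= high_threshold:
            high.append(cid)
        elif mx <= low_threshold:
            low.append(cid)
        else:
            neither.append(cid)
    return RelatednessGroups(
        high=high,
        low=low,
        neither=neither,
        k_top=k_top,
        high_threshold=high_threshold,
        low_threshold=low_threshold,
    )


def scale_diagnostics(rel: RelationshipMatrix) -> ScaleDiagnostics:
    """Exact means of diagonal and strict off-diagonal entries."""
    n = rel.n
    if n < 2:
        raise ValueError("need at least 2 individuals")
    diag = np.diag(rel.values)
    total = rel.values.sum()
    off = (total - diag.sum()) / (n * n - n)
    return ScaleDiagnostics(mean_diagonal=float(diag.mean()), mean_offdiagonal=float(off))
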