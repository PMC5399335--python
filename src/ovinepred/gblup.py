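"""Breeding-value prediction by solving Henderson's mixed-model equations.

At fixed variance components the MME for the full model are

    [ X'X      X'Z*            ] [ b ]   [ X'y ]
    [ Z*'X     Z*'Z* + D       ] [ u ] = [ Z*'y ]

(in units of the residual variance), where Z* stacks the random-term
designs and D holds K^-1 lambda_a for the additive term (K the genomic or
pedigree relationship matrix over phenotyped and predict animals,
lambda = v_residual / v_term) and I lambda for the i.i.d. terms.
Unphenotyped animals in ``predict_ids`` receive BLUPs purely through their
relationship rows.  Replacing A by G in K is what turns pedigree BLUP into
GBLUP; the numbers fall out of the same equations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from ovinepred.phenomodel import PhenotypeDesign, VarianceComponents
from ovinepred.relmat import RelationshipMatrix

__all__ = ["PredictionResult", "solve_mme", "reliability"]

_RIDGE = 1e-8


@dataclass
class PredictionResult:
    """Per-animal predicted additive genetic values."""

    ids: np.ndarray
    gbv: np.ndarray
    method: str
    fixed_solutions: dict = field(default_factory=dict)
    reliability: np.ndarray | None = None
    mme_residual: float = 0.0

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.gbv = np.asarray(self.gbv, dtype=np.float64)
        if len(set(self.ids)) != self.ids.size:
            raise ValueError("prediction ids must be unique")
        if not np.isfinite(self.gbv).all():
            raise ValueError("gbv must be finite")
        if not self.method:
            raise ValueError("method tag must be set")

    def gbv_for(self, wanted_ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        return self.gbv[[lookup[w] for w in wanted_ids]]


def _assemble(design: PhenotypeDesign, rel: RelationshipMatrix, vc: VarianceComponents, predict_ids):
    """Coefficient matrix, right-hand side and block layout of the MME."""
    X, y = design.X, design.y
    n, p = X.shape

    predict_ids = [i for i in predict_ids if i not in set(design.animal_ids)]
    all_animals = np.concatenate([design.animal_ids, np.array(predict_ids, dtype=object)])
    missing = [i for i in all_animals if i not in set(rel.ids)]
    if missing:
        raise KeyError(f"animals not in relationship matrix: {missing[:10]}")

    K = rel.submatrix(all_animals).values
    n_a = all_animals.size
    Z1 = design.Z1
    Za = sp.hstack([Z1, sp.csr_matrix((n, n_a - Z1.shape[1]))]).tocsr()

    lam_a = vc.v_residual / vc.v_additive
    Kinv, ridged = _inv_psd(K)
    if ridged:
        warnings.warn(
            f"relationship matrix not positive definite; added {_RIDGE} to the diagonal",
            stacklevel=3,
        )

    blocks = [("additive", Za, Kinv * lam_a)]
    if vc.v_maternal > 0 and design.term_active("maternal"):
        blocks.append(
            ("maternal", design.W, np.eye(design.dam_ids.size) * (vc.v_residual / vc.v_maternal))
        )
    if vc.v_breed > 0 and design.term_active("breed"):
        ZQ = sp.csr_matrix(design.Z1 @ design.Q)
        blocks.append(
            ("breed", ZQ, np.eye(len(design.breed_labels)) * (vc.v_residual / vc.v_breed))
        )
    if vc.v_sireflock > 0 and design.term_active("sireflock"):
        blocks.append(
            (
                "sireflock",
                design.Z2,
                np.eye(design.sireflock_ids.size) * (vc.v_residual / vc.v_sireflock),
            )
        )

    Zs = [sp.csr_matrix(Z) for _, Z, _ in blocks]
    sizes = [Z.shape[1] for Z in Zs]
    dim = p + sum(sizes)
    C = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    C[:p, :p] = X.T @ X
    rhs[:p] = X.T @ y
    offs = np.cumsum([p] + sizes)
    for bi, Z in enumerate(Zs):
        lo, hi = offs[bi], offs[bi + 1]
        XtZ = X.T @ Z
        C[:p, lo:hi] = XtZ
        C[lo:hi, :p] = XtZ.T
        for bj in range(bi, len(Zs)):
            lo2, hi2 = offs[bj], offs[bj + 1]
            ZtZ = (Zs[bi].T @ Zs[bj]).toarray()
            C[lo:hi, lo2:hi2] = ZtZ
            C[lo2:hi2, lo:hi] = ZtZ.T
        rhs[lo:hi] = np.asarray(Z.T @ y).ravel()
        C[lo:hi, lo:hi] += blocks[bi][2]
    return C, rhs, offs, blocks, all_animals


def _inv_psd(K: np.ndarray):
    # a marker-based K is often singular (centered coding forces a zero
    # eigenvalue), which Cholesky may "survive" with a uselessly conditioned
    # factor — detect that and fall back to the documented 1e-6 ridge
    eye = np.eye(K.shape[0])
    try:
        cf = sla.cho_factor(K, lower=True, check_finite=False)
        Kinv = sla.cho_solve(cf, eye, check_finite=False)
        if np.abs(K @ Kinv - eye).max() < 1e-8:
            return Kinv, False
    except np.linalg.LinAlgError:
        pass
    Kr = K + _RIDGE * eye
    cf = sla.cho_factor(Kr, lower=True, check_finite=False)
    return sla.cho_solve(cf, eye, check_finite=False), True


def solve_mme(
    design: PhenotypeDesign,
    rel: RelationshipMatrix,
    vc: VarianceComponents,
    predict_ids=(),
    method: str | None = None,
) -> PredictionResult:
    """Solve the MME; returns breeding values for phenotyped and predict animals.

    ``method`` tags the result (defaults to PBLUP/GBLUP from the matrix
    source).  ``mme_residual`` reports the max absolute residual of the
    solved system relative to the right-hand-side scale.
    """
    if vc.v_residual <= 0:
        raise ValueError("residual variance must be positive")
    if method is None:
        method = "PBLUP" if rel.source == "pedigree" else "GBLUP"

    predict_list = list(predict_ids)
    if vc.v_additive <= 0:
        # full-shrinkage limit: every breeding value is 0
        extra = [i for i in predict_list if i not in set(design.animal_ids)]
        ids = np.concatenate([design.animal_ids, np.array(extra, dtype=object)])
        beta, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        return PredictionResult(
            ids=ids,
            gbv=np.zeros(ids.size),
            method=method,
            fixed_solutions=dict(zip(design.x_names, beta)),
        )

    C, rhs, offs, blocks, all_animals = _assemble(design, rel, vc, predict_list)
    lu = sla.lu_factor(C, check_finite=False)
    sol = sla.lu_solve(lu, rhs, check_finite=False)
    scale = max(np.abs(rhs).max(), 1.0)
    for _ in range(3):  # iterative refinement: C can be badly conditioned
        r = rhs - C @ sol
        resid = float(np.abs(r).max()) / scale
        if resid < 1e-12:
            break
        sol = sol + sla.lu_solve(lu, r, check_finite=False)
    resid = float(np.abs(C @ sol - rhs).max()) / scale
    if resid > 1e-6:
        warnings.warn(f"MME solve residual {resid:.2e} exceeds 1e-6 of scale", stacklevel=2)

    p = design.X.shape[1]
    a_lo, a_hi = offs[0], offs[1]
    return PredictionResult(
        ids=all_animals,
        gbv=sol[a_lo:a_hi],
        method=method,
        fixed_solutions=dict(zip(design.x_names, sol[:p])),
        mme_residual=resid,
    )


def reliability(
    design: PhenotypeDesign,
    rel: RelationshipMatrix,
    vc: VarianceComponents,
    ids=None,
) -> dict:
    """Prediction-error-variance reliability per animal.

    r_i = 1 - PEV_i / (v_additive * K_ii), with PEV from the additive block
    of the inverse MME coefficient matrix.
    """
    if vc.v_additive <= 0:
        raise ValueError("reliability undefined at zero additive variance")
    predict = [] if ids is None else [i for i in ids if i not in set(design.animal_ids)]
    C, rhs, offs, blocks, all_animals = _assemble(design, rel, vc, predict)
    Cinv = sla.inv(C, check_finite=False)
    a_lo, a_hi = offs[0], offs[1]
    pev = np.diag(Cinv)[a_lo:a_hi] * vc.v_residual
    K = rel.submatrix(all_animals).values
    rr = 1.0 - pev / (vc.v_additive * np.diag(K))
    rr = np.clip(rr, 0.0, 1.0)
    out = dict(zip(all_animals, rr))
    if ids is not None:
        return {i: out[i] for i in ids}
    return out
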