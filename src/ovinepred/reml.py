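"""REML variance components by average information with EM fallback.

The model is the full mixed model held by :class:`PhenotypeDesign`:

    y = Xb + Z1 a + W w + Z1 Q q + Z2 s + e

with a ~ N(0, K sigma_a^2) for K the supplied relationship matrix (A or G)
and i.i.d. maternal, breed and sire-by-flock effects.  The restricted
likelihood is evaluated in the phenotypic-covariance form

    V(theta) = sum_i theta_i Z_i K_i Z_i' + theta_e I,
    -2 lR = log|V| + log|X' V^-1 X| + y' P y,

which for the desk-scale record counts this pipeline uses (n up to a few
thousand) is direct, numerically transparent and fast enough.  Updates are
average-information (AI) steps with step-halving on likelihood decreases; an
update that would push a component negative falls back to the EM-type
multiplicative fixed point theta_i <- theta_i * (y'P V_i P y) / tr(P V_i),
which preserves positivity and shares the REML score's stationary points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from ovinepred.phenomodel import PhenotypeDesign, VarianceComponents
from ovinepred.relmat import RelationshipMatrix

__all__ = ["REMLResult", "fit_reml", "restricted_loglik"]

_TERMS = ("additive", "maternal", "breed", "sireflock")
_FLOOR_FRAC = 1e-8
_MAX_ITER = 200
_LL_TOL = 1e-8
_GRAD_TOL = 1e-6


@dataclass
class REMLResult:
    components: VarianceComponents
    loglik: float
    n_iter: int
    converged: bool
    se: dict

    def __post_init__(self) -> None:
        if not np.isfinite(self.loglik):
            raise ValueError("restricted log-likelihood must be finite")


def _term_covariances(design: PhenotypeDesign, rel: RelationshipMatrix, terms):
    """Observation-level covariance contribution V_i = Z_i K_i Z_i' per term."""
    n = design.n_records
    out = []
    for term in terms:
        Z = design.random_design(term)
        if term == "additive":
            K = rel.submatrix(design.animal_ids).values
            Zd = np.asarray(Z.todense()) if hasattr(Z, "todense") else Z
            Vi = Zd @ K @ Zd.T
        else:
            Zd = np.asarray(Z.todense()) if hasattr(Z, "todense") else np.asarray(Z)
            Vi = Zd @ Zd.T
        out.append(np.ascontiguousarray(Vi, dtype=np.float64))
    out.append(np.eye(n))  # residual
    return out


def _active_terms(design: PhenotypeDesign, terms=None):
    if terms is None:
        terms = [t for t in _TERMS if design.term_active(t)]
    else:
        terms = list(terms)
        for t in terms:
            if t not in _TERMS:
                raise KeyError(f"unknown random term {t!r}")
            if not design.term_active(t):
                raise ValueError(f"term {t!r} has no support in this design")
    return terms


def _vc_to_theta(start: VarianceComponents, terms) -> np.ndarray:
    attr = {
        "additive": "v_additive",
        "maternal": "v_maternal",
        "breed": "v_breed",
        "sireflock": "v_sireflock",
    }
    theta = [getattr(start, attr[t]) for t in terms] + [start.v_residual]
    theta = np.asarray(theta, dtype=np.float64)
    if (theta[:-1] < 0).any() or theta[-1] <= 0:
        raise ValueError("starting variances must be positive")
    return theta


def _loglik_and_P(X, y, V):
    """Restricted log-likelihood, the projection matrix P and Py."""
    cf = sla.cho_factor(V, lower=True, check_finite=False)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv = sla.cho_solve(cf, np.eye(V.shape[0]), check_finite=False)
    XtVinv = X.T @ Vinv
    XtVinvX = XtVinv @ X
    cf2 = sla.cho_factor(XtVinvX, lower=True, check_finite=False)
    logdet_x = 2.0 * np.sum(np.log(np.diag(cf2[0])))
    B = sla.cho_solve(cf2, XtVinv, check_finite=False)  # (X'V^-1X)^-1 X'V^-1
    P = Vinv - XtVinv.T @ B
    Py = P @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return ll, P, Py


def restricted_loglik(
    design: PhenotypeDesign,
    rel: RelationshipMatrix,
    vc: VarianceComponents,
    terms=None,
) -> float:
    """Restricted log-likelihood at the given variance components."""
    terms = _active_terms(design, terms)
    Vis = _term_covariances(design, rel, terms)
    theta = _vc_to_theta(vc, terms)
    V = sum(t * Vi for t, Vi in zip(theta, Vis))
    ll, _, _ = _loglik_and_P(design.X, design.y, V)
    return ll


def _theta_to_vc(theta, terms, se_map=None, h2_se=None) -> VarianceComponents:
    vals = dict(zip(terms, theta[:-1]))
    return VarianceComponents(
        v_additive=float(vals.get("additive", 0.0)),
        v_maternal=float(vals.get("maternal", 0.0)),
        v_breed=float(vals.get("breed", 0.0)),
        v_sireflock=float(vals.get("sireflock", 0.0)),
        v_residual=float(theta[-1]),
        se=se_map or {},
        h2_se=h2_se,
    )


def fit_reml(
    design: PhenotypeDesign,
    rel: RelationshipMatrix,
    start: VarianceComponents | None = None,
    terms=None,
    max_iter: int = _MAX_ITER,
) -> REMLResult:
    """Estimate variance components by AI-REML.

    ``terms`` selects the random terms to model (default: every term with
    support in the design).  Non-convergence within ``max_iter`` flags the
    result rather than raising.  Standard errors come from the inverse AI
    matrix at the optimum; the heritability SE is by the delta method.
    """
    terms = _active_terms(design, terms)
    X, y = design.X, design.y
    n = y.size
    Vis = _term_covariances(design, rel, terms)
    k = len(Vis)

    if start is None:
        vp = float(np.var(y))
        theta = np.full(k, 0.5 * vp / max(k - 1, 1))
        theta[-1] = 0.5 * vp
    else:
        theta = _vc_to_theta(start, terms)

    total = theta.sum()
    floor = _FLOOR_FRAC * total

    ll_prev = -np.inf
    converged = False
    it = 0
    AI = np.eye(k)
    for it in range(1, max_iter + 1):
        V = sum(t * Vi for t, Vi in zip(theta, Vis))
        try:
            ll, P, Py = _loglik_and_P(X, y, V)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular phenotypic covariance at iteration {it}"
            ) from exc

        # score and average-information matrix
        PVi = [P @ Vi for Vi in Vis]
        ViPy = [Vi @ Py for Vi in Vis]
        score = np.array(
            [-0.5 * (np.trace(PVi_i) - float(Py @ ViPy_i)) for PVi_i, ViPy_i in zip(PVi, ViPy)]
        )
        AI = np.empty((k, k))
        PViPy = [P @ v for v in ViPy]
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(ViPy[i] @ PViPy[j])

        # convergence: relative loglik change and projected gradient norm
        grad = score.copy()
        at_floor = theta <= floor * (1 + 1e-12)
        grad[at_floor & (grad < 0)] = 0.0
        rel_change = abs(ll - ll_prev) / (abs(ll) + 1.0)
        if rel_change < _LL_TOL and np.linalg.norm(grad) < _GRAD_TOL * max(1.0, abs(ll)):
            converged = True
            break
        ll_prev = ll

        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = score / np.maximum(np.diag(AI), 1e-12)
        proposal = theta + delta
        if (proposal < floor).any():
            # EM-type multiplicative fallback: positive by construction
            num = np.array([float(Py @ v) for v in ViPy])
            den = np.array([np.trace(p) for p in PVi])
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(den > 0, num / den, 1.0)
            proposal = np.maximum(theta * ratio, floor)
        else:
            # step-halving if the AI step lowers the restricted likelihood
            for _ in range(8):
                Vn = sum(t * Vi for t, Vi in zip(proposal, Vis))
                try:
                    ll_new, _, _ = _loglik_and_P(X, y, Vn)
                except np.linalg.LinAlgError:
                    ll_new = -np.inf
                if ll_new >= ll - 1e-10:
                    break
                proposal = theta + 0.5 * (proposal - theta)
        theta = np.maximum(proposal, floor)

    # SEs from inverse AI at the optimum
    try:
        ai_inv = np.linalg.inv(AI)
        se_vec = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
    except np.linalg.LinAlgError:
        ai_inv = np.full((k, k), np.nan)
        se_vec = np.full(k, np.nan)
    se_map = {t: float(s) for t, s in zip(list(terms) + ["residual"], se_vec)}

    h2_se = _h2_se_delta(theta, ai_inv, terms)
    vc = _theta_to_vc(theta, terms, se_map, h2_se)
    V = sum(t * Vi for t, Vi in zip(theta, Vis))
    ll, _, _ = _loglik_and_P(X, y, V)
    return REMLResult(components=vc, loglik=float(ll), n_iter=it, converged=converged, se=se_map)


def _h2_se_delta(theta, ai_inv, terms) -> float | None:
    """Delta-method SE of h2 = v_a / (v_a + v_m + v_sf + v_e).

    The breed component is excluded from the denominator, so its gradient
    entry is zero.
    """
    if not np.isfinite(ai_inv).all():
        return None
    labels = list(terms) + ["residual"]
    in_denom = np.array([lab != "breed" for lab in labels], dtype=float)
    try:
        ia = labels.index("additive")
    except ValueError:
        return None
    va = theta[ia]
    denom = float(np.sum(theta * in_denom))
    grad = -va / denom**2 * in_denom
    grad[ia] += 1.0 / denom
    var = float(grad @ ai_inv @ grad)
    return float(np.sqrt(max(var, 0.0)))
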