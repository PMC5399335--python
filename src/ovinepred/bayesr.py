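"""BayesR: SNP effects under a four-component normal mixture, by Gibbs sampling.

Each SNP effect is drawn from one of four normal components with variances
(0, 0.0001, 0.001, 0.01) x sigma_g2, where sigma_g2 is the assumed total
genetic variance (taken from a GREML fit); mixture proportions carry a
Dirichlet prior.  The sampler follows the model

    y = Xb + M1 m + W w + Z1 Q q + Z2 s + e

and per iteration (i) block-samples fixed effects, (ii) samples each
non-SNP random term and its variance (scaled inverse chi-squared, nu = 4),
(iii) sweeps the SNPs in a freshly seeded random order, sampling component
membership from its marginal likelihood and then the effect from its normal
full conditional, updating the residual incrementally, (iv) samples the
mixture proportions from Dirichlet(alpha + counts) and (v) the residual
variance from its full conditional.  The SNP sweep is JIT-compiled; all
randomness flows from the single seed in the priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from numba import njit

from ovinepred.containers import GenotypeMatrix
from ovinepred.phenomodel import PhenotypeDesign
from ovinepred.relmat import centered_coding

__all__ = ["BayesRPriors", "BayesRPosterior", "run_bayesr", "component_variances", "effective_sample_size"]

_NEG_INF = -1e300


@dataclass
class BayesRPriors:
    """Prior settings of the four-component mixture sampler."""

    sigma_g2: float
    variance_ratios: tuple = (0.0, 1e-4, 1e-3, 1e-2)
    dirichlet_alpha: tuple = (1.0, 1.0, 1.0, 1.0)
    n_iter: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    fix_pi: tuple | None = None  # pin mixture proportions (skips the Dirichlet draw)
    sample_sigma_g2: bool = False  # re-sample sigma_g2 instead of keeping it fixed
    nu_random: float = 4.0  # scaled-inv-chi2 df for the non-SNP random terms

    def __post_init__(self) -> None:
        if self.sigma_g2 <= 0:
            raise ValueError("sigma_g2 must be positive")
        ratios = tuple(float(v) for v in self.variance_ratios)
        if len(ratios) != 4 or ratios[0] != 0.0 or any(np.diff(ratios) < 0):
            raise ValueError("variance_ratios must be 4 nondecreasing values starting at 0")
        self.variance_ratios = ratios
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.fix_pi is not None:
            fp = np.asarray(self.fix_pi, dtype=float)
            if fp.size != 4 or fp.min() < 0 or abs(fp.sum() - 1) > 1e-9:
                raise ValueError("fix_pi must be 4 nonnegative values summing to 1")
            self.fix_pi = tuple(fp)


@dataclass
class BayesRPosterior:
    """Posterior summaries over post-burn-in thinned samples."""

    snp_ids: np.ndarray
    snp_effect_means: np.ndarray
    component_probs: np.ndarray
    pi_mean: np.ndarray
    pi_trace: np.ndarray  # kept-sample mixture proportions, (n_kept, 4)
    ids: np.ndarray
    gbv: np.ndarray
    other_effect_means: dict
    chain_diagnostics: dict
    sigma_e2_mean: float

    def __post_init__(self) -> None:
        if np.abs(self.component_probs.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("component_probs rows must sum to 1")
        if abs(self.pi_mean.sum() - 1.0) > 1e-9:
            raise ValueError("pi_mean must sum to 1")

    def gbv_for(self, wanted_ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        return self.gbv[[lookup[w] for w in wanted_ids]]


def component_variances(priors: BayesRPriors) -> np.ndarray:
    """Elementwise component variances: variance_ratios x sigma_g2."""
    return np.asarray(priors.variance_ratios, dtype=float) * priors.sigma_g2


@njit(fastmath=False)
def _snp_sweep(M, r, beta, comp, xtx, logpi, sig2, sige2, order, u, z):
    n = M.shape[0]
    counts = np.zeros(4, dtype=np.int64)
    ll = np.empty(4)
    for t in range(order.size):
        j = order[t]
        bj = beta[j]
        if bj != 0.0:
            for i in range(n):
                r[i] += M[i, j] * bj
        rhs = 0.0
        for i in range(n):
            rhs += M[i, j] * r[i]
        xx = xtx[j]
        best = _NEG_INF
        for k in range(4):
            if logpi[k] <= _NEG_INF:
                ll[k] = _NEG_INF
            else:
                v = xx * xx * sig2[k] + xx * sige2
                if v <= 0.0:
                    ll[k] = logpi[k]
                else:
                    ll[k] = logpi[k] - 0.5 * np.log(v) - 0.5 * rhs * rhs / v
            if ll[k] > best:
                best = ll[k]
        tot = 0.0
        for k in range(4):
            if ll[k] > _NEG_INF:
                ll[k] = np.exp(ll[k] - best)
            else:
                ll[k] = 0.0
            tot += ll[k]
        target = u[t] * tot
        acc = 0.0
        pick = 0
        for k in range(4):
            acc += ll[k]
            if target <= acc:
                pick = k
                break
        comp[j] = pick
        counts[pick] += 1
        if sig2[pick] > 0.0:
            prec = xx + sige2 / sig2[pick]
            mean = rhs / prec
            sd = np.sqrt(sige2 / prec)
            bnew = mean + sd * z[t]
            beta[j] = bnew
            for i in range(n):
                r[i] -= M[i, j] * bnew
        else:
            beta[j] = 0.0
    return counts


def _sample_class_term(r, Z, counts_per_level, u_old, sigma2, sige2, rng):
    """One-hot random term: add back, sample each level, subtract."""
    r += Z @ u_old
    rhs = np.asarray(Z.T @ r).ravel()
    prec = counts_per_level + sige2 / sigma2
    mean = rhs / prec
    u_new = mean + np.sqrt(sige2 / prec) * rng.standard_normal(mean.size)
    r -= Z @ u_new
    return u_new


def _sample_dense_term(r, Z, ZtZ, u_old, sigma2, sige2, rng):
    """Small dense random term (breed effects through Q): joint draw."""
    r += Z @ u_old
    rhs = np.asarray(Z.T @ r).ravel()
    A = ZtZ / sige2 + np.eye(ZtZ.shape[0]) / sigma2
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, rhs / sige2)
    u_new = mean + sla.solve_triangular(L.T, rng.standard_normal(mean.size))
    r -= Z @ u_new
    return u_new


def _sample_variance(u, nu0, s0, rng):
    """Scaled-inverse-chi-squared full conditional for a term variance."""
    q = u.size
    ssq = float(u @ u)
    df = q + nu0
    return (ssq + nu0 * s0) / rng.chisquare(df)


def run_bayesr(
    design: PhenotypeDesign,
    geno: GenotypeMatrix,
    priors: BayesRPriors,
) -> BayesRPosterior:
    """Run the Gibbs sampler and summarize the posterior.

    ``geno`` must contain every phenotyped animal; extra individuals
    (validation sires) get genomic breeding values through the posterior
    mean SNP effects.  Genotypes are centered by twice the observed allele
    frequency of the supplied individuals — the same coding that builds the
    genomic relationship matrix.
    """
    rng = np.random.default_rng(priors.seed)
    M_all, freqs = centered_coding(geno)
    sub = geno.loc_individuals(design.animal_ids)
    M_a, _ = centered_coding(sub, freqs=freqs)
    M = np.asfortranarray(design.Z1 @ M_a)
    n, m = M.shape
    y = design.y.copy()
    X = design.X
    xtx = np.einsum("ij,ij->j", M, M)

    sig_g2 = float(priors.sigma_g2)
    ratios = np.asarray(priors.variance_ratios)
    sige2 = float(np.var(y)) * 0.5
    vp = float(np.var(y))

    # non-SNP random terms
    terms = {}
    for name in ("maternal", "breed", "sireflock"):
        if not design.term_active(name):
            continue
        Z = design.random_design(name)
        if name == "breed":
            Z = np.asarray(Z.todense()) if hasattr(Z, "todense") else np.asarray(Z)
            terms[name] = {
                "Z": Z,
                "ZtZ": Z.T @ Z,
                "u": np.zeros(Z.shape[1]),
                "sigma2": 0.05 * vp,
                "dense": True,
            }
        else:
            counts = np.asarray(Z.sum(axis=0)).ravel()
            terms[name] = {
                "Z": Z,
                "counts": counts,
                "u": np.zeros(Z.shape[1]),
                "sigma2": 0.05 * vp,
                "dense": False,
            }
    nu0 = priors.nu_random
    s0 = 0.05 * vp / 2.0  # prior scale: mode matches the starting variance

    XtX = X.T @ X
    Lx = np.linalg.cholesky(XtX)
    beta_fix = np.zeros(X.shape[1])
    beta = np.zeros(m)
    comp = np.zeros(m, dtype=np.int64)
    r = y.copy()

    pi = np.full(4, 0.25) if priors.fix_pi is None else np.asarray(priors.fix_pi, dtype=float)
    alpha = np.asarray(priors.dirichlet_alpha, dtype=float)

    n_kept = 0
    beta_sum = np.zeros(m)
    comp_hits = np.zeros((m, 4))
    pi_sum = np.zeros(4)
    pi_trace = []
    fix_sum = np.zeros(X.shape[1])
    term_sums = {k: np.zeros(v["u"].size) for k, v in terms.items()}
    sige2_trace = []
    nonzero_trace = []

    for it in range(priors.n_iter):
        # (i) fixed effects
        r += X @ beta_fix
        mean = sla.cho_solve((Lx, True), X.T @ r)
        beta_fix = mean + np.sqrt(sige2) * sla.solve_triangular(
            Lx.T, rng.standard_normal(mean.size)
        )
        r -= X @ beta_fix

        # (ii) non-SNP random terms and their variances
        for name, tm in terms.items():
            if tm["dense"]:
                tm["u"] = _sample_dense_term(r, tm["Z"], tm["ZtZ"], tm["u"], tm["sigma2"], sige2, rng)
            else:
                tm["u"] = _sample_class_term(r, tm["Z"], tm["counts"], tm["u"], tm["sigma2"], sige2, rng)
            tm["sigma2"] = _sample_variance(tm["u"], nu0, s0, rng)

        # (iii) SNP sweep in a fresh random order
        sig2 = ratios * sig_g2
        with np.errstate(divide="ignore"):
            logpi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), _NEG_INF)
        order = rng.permutation(m)
        u01 = rng.random(m)
        z = rng.standard_normal(m)
        counts = _snp_sweep(M, r, beta, comp, xtx, logpi, sig2, sige2, order, u01, z)
        if not np.isfinite(r).all():
            raise FloatingPointError(f"non-finite residual at iteration {it}")

        # (iv) mixture proportions
        if priors.fix_pi is None:
            pi = rng.dirichlet(alpha + counts)

        # optional sigma_g2 update from the realized SNP effects
        if priors.sample_sigma_g2:
            nz = comp > 0
            if nz.any():
                ssq = float(np.sum(beta[nz] ** 2 / ratios[comp[nz]]))
                df = int(nz.sum()) + nu0
                sig_g2 = (ssq + nu0 * priors.sigma_g2 / 2.0) / rng.chisquare(df)

        # (v) residual variance
        sige2 = float(r @ r) / rng.chisquare(n)

        if it >= priors.burn_in and (it - priors.burn_in) % priors.thin == 0:
            n_kept += 1
            beta_sum += beta
            comp_hits[np.arange(m), comp] += 1.0
            pi_sum += pi
            pi_trace.append(pi.copy())
            fix_sum += beta_fix
            for name, tm in terms.items():
                term_sums[name] += tm["u"]
            sige2_trace.append(sige2)
            nonzero_trace.append(int((comp > 0).sum()))

    # no-drift check: residual rebuilt from scratch must match the running one
    r_direct = y - X @ beta_fix - M @ beta
    for name, tm in terms.items():
        r_direct = r_direct - np.asarray(tm["Z"] @ tm["u"]).ravel()
    drift = float(np.abs(r_direct - r).max())

    beta_mean = beta_sum / n_kept
    gbv = M_all @ beta_mean
    other = {name: term_sums[name] / n_kept for name in term_sums}
    other["fixed"] = fix_sum / n_kept
    sige2_trace = np.asarray(sige2_trace)
    nonzero_trace = np.asarray(nonzero_trace, dtype=float)
    diagnostics = {
        "ess_sigma_e2": effective_sample_size(sige2_trace),
        "ess_nonzero": effective_sample_size(nonzero_trace),
        "n_kept": n_kept,
        "residual_drift": drift,
        "mean_nonzero": float(nonzero_trace.mean()),
    }
    return BayesRPosterior(
        snp_ids=geno.snp_ids.copy(),
        snp_effect_means=beta_mean,
        component_probs=comp_hits / n_kept,
        pi_mean=pi_sum / n_kept,
        pi_trace=np.asarray(pi_trace),
        ids=geno.ids.copy(),
        gbv=gbv,
        other_effect_means=other,
        chain_diagnostics=diagnostics,
        sigma_e2_mean=float(sige2_trace.mean()),
    )


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1] if k + 1 < n else rho[k]
        if pair < 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))
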