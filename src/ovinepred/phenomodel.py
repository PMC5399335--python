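"""Mixed-model design shared by REML, GBLUP and BayesR.

The model is

    y = Xb + Z1 a + W w + Z1 Q q + Z2 s + e

where ``b`` are fixed effects (birth type, rearing type, gender, age at
measurement, optional weight at measurement, and contemporary group = site x
birth year x management group), ``a`` random additive genetic effects, ``w``
random maternal (dam) effects, ``q`` random breed effects entering through
the pedigree breed-proportion matrix ``Q``, and ``s`` random sire-by-flock
interaction effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["PhenotypeDesign", "VarianceComponents", "build_design"]


@dataclass
class VarianceComponents:
    """Variance components of the mixed model and derived heritability.

    Heritability uses v_additive / (v_additive + v_maternal + v_sireflock +
    v_residual): between-breed variance is not within-population genetic
    variance and is excluded from the denominator.
    """

    v_additive: float
    v_residual: float
    v_maternal: float = 0.0
    v_breed: float = 0.0
    v_sireflock: float = 0.0
    se: dict = field(default_factory=dict)
    h2_se: float | None = None

    def __post_init__(self) -> None:
        for name in ("v_additive", "v_residual", "v_maternal", "v_breed", "v_sireflock"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def h2(self) -> float:
        denom = self.v_additive + self.v_maternal + self.v_sireflock + self.v_residual
        return self.v_additive / denom

    def as_dict(self) -> dict:
        return {
            "v_additive": self.v_additive,
            "v_maternal": self.v_maternal,
            "v_breed": self.v_breed,
            "v_sireflock": self.v_sireflock,
            "v_residual": self.v_residual,
            "h2": self.h2,
        }


@dataclass
class PhenotypeDesign:
    """Response, fixed-effect design and random-term incidence structures."""

    y: np.ndarray
    X: np.ndarray
    x_names: list
    Z1: sp.csr_matrix
    animal_ids: np.ndarray
    W: sp.csr_matrix
    dam_ids: np.ndarray
    Q: np.ndarray
    breed_labels: list
    Z2: sp.csr_matrix
    sireflock_ids: np.ndarray
    trait_label: str = "trait"
    breed_term_dropped: bool = False
    unknown_dam_ids: list = field(default_factory=list)
    dropped_ids: list = field(default_factory=list)
    source_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValueError("X row count does not match y")
        for name, Z, n_levels in (
            ("Z1", self.Z1, self.animal_ids.size),
            ("W", self.W, self.dam_ids.size),
            ("Z2", self.Z2, self.sireflock_ids.size),
        ):
            if Z.shape != (n, n_levels):
                raise ValueError(f"{name} shape {Z.shape} inconsistent with design")
            per_row = np.diff(Z.indptr)
            if (per_row > 1).any():
                raise ValueError(f"{name} must have at most one nonzero per row")
            if Z.nnz and not np.all(Z.data == 1.0):
                raise ValueError(f"{name} entries must be 1")
        if (np.diff(self.Z1.indptr) != 1).any():
            raise ValueError("every record must map to exactly one animal in Z1")
        if self.Q.shape != (self.animal_ids.size, len(self.breed_labels)):
            raise ValueError("Q must be animals x breeds")
        if self.Q.size:
            if self.Q.min() < -1e-12 or np.abs(self.Q.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError("rows of Q must be nonnegative and sum to 1")

    @property
    def n_records(self) -> int:
        return self.y.size

    def term_active(self, term: str) -> bool:
        """Whether a random term has any support in this design."""
        if term == "additive":
            return True
        if term == "maternal":
            return self.W.nnz > 0
        if term == "breed":
            return not self.breed_term_dropped
        if term == "sireflock":
            return self.Z2.nnz > 0
        raise KeyError(term)

    def random_design(self, term: str) -> sp.csr_matrix | np.ndarray:
        """Observation-level design matrix of a random term."""
        if term == "additive":
            return self.Z1
        if term == "maternal":
            return self.W
        if term == "breed":
            return self.Z1 @ self.Q
        if term == "sireflock":
            return self.Z2
        raise KeyError(term)


def _incidence(labels: np.ndarray, levels: np.ndarray) -> sp.csr_matrix:
    """One-hot incidence; empty-string labels give all-zero rows."""
    lookup = {v: i for i, v in enumerate(levels)}
    rows, cols = [], []
    for i, lab in enumerate(labels):
        j = lookup.get(lab)
        if j is not None:
            rows.append(i)
            cols.append(j)
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(labels.size, levels.size))


def build_design(pheno_table: pd.DataFrame, ped, trait: str = "trait") -> PhenotypeDesign:
    """Assemble the mixed-model design from a phenotype table and pedigree.

    Categorical covariates are dummy-coded against a dropped reference
    level; age (and weight, when present) are centered.  Contemporary group
    is flock x birth year x management group.  Rows with a missing response
    are dropped and recorded in ``dropped_ids``.  Raises if the fixed-effect
    design is rank-deficient, naming the confounded columns.
    """
    t = pheno_table.copy()
    if trait not in t.columns:
        raise KeyError(f"trait column {trait!r} not in phenotype table")
    missing_y = t[trait].isna()
    dropped = t.loc[missing_y, "id"].tolist()
    t = t.loc[~missing_y].reset_index(drop=True)
    if len(t) == 0:
        raise ValueError("no records with non-missing response")

    y = t[trait].to_numpy(dtype=np.float64)
    n = y.size

    cols = [np.ones(n)]
    names = ["intercept"]
    t["cg"] = (
        t["flock"].astype(str)
        + "_Y"
        + t["birth_year"].astype(str)
        + "_"
        + t["mgmt_group"].astype(str)
    )
    for cat in ("birth_type", "rearing_type", "gender", "cg"):
        if cat not in t.columns:
            continue
        levels = sorted(pd.unique(t[cat].astype(str)))
        for lev in levels[1:]:  # first level is the reference
            cols.append((t[cat].astype(str) == lev).to_numpy(dtype=np.float64))
            names.append(f"{cat}[{lev}]")
    for cont in ("age", "weight"):
        if cont in t.columns:
            v = t[cont].to_numpy(dtype=np.float64)
            cols.append(v - v.mean())
            names.append(cont)
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _confounded_columns(X, names)
        raise ValueError(f"fixed-effect design is rank-deficient; confounded columns: {bad}")

    animal_ids = pd.unique(t["id"]).astype(object)
    Z1 = _incidence(t["id"].to_numpy(dtype=object), animal_ids)

    dams = t.get("dam", pd.Series([""] * n)).fillna("").to_numpy(dtype=object)
    dam_ids = pd.unique(dams[dams != ""]).astype(object)
    W = _incidence(dams, dam_ids)
    unknown_dam = t.loc[dams == "", "id"].tolist()

    ped_rows = ped.rows_for(animal_ids)
    frac_cols = [f"breed_{b}" for b in ped.breeds]
    Q = ped_rows[frac_cols].to_numpy(dtype=np.float64)
    # a rank-1 Q (single breed or identical mixtures) is confounded with the
    # intercept: drop the breed term
    breed_dropped = np.linalg.matrix_rank(Q - Q[0][None, :], tol=1e-10) == 0

    sires = t.get("sire", pd.Series([""] * n)).fillna("").to_numpy(dtype=object)
    sf = np.array(
        [f"{s}|{f}" if s != "" else "" for s, f in zip(sires, t["flock"].astype(str))],
        dtype=object,
    )
    sf_ids = pd.unique(sf[sf != ""]).astype(object)
    Z2 = _incidence(sf, sf_ids)

    return PhenotypeDesign(
        y=y,
        X=X,
        x_names=names,
        Z1=Z1,
        animal_ids=animal_ids,
        W=W,
        dam_ids=dam_ids,
        Q=Q,
        breed_labels=list(ped.breeds),
        Z2=Z2,
        sireflock_ids=sf_ids,
        trait_label=trait,
        breed_term_dropped=bool(breed_dropped),
        unknown_dam_ids=unknown_dam,
        dropped_ids=dropped,
        source_table=t,
    )


def _confounded_columns(X: np.ndarray, names: list) -> list:
    """Columns whose removal restores full rank (greedy, for error messages)."""
    bad = []
    keep = list(range(X.shape[1]))
    while np.linalg.matrix_rank(X[:, keep]) < len(keep):
        for j in reversed(keep):
            trial = [k for k in keep if k != j]
            if np.linalg.matrix_rank(X[:, trial]) == np.linalg.matrix_rank(X[:, keep]):
                bad.append(names[j])
                keep = trial
                break
    return bad
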