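"""Synthetic multi-breed sheep population generator.

The generator stands in for the industry reference data the pipeline was
designed around: a large multi-breed/crossbred reference population
(Merino-dominated, with Border Leicester maternal and Poll Dorset / White
Suffolk terminal sire breeds), genotyped at two marker densities roughly a
1:10 SNP-count ratio apart, with progeny-tested purebred validation sires.

Breeds are produced by gene-dropping: a shared ancestral haplotype pool is
evolved forward under Wright-Fisher reproduction with recombination (Haldane
map, 1 Morgan per synthetic chromosome) independently per breed, so
between-breed allele-frequency divergence (F\\ :sub:`ST`) grows with
``divergence_generations`` and within-breed linkage disequilibrium builds up
through drift.  Crossbred reference animals are bred from the founder
generation according to ``cross_design``.  QTL are a random subset of
dense-panel loci and are removed from the genotyping panels by default, so
that marker-based prediction works through linkage disequilibrium — the
mechanism whose density-dependence the pipeline is built to measure.

Phenotypes follow the mixed model

    y = Xb + Z1 a + W w + Z1 Q q + Z2 s + e

with additive (a = true breeding value from QTL), maternal (w, per dam),
breed-proportion (q, through the pedigree breed-fraction matrix Q) and
sire-by-flock interaction (s) random terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ovinepred.containers import GenotypeMatrix, Pedigree

__all__ = [
    "PopulationConfig",
    "TrueGeneticValues",
    "ProgenyTestEBV",
    "simulate_population",
    "simulate_hwe_genotypes",
    "subset_density",
    "simulate_phenotypes",
    "simulate_progeny_ebv",
    "progeny_mean_accuracy",
]

_DEFAULT_BREEDS = ("Merino", "BL", "PD", "WS")


@dataclass
class PopulationConfig:
    """Study-condition knobs for the synthetic population.

    Defaults emulate the reference-population composition the pipeline
    targets: four major breeds, a Merino-dominated dam base with roughly 40%
    terminal-sired, 20% maternal-sired and 40% Merino-sired reference
    animals, eight linked flocks, and a moderate panel that retains ~9.5%
    of the dense panel (the 48,559 : 510,174 SNP-count ratio).
    """

    n_breeds: int = 4
    breed_labels: tuple = _DEFAULT_BREEDS
    divergence_generations: int = 50
    n_founders_per_breed: int = 200
    n_reference: int = 2000
    n_validation_sires_per_breed: int = 25
    cross_design: list | None = None  # (sire_breed, dam_breed, n_offspring)
    n_snps_dense: int = 10_000
    density_ratio: float = 0.095
    n_qtl: int = 500
    qtl_effect_distribution: str = "gaussian"  # gaussian | few_large | mixture
    h2_target: float = 0.3
    var_maternal: float = 0.05
    var_breed: float = 0.05
    var_sireflock: float = 0.05
    n_flocks: int = 8
    seed: int = 0
    # engine parameters
    effective_size: int = 100  # Wright-Fisher N during breed divergence
    n_chromosomes: int = 10  # 1 Morgan each
    qtl_observed: bool = False  # keep QTL on the dense panel only
    distant_generations: int = 3  # extra generations separating low-related sires

    def __post_init__(self) -> None:
        self.breed_labels = tuple(self.breed_labels)[: self.n_breeds]
        if len(self.breed_labels) != self.n_breeds:
            # extend with generic labels if fewer names than breeds
            extra = [f"B{i}" for i in range(len(self.breed_labels), self.n_breeds)]
            self.breed_labels = tuple(self.breed_labels) + tuple(extra)
        if self.cross_design is None:
            self.cross_design = self._default_cross_design()
        counts = [
            self.n_breeds,
            self.n_founders_per_breed,
            self.n_reference,
            self.n_validation_sires_per_breed,
            self.n_snps_dense,
            self.n_qtl,
            self.n_flocks,
            self.effective_size,
            self.n_chromosomes,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts in PopulationConfig must be positive")
        if not 0 < self.density_ratio <= 1:
            raise ValueError("density_ratio must be in (0, 1]")
        if not 0 < self.h2_target <= 1:
            raise ValueError("h2_target must be in (0, 1]")
        nongenetic = self.var_maternal + self.var_breed + self.var_sireflock
        if min(self.var_maternal, self.var_breed, self.var_sireflock) < 0:
            raise ValueError("variance fractions must be nonnegative")
        # the h2 = 1 boundary (zero residual) is allowed as a degenerate case
        if self.h2_target + nongenetic > 1:
            raise ValueError(
                "h2_target + var_maternal + var_breed + var_sireflock must not exceed 1 "
                "(residual variance cannot be negative)"
            )
        if self.n_qtl > self.n_snps_dense:
            raise ValueError("n_qtl cannot exceed n_snps_dense")
        for sb, db, k in self.cross_design:
            if sb not in self.breed_labels or db not in self.breed_labels:
                raise ValueError(f"cross_design breed ({sb}, {db}) not in breed_labels")
            if k <= 0:
                raise ValueError("cross_design offspring counts must be positive")
        if self.n_breeds > 1 and not self.cross_design:
            raise ValueError("cross_design must be non-empty for a multi-breed population")
        if self.qtl_effect_distribution not in {"gaussian", "few_large", "mixture"}:
            raise ValueError(f"unknown qtl_effect_distribution {self.qtl_effect_distribution!r}")

    def _default_cross_design(self) -> list:
        b = self.breed_labels
        n = self.n_reference
        if self.n_breeds == 1:
            return [(b[0], b[0], n)]
        dam = b[0]  # Merino dam base
        if self.n_breeds >= 4:
            shares = [(b[0], 0.40), (b[1], 0.20), (b[2], 0.20), (b[3], 0.20)]
        else:
            shares = [(lbl, 1.0 / self.n_breeds) for lbl in b]
        design = [(sire, dam, int(round(f * n))) for sire, f in shares]
        # fix rounding so offspring total equals n_reference
        diff = n - sum(k for _, _, k in design)
        sire0, dam0, k0 = design[0]
        design[0] = (sire0, dam0, k0 + diff)
        return design


@dataclass
class TrueGeneticValues:
    """Ground truth of the simulation: QTL effects and true breeding values."""

    qtl_ids: np.ndarray
    qtl_effects: np.ndarray
    ids: np.ndarray
    tbv: np.ndarray
    additive_variance: float
    realized_var_components: dict = field(default_factory=dict)

    def tbv_for(self, wanted_ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        return self.tbv[[lookup[w] for w in wanted_ids]]


@dataclass
class ProgenyTestEBV:
    """Progeny-test EBVs for validation sires."""

    sire_id: np.ndarray
    ebv: np.ndarray
    accuracy: np.ndarray
    n_progeny: np.ndarray

    def __post_init__(self) -> None:
        self.sire_id = np.asarray(self.sire_id, dtype=object)
        self.ebv = np.asarray(self.ebv, dtype=np.float64)
        self.accuracy = np.asarray(self.accuracy, dtype=np.float64)
        self.n_progeny = np.asarray(self.n_progeny, dtype=np.int64)
        if not np.isfinite(self.ebv).all():
            raise ValueError("ebv must be finite")
        if ((self.accuracy < 0) | (self.accuracy > 1)).any():
            raise ValueError("accuracy must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.sire_id,
                "ebv": self.ebv,
                "accuracy": self.accuracy,
                "n_progeny": self.n_progeny,
            }
        )


# ---------------------------------------------------------------------------
# Haplotype engine
# ---------------------------------------------------------------------------


def _genetic_map(cfg: PopulationConfig, rng: np.random.Generator):
    """Marker map: chromosome labels, bp positions, per-interval recombination."""
    m = cfg.n_snps_dense
    per_chrom = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes)
    per_chrom[: m % cfg.n_chromosomes] += 1
    chrom, pos_bp, gpos = [], [], []
    for c, k in enumerate(per_chrom, start=1):
        g = np.sort(rng.uniform(0.0, 1.0, k))  # Morgans along a 1 Morgan chromosome
        chrom.extend([str(c)] * k)
        gpos.append(g)
        pos_bp.append(np.round(g * 1e8).astype(np.int64))  # 1 cM / Mb
    gpos = np.concatenate(gpos)
    pos_bp = np.concatenate(pos_bp)
    chrom = np.array(chrom, dtype=object)
    # recombination fraction between adjacent loci (Haldane); 0.5 across chromosomes
    d = np.diff(gpos)
    rec = 0.5 * (1.0 - np.exp(-2.0 * d))
    new_chrom = chrom[1:] != chrom[:-1]
    rec[new_chrom] = 0.5
    rec = np.clip(rec, 0.0, 0.5)
    return chrom, pos_bp, rec


def _gametes(haps: np.ndarray, parents: np.ndarray, rec: np.ndarray, rng) -> np.ndarray:
    """One gamete per entry of ``parents`` from diploid haplotype store ``haps``.

    ``haps`` has rows (2i, 2i+1) for individual i.  Meiosis is the Markov
    switch process equivalent to a crossover point process at marker
    resolution: the transmitted haplotype switches between the two parental
    haplotypes at each marker interval with its recombination fraction.
    """
    k = parents.size
    a = haps[2 * parents]
    b = haps[2 * parents + 1]
    start = rng.integers(0, 2, size=(k, 1))
    switches = rng.random((k, rec.size)) < rec[None, :]
    phase = np.empty((k, rec.size + 1), dtype=np.int8)
    phase[:, :1] = start
    np.cumsum(switches, axis=1, out=phase[:, 1:], dtype=np.int8)
    phase[:, 1:] += start
    phase &= 1
    return np.where(phase == 0, a, b)


def _wright_fisher(haps: np.ndarray, n_generations: int, rec: np.ndarray, rng) -> np.ndarray:
    n_ind = haps.shape[0] // 2
    for _ in range(n_generations):
        sires = rng.integers(0, n_ind, size=n_ind)
        dams = rng.integers(0, n_ind, size=n_ind)
        new = np.empty_like(haps)
        new[0::2] = _gametes(haps, sires, rec, rng)
        new[1::2] = _gametes(haps, dams, rec, rng)
        haps = new
    return haps


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------


def simulate_population(config: PopulationConfig):
    """Simulate genotypes, pedigree and true genetic values.

    Returns
    -------
    (GenotypeMatrix, Pedigree, TrueGeneticValues)
        The genotype matrix holds the full dense panel *including* QTL
        columns; :func:`subset_density` builds the genotyping panels and
        drops QTL unless ``config.qtl_observed``.  Pedigree roles label
        founders, reference animals and validation sires; validation sires
        split into a half used as sires of reference progeny (genetically
        close to the reference) and a half bred ``distant_generations``
        further down the within-breed drift line (genetically remote).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snps_dense
    chrom, pos_bp, rec = _genetic_map(cfg, rng)
    snp_ids = np.array([f"snp{j:06d}" for j in range(m)], dtype=object)

    p0 = rng.uniform(0.1, 0.9, m)
    n_e = cfg.effective_size

    ids: list = []
    rows: list = []
    hap_store: list = []  # per-individual haplotype pairs, aligned with ids
    roles: dict = {}
    founder_males: dict = {}
    founder_females: dict = {}
    distant_males: dict = {}

    for b_idx, breed in enumerate(cfg.breed_labels):
        pool = (rng.random((2 * n_e, m)) < p0[None, :]).astype(np.int8)
        pool = _wright_fisher(pool, cfg.divergence_generations, rec, rng)

        # founders: offspring of random pool individuals
        n_f = cfg.n_founders_per_breed
        sires = rng.integers(0, n_e, n_f)
        dams = rng.integers(0, n_e, n_f)
        h1 = _gametes(pool, sires, rec, rng)
        h2 = _gametes(pool, dams, rec, rng)
        founder_males[breed] = []
        founder_females[breed] = []
        for i in range(n_f):
            an_id = f"{breed}_F{i:04d}"
            ids.append(an_id)
            hap_store.append((h1[i], h2[i]))
            (founder_males if i % 2 == 0 else founder_females)[breed].append(an_id)
            rows.append(_ped_row(cfg, an_id, "", "", breed_vec(cfg, b_idx), 0, rng))
            roles[an_id] = "founder"

        # remote relatives: continue within-breed drift a few generations more
        if cfg.distant_generations > 0 and cfg.n_validation_sires_per_breed > 1:
            pool2 = _wright_fisher(pool, cfg.distant_generations, rec, rng)
            n_d = cfg.n_validation_sires_per_breed // 2
            sires = rng.integers(0, n_e, n_d)
            dams = rng.integers(0, n_e, n_d)
            h1 = _gametes(pool2, sires, rec, rng)
            h2 = _gametes(pool2, dams, rec, rng)
            distant_males[breed] = []
            for i in range(n_d):
                an_id = f"{breed}_D{i:04d}"
                ids.append(an_id)
                hap_store.append((h1[i], h2[i]))
                distant_males[breed].append(an_id)
                rows.append(_ped_row(cfg, an_id, "", "", breed_vec(cfg, b_idx), 0, rng))
                roles[an_id] = "validation_sire"
        else:
            distant_males[breed] = []

    # validation sires: connected half are founder males used in matings
    connected_sires: dict = {}
    for breed in cfg.breed_labels:
        n_conn = cfg.n_validation_sires_per_breed - len(distant_males[breed])
        males = founder_males[breed]
        if n_conn > len(males):
            raise ValueError(
                f"breed {breed}: {n_conn} connected validation sires requested but only "
                f"{len(males)} founder males available"
            )
        connected_sires[breed] = males[:n_conn]
        for an_id in connected_sires[breed]:
            roles[an_id] = "validation_sire"

    id_to_idx = {v: i for i, v in enumerate(ids)}
    breed_frac = {ids[i]: rows[i][3] for i in range(len(ids))}

    # crossbred / purebred reference offspring
    ref_counter = 0
    for sire_breed, dam_breed, n_off in cfg.cross_design:
        # sires: validation-connected sires plus extra founder males of the breed
        sire_pool = list(connected_sires[sire_breed])
        extra = [x for x in founder_males[sire_breed] if x not in set(sire_pool)]
        # each sire gets on the order of 20 progeny, as in an AI-linked flock scheme
        want_sires = max(1, int(np.ceil(n_off / 20)))
        sire_pool = (sire_pool + extra)[: max(want_sires, len(connected_sires[sire_breed]))]
        dam_pool = founder_females[dam_breed]
        sire_pick = np.array(sire_pool, dtype=object)[rng.integers(0, len(sire_pool), n_off)]
        dam_pick = np.array(dam_pool, dtype=object)[rng.integers(0, len(dam_pool), n_off)]
        sire_idx = np.array([id_to_idx[s] for s in sire_pick])
        dam_idx = np.array([id_to_idx[d] for d in dam_pick])
        h_s = _meiosis_from_store(hap_store, sire_idx, rec, rng)
        h_d = _meiosis_from_store(hap_store, dam_idx, rec, rng)
        for i in range(n_off):
            an_id = f"REF{ref_counter:05d}"
            ref_counter += 1
            ids.append(an_id)
            hap_store.append((h_s[i], h_d[i]))
            frac = 0.5 * (breed_frac[sire_pick[i]] + breed_frac[dam_pick[i]])
            rows.append(_ped_row(cfg, an_id, sire_pick[i], dam_pick[i], frac, 1, rng))
            roles[an_id] = "reference"
            breed_frac[an_id] = frac
            id_to_idx[an_id] = len(ids) - 1

    calls = np.empty((len(ids), m), dtype=np.int8)
    for i, (ha, hb) in enumerate(hap_store):
        calls[i] = ha + hb

    geno = GenotypeMatrix(
        ids=np.array(ids, dtype=object),
        snp_ids=snp_ids,
        chrom=chrom,
        pos=pos_bp,
        calls=calls,
    )

    ped_table = pd.DataFrame(
        rows, columns=["id", "sire", "dam", "_frac", "birth_year", "flock"]
    )
    frac_mat = np.vstack(ped_table.pop("_frac").to_numpy())
    for j, breed in enumerate(cfg.breed_labels):
        ped_table[f"breed_{breed}"] = frac_mat[:, j]
    ped_table["role"] = [roles[i] for i in ped_table["id"]]
    ped = Pedigree(table=ped_table, breeds=list(cfg.breed_labels))

    truth = _draw_qtl_effects(cfg, geno, rng)
    return geno, ped, truth


def breed_vec(cfg: PopulationConfig, b_idx: int) -> np.ndarray:
    v = np.zeros(cfg.n_breeds)
    v[b_idx] = 1.0
    return v


def _ped_row(cfg, an_id, sire, dam, frac, birth_year, rng):
    flock = f"FL{int(rng.integers(0, cfg.n_flocks)) + 1}"
    return [an_id, sire, dam, np.asarray(frac, dtype=float), birth_year, flock]


def _meiosis_from_store(hap_store, idx: np.ndarray, rec, rng) -> np.ndarray:
    m = hap_store[0][0].size
    haps = np.empty((2 * idx.size, m), dtype=np.int8)
    for k, i in enumerate(idx):
        haps[2 * k] = hap_store[i][0]
        haps[2 * k + 1] = hap_store[i][1]
    return _gametes(haps, np.arange(idx.size), rec, rng)


def _draw_qtl_effects(cfg: PopulationConfig, geno: GenotypeMatrix, rng) -> TrueGeneticValues:
    m = geno.n_snps
    qtl_idx = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    if cfg.qtl_effect_distribution == "gaussian":
        eff = rng.standard_normal(cfg.n_qtl)
    elif cfg.qtl_effect_distribution == "few_large":
        # one in ten QTL (at least one) carries a 10x-SD effect
        eff = 0.1 * rng.standard_normal(cfg.n_qtl)
        n_large = max(1, cfg.n_qtl // 10)
        large = rng.choice(cfg.n_qtl, n_large, replace=False)
        eff[large] = rng.standard_normal(n_large)
    else:  # mixture: BayesR-style three non-null classes
        comp = rng.choice(3, size=cfg.n_qtl, p=(0.7, 0.25, 0.05))
        scale = np.array([0.03, 0.1, 0.3])[comp]
        eff = scale * rng.standard_normal(cfg.n_qtl)

    dos = geno.calls[:, qtl_idx].astype(np.float64)
    # founders define the scaling population
    founder = np.array([not i.startswith("REF") for i in geno.ids])
    p = dos[founder].mean(axis=0) / 2.0
    centered = dos - 2.0 * p[None, :]
    tbv = centered @ eff
    v_founder = tbv[founder].var()
    if v_founder <= 0:
        raise ValueError("degenerate QTL draw: zero additive variance among founders")
    target_va = cfg.h2_target  # phenotypic variance normalized to 1
    scale = np.sqrt(target_va / v_founder)
    eff = eff * scale
    tbv = tbv * scale
    return TrueGeneticValues(
        qtl_ids=geno.snp_ids[qtl_idx],
        qtl_effects=eff,
        ids=geno.ids.copy(),
        tbv=tbv,
        additive_variance=target_va,
    )


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------


def subset_density(
    geno: GenotypeMatrix,
    density_ratio: float,
    seed: int,
    exclude_snp_ids=(),
) -> GenotypeMatrix:
    """Evenly spaced (by map position, seeded jitter) marker subset.

    ``exclude_snp_ids`` (typically the QTL when they are unobserved) are
    dropped before spacing; the retained panel has
    ``round(density_ratio * m)`` SNPs where ``m`` counts the post-exclusion
    panel, and stays sorted by (chrom, pos).
    """
    if not 0 < density_ratio <= 1:
        raise ValueError("density_ratio must be in (0, 1]")
    order = np.lexsort((geno.pos, _chrom_sort_key(geno.chrom)))
    g = geno.subset_snps(order)
    if exclude_snp_ids is not None and len(exclude_snp_ids) > 0:
        drop = set(exclude_snp_ids)
        keep = np.array([s not in drop for s in g.snp_ids])
        g = g.subset_snps(np.flatnonzero(keep))
    m = g.n_snps
    if density_ratio == 1:
        return g
    k = int(round(density_ratio * m))
    k = max(1, k)
    rng = np.random.default_rng(seed)
    # cumulative map coordinate: chromosome index * 2e8 bp + position
    ckey = _chrom_sort_key(g.chrom)
    coord = ckey.astype(np.float64) * 2e8 + g.pos
    total = coord[-1] - coord[0]
    targets = coord[0] + (np.arange(k) + 0.5) / k * total
    targets = targets + rng.uniform(-0.4, 0.4, k) * total / k
    idx = np.searchsorted(coord, targets)
    idx = np.clip(idx, 0, m - 1)
    idx = np.unique(idx)
    if idx.size < k:  # collisions: fill with unused markers nearest to gaps
        unused = np.setdiff1d(np.arange(m), idx)
        fill = rng.choice(unused, size=k - idx.size, replace=False)
        idx = np.sort(np.concatenate([idx, fill]))
    return g.subset_snps(idx)


def _chrom_sort_key(chrom: np.ndarray) -> np.ndarray:
    def key(c):
        try:
            return int(c)
        except (TypeError, ValueError):
            # stable (hash() is salted per process) ordinal for non-numeric labels
            return 10_000 + sum(str(c).encode())

    return np.array([key(c) for c in chrom], dtype=np.int64)


def simulate_hwe_genotypes(
    n: int, m: int, seed: int, maf_range=(0.05, 0.5)
) -> GenotypeMatrix:
    """Unstructured population in Hardy-Weinberg equilibrium (no LD).

    The simplest substrate for relationship-matrix scale checks: allele
    frequencies uniform on ``maf_range`` and independent binomial(2, p)
    dosages.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_range[0], maf_range[1], m)
    calls = rng.binomial(2, p[None, :], size=(n, m)).astype(np.int8)
    return GenotypeMatrix(
        ids=np.array([f"id{i:05d}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"snp{j:06d}" for j in range(m)], dtype=object),
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1) * 1000,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    geno: GenotypeMatrix,
    ped: Pedigree,
    truth: TrueGeneticValues,
    config: PopulationConfig,
    seed: int,
    fixed_effect_scale: float = 1.0,
):
    """Phenotypes for reference animals under the full mixed model.

    Returns a :class:`~ovinepred.phenomodel.PhenotypeDesign` whose
    ``source_table`` attribute is the TSV-ready phenotype table.  Fixed
    effects are birth type, rearing type, gender, age at measurement and
    contemporary group (flock x birth year x management group), each with a
    modest effect (at most 0.5 phenotypic SD, scaled by
    ``fixed_effect_scale``).  Random contributions: true breeding value,
    per-dam maternal effect, breed deviations through the breed-fraction
    matrix, sire-by-flock interaction, and a residual rescaled to its exact
    target variance.  Realized component variances are recorded in
    ``truth.realized_var_components``.
    """
    from ovinepred.phenomodel import build_design

    cfg = config
    rng = np.random.default_rng(seed)
    tab = ped.table
    is_ref = (tab["role"] == "reference").to_numpy()
    ref = tab.loc[is_ref].reset_index(drop=True)
    n = len(ref)
    if n == 0:
        raise ValueError("no reference animals in pedigree")
    if cfg.var_maternal > 0 and (ref["dam"] == "").any():
        raise ValueError("maternal variance requested but some phenotyped animals lack a dam")

    tbv = truth.tbv_for(ref["id"])

    # fixed effects (phenotypic SD is 1 by construction)
    s = fixed_effect_scale
    birth_type = rng.choice([1, 2, 3], size=n, p=[0.35, 0.5, 0.15])
    rearing_type = np.minimum(birth_type, rng.choice([1, 2, 3], size=n, p=[0.4, 0.45, 0.15]))
    gender = rng.choice(["M", "F"], size=n)
    age = rng.normal(300.0, 30.0, n)
    mgmt = rng.choice(["G1", "G2"], size=n)
    cg_label = ref["flock"].astype(str) + "_Y" + ref["birth_year"].astype(str) + "_" + mgmt
    cg_levels = pd.unique(cg_label)
    cg_eff = dict(zip(cg_levels, s * rng.normal(0.0, 0.25, cg_levels.size)))
    bt_eff = {1: 0.0, 2: -0.25 * s, 3: -0.45 * s}
    rt_eff = {1: 0.0, 2: -0.15 * s, 3: -0.30 * s}
    sex_eff = {"M": 0.3 * s, "F": 0.0}
    xb = (
        np.array([bt_eff[b] for b in birth_type])
        + np.array([rt_eff[r] for r in rearing_type])
        + np.array([sex_eff[g] for g in gender])
        + (0.25 * s / 30.0) * (age - 300.0)
        + np.array([cg_eff[c] for c in cg_label])
    )

    # random terms; each realized contribution vector is rescaled so its
    # sample variance over phenotyped animals matches the configured
    # fraction exactly (the level effects are scaled by the same factor)
    dams = ref["dam"].to_numpy()
    dam_levels = pd.unique(dams[dams != ""])
    w = dict(zip(dam_levels, _scaled_normal(rng, dam_levels.size, cfg.var_maternal)))
    maternal = _match_variance(np.array([w.get(d, 0.0) for d in dams]), cfg.var_maternal)

    q = _scaled_normal(rng, cfg.n_breeds, cfg.var_breed)
    frac_cols = [f"breed_{b}" for b in ped.breeds]
    breed_term = _match_variance(ref[frac_cols].to_numpy() @ q, cfg.var_breed)

    sf_label = ref["sire"].astype(str) + "|" + ref["flock"].astype(str)
    sf_levels = pd.unique(sf_label)
    sf = dict(zip(sf_levels, _scaled_normal(rng, sf_levels.size, cfg.var_sireflock)))
    sireflock = _match_variance(np.array([sf[x] for x in sf_label]), cfg.var_sireflock)

    var_e = 1.0 - cfg.h2_target - cfg.var_maternal - cfg.var_breed - cfg.var_sireflock
    e = _scaled_normal(rng, n, var_e, exact=True)

    y = xb + tbv + maternal + breed_term + sireflock + e

    truth.realized_var_components = {
        "additive": float(np.var(tbv)),
        "maternal": float(np.var(maternal)),
        "breed": float(np.var(breed_term)),
        "sireflock": float(np.var(sireflock)),
        "residual": float(np.var(e)),
    }

    table = pd.DataFrame(
        {
            "id": ref["id"],
            "trait": y,
            "birth_type": birth_type,
            "rearing_type": rearing_type,
            "gender": gender,
            "age": age,
            "flock": ref["flock"],
            "birth_year": ref["birth_year"],
            "mgmt_group": mgmt,
            "sire": ref["sire"],
            "dam": ref["dam"],
        }
    )
    design = build_design(table, ped, trait="trait")
    return design


def _match_variance(v: np.ndarray, target_var: float) -> np.ndarray:
    """Scale a realized contribution vector to its exact target variance."""
    if target_var <= 0:
        return np.zeros_like(v)
    s = v.var()
    if s <= 0:
        return v
    return v * np.sqrt(target_var / s)


def _scaled_normal(rng, size: int, target_var: float, exact: bool = False) -> np.ndarray:
    """Mean-zero normal draws; with ``exact`` the sample variance is matched."""
    if target_var <= 0 or size == 0:
        return np.zeros(size)
    z = rng.standard_normal(size)
    if exact and size > 1:
        z = z - z.mean()
        sd = z.std()
        if sd > 0:
            z = z / sd
    return np.sqrt(target_var) * z


# ---------------------------------------------------------------------------
# Progeny-test EBVs
# ---------------------------------------------------------------------------


def progeny_mean_accuracy(n_progeny, h2: float) -> np.ndarray:
    """Reliability (correlation scale) of a half-sib progeny-mean EBV.

    accuracy = sqrt(0.25 n h2 / (1 + 0.25 (n - 1) h2))
    """
    if not 0 < h2 <= 1:
        raise ValueError("h2 must be in (0, 1]")
    n = np.asarray(n_progeny, dtype=np.float64)
    return np.sqrt(0.25 * n * h2 / (1.0 + 0.25 * (n - 1.0) * h2))


def simulate_progeny_ebv(
    truth: TrueGeneticValues,
    sires,
    n_progeny,
    h2: float,
    seed: int,
) -> ProgenyTestEBV:
    """Progeny-test EBVs: accuracy-attenuated true breeding values.

    ebv = accuracy^2 * tbv + accuracy * sqrt(1 - accuracy^2) * sigma_a * z,
    so that corr(ebv, tbv) equals the half-sib progeny-mean accuracy exactly
    in expectation, and the recorded accuracy is that formula's value.
    """
    sires = np.asarray(list(sires), dtype=object)
    if np.isscalar(n_progeny):
        n_progeny = np.full(sires.size, int(n_progeny))
    n_progeny = np.asarray(n_progeny, dtype=np.int64)
    if (n_progeny < 1).any():
        raise ValueError("n_progeny must be >= 1")
    rng = np.random.default_rng(seed)
    acc = progeny_mean_accuracy(n_progeny, h2)
    tbv = truth.tbv_for(sires)
    sigma_a = np.sqrt(truth.additive_variance)
    z = rng.standard_normal(sires.size)
    ebv = acc**2 * tbv + acc * np.sqrt(1.0 - acc**2) * sigma_a * z
    return ProgenyTestEBV(sire_id=sires, ebv=ebv, accuracy=acc, n_progeny=n_progeny)
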