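"""End-to-end experiment orchestration.

``run_experiment`` drives: simulate population -> build dense/moderate
panels -> SNP + sample QC -> genomic relationship matrices -> REML variance
components -> GBLUP (and optionally BayesR) per panel -> progeny-test EBVs
for validation sires -> accuracy per breed and per relatedness stratum.
Every stage artifact is persisted under the output directory; stages are
content-addressed by a hash of their parameters and upstream hashes, so
re-running with an unchanged upstream stage reloads instead of recomputing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ovinepred import io as opio
from ovinepred.bayesr import BayesRPriors, run_bayesr
from ovinepred.containers import GenotypeMatrix, Pedigree
from ovinepred.gblup import solve_mme
from ovinepred.phenomodel import build_design
from ovinepred.qc import QCThresholds, apply_snp_report, filter_duplicate_samples, filter_snps
from ovinepred.relmat import classify_relatedness, compute_grm, compute_nrm, scale_diagnostics
from ovinepred.reml import fit_reml
from ovinepred.simdata import (
    PopulationConfig,
    simulate_phenotypes,
    simulate_population,
    simulate_progeny_ebv,
    subset_density,
)
from ovinepred.validate import accuracy, stratified_comparison

log = logging.getLogger("ovinepred")

__all__ = ["ExperimentConfig", "run_experiment", "load_config"]


@dataclass
class ExperimentConfig:
    simulation: PopulationConfig
    qc: QCThresholds = field(default_factory=QCThresholds)
    panels: tuple = ("moderate", "dense")
    methods: tuple = ("GBLUP",)
    reference_definition: str = "all"
    bayesr: dict = field(default_factory=dict)  # overrides for BayesRPriors
    validation_n_progeny: int = 60
    run_pblup: bool = False
    output_dir: str = "experiment_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for p in self.panels:
            if p not in ("moderate", "dense"):
                raise ValueError(f"unknown panel {p!r}")
        self.panels = tuple(self.panels)
        self.methods = tuple(self.methods)
        rd = self.reference_definition
        if rd != "all":
            kind, _, arg = rd.partition(":")
            if kind not in ("purebred", "crossbred", "combined") or not arg:
                raise ValueError(f"bad reference_definition {rd!r}")
            breeds = arg.split("+") if kind == "combined" else arg.split("x")
            for b in breeds:
                if b and b not in self.simulation.breed_labels:
                    raise ValueError(f"reference_definition names unknown breed {b!r}")


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim = PopulationConfig(**raw.pop("simulation", {}))
    qc = QCThresholds(**raw.pop("qc", {}))
    return ExperimentConfig(simulation=sim, qc=qc, **raw)


def _stage_key(name: str, params, upstream: str = "") -> str:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    blob = json.dumps([name, params, upstream], sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _select_reference(cfg: ExperimentConfig, ped: Pedigree) -> np.ndarray:
    """Ids of reference animals under the configured reference definition."""
    t = ped.table
    ref = t[t["role"] == "reference"]
    rd = cfg.reference_definition
    if rd == "all":
        return ref["id"].to_numpy(dtype=object)
    kind, _, arg = rd.partition(":")
    breed_of = dict(zip(t["id"], _main_breed(t, ped.breeds)))
    if kind == "purebred":
        keep = ref[[f"breed_{arg}"]].to_numpy().ravel() >= 1.0 - 1e-9
        return ref.loc[keep, "id"].to_numpy(dtype=object)
    if kind == "crossbred":
        sire_b, dam_b = arg.split("x")
        keep = np.array(
            [
                breed_of.get(s) == sire_b and breed_of.get(d) == dam_b
                for s, d in zip(ref["sire"], ref["dam"])
            ]
        )
        return ref.loc[keep, "id"].to_numpy(dtype=object)
    # combined:<b1>+<b2>: union of crossbreds sired by those breeds
    sires = set(arg.split("+"))
    keep = np.array([breed_of.get(s) in sires for s in ref["sire"]])
    return ref.loc[keep, "id"].to_numpy(dtype=object)


def _main_breed(table: pd.DataFrame, breeds) -> list:
    frac = table[[f"breed_{b}" for b in breeds]].to_numpy()
    return [breeds[i] if frac[k, i] >= 1.0 - 1e-9 else None for k, i in enumerate(frac.argmax(axis=1))]


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute all stages; returns a report dict of output table paths."""
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "experiment.log")
    log.addHandler(fh)
    report: dict = {"tables": {}, "stages": {}}
    try:
        return _run_stages(cfg, out, report)
    except Exception as exc:
        stage = report.get("failed_stage", "unknown")
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()


def _cache_dir(out: Path, key: str) -> Path:
    d = out / "cache" / key
    d.mkdir(parents=True, exist_ok=True)
    return d


def _run_stages(cfg: ExperimentConfig, out: Path, report: dict) -> dict:
    sim = cfg.simulation

    # --- simulate -----------------------------------------------------------
    report["failed_stage"] = "simulate"
    sim_key = _stage_key("simulate", asdict(sim))
    cache = _cache_dir(out, sim_key)
    if (cache / "_complete").exists():
        log.info("simulate: cache hit %s", sim_key)
        geno = opio.read_plink(cache / "dense_all")
        ped = opio.read_pedigree(cache / "pedigree.tsv")
        truth_tab = pd.read_csv(cache / "truth.tsv", sep="\t")
        qtl_tab = pd.read_csv(cache / "qtl.tsv", sep="\t")
        from ovinepred.simdata import TrueGeneticValues

        truth = TrueGeneticValues(
            qtl_ids=qtl_tab["qtl_id"].to_numpy(dtype=object),
            qtl_effects=np.load(cache / "qtl_effects.npy"),  # bit-exact, unlike TSV text
            ids=truth_tab["id"].to_numpy(dtype=object),
            tbv=np.load(cache / "tbv.npy"),
            additive_variance=float(json.loads((cache / "meta.json").read_text())["va"]),
        )
    else:
        geno, ped, truth = simulate_population(sim)
        opio.write_plink(geno, cache / "dense_all")
        opio.write_pedigree(ped, cache / "pedigree.tsv")
        pd.DataFrame({"id": truth.ids, "tbv": truth.tbv}).to_csv(
            cache / "truth.tsv", sep="\t", index=False
        )
        pd.DataFrame({"qtl_id": truth.qtl_ids, "effect": truth.qtl_effects}).to_csv(
            cache / "qtl.tsv", sep="\t", index=False
        )
        np.save(cache / "tbv.npy", truth.tbv)
        np.save(cache / "qtl_effects.npy", truth.qtl_effects)
        (cache / "meta.json").write_text(json.dumps({"va": truth.additive_variance}))
        (cache / "_complete").touch()
    report["stages"]["simulate"] = sim_key

    # --- panels + QC --------------------------------------------------------
    report["failed_stage"] = "panels_qc"
    exclude = () if sim.qtl_observed else truth.qtl_ids
    panels: dict[str, GenotypeMatrix] = {}
    if "dense" in cfg.panels:
        panels["dense"] = subset_density(geno, 1.0, seed=sim.seed + 1, exclude_snp_ids=exclude)
    if "moderate" in cfg.panels:
        panels["moderate"] = subset_density(
            geno, sim.density_ratio, seed=sim.seed + 2, exclude_snp_ids=truth.qtl_ids
        )
    qc_rows = []
    for label in list(panels):
        rep = filter_snps(panels[label], cfg.qc)
        panels[label] = apply_snp_report(panels[label], rep)
        for snp, rule, stat in rep.removal_log:
            qc_rows.append({"panel": label, "item": snp, "rule": rule, "statistic": stat})
    dup = filter_duplicate_samples(panels[list(panels)[0]], cfg.qc)
    for sid, rule, stat in dup.removal_log:
        qc_rows.append({"panel": "samples", "item": sid, "rule": rule, "statistic": stat})
    kept_samples = set(dup.kept_samples)
    for label in list(panels):
        keep = np.array([i in kept_samples for i in panels[label].ids])
        panels[label] = panels[label].subset_individuals(np.flatnonzero(keep))
    pd.DataFrame(qc_rows, columns=["panel", "item", "rule", "statistic"]).to_csv(
        out / "qc_removals.tsv", sep="\t", index=False
    )
    report["tables"]["qc_removals"] = str(out / "qc_removals.tsv")

    # --- phenotypes + design ------------------------------------------------
    report["failed_stage"] = "phenotypes"
    design_all = simulate_phenotypes(geno, ped, truth, sim, seed=sim.seed + 3)
    table = design_all.source_table
    ref_ids = set(_select_reference(cfg, ped)) & kept_samples
    table = table[table["id"].isin(ref_ids)].reset_index(drop=True)
    if len(table) < 30:
        raise ValueError(f"reference definition {cfg.reference_definition!r} leaves "
                         f"{len(table)} phenotyped animals")
    design = build_design(table, ped, trait="trait")
    opio.write_phenotypes(table, out / "phenotypes.tsv")
    report["tables"]["phenotypes"] = str(out / "phenotypes.tsv")

    val_ids = [
        i
        for i in ped.table.loc[ped.table["role"] == "validation_sire", "id"]
        if i in kept_samples
    ]

    # --- relationship matrices ----------------------------------------------
    report["failed_stage"] = "relationships"
    grms = {}
    needed = list(design.animal_ids) + val_ids
    for label, panel in panels.items():
        sub = panel.loc_individuals(needed)
        grms[label] = compute_grm(sub, panel_label=label)
    diag_rows = []
    for label, G in grms.items():
        d = scale_diagnostics(G)
        diag_rows.append(
            {"matrix": f"G-{label}", "mean_diagonal": d.mean_diagonal, "mean_offdiag": d.mean_offdiagonal}
        )
    nrm = None
    if cfg.run_pblup:
        nrm = compute_nrm(ped)
        d = scale_diagnostics(nrm)
        diag_rows.append(
            {"matrix": "A", "mean_diagonal": d.mean_diagonal, "mean_offdiag": d.mean_offdiagonal}
        )
    pd.DataFrame(diag_rows).to_csv(out / "scale_diagnostics.tsv", sep="\t", index=False)
    report["tables"]["scale_diagnostics"] = str(out / "scale_diagnostics.tsv")

    # --- REML ----------------------------------------------------------------
    report["failed_stage"] = "reml"
    vc_rows = []
    vcs = {}
    for label in panels:
        res = fit_reml(design, grms[label])
        vcs[label] = res.components
        row = {"model": f"GBLUP-{label}", **res.components.as_dict(),
               "h2_se": res.components.h2_se, "loglik": res.loglik,
               "converged": res.converged, "n_iter": res.n_iter}
        vc_rows.append(row)
    if cfg.run_pblup and nrm is not None:
        res = fit_reml(design, nrm)
        vcs["pedigree"] = res.components
        vc_rows.append({"model": "PBLUP", **res.components.as_dict(),
                        "h2_se": res.components.h2_se, "loglik": res.loglik,
                        "converged": res.converged, "n_iter": res.n_iter})
    pd.DataFrame(vc_rows).to_csv(out / "variance_components.tsv", sep="\t", index=False)
    report["tables"]["variance_components"] = str(out / "variance_components.tsv")

    # --- prediction -----------------------------------------------------------
    report["failed_stage"] = "prediction"
    preds = {}
    for label in panels:
        pr = solve_mme(design, grms[label], vcs[label], predict_ids=val_ids,
                       method=f"GBLUP-{label}")
        preds[f"GBLUP-{label}"] = pr
        if "BayesR" in cfg.methods:
            sub = panels[label].loc_individuals(needed)
            priors = BayesRPriors(
                sigma_g2=vcs[label].v_additive,
                seed=sim.seed + 7,
                **cfg.bayesr,
            )
            post = run_bayesr(design, sub, priors)
            preds[f"BayesR-{label}"] = _as_prediction(post, f"BayesR-{label}")
    for name, pr in preds.items():
        df = pd.DataFrame({"id": pr.ids, "gbv": pr.gbv, "method": pr.method})
        df.to_csv(out / f"gbv_{name}.tsv", sep="\t", index=False)
        report["tables"][f"gbv_{name}"] = str(out / f"gbv_{name}.tsv")

    # --- validation -----------------------------------------------------------
    report["failed_stage"] = "validation"
    ebv = simulate_progeny_ebv(
        truth, val_ids, cfg.validation_n_progeny, sim.h2_target, seed=sim.seed + 5
    ).to_frame()
    ebv.to_csv(out / "validation_ebv.tsv", sep="\t", index=False)
    breed_of = dict(zip(ped.table["id"], _main_breed(ped.table, ped.breeds)))
    groups = {i: breed_of.get(i) or "crossbred" for i in val_ids}
    acc_rows = []
    for name, pr in preds.items():
        sub_pred = _subset_prediction(pr, val_ids)
        for res in accuracy(sub_pred, ebv, groups=groups):
            acc_rows.append(
                {"method": name, "breed": res.group_label, "r": res.r, "n": res.n,
                 "se": res.se, "regression_coef": res.regression_coef}
            )
    pd.DataFrame(acc_rows).to_csv(out / "accuracy_by_breed.tsv", sep="\t", index=False)
    report["tables"]["accuracy_by_breed"] = str(out / "accuracy_by_breed.tsv")

    first = list(panels)[0]
    strata_groups = classify_relatedness(grms[first], list(design.animal_ids), val_ids)
    strata = strata_groups.label_of()
    if len(preds) > 1:
        comp = stratified_comparison(
            {k: _subset_prediction(v, val_ids) for k, v in preds.items()},
            ebv,
            strata,
            seed=sim.seed + 6,
        )
        comp.to_csv(out / "stratified_accuracy.tsv", sep="\t", index=False)
        report["tables"]["stratified_accuracy"] = str(out / "stratified_accuracy.tsv")

    report["failed_stage"] = None
    report["checksums"] = {
        name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
        for name, p in report["tables"].items()
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _as_prediction(post, method: str):
    from ovinepred.gblup import PredictionResult

    return PredictionResult(ids=post.ids, gbv=post.gbv, method=method)


def _subset_prediction(pr, ids):
    from ovinepred.gblup import PredictionResult

    return PredictionResult(
        ids=np.asarray(list(ids), dtype=object),
        gbv=pr.gbv_for(ids),
        method=pr.method,
        fixed_solutions=pr.fixed_solutions,
    )
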