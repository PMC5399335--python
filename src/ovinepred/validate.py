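"""Empirical accuracy and bias of genomic predictions.

Accuracy is the Pearson correlation between predicted breeding values and a
benchmark (progeny-test EBV, or true breeding values on simulated data),
reported per group with the standard error sqrt((1 - r^2) / (n - 2)) and the
ordinary-least-squares regression slope of the benchmark on the prediction
(a slope of 1 means unbiased dispersion).  An optional covariate adjustment
removes group means over a strain label from both variables before
correlating — the guard against inflating within-breed accuracy by pooling
divergent strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ovinepred.gblup import PredictionResult

__all__ = ["AccuracyResult", "accuracy", "stratified_comparison"]


@dataclass
class AccuracyResult:
    group_label: str
    r: float
    n: int
    se: float
    regression_coef: float
    flagged: bool = False  # zero-variance or low-n conditions

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")


def _pair(pred: PredictionResult, ebv_table: pd.DataFrame):
    eb = ebv_table.set_index("id")["ebv"]
    common = [i for i in pred.ids if i in eb.index]
    g = pred.gbv_for(common)
    e = eb.loc[common].to_numpy(dtype=float)
    return np.asarray(common, dtype=object), g, e


def _adjust(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    out = values.astype(float).copy()
    for lab in pd.unique(labels):
        mask = labels == lab
        out[mask] -= out[mask].mean()
    return out


def _one_group(label: str, g: np.ndarray, e: np.ndarray) -> AccuracyResult:
    n = g.size
    if n < 3:
        raise ValueError(f"group {label!r} has fewer than 3 paired observations")
    if g.std() == 0 or e.std() == 0:
        return AccuracyResult(label, np.nan, n, np.nan, np.nan, flagged=True)
    r = float(np.corrcoef(g, e)[0, 1])
    se = float(np.sqrt((1.0 - r**2) / (n - 2)))
    slope = float(np.cov(g, e, ddof=1)[0, 1] / np.var(g, ddof=1))
    return AccuracyResult(label, r, n, se, slope)


def accuracy(
    pred: PredictionResult,
    ebv_table: pd.DataFrame,
    groups: dict | None = None,
    covariate_adjust: dict | None = None,
) -> list[AccuracyResult]:
    """Per-group accuracy of predictions against benchmark EBVs.

    ``ebv_table`` needs columns ``id`` and ``ebv``.  ``groups`` maps animal
    id to a group label (breed, relatedness class...); omitted means one
    pooled group.  ``covariate_adjust`` maps id to a strain label whose
    group means are removed from both variables first.
    """
    ids, g, e = _pair(pred, ebv_table)
    if covariate_adjust is not None:
        strain = np.array([covariate_adjust.get(i, "_none") for i in ids], dtype=object)
        g = _adjust(g, strain)
        e = _adjust(e, strain)
    if groups is None:
        return [_one_group("all", g, e)]
    labels = np.array([groups.get(i) for i in ids], dtype=object)
    out = []
    for lab in pd.unique(labels[labels != np.array(None)]):
        mask = labels == lab
        out.append(_one_group(str(lab), g[mask], e[mask]))
    return out


def stratified_comparison(
    pred_by_panel: dict,
    ebv_table: pd.DataFrame,
    strata: dict,
    n_bootstrap: int = 1000,
    seed: int = 0,
    covariate_adjust: dict | None = None,
) -> pd.DataFrame:
    """Accuracy per stratum and panel, plus paired differences between panels.

    ``pred_by_panel`` maps panel labels to :class:`PredictionResult` over the
    same validation ids; ``strata`` maps id to a stratum label (relatedness
    class or breed).  For each pair of panels, the accuracy difference per
    stratum gets a seeded paired-bootstrap percentile interval.  Strata with
    fewer than 10 animals are reported with ``low_n`` set.
    """
    panels = list(pred_by_panel)
    rows = []
    paired = {}
    for panel in panels:
        ids, g, e = _pair(pred_by_panel[panel], ebv_table)
        if covariate_adjust is not None:
            strain = np.array([covariate_adjust.get(i, "_none") for i in ids], dtype=object)
            g = _adjust(g, strain)
            e = _adjust(e, strain)
        paired[panel] = (ids, g, e)
    base_ids = list(paired[panels[0]][0])
    for panel in panels[1:]:
        if list(paired[panel][0]) != base_ids:
            raise ValueError("all panels must cover the same validation ids")

    labels = np.array([strata.get(i) for i in base_ids], dtype=object)
    strat_levels = [s for s in pd.unique(labels) if s is not None]

    for stratum in strat_levels:
        mask = labels == stratum
        for panel in panels:
            _, g, e = paired[panel]
            res = _one_group(str(stratum), g[mask], e[mask])
            rows.append(
                {
                    "stratum": stratum,
                    "panel": panel,
                    "comparison": "",
                    "r": res.r,
                    "n": res.n,
                    "se": res.se,
                    "regression_coef": res.regression_coef,
                    "diff": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "low_n": res.n < 10,
                }
            )

    rng = np.random.default_rng(seed)
    for stratum in strat_levels:
        mask = labels == stratum
        idx = np.flatnonzero(mask)
        for a in range(len(panels)):
            for b in range(a + 1, len(panels)):
                pa, pb = panels[a], panels[b]
                _, ga, ea = paired[pa]
                _, gb, eb = paired[pb]
                ra = _corr(ga[idx], ea[idx])
                rb = _corr(gb[idx], eb[idx])
                diff = rb - ra
                boots = np.empty(n_bootstrap)
                for t in range(n_bootstrap):
                    take = rng.choice(idx, size=idx.size, replace=True)
                    boots[t] = _corr(gb[take], eb[take]) - _corr(ga[take], ea[take])
                lo, hi = np.nanpercentile(boots, [2.5, 97.5])
                rows.append(
                    {
                        "stratum": stratum,
                        "panel": "",
                        "comparison": f"{pb} - {pa}",
                        "r": np.nan,
                        "n": int(idx.size),
                        "se": np.nan,
                        "regression_coef": np.nan,
                        "diff": diff,
                        "ci_low": lo,
                        "ci_high": hi,
                        "low_n": idx.size < 10,
                    }
                )
    return pd.DataFrame(rows)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])
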