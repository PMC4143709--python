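"""Covariate adjustment of longitudinal traits.

The trait at each exam is regressed (OLS) on an intercept, age, sex,
age x sex and the exam's medication indicator; the residuals — not the
raw measurements — feed the phenotype-side clustering.  Adjustment is
cross-sectional per exam, the minimal reading of residualize-then-cluster;
no joint longitudinal model is fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import statsmodels.api as sm

from .panels import TraitPanel

__all__ = ["adjust_covariates", "assemble_vectors"]


def _design_at(panel: TraitPanel, t: int) -> tuple[np.ndarray, list[str]]:
    age = np.asarray(panel.covariates["age"], dtype=float)
    sex = np.asarray(panel.covariates["sex"], dtype=float)
    med = panel.medication_at(t)
    cols = [np.ones(len(age)), age, sex, age * sex, med]
    names = ["intercept", "age", "sex", "age_sex", "medication"]
    return np.column_stack(cols), names


def _drop_collinear(X: np.ndarray, names: list[str]):
    """Greedy left-to-right column selection keeping a full-rank design."""
    keep: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropped collinear covariate columns: {dropped}",
                      stacklevel=3)
    return X[:, keep], [names[j] for j in keep]


def adjust_covariates(panel: TraitPanel) -> TraitPanel:
    """Residualize each exam's trait on the covariate design.

    Returns a new panel with ``adjusted`` filled by per-exam OLS
    residuals (missing trait values stay missing and are excluded from
    the fit at that exam).  Requires enough subjects for the 5-column
    design.
    """
    n, T = panel.raw.shape
    if n < 7:
        raise ValueError("need at least p+2 = 7 subjects for adjustment")
    adjusted = np.full_like(panel.raw, np.nan, dtype=float)
    for t in range(T):
        X, names = _design_at(panel, t)
        X, names = _drop_collinear(X, names)
        y = panel.raw[:, t]
        ok = np.isfinite(y)
        if ok.sum() < X.shape[1] + 2:
            raise ValueError(f"too few observed traits at exam {t}")
        fit = sm.OLS(y[ok], X[ok]).fit()
        adjusted[ok, t] = fit.resid
    return replace(panel, adjusted=adjusted)


def assemble_vectors(panel: TraitPanel) -> np.ndarray:
    """Complete subjects x T matrix of adjusted trajectories.

    Rows follow the input subject order.  A subject missing an exam gets
    that exam filled by carrying their last observed adjusted value
    forward (first observed value backward for leading gaps), with a
    warning; an all-missing subject is rejected.
    """
    if panel.adjusted is None:
        raise ValueError("panel has no adjusted traits; run adjust_covariates")
    vecs = np.array(panel.adjusted, dtype=float)
    missing = ~np.isfinite(vecs)
    if missing.any():
        if np.any(missing.all(axis=1)):
            bad = panel.subjects[missing.all(axis=1)]
            raise ValueError(f"subjects with no observed exams: {list(bad)}")
        warnings.warn(
            f"carried forward last observed values for "
            f"{int(missing.any(axis=1).sum())} subjects with missing exams",
            stacklevel=2)
        for i in np.flatnonzero(missing.any(axis=1)):
            row = vecs[i]
            obs = np.flatnonzero(np.isfinite(row))
            # leading gap: backfill with first observation, then LOCF
            row[:obs[0]] = row[obs[0]]
            for t in range(obs[0] + 1, len(row)):
                if not np.isfinite(row[t]):
                    row[t] = row[t - 1]
    return vecs
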