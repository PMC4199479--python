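"""Covariate-adjusted association, tiled stepwise regression, and
multi-cohort combination.

Single-variant analysis is OLS of the (optionally log-transformed) CALM
count on intercept + age + sex + coded genotype.  The tiled procedure first
pre-adjusts the trait for age and sex, screens each hotspot-delimited tile
(overall F-test at 0.2 or any single-variant p < 0.05), runs forward
stepwise selection with backward elimination (entry and stay alpha 0.05)
within retained tiles, then pools survivors per chromosome and genome-wide
with the same rule.  Cohort evidence is combined either by Liptak's
sqrt(n)-weighted Z method on p-values (meta) or by pooling individual-level
data with cohort indicator covariates (mega).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import (
    SEX_CODE,
    AssociationResult,
    DomainError,
    MetaResult,
    transform_trait,
)

log = logging.getLogger(__name__)

_TINY_P = np.finfo(float).tiny


@dataclass(frozen=True)
class ModelSpec:
    """Which trait scale and genetic model a regression uses."""

    trait_transform: str = "unt"      # unt | log
    genetic_model: str = "add"        # add | dom | add_collapsed
    entry_alpha: float = 0.05
    stay_alpha: float = 0.05
    tile_screen_alpha: float = 0.2
    single_snv_screen_alpha: float = 0.05

    @property
    def tag(self) -> str:
        return f"{self.trait_transform}_{self.genetic_model}"

    def apply_transform(self, trait):
        return transform_trait(trait) if self.trait_transform == "log" else np.asarray(trait, dtype=float)


# ---------------------------------------------------------------------------
# OLS core

@dataclass(frozen=True)
class OLSFit:
    beta: np.ndarray         # coefficients, intercept first
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray            # two-sided, t distribution with n-k df
    n: int
    df_resid: int
    rss: float
    f_p: float               # overall F-test p (all non-intercept terms)


def fit_ols(X: np.ndarray, y: np.ndarray) -> OLSFit:
    """OLS via normal equations; X must already contain the intercept column."""
    n, k = X.shape
    if n <= k:
        raise DomainError(f"need more observations ({n}) than parameters ({k})")
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    df = n - k
    rss = float(resid @ resid)
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    tss = float(((y - y.mean()) ** 2).sum())
    if k > 1 and rss < tss:
        f = ((tss - rss) / (k - 1)) / sigma2 if sigma2 > 0 else np.inf
        f_p = float(stats.f.sf(f, k - 1, df)) if np.isfinite(f) else _TINY_P
    elif k > 1:
        f_p = 1.0
    else:
        f_p = np.nan
    return OLSFit(beta=beta, se=se, t=t, p=np.maximum(p, _TINY_P), n=n, df_resid=df, rss=rss, f_p=f_p)


def encode_covariates(pheno: pd.DataFrame) -> pd.DataFrame:
    """Numeric age + sex (female=0, male=1) design block from a phenotype table."""
    sex = pheno["sex"].map(SEX_CODE)
    if sex.isna().any():
        raise DomainError("sex column contains values other than male/female")
    return pd.DataFrame({"age": pheno["age"].astype(float), "sex": sex.astype(float)}, index=pheno.index)


# ---------------------------------------------------------------------------
# single-variant regression and trait residualization

def single_variant_regression(trait, covariates: pd.DataFrame, genotype,
                              spec: ModelSpec = ModelSpec(), target_id: str = "") -> AssociationResult:
    """Covariate-adjusted OLS for one coded variant; complete-case."""
    y = spec.apply_transform(np.asarray(trait, dtype=float))
    g = np.asarray(genotype, dtype=float)
    cov = covariates.to_numpy(dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g) | np.isnan(cov).any(axis=1))
    y, g, cov = y[keep], g[keep], cov[keep]
    n = y.size
    if np.unique(g).size < 2:
        return AssociationResult(target_id, spec.tag, np.nan, np.nan, np.nan, n, reason="constant_genotype")
    if n < cov.shape[1] + 3:
        return AssociationResult(target_id, spec.tag, np.nan, np.nan, np.nan, n, reason="too_few_complete_cases")
    X = np.column_stack([np.ones(n), cov, g])
    fit = fit_ols(X, y)
    return AssociationResult(target_id, spec.tag, float(fit.beta[-1]), float(fit.se[-1]),
                             float(fit.p[-1]), n)


def residualize_trait(trait, covariates: pd.DataFrame):
    """Residuals of trait on intercept + covariates; NaN where incomplete."""
    y = np.asarray(trait, dtype=float)
    cov = covariates.to_numpy(dtype=float)
    keep = ~(np.isnan(y) | np.isnan(cov).any(axis=1))
    X = np.column_stack([np.ones(keep.sum()), cov[keep]])
    beta = np.linalg.solve(X.T @ X, X.T @ y[keep])
    out = np.full(y.shape, np.nan)
    out[keep] = y[keep] - X @ beta
    return out


# ---------------------------------------------------------------------------
# tiled regression

@dataclass
class TiledModel:
    """Final joint model of the tiled stepwise procedure."""

    selected: list = field(default_factory=list)          # (column, beta, p) in entry order
    intercept: float = np.nan
    screen: dict = field(default_factory=dict)            # tile id -> dict of screen outcomes
    trace: list = field(default_factory=list)             # (level, action, column, p) events
    n_used: int = 0

    @property
    def selected_ids(self) -> list:
        return [c for c, _, _ in self.selected]


class TiledRegression(BaseEstimator):
    """Tile-screened forward stepwise regression with backward elimination.

    Fit on ``X`` = coded genotype columns (common variants and/or collapsed
    rare columns), ``y`` = covariate-residualized trait, with a mapping of
    column -> tile id and column -> (chrom, pos) for deterministic
    tie-breaking (lower genomic coordinate enters first on equal p).
    """

    def __init__(self, entry_alpha: float = 0.05, stay_alpha: float = 0.05,
                 tile_screen_alpha: float = 0.2, single_snv_screen_alpha: float = 0.05):
        self.entry_alpha = entry_alpha
        self.stay_alpha = stay_alpha
        self.tile_screen_alpha = tile_screen_alpha
        self.single_snv_screen_alpha = single_snv_screen_alpha

    def fit(self, X: pd.DataFrame, y, column_tiles: Mapping, column_positions: Mapping | None = None):
        y = np.asarray(y, dtype=float)
        pos = dict(column_positions or {})
        self.model_ = tiled_regression(
            y, X, column_tiles, positions=pos,
            entry_alpha=self.entry_alpha, stay_alpha=self.stay_alpha,
            tile_screen_alpha=self.tile_screen_alpha,
            single_snv_screen_alpha=self.single_snv_screen_alpha,
        )
        self.selected_ = self.model_.selected_ids
        self.trace_ = self.model_.trace
        self.screen_ = self.model_.screen
        return self


def _complete_fit(y: np.ndarray, X: pd.DataFrame, cols: Sequence) -> OLSFit | None:
    """Complete-case OLS of y on intercept + the named columns."""
    sub = X[list(cols)].to_numpy(dtype=float)
    keep = ~(np.isnan(y) | np.isnan(sub).any(axis=1))
    n = int(keep.sum())
    if n <= len(cols) + 1:
        return None
    design = np.column_stack([np.ones(n), sub[keep]])
    try:
        return fit_ols(design, y[keep])
    except np.linalg.LinAlgError:
        return None


def _stepwise(y: np.ndarray, X: pd.DataFrame, candidates: Sequence, entry_alpha: float,
              stay_alpha: float, positions: Mapping, trace: list, level: str) -> list:
    """Forward entry (best p < entry_alpha) with backward elimination (p >= stay_alpha)."""

    def sort_key(col):
        return positions.get(col, ("", 0))

    model: list = []
    candidates = list(candidates)
    while True:
        best_col, best_p = None, np.inf
        for col in candidates:
            if col in model:
                continue
            fit = _complete_fit(y, X, model + [col])
            if fit is None:
                continue
            p = fit.p[-1]
            if p < best_p - 1e-15 or (abs(p - best_p) <= 1e-15 and best_col is not None
                                      and sort_key(col) < sort_key(best_col)):
                best_col, best_p = col, p
        if best_col is None or not (best_p < entry_alpha):
            break
        model.append(best_col)
        trace.append((level, "enter", best_col, float(best_p)))
        # backward look: drop the least significant term while any fails the stay rule
        while len(model) > 1:
            fit = _complete_fit(y, X, model)
            if fit is None:
                break
            term_p = fit.p[1:]
            worst = int(np.argmax(term_p))
            if term_p[worst] >= stay_alpha:
                removed = model.pop(worst)
                trace.append((level, "remove", removed, float(term_p[worst])))
            else:
                break
    return model


def tiled_regression(y: np.ndarray, X: pd.DataFrame, column_tiles: Mapping,
                     positions: Mapping | None = None, entry_alpha: float = 0.05,
                     stay_alpha: float = 0.05, tile_screen_alpha: float = 0.2,
                     single_snv_screen_alpha: float = 0.05) -> TiledModel:
    """Run the full tile screen -> tile / chromosome / genome stepwise cascade."""
    positions = dict(positions or {})
    model = TiledModel()
    by_tile: dict = {}
    for col, tile in column_tiles.items():
        if col in X.columns:
            by_tile.setdefault(tile, []).append(col)

    tile_survivors: dict = {}
    for tile, cols in sorted(by_tile.items()):
        cols = sorted(cols, key=lambda c: positions.get(c, ("", 0)))
        outcome: dict = {"n_columns": len(cols)}
        joint = _complete_fit(y, X, cols)
        if joint is None:
            outcome["f_p"] = None
            log.info("tile %s: joint model not estimable; single-variant screen only", tile)
        else:
            outcome["f_p"] = float(joint.f_p)
        single_ps = {}
        for col in cols:
            fit = _complete_fit(y, X, [col])
            single_ps[col] = float(fit.p[-1]) if fit is not None else np.nan
        outcome["single_p"] = single_ps
        retained = (outcome["f_p"] is not None and outcome["f_p"] < tile_screen_alpha) or any(
            p < single_snv_screen_alpha for p in single_ps.values() if not np.isnan(p)
        )
        outcome["retained"] = bool(retained)
        model.screen[tile] = outcome
        model.trace.append(("tile-screen", "retain" if retained else "drop", f"tile{tile}",
                            outcome["f_p"] if outcome["f_p"] is not None else np.nan))
        if retained:
            tile_survivors[tile] = _stepwise(y, X, cols, entry_alpha, stay_alpha, positions,
                                             model.trace, f"tile{tile}")

    # chromosome level
    chrom_survivors: dict = {}
    for tile, cols in tile_survivors.items():
        for col in cols:
            chrom = positions.get(col, ("", 0))[0]
            chrom_survivors.setdefault(chrom, []).append(col)
    chrom_selected = []
    for chrom, cols in sorted(chrom_survivors.items()):
        chrom_selected.extend(_stepwise(y, X, cols, entry_alpha, stay_alpha, positions,
                                        model.trace, f"chrom:{chrom}"))

    # genome level
    final_cols = _stepwise(y, X, chrom_selected, entry_alpha, stay_alpha, positions,
                           model.trace, "genome")
    if final_cols:
        fit = _complete_fit(y, X, final_cols)
        model.intercept = float(fit.beta[0])
        model.n_used = fit.n
        model.selected = [(c, float(b), float(p))
                          for c, b, p in zip(final_cols, fit.beta[1:], fit.p[1:])]
    return model


# ---------------------------------------------------------------------------
# multi-cohort combination

def liptak_meta(cohort_p: Sequence[float], cohort_n: Sequence[int], target_id: str = "",
                model: str = "", betas: Sequence[float] | None = None, signed: bool = False) -> MetaResult:
    """Liptak/Stouffer combination: Z = sum(sqrt(n_i) z_i) / sqrt(sum n_i).

    Default (unsigned) convention maps each two-sided cohort p through
    z = Phi^-1(1 - p) regardless of the cohort effect sign; this is the
    convention that reproduces the published meta column.  ``signed=True``
    multiplies each z by sign(beta) instead.
    """
    p = np.asarray(cohort_p, dtype=float)
    n = np.asarray(cohort_n, dtype=float)
    if p.shape != n.shape:
        raise DomainError("cohort p-value and size lists differ in length")
    if np.any((p <= 0) | (p >= 1)):
        raise DomainError("cohort p-values must lie strictly in (0, 1)")
    if np.any(n < 1):
        raise DomainError("cohort sizes must be >= 1")
    z = stats.norm.isf(p)
    if signed:
        if betas is None:
            raise DomainError("signed combination requires cohort betas")
        z = z * np.sign(np.asarray(betas, dtype=float))
    combined_z = float(np.sum(np.sqrt(n) * z) / np.sqrt(n.sum()))
    combined_p = float(stats.norm.sf(combined_z))
    return MetaResult(target_id, model, tuple(p.tolist()), tuple(int(v) for v in n),
                      combined_z, combined_p)


def mega_analysis(trait, covariates: pd.DataFrame, genotype, cohorts,
                  spec: ModelSpec = ModelSpec(), target_id: str = "") -> AssociationResult:
    """Pooled individual-level regression with cohort indicator covariates."""
    cohorts = pd.Series(list(cohorts))
    labels = cohorts.dropna().unique()
    if len(labels) < 2:
        raise DomainError("mega-analysis requires at least two cohorts")
    dummies = pd.get_dummies(cohorts, drop_first=True, dtype=float)
    dummies.index = covariates.index
    y = spec.apply_transform(np.asarray(trait, dtype=float))
    g = np.asarray(genotype, dtype=float)
    cov = pd.concat([covariates.reset_index(drop=True), dummies.reset_index(drop=True)], axis=1)
    covm = cov.to_numpy(dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g) | np.isnan(covm).any(axis=1))
    y, g, covm = y[keep], g[keep], covm[keep]
    n = y.size
    if np.unique(g).size < 2:
        return AssociationResult(target_id, spec.tag + "_mega", np.nan, np.nan, np.nan, n,
                                 reason="constant_genotype")
    X = np.column_stack([np.ones(n), covm, g])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return AssociationResult(target_id, spec.tag + "_mega", np.nan, np.nan, np.nan, n,
                                 reason="collinear_design")
    fit = fit_ols(X, y)
    return AssociationResult(target_id, spec.tag + "_mega", float(fit.beta[-1]), float(fit.se[-1]),
                             float(fit.p[-1]), n)
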