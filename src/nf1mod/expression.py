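"""Expression-phenotype screen.

Transcript abundance in lymphoblastoid cell lines is treated as an
intermediate phenotype: each transcript's log2 expression is regressed
against a quantitative trait, p-values are corrected with the
Benjamini-Hochberg step-up, and candidates are filtered on FDR (< 0.3),
mean expression level (>= 6) and expression range (>= 2), with a rescue
list for genes kept on biological grounds despite failing the level/range
filters.  A qPCR-style verification step retains candidates whose relative
expression remains nominally associated (p < 0.05).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import DomainError, TranscriptSummary

log = logging.getLogger(__name__)

_TINY_P = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# preprocessing

def quantile_normalize(mat: np.ndarray) -> np.ndarray:
    """Rank-mean quantile normalization across columns (samples).

    Each sample's sorted values are replaced by the rank-wise mean profile;
    ties receive the average of the reference values at the tied ranks.
    Leaves per-sample rank order unchanged.
    """
    mat = np.asarray(mat, dtype=float)
    n, m = mat.shape
    ref = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(m):
        ranks = stats.rankdata(mat[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return out


def preprocess_expression(raw: pd.DataFrame, background=0.0) -> pd.DataFrame:
    """Background-subtract, floor at zero, quantile-normalize, log2(x+1).

    ``raw`` is transcripts x samples of nonnegative intensities;
    ``background`` is a scalar or per-sample offset.
    """
    vals = raw.to_numpy(dtype=float) - np.asarray(background, dtype=float)
    vals = np.maximum(vals, 0.0)
    zero_var = vals.std(axis=0) == 0
    if zero_var.any():
        log.warning("%d sample column(s) have zero variance", int(zero_var.sum()))
    vals = quantile_normalize(vals)
    return pd.DataFrame(np.log2(vals + 1.0), index=raw.index, columns=raw.columns)


class ExpressionPreprocessor(BaseEstimator, TransformerMixin):
    """Transformer form of :func:`preprocess_expression`.

    ``fit`` learns the rank-mean reference profile from the training matrix
    (samples as columns); ``transform`` maps each sample's ranks onto it and
    returns log2(x+1) values.
    """

    def __init__(self, background: float = 0.0):
        self.background = background

    def fit(self, X: pd.DataFrame, y=None):
        vals = np.maximum(X.to_numpy(dtype=float) - self.background, 0.0)
        self.reference_ = np.sort(vals, axis=0).mean(axis=1)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        vals = np.maximum(X.to_numpy(dtype=float) - self.background, 0.0)
        n = vals.shape[0]
        grid = np.arange(1, n + 1, dtype=float)
        ref = np.interp(np.linspace(1, len(self.reference_), n), np.arange(1, len(self.reference_) + 1),
                        self.reference_)
        out = np.empty_like(vals)
        for j in range(vals.shape[1]):
            ranks = stats.rankdata(vals[:, j], method="average")
            out[:, j] = np.interp(ranks, grid, ref)
        return pd.DataFrame(np.log2(out + 1.0), index=X.index, columns=X.columns)


# ---------------------------------------------------------------------------
# per-transcript regression

@dataclass(frozen=True)
class SimpleRegression:
    slope: float
    p_value: float
    n: int


def regress_trait_on_transcript(trait, expression) -> SimpleRegression:
    """OLS of trait on a single transcript's expression (trait as response).

    Two-sided p from the t distribution with n-2 df.  Zero-variance
    expression yields a flagged (NaN) result rather than an error.
    """
    y = np.asarray(trait, dtype=float)
    x = np.asarray(expression, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    n = y.size
    if n < 3:
        raise DomainError(f"need >= 3 paired observations, got {n}")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        return SimpleRegression(slope=np.nan, p_value=np.nan, n=n)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    resid = y - y.mean() - slope * (x - x.mean())
    s2 = np.sum(resid**2) / (n - 2)
    if s2 == 0:
        return SimpleRegression(slope=float(slope), p_value=_TINY_P, n=n)
    t = slope / np.sqrt(s2 / sxx)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return SimpleRegression(slope=float(slope), p_value=float(max(p, _TINY_P)), n=n)


def _mass_simple_regression(Y: np.ndarray, trait: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (slope, p) of trait on each row of ``Y`` (transcripts x samples)."""
    y = trait - trait.mean()
    X = Y - Y.mean(axis=1, keepdims=True)
    sxx = (X**2).sum(axis=1)
    sxy = X @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        n = trait.size
        rss = (y**2).sum() - slope * sxy
        s2 = rss / (n - 2)
        t = slope / np.sqrt(s2 / sxx)
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(sxx == 0, np.nan, np.maximum(p, _TINY_P))
    slope = np.where(sxx == 0, np.nan, slope)
    return slope, p


# ---------------------------------------------------------------------------
# FDR

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved.

    Missing entries are excluded from the correction and returned missing.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    obs = ~np.isnan(p)
    pv = p[obs]
    if np.any((pv <= 0) | (pv > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[obs] = qv
    return out


# ---------------------------------------------------------------------------
# candidate filtering and verification

def filter_candidates(
    summaries: Sequence[TranscriptSummary],
    fdr_threshold: float = 0.3,
    level_threshold: float = 6.0,
    range_threshold: float = 2.0,
    rescue_list: Iterable[str] = (),
) -> list[TranscriptSummary]:
    """Apply the FDR / level / range filters with a biological rescue list.

    A transcript passes iff fdr_q < ``fdr_threshold`` and mean level >=
    ``level_threshold`` and range >= ``range_threshold``; transcripts on the
    rescue list need only the FDR condition and are flagged "rescued" when
    they would otherwise fail on level/range.
    """
    rescue = set(rescue_list)
    out = []
    for s in summaries:
        if np.isnan(s.fdr_q) or not (s.fdr_q < fdr_threshold):
            continue
        meets = s.mean_level >= level_threshold and s.level_range >= range_threshold
        if meets:
            flag = "pass"
        elif s.transcript_id in rescue:
            flag = "rescued"
        else:
            continue
        out.append(TranscriptSummary(s.transcript_id, s.mean_level, s.level_range,
                                     s.slope, s.p_value, s.fdr_q, flag))
    return out


def delta_delta_ct(ct_target_sample: float, ct_control_sample: float,
                   ct_target_ref: float, ct_control_ref: float) -> float:
    """Relative expression by the double-delta-Ct method: 2^-ddCt."""
    ddct = (ct_target_sample - ct_control_sample) - (ct_target_ref - ct_control_ref)
    return float(2.0 ** (-ddct))


def verify_candidates(qpcr: pd.DataFrame, trait, alpha: float = 0.05) -> list[str]:
    """Re-test candidates on qPCR relative expression (samples x candidates).

    Keeps candidates whose regression of trait on qPCR expression is
    nominally significant at ``alpha``.
    """
    verified = []
    for cid in qpcr.columns:
        res = regress_trait_on_transcript(trait, qpcr[cid])
        if not np.isnan(res.p_value) and res.p_value < alpha:
            verified.append(str(cid))
    return verified


# ---------------------------------------------------------------------------
# screen estimator

class TranscriptScreen(BaseEstimator):
    """Per-transcript trait-on-expression regression screen with BH FDR.

    Fit on ``X`` = samples x transcripts log2 expression and ``y`` = trait.
    Fitted attributes: ``summary_`` (DataFrame with slope, p, q, level,
    range, flag), ``summaries_`` (TranscriptSummary list for every
    transcript, ordered as the columns of X) and ``candidates_`` (ids
    surviving the filters).
    """

    def __init__(self, fdr_threshold: float = 0.3, level_threshold: float = 6.0,
                 range_threshold: float = 2.0, rescue_list: Iterable[str] = ()):
        self.fdr_threshold = fdr_threshold
        self.level_threshold = level_threshold
        self.range_threshold = range_threshold
        self.rescue_list = tuple(rescue_list)

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        keep = ~np.isnan(y)
        Y = X.to_numpy(dtype=float).T[:, keep]  # transcripts x samples
        slope, p = _mass_simple_regression(Y, y[keep])
        q = bh_fdr(p)
        level = Y.mean(axis=1)
        rng = Y.max(axis=1) - Y.min(axis=1)
        self.summary_ = pd.DataFrame(
            {"mean_level": level, "level_range": rng, "slope": slope, "p_value": p, "fdr_q": q},
            index=X.columns,
        )
        summaries = [
            TranscriptSummary(str(tid), float(r.mean_level), float(r.level_range),
                              float(r.slope), float(r.p_value), float(r.fdr_q), "fail")
            for tid, r in self.summary_.iterrows()
        ]
        kept = filter_candidates(summaries, self.fdr_threshold, self.level_threshold,
                                 self.range_threshold, self.rescue_list)
        flags = {s.transcript_id: s.candidate_flag for s in kept}
        self.summaries_ = [
            TranscriptSummary(s.transcript_id, s.mean_level, s.level_range, s.slope,
                              s.p_value, s.fdr_q, flags.get(s.transcript_id, "fail"))
            for s in summaries
        ]
        self.summary_["candidate_flag"] = [s.candidate_flag for s in self.summaries_]
        self.candidates_ = [s.transcript_id for s in kept]
        return self


def screen_transcripts(expression: pd.DataFrame, trait, **params) -> pd.DataFrame:
    """Functional wrapper around :class:`TranscriptScreen`.

    ``expression`` is transcripts x samples (file orientation); returns the
    per-transcript summary table.
    """
    est = TranscriptScreen(**params).fit(expression.T, np.asarray(trait, dtype=float))
    return est.summary_
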