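"""Variant-level quality control and genotype coding.

The QC pipeline runs in a fixed order: mask low-quality calls, drop
high-missingness samples, drop high-missingness variants, drop monomorphic
variants.  Hardy-Weinberg failures (exact test, p < 0.03) are flagged but
never removed, since in highly ascertained samples departures from HWE can
mark causative variants.  Coding schemes: additive dosage (add), dominant
indicator (dom), and additive with rare variants collapsed per tile
(add_collapsed).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    RARE_MAF_THRESHOLD,
    DomainError,
    GenotypeMatrix,
    QCReport,
    SampleRecord,
    TileMap,
)

# ---------------------------------------------------------------------------
# elementary QC steps


def mask_low_quality_calls(g: GenotypeMatrix, threshold: float = 99.0) -> tuple[GenotypeMatrix, int]:
    """Set calls with quality strictly below ``threshold`` to missing."""
    if g.quality is None:
        return g, 0
    mask = (g.quality < threshold) & g.calls.notna()
    calls = g.calls.mask(mask)
    return GenotypeMatrix(calls=calls, quality=g.quality, variants=g.variants), int(mask.to_numpy().sum())


def filter_samples_by_missingness(g: GenotypeMatrix, threshold: float = 0.30) -> tuple[GenotypeMatrix, dict]:
    """Drop samples with missing fraction strictly greater than ``threshold``."""
    if g.n_variants == 0 or g.n_samples == 0:
        return g, {}
    frac = g.calls.isna().mean(axis=1)
    dropped = {sid: "sample_missingness" for sid in frac.index[frac > threshold]}
    keep = [s for s in g.sample_ids if s not in dropped]
    return g.subset(samples=keep), dropped


def filter_variants_by_missingness(g: GenotypeMatrix, threshold: float = 0.20) -> tuple[GenotypeMatrix, dict]:
    """Drop variants with missing fraction strictly greater than ``threshold``."""
    if g.n_variants == 0 or g.n_samples == 0:
        return g, {}
    frac = g.calls.isna().mean(axis=0)
    dropped = {vid: "variant_missingness" for vid in frac.index[frac > threshold]}
    keep = [v for v in g.variant_ids if v not in dropped]
    return g.subset(variants=keep), dropped


def drop_monomorphic(g: GenotypeMatrix) -> tuple[GenotypeMatrix, dict]:
    """Drop variants whose non-missing calls are all identical (or all missing)."""
    dropped: dict[str, str] = {}
    for vid in g.variant_ids:
        vals = g.calls[vid].dropna().unique()
        if len(vals) == 0:
            dropped[vid] = "all_missing"
        elif len(vals) == 1:
            dropped[vid] = "monomorphic"
    keep = [v for v in g.variant_ids if v not in dropped]
    return g.subset(variants=keep), dropped


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional HWE test on genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one (the
    standard exact formulation for biallelic markers).
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise DomainError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise DomainError("at least one genotype is required")
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(h) up to a constant: n! / (h! ((nr-h)/2)! (n-(nr+h)/2)!) * 2^h
    rare_hom = (n_rare - hets) // 2
    common_hom = n - rare_hom - hets
    logp = hets * np.log(2.0) - gammaln(hets + 1) - gammaln(rare_hom + 1) - gammaln(common_hom + 1)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-9)].sum()))


def hwe_genotype_counts(calls: pd.Series) -> tuple[int, int, int]:
    """(hom-major, het, hom-minor) counts from a minor-dosage call vector."""
    v = calls.dropna().to_numpy()
    return int((v == 0).sum()), int((v == 1).sum()), int((v == 2).sum())


# ---------------------------------------------------------------------------
# relatedness and trios


def select_unrelated(samples: Sequence[SampleRecord]) -> list[str]:
    """Deterministically keep at most one member per family.

    Samples sharing a parent id, or linked parent/child within the set, are
    clustered; the lexicographically smallest sample id in each cluster is
    retained.  Singletons are always retained.
    """
    ids = [s.sample_id for s in samples]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    present = set(ids)
    by_parent: dict[str, list[str]] = {}
    for s in samples:
        for link in (s.father_id, s.mother_id):
            if link is None:
                continue
            if link in present:
                union(s.sample_id, link)
            by_parent.setdefault(link, []).append(s.sample_id)
    for sibs in by_parent.values():
        for other in sibs[1:]:
            union(sibs[0], other)
    clusters: dict[str, list[str]] = {}
    for i in ids:
        clusters.setdefault(find(i), []).append(i)
    return sorted(min(members) for members in clusters.values())


def mendelian_trio_check(child: float, father: float, mother: float) -> str:
    """Classify a trio of minor-dosage calls.

    Returns "untestable" if any member is missing, "inconsistent" if no pair
    of transmitted parental alleles can produce the child call, else
    "consistent".
    """
    vals = (child, father, mother)
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        return "untestable"
    child, father, mother = (int(v) for v in vals)
    transmissible = {0: {0}, 1: {0, 1}, 2: {1}}
    possible = {a + b for a in transmissible[father] for b in transmissible[mother]}
    return "consistent" if child in possible else "inconsistent"


# ---------------------------------------------------------------------------
# allele frequency and coding


@dataclass(frozen=True)
class MafResult:
    maf: float
    folded: bool  # True when the coded allele is actually the major one


def compute_maf(calls) -> MafResult:
    """Minor allele frequency from a dosage vector, folded to <= 0.5."""
    v = pd.Series(calls).dropna().to_numpy(dtype=float)
    if v.size == 0:
        raise DomainError("all calls missing; MAF undefined")
    freq = v.sum() / (2.0 * v.size)
    if freq > 0.5:
        return MafResult(maf=1.0 - freq, folded=True)
    return MafResult(maf=freq, folded=False)


def code_additive(calls: pd.Series) -> pd.Series:
    """Additive coding: the number of minor alleles (identity on dosage)."""
    return calls.astype(float)


def code_dominant(calls: pd.Series) -> pd.Series:
    """Dominant coding: presence (1) or absence (0) of the minor allele."""
    return (calls >= 1).astype(float).mask(calls.isna())


def collapse_rare_variants(
    g: GenotypeMatrix,
    tiles: TileMap,
    rare_ids: Sequence[str],
    mode: str = "presence",
) -> pd.DataFrame:
    """Collapse rare variants into one column per tile.

    ``mode="presence"`` (default): per sample and tile, the proportion of
    non-missing rare sites at which the sample carries at least one minor
    allele.  ``mode="allele_fraction"``: minor-allele count over twice the
    non-missing rare sites.  Tiles with no rare variant produce no column;
    a sample missing at every rare site in a tile is missing.
    """
    if mode not in ("presence", "allele_fraction"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    if g.variants is None:
        raise DomainError("collapsing requires variant positions")
    cols = {}
    tile_of = {
        vid: tiles.assign(str(g.variants.at[vid, "chrom"]), int(g.variants.at[vid, "pos"]))
        for vid in rare_ids
    }
    for tile_id in sorted(set(tile_of.values())):
        vids = [v for v in rare_ids if tile_of[v] == tile_id]
        sub = g.calls[vids]
        n_obs = sub.notna().sum(axis=1)
        if mode == "presence":
            num = (sub >= 1).sum(axis=1)
            val = num / n_obs
        else:
            val = sub.sum(axis=1) / (2.0 * n_obs)
        cols[f"tile{tile_id}_collapsed"] = val.mask(n_obs == 0)
    return pd.DataFrame(cols, index=g.calls.index)


# ---------------------------------------------------------------------------
# estimators


class GenotypeQC(BaseEstimator, TransformerMixin):
    """QC transformer: mask -> sample filter -> variant filter -> monomorphic drop.

    HWE is tested on the unrelated subset (one member per family) and
    failures at ``hwe_alpha`` are flagged in the report, never removed.

    Parameters
    ----------
    quality_threshold : calls with quality below this are masked (default 99).
    sample_missingness : samples with a greater missing fraction are dropped.
    variant_missingness : variants with a greater missing fraction are dropped.
    hwe_alpha : flag threshold for the exact HWE p-value.
    """

    def __init__(self, quality_threshold: float = 99.0, sample_missingness: float = 0.30,
                 variant_missingness: float = 0.20, hwe_alpha: float = 0.03):
        self.quality_threshold = quality_threshold
        self.sample_missingness = sample_missingness
        self.variant_missingness = variant_missingness
        self.hwe_alpha = hwe_alpha

    def fit(self, g: GenotypeMatrix, samples: Sequence[SampleRecord] | None = None):
        self.filtered_, self.report_ = self._run(g, samples)
        return self

    def transform(self, g: GenotypeMatrix, samples: Sequence[SampleRecord] | None = None) -> GenotypeMatrix:
        filtered, _ = self._run(g, samples)
        return filtered

    def fit_transform(self, g, samples=None, **kw):  # noqa: D102 - sklearn signature
        return self.fit(g, samples=samples).filtered_

    def _run(self, g: GenotypeMatrix, samples) -> tuple[GenotypeMatrix, QCReport]:
        report = QCReport()
        g, report.masked_calls = mask_low_quality_calls(g, self.quality_threshold)
        g, ex_s = filter_samples_by_missingness(g, self.sample_missingness)
        report.excluded_samples.update(ex_s)
        g, ex_v = filter_variants_by_missingness(g, self.variant_missingness)
        report.excluded_variants.update(ex_v)
        g, ex_m = drop_monomorphic(g)
        report.excluded_variants.update(ex_m)
        if samples is not None:
            retained = {s.sample_id for s in samples} & set(g.sample_ids)
            unrelated = select_unrelated([s for s in samples if s.sample_id in retained])
        else:
            unrelated = g.sample_ids
        sub = g.calls.loc[[s for s in unrelated if s in g.calls.index]]
        for vid in g.variant_ids:
            counts = hwe_genotype_counts(sub[vid])
            if sum(counts) == 0:
                continue
            p = hwe_exact_test(*counts)
            if p < self.hwe_alpha:
                report.hwe_flags[vid] = p
        report.retained_dimensions = (g.n_samples, g.n_variants)
        self.unrelated_ = unrelated
        return g, report


class VariantCoder(BaseEstimator, TransformerMixin):
    """Code a QC'd genotype matrix under one of three schemes.

    add: minor-allele count for every variant; dom: minor-allele presence
    for every variant; add_collapsed: minor-allele count for common variants
    plus one collapsed column per tile for the rare ones (MAF < 0.05,
    computed on the analysis cohort after QC).
    """

    def __init__(self, scheme: str = "add", tiles: TileMap | None = None,
                 rare_threshold: float = RARE_MAF_THRESHOLD, collapse_mode: str = "presence"):
        self.scheme = scheme
        self.tiles = tiles
        self.rare_threshold = rare_threshold
        self.collapse_mode = collapse_mode

    def fit(self, g: GenotypeMatrix, y=None):
        self.maf_ = pd.Series({vid: compute_maf(g.calls[vid]).maf for vid in g.variant_ids})
        self.rare_ids_ = [v for v in g.variant_ids if self.maf_[v] < self.rare_threshold]
        self.common_ids_ = [v for v in g.variant_ids if v not in set(self.rare_ids_)]
        return self

    def transform(self, g: GenotypeMatrix) -> pd.DataFrame:
        if self.scheme not in ("add", "dom", "add_collapsed"):
            raise ValueError(f"unknown coding scheme {self.scheme!r}")
        if self.scheme == "add":
            coded = g.calls.astype(float).copy()
        elif self.scheme == "dom":
            coded = pd.DataFrame({v: code_dominant(g.calls[v]) for v in g.variant_ids},
                                 index=g.calls.index)
        else:
            if self.tiles is None:
                raise DomainError("add_collapsed coding requires a tile map")
            common = g.calls[self.common_ids_].astype(float)
            collapsed = collapse_rare_variants(g, self.tiles, self.rare_ids_, mode=self.collapse_mode)
            coded = pd.concat([common, collapsed], axis=1)
        self.column_tiles_ = self._column_tiles(g, coded)
        self.column_positions_ = self._column_positions(g, coded)
        return coded

    def _column_tiles(self, g: GenotypeMatrix, coded: pd.DataFrame) -> dict:
        if self.tiles is None or g.variants is None:
            return {}
        out = {}
        for col in coded.columns:
            if col in g.variants.index:
                out[col] = self.tiles.assign(str(g.variants.at[col, "chrom"]), int(g.variants.at[col, "pos"]))
            else:  # collapsed column named tile<k>_collapsed
                out[col] = int(str(col).removeprefix("tile").split("_")[0])
        return out

    def _column_positions(self, g: GenotypeMatrix, coded: pd.DataFrame) -> dict:
        out = {}
        for col in coded.columns:
            if g.variants is not None and col in g.variants.index:
                out[col] = (str(g.variants.at[col, "chrom"]), int(g.variants.at[col, "pos"]))
            elif self.tiles is not None:
                k = int(str(col).removeprefix("tile").split("_")[0])
                row = self.tiles.tiles.loc[k]
                out[col] = (str(row["chrom"]), int(row["start"]) + 1)
            else:
                out[col] = ("", 0)
        return out


def qc_genotypes(g: GenotypeMatrix, samples: Sequence[SampleRecord] | None = None,
                 **params) -> tuple[GenotypeMatrix, QCReport]:
    """Functional wrapper around :class:`GenotypeQC`."""
    est = GenotypeQC(**params).fit(g, samples=samples)
    return est.filtered_, est.report_
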