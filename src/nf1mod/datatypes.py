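"""Core domain types shared by every stage of the pipeline.

The analysis revolves around three cohorts of NF1 patients (a discovery
cohort and two replication cohorts), a count-valued quantitative trait
(number of cafe-au-lait macules, CALM), a samples-by-variants genotype
matrix with per-call quality scores, and a partition of the candidate
region into "tiles" bounded by recombination hotspots.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: MAF below which a variant is classed as rare (and eligible for collapsing).
RARE_MAF_THRESHOLD = 0.05

#: Sex coding used in every design matrix: female=0, male=1.
SEX_CODE = {"female": 0.0, "male": 1.0}


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class DomainError(ValueError):
    """An argument is outside the mathematical domain of an operation."""


class SampleMismatchError(ValueError):
    """Genotype and phenotype files describe different sample sets."""


class InfeasibleLDError(ValueError):
    """A requested (MAF, correlation) combination violates the Frechet bound."""


@dataclass(frozen=True)
class SampleRecord:
    """One study participant."""

    sample_id: str
    age: float
    sex: str
    cohort: str
    father_id: str | None = None
    mother_id: str | None = None
    ancestry: str = "EA"

    def __post_init__(self) -> None:
        if not (self.age >= 0):
            raise DomainError(f"age must be >= 0, got {self.age!r} for {self.sample_id}")
        if self.sex not in SEX_CODE:
            raise FormatError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant with its data-determined minor allele."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    minor_allele: str
    maf: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5):
            raise DomainError(f"maf must lie in [0, 0.5], got {self.maf}")

    @property
    def rarity_class(self) -> str:
        return "rare" if self.maf < RARE_MAF_THRESHOLD else "common"


def transform_trait(raw):
    """log10(x + 10) transform of a nonnegative count trait.

    Strictly increasing; maps 0 to exactly 1.  Accepts scalars or arrays;
    NaN (missing) propagates.
    """
    arr = np.asarray(raw, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise DomainError("trait values must be nonnegative")
    out = np.log10(arr + 10.0)
    if np.isscalar(raw) or arr.ndim == 0:
        return float(out)
    return out


@dataclass
class GenotypeMatrix:
    """Samples x variants minor-allele dosage calls with per-call quality.

    ``calls`` is a float DataFrame (rows = sample ids, columns = variant
    ids) with values in {0, 1, 2} and NaN for missing.  ``quality`` is an
    equally shaped DataFrame of nonnegative per-call scores (NaN = not
    scored).  ``variants`` carries per-variant metadata indexed by variant
    id with at least columns chrom, pos, ref, alt.
    """

    calls: pd.DataFrame
    quality: pd.DataFrame | None = None
    variants: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise FormatError(
                f"call at sample {self.calls.index[bad[0]]!r}, variant "
                f"{self.calls.columns[bad[1]]!r} is not in {{0,1,2,missing}}"
            )
        if self.quality is not None and self.quality.shape != self.calls.shape:
            raise FormatError("quality matrix shape differs from calls")
        if self.variants is not None and not self.variants.index.equals(self.calls.columns):
            raise FormatError("variant metadata index differs from call columns")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def subset(self, samples=None, variants=None) -> "GenotypeMatrix":
        calls = self.calls
        quality = self.quality
        var = self.variants
        if samples is not None:
            calls = calls.loc[list(samples)]
            quality = None if quality is None else quality.loc[list(samples)]
        if variants is not None:
            calls = calls[list(variants)]
            quality = None if quality is None else quality[list(variants)]
            var = None if var is None else var.loc[list(variants)]
        return GenotypeMatrix(calls=calls.copy(), quality=None if quality is None else quality.copy(),
                              variants=None if var is None else var.copy())


@dataclass
class TileMap:
    """Ordered, non-overlapping half-open genomic intervals covering each chromosome.

    Tiles are derived from recombination-hotspot intervals: boundaries sit at
    hotspot midpoints so every base (including bases inside a hotspot) belongs
    to exactly one tile.  Coordinates are 0-based half-open.
    """

    tiles: pd.DataFrame  # columns: chrom, start, end; RangeIndex = tile id
    source: pd.DataFrame | None = None  # the hotspot intervals used

    @classmethod
    def from_hotspots(cls, hotspots: pd.DataFrame, chrom_lengths: dict[str, float] | None = None) -> "TileMap":
        """Build tiles from 0-based half-open hotspot intervals.

        ``k`` hotspots on one chromosome yield ``k + 1`` tiles.  Chromosome
        ends bound the first and last tile; if a length is not supplied the
        last tile is open-ended (+inf).
        """
        chrom_lengths = dict(chrom_lengths or {})
        hotspots = hotspots.copy()
        rows = []
        chroms = list(dict.fromkeys(hotspots["chrom"])) if len(hotspots) else []
        for c in chrom_lengths:
            if c not in chroms:
                chroms.append(c)
        for chrom in chroms:
            sub = hotspots[hotspots["chrom"] == chrom].sort_values("start") if len(hotspots) else hotspots
            starts = sub["start"].to_numpy() if len(sub) else np.array([])
            ends = sub["end"].to_numpy() if len(sub) else np.array([])
            if len(starts) and np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"overlapping hotspot intervals on {chrom}")
            mids = ((starts + ends) // 2).astype(float)
            bounds = np.concatenate([[0.0], mids, [chrom_lengths.get(chrom, np.inf)]])
            for s, e in zip(bounds[:-1], bounds[1:]):
                rows.append({"chrom": chrom, "start": s, "end": e})
        tiles = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return cls(tiles=tiles, source=hotspots)

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def assign(self, chrom: str, pos: int) -> int:
        """Tile id of a 1-based variant position (maps to exactly one tile)."""
        sub = self.tiles[self.tiles["chrom"] == chrom]
        if sub.empty:
            raise DomainError(f"no tiles on chromosome {chrom!r}")
        zero_based = pos - 1
        hit = sub[(sub["start"] <= zero_based) & (zero_based < sub["end"])]
        if hit.empty:
            raise DomainError(f"position {chrom}:{pos} falls outside every tile")
        return int(hit.index[0])

    def assign_positions(self, chroms: Sequence[str], positions: Sequence[int]) -> np.ndarray:
        return np.array([self.assign(c, p) for c, p in zip(chroms, positions)], dtype=int)


@dataclass(frozen=True)
class AssociationResult:
    """Per-variant (or per-region/transcript) regression result."""

    target_id: str
    model: str
    beta: float
    se: float
    p_value: float
    n_used: int
    reason: str | None = None  # set when the fit was not possible


@dataclass(frozen=True)
class MetaResult:
    """Liptak (weighted-Z) combination of per-cohort p-values."""

    target_id: str
    model: str
    cohort_p_values: tuple
    cohort_sizes: tuple
    combined_z: float
    combined_p: float

    def __post_init__(self) -> None:
        if len(self.cohort_p_values) != len(self.cohort_sizes):
            raise FormatError("cohort p-value and size lists differ in length")


@dataclass(frozen=True)
class TranscriptSummary:
    """Per-transcript output of the expression-phenotype screen."""

    transcript_id: str
    mean_level: float
    level_range: float
    slope: float
    p_value: float
    fdr_q: float
    candidate_flag: str  # pass | fail | rescued


@dataclass
class QCReport:
    """Machine-readable record of every QC exclusion and flag."""

    excluded_samples: dict = field(default_factory=dict)   # id -> reason code
    excluded_variants: dict = field(default_factory=dict)  # id -> reason code
    masked_calls: int = 0
    hwe_flags: dict = field(default_factory=dict)          # variant id -> exact p
    retained_dimensions: tuple = (0, 0)

    def to_dict(self) -> dict:
        return {
            "excluded_samples": self.excluded_samples,
            "excluded_variants": self.excluded_variants,
            "masked_calls": self.masked_calls,
            "hwe_flags": self.hwe_flags,
            "retained_dimensions": list(self.retained_dimensions),
        }
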