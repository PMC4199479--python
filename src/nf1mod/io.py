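"""Readers and writers for the pipeline's file formats.

Formats: phenotype/covariate TSV, genotype TSV ("dosage:quality" cells) and
a minimal VCF subset (GT, optional GQ), hotspot BED (0-based half-open),
and results TSV.  Every reader/writer pair round-trips.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AssociationResult,
    FormatError,
    GenotypeMatrix,
    MetaResult,
    SampleMismatchError,
    SampleRecord,
    TileMap,
)

log = logging.getLogger(__name__)

_PHENO_REQUIRED = ("sample_id", "age", "sex", "cohort")
_PHENO_RESERVED = set(_PHENO_REQUIRED) | {"father_id", "mother_id", "ancestry"}


# ---------------------------------------------------------------------------
# phenotype table

def read_phenotype_table(path) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Read a phenotype/covariate TSV.

    Returns one :class:`SampleRecord` per row plus the full table indexed by
    sample id (trait columns numeric, empty cells -> NaN).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in _PHENO_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"phenotype table is missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicated sample_id {dup!r} in phenotype table")
    ages = pd.to_numeric(df["age"], errors="coerce")
    bad = ages.isna() & df["age"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise FormatError(f"non-numeric age {df['age'].iloc[row]!r} on line {row + 2}")
    df["age"] = ages

    records = []
    for _, r in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(r["sample_id"]),
                age=float(r["age"]),
                sex=str(r["sex"]),
                cohort=str(r["cohort"]),
                father_id=_opt(r.get("father_id")),
                mother_id=_opt(r.get("mother_id")),
                ancestry=str(r["ancestry"]) if _opt(r.get("ancestry")) else "EA",
            )
        )
    table = df.set_index("sample_id")
    for col in table.columns:
        if col not in _PHENO_RESERVED:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    # trio links must reference existing samples
    ids = set(table.index)
    for rec in records:
        for link in (rec.father_id, rec.mother_id):
            if link is not None and link not in ids:
                log.warning("sample %s links parent %s absent from the table", rec.sample_id, link)
    return records, table


def _opt(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or (isinstance(v, str) and not v):
        return None
    return str(v)


def write_phenotype_table(table: pd.DataFrame, path) -> None:
    """Inverse of :func:`read_phenotype_table` (table indexed by sample_id)."""
    table.to_csv(path, sep="\t", index=True, index_label="sample_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes(path, dialect: str = "tsv", phenotype: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from the TSV dialect or a minimal VCF.

    TSV: rows = variants, columns = samples, cells "dosage:quality" with "."
    for missing.  VCF: GT parsed to alt dosage then folded so calls count the
    data-determined minor allele; GQ (if present) becomes the quality score.

    When ``phenotype`` (a table indexed by sample id) is given, the sample
    sets must agree exactly and rows are reordered to the phenotype order.
    """
    if dialect == "tsv":
        g = _read_genotypes_tsv(path)
    elif dialect == "vcf":
        g = _read_genotypes_vcf(path)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    if phenotype is not None:
        want = list(phenotype.index)
        have = set(g.sample_ids)
        if have != set(want):
            missing = sorted(set(want) - have)
            extra = sorted(have - set(want))
            raise SampleMismatchError(
                f"sample sets differ: missing from genotypes {missing}, unknown to phenotypes {extra}"
            )
        g = g.subset(samples=want)
    return g


def _read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = ["variant_id", "chrom", "pos", "ref", "alt"]
    for col in meta_cols:
        if col not in df.columns:
            raise FormatError(f"genotype TSV is missing required column {col!r}")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    n_var = len(df)
    calls = np.full((len(sample_ids), n_var), np.nan)
    qual = np.full((len(sample_ids), n_var), np.nan)
    for j in range(n_var):
        for i, sid in enumerate(sample_ids):
            cell = df[sid].iloc[j]
            if cell == "." or (isinstance(cell, float) and np.isnan(cell)):
                continue
            try:
                d, q = str(cell).split(":")
                calls[i, j] = float(d)
                qual[i, j] = float(q)
            except Exception as exc:
                raise FormatError(
                    f"malformed cell {cell!r} at variant {df['variant_id'].iloc[j]!r}, sample {sid!r}"
                ) from exc
    calls = _fold_to_minor(calls)
    variants = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str).to_numpy(),
            "pos": df["pos"].astype(int).to_numpy(),
            "ref": df["ref"].to_numpy(),
            "alt": df["alt"].to_numpy(),
        },
        index=pd.Index(df["variant_id"], name="variant_id"),
    )
    return GenotypeMatrix(
        calls=pd.DataFrame(calls, index=sample_ids, columns=variants.index),
        quality=pd.DataFrame(qual, index=sample_ids, columns=variants.index),
        variants=variants,
    )


def _fold_to_minor(calls: np.ndarray) -> np.ndarray:
    """Flip dosage columns whose coded-allele frequency exceeds 0.5.

    Readers normalize once so that every column counts the data-determined
    minor allele; a second read of the written matrix is then a fixed point.
    """
    calls = calls.copy()
    for j in range(calls.shape[1]):
        col = calls[:, j]
        obs = col[~np.isnan(col)]
        if obs.size and obs.mean() / 2.0 > 0.5:
            calls[:, j] = np.where(np.isnan(col), np.nan, 2.0 - col)
    return calls


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows_calls, rows_qual, meta, vids = [], [], [], []
    for v in vcf:
        gts = v.genotypes  # [[a0, a1, phased], ...]
        dose = np.array(
            [np.nan if (g[0] < 0 or g[1] < 0) else float(g[0] > 0) + float(g[1] > 0) for g in gts]
        )
        try:
            gq = np.asarray(v.format("GQ"), dtype=float).reshape(-1)
            gq = np.where(gq < 0, np.nan, gq)  # '.' round-trips as INT_MIN
        except Exception:
            gq = np.full(len(sample_ids), np.nan)
        gq = np.where(np.isnan(dose), np.nan, gq)
        # fold to the minor allele determined from the data
        nonmiss = dose[~np.isnan(dose)]
        if nonmiss.size and nonmiss.mean() / 2.0 > 0.5:
            dose = 2.0 - dose
        rows_calls.append(dose)
        rows_qual.append(gq)
        vids.append(v.ID or f"{v.CHROM}:{v.POS}")
        meta.append({"chrom": str(v.CHROM), "pos": int(v.POS), "ref": v.REF, "alt": v.ALT[0] if v.ALT else "."})
    variants = pd.DataFrame(meta, index=pd.Index(vids, name="variant_id"))
    calls = pd.DataFrame(np.array(rows_calls).T, index=sample_ids, columns=variants.index)
    qual = pd.DataFrame(np.array(rows_qual).T, index=sample_ids, columns=variants.index)
    return GenotypeMatrix(calls=calls, quality=qual, variants=variants)


def write_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    """Inverse of the TSV genotype reader."""
    if g.variants is None or g.quality is None:
        raise FormatError("writing the TSV dialect requires variant metadata and qualities")
    with open(path, "w") as fh:
        fh.write("\t".join(["variant_id", "chrom", "pos", "ref", "alt"] + g.sample_ids) + "\n")
        for vid in g.variant_ids:
            m = g.variants.loc[vid]
            cells = []
            for sid in g.sample_ids:
                d = g.calls.at[sid, vid]
                if np.isnan(d):
                    cells.append(".")
                else:
                    q = g.quality.at[sid, vid]
                    qs = "%g" % q if not np.isnan(q) else "0"
                    cells.append(f"{int(d)}:{qs}")
            fh.write("\t".join([str(vid), str(m['chrom']), str(int(m['pos'])), str(m['ref']), str(m['alt'])] + cells) + "\n")


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT:GQ) rendering of the matrix.

    Calls are emitted with ALT as the coded (minor) allele, so reading the
    file back yields the same dosages as the TSV rendering whenever the
    coded allele is indeed the minor one.
    """
    if g.variants is None:
        raise FormatError("writing VCF requires variant metadata")
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(g.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.sample_ids) + "\n")
        for vid in g.variant_ids:
            m = g.variants.loc[vid]
            cells = []
            for sid in g.sample_ids:
                d = g.calls.at[sid, vid]
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    q = 0 if g.quality is None or np.isnan(g.quality.at[sid, vid]) else int(round(g.quality.at[sid, vid]))
                    cells.append(f"{gt_of[int(d)]}:{q}")
            fh.write(
                f"{m['chrom']}\t{int(m['pos'])}\t{vid}\t{m['ref']}\t{m['alt']}\t.\tPASS\t.\tGT:GQ\t"
                + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# hotspots / tiles

def read_hotspots(path, chrom_lengths: dict[str, float] | None = None) -> TileMap:
    """Read a BED of recombination-hotspot intervals and build the tile map.

    Unsorted input is sorted with a logged notice; overlapping hotspots are
    an error.
    """
    bed = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"])
    bed["chrom"] = bed["chrom"].astype(str)
    for chrom, sub in bed.groupby("chrom"):
        if not sub["start"].is_monotonic_increasing:
            log.info("hotspot intervals on %s are unsorted; sorting", chrom)
    bed = bed.sort_values(["chrom", "start"]).reset_index(drop=True)
    return TileMap.from_hotspots(bed, chrom_lengths=chrom_lengths)


def write_hotspots(bed: pd.DataFrame, path) -> None:
    bed[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# results

_ASSOC_COLS = ["target_id", "model", "beta", "se", "p", "n"]
_META_COLS = ["target_id", "model", "combined_z", "combined_p"]


def write_results(results: Sequence, path) -> None:
    """Write a homogeneous list of association or meta results as TSV."""
    kinds = {type(r) for r in results}
    if len(kinds) > 1:
        raise FormatError(f"mixed result types {sorted(k.__name__ for k in kinds)}")
    kind = kinds.pop() if kinds else AssociationResult
    with open(path, "w") as fh:
        if kind is MetaResult:
            fh.write("\t".join(_META_COLS) + "\n")
            for r in results:
                fh.write(f"{r.target_id}\t{r.model}\t{_f(r.combined_z)}\t{_f(r.combined_p)}\n")
        else:
            fh.write("\t".join(_ASSOC_COLS) + "\n")
            for r in results:
                fh.write(f"{r.target_id}\t{r.model}\t{_f(r.beta)}\t{_f(r.se)}\t{_f(r.p_value)}\t{r.n_used}\n")


def _f(x: float) -> str:
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else "%.6g" % x


def read_results(path) -> list:
    """Inverse of :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    out = []
    if "combined_p" in df.columns:
        for _, r in df.iterrows():
            out.append(MetaResult(str(r["target_id"]), str(r["model"]), (), (),
                                  float(r["combined_z"]), float(r["combined_p"])))
    else:
        for _, r in df.iterrows():
            out.append(AssociationResult(str(r["target_id"]), str(r["model"]), float(r["beta"]),
                                         float(r["se"]), float(r["p"]), int(r["n"])))
    return out
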