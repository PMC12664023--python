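"""Canonical in-memory data model and standard-format I/O.

Genotypes live in a :class:`GenotypeMatrix`: an individuals x SNPs dosage
matrix (count of the per-SNP "counted" allele, 0/1/2, NaN for missing)
plus per-SNP metadata.  The counted allele is allele1 of the MAP/PED pair
as first encountered; minor-allele frequency is computed downstream, so
allele orientation does not affect r², the GRM, or regression p-values
(effect signs flip with orientation).

Coordinates are 1-based inclusive everywhere inside the package;
conversions happen only at the I/O boundary (BED is 0-based half-open
on disk).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SampleTable",
    "IntervalTable",
    "read_plink_text",
    "write_plink_text",
    "read_intervals",
    "read_sample_table",
    "write_sample_table",
]

#: Sex-chromosome labels for chicken (Gallus gallus).
DEFAULT_SEX_LABELS = frozenset({"Z", "W"})

SNP_INFO_COLUMNS = ["snp_id", "chrom", "pos", "allele1", "allele2"]


@dataclasses.dataclass
class GenotypeMatrix:
    """Dosage matrix with SNP metadata.

    Parameters
    ----------
    dosages
        float array of shape (n_individuals, n_snps) holding counts of
        allele1 in {0, 1, 2}; missing calls are NaN.
    snp_info
        DataFrame with columns snp_id, chrom (str), pos (1-based bp),
        allele1, allele2.
    sample_ids
        Ordered individual identifiers.
    """

    dosages: np.ndarray
    snp_info: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        self.snp_info = pd.DataFrame(self.snp_info).reset_index(drop=True)
        missing_cols = set(SNP_INFO_COLUMNS) - set(self.snp_info.columns)
        if missing_cols:
            raise ValueError(f"snp_info lacks columns: {sorted(missing_cols)}")
        self.snp_info["chrom"] = self.snp_info["chrom"].astype(str)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.snp_info) != m:
            raise ValueError(f"{len(self.snp_info)} SNP records for {m} columns")
        if self.snp_info["snp_id"].duplicated().any():
            dupes = self.snp_info.loc[self.snp_info["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate SNP ids: {list(dupes[:5])}")
        if (self.snp_info["pos"].to_numpy() < 0).any():
            raise ValueError("negative SNP positions")
        with np.errstate(invalid="ignore"):
            bad = np.logical_and(~np.isnan(self.dosages), ~np.isin(self.dosages, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Frequency of allele1 per SNP over non-missing calls (NaN if none)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subset_snps(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            snp_info=self.snp_info.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def subset_individuals(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            snp_info=self.snp_info,
            sample_ids=[self.sample_ids[i] for i in idx],
        )


class SampleTable(pd.DataFrame):
    """Phenotype/fixed-effect table: sample_id, pen, rearing_pen, kbf_score, log_kbf.

    A thin DataFrame subclass so standard pandas operations keep working;
    :meth:`validate` enforces the invariants (scores in [0, 10], factors
    non-missing).
    """

    _metadata: list[str] = []
    REQUIRED = ["sample_id", "pen", "rearing_pen", "kbf_score"]

    @property
    def _constructor(self):
        return SampleTable

    @classmethod
    def from_records_checked(cls, df: pd.DataFrame) -> "SampleTable":
        out = cls(pd.DataFrame(df).copy())
        out.validate()
        return out

    def validate(self) -> None:
        missing = set(self.REQUIRED) - set(self.columns)
        if missing:
            raise ValueError(f"sample table lacks columns: {sorted(missing)}")
        score = pd.to_numeric(self["kbf_score"], errors="raise")
        if ((score < 0) | (score > 10)).any():
            raise ValueError("kbf_score outside [0, 10]")


@dataclasses.dataclass
class Interval:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    name: str
    strand: str  # "+", "-" or "unknown"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError("negative coordinates")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end} for {self.name}")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclasses.dataclass
class IntervalTable:
    """Genomic features (genes/QTL) as 1-based inclusive intervals."""

    records: list[Interval]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.chrom, r.start, r.end, r.name, r.strand) for r in self.records],
            columns=["chrom", "start", "end", "name", "strand"],
        )


# ---------------------------------------------------------------------------
# PLINK text dialect


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK PED/MAP text files into a GenotypeMatrix.

    The counted allele of each SNP is allele1 of the MAP/PED pair as
    encountered: with a plain 4-column MAP that is the first non-missing
    allele seen in the PED column pair; a 6-column MAP (the dialect
    :func:`write_plink_text` emits) names the counted/other allele
    explicitly in columns 5-6, which makes round trips lossless even
    when a SNP's first call is homozygous for the other allele.
    "0 0" is a missing call.  Chromosome labels are kept verbatim
    (including "0" for unmapped).
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    snp_rows = []
    map_alleles: list[tuple[str, str] | None] = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"{map_path}:{lineno}: expected >=4 MAP fields, got {len(fields)}")
        chrom, snp_id = fields[0], fields[1]
        try:
            pos = int(fields[3])
        except ValueError as exc:
            raise ValueError(f"{map_path}:{lineno}: bad bp position {fields[3]!r}") from exc
        snp_rows.append((snp_id, chrom, pos))
        map_alleles.append((fields[4], fields[5]) if len(fields) >= 6 else None)
    m = len(snp_rows)

    sample_ids: list[str] = []
    allele1 = np.array([a[0] if a else "" for a in map_alleles], dtype=object)
    allele2 = np.array([a[1] if a else "" for a in map_alleles], dtype=object)
    parsed = []  # (lineno, a, b) per individual; dosages resolved once alleles are known
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * m:
            raise ValueError(
                f"{ped_path}:{lineno}: expected {6 + 2 * m} fields for {m} MAP SNPs, got {len(fields)}"
            )
        sample_ids.append(fields[1])
        a = np.array(fields[6::2], dtype=object)
        b = np.array(fields[7::2], dtype=object)
        miss = (a == "0") & (b == "0")
        if ((a == "0") ^ (b == "0")).any():
            j = int(np.flatnonzero((a == "0") ^ (b == "0"))[0])
            raise ValueError(f"{ped_path}:{lineno}: half-missing genotype at SNP {j + 1}")
        # first-encountered convention for SNPs the MAP left unoriented
        need1 = (allele1 == "") & ~miss
        allele1[need1] = a[need1]
        need2 = (allele2 == "") & ~miss
        pick_a = need2 & (a != allele1)
        allele2[pick_a] = a[pick_a]
        pick_b = need2 & ~pick_a & (b != allele1)
        allele2[pick_b] = b[pick_b]
        bad = ~miss & (((a != allele1) & (a != allele2)) | ((b != allele1) & (b != allele2)))
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise ValueError(f"{ped_path}:{lineno}: unexpected allele at SNP {j + 1}")
        parsed.append((a, b, miss))

    dosage_rows = []
    for a, b, miss in parsed:
        row = (a == allele1).astype(float) + (b == allele1).astype(float)
        row[miss] = np.nan
        dosage_rows.append(row)
    allele1 = [x if x else None for x in allele1]
    allele2 = [x if x else None for x in allele2]

    snp_info = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"])
    snp_info["allele1"] = [a if a is not None else "A" for a in allele1]
    snp_info["allele2"] = [
        b if b is not None else ("B" if a != "B" else "A") for a, b in zip(snp_info["allele1"], allele2)
    ]
    dosages = np.array(dosage_rows, dtype=float) if dosage_rows else np.empty((0, m))
    return GenotypeMatrix(dosages=dosages, snp_info=snp_info, sample_ids=sample_ids)


def write_plink_text(geno: GenotypeMatrix, ped_path, map_path) -> tuple[Path, Path]:
    """Write a GenotypeMatrix as PLINK PED/MAP text; inverse of read_plink_text.

    The MAP carries two extra columns naming the counted and other
    allele, so the dosage orientation survives the round trip.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    info = geno.snp_info
    with open(map_path, "w") as fh:
        for rec in info.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.snp_id}\t0\t{rec.pos}\t{rec.allele1}\t{rec.allele2}\n")
    a1 = info["allele1"].astype(str).to_numpy()
    a2 = info["allele2"].astype(str).to_numpy()
    # per-SNP genotype strings indexed by dosage code (0,1,2; 3 = missing)
    pair = np.empty((4, geno.n_snps), dtype=object)
    pair[0] = [f"{x} {x}" for x in a2]
    pair[1] = [f"{x} {y}" for x, y in zip(a1, a2)]
    pair[2] = [f"{x} {x}" for x in a1]
    pair[3] = "0 0"
    codes = np.where(np.isnan(geno.dosages), 3, geno.dosages).astype(int)
    cols = np.arange(geno.n_snps)
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(geno.sample_ids):
            fh.write(f"{sid} {sid} 0 0 0 -9 " + " ".join(pair[codes[i], cols]) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# Interval formats


def _gff3_name(attributes: str) -> str:
    attrs = {}
    for chunk in attributes.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            attrs[k.strip()] = v.strip()
    for key in ("Name", "gene_name", "gene_id", "ID"):
        if key in attrs:
            return attrs[key]
    return "."


def read_intervals(path, format: str) -> IntervalTable:
    """Read a BED (3+ column) or GFF3 feature file into an IntervalTable.

    BED's 0-based half-open coordinates become 1-based inclusive; GFF3 is
    already 1-based inclusive and is preserved.  Strand "." maps to
    "unknown".
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unrecognized interval format {format!r}")
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if fmt == "BED":
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom = fields[0]
            start0, end0 = int(fields[1]), int(fields[2])
            if start0 < 0 or end0 < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinates")
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            start, end = start0 + 1, end0
        else:
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom = fields[0]
            start, end = int(fields[3]), int(fields[4])
            if start < 0 or end < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinates")
            strand = fields[6]
            name = _gff3_name(fields[8])
        records.append(
            Interval(chrom=chrom, start=start, end=end, name=name, strand=strand if strand in ("+", "-") else "unknown")
        )
    return IntervalTable(records=records)


# ---------------------------------------------------------------------------
# Sample table TSV


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pen": str, "rearing_pen": str})
    return SampleTable.from_records_checked(df)


def write_sample_table(samples: pd.DataFrame, path) -> Path:
    path = Path(path)
    samples.to_csv(path, sep="\t", index=False)
    return path
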