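"""SNP-level quality control.

Filters, in reporting precedence (structural rules first, one count per
SNP): unmapped SNPs (chromosome "0"/missing or position 0), sex-chromosome
SNPs (chicken Z/W by default), call rate below the threshold (strict),
minor allele frequency below the threshold (strict; denominator is
non-missing calls), and SNPs heterozygous in every individual.  No
Hardy-Weinberg filter is applied: the target population is a two-way
cross, where HWE deviations are expected rather than artifacts.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from keelgen.dataio import DEFAULT_SEX_LABELS, GenotypeMatrix

__all__ = ["QcReport", "apply_qc"]


@dataclasses.dataclass
class QcReport:
    n_input_snps: int
    n_removed_unmapped: int
    n_removed_sexchrom: int
    n_removed_callrate: int
    n_removed_maf: int
    n_removed_allhet: int
    n_retained: int
    maf_min: float
    call_rate_min: float
    sex_labels: list[str]

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_unmapped
            + self.n_removed_sexchrom
            + self.n_removed_callrate
            + self.n_removed_maf
            + self.n_removed_allhet
        )
        if removed + self.n_retained != self.n_input_snps:
            raise ValueError("QC counts do not add up to the input SNP count")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def log_lines(self) -> list[str]:
        return [
            f"QC input SNPs: {self.n_input_snps}",
            f"  removed unmapped:            {self.n_removed_unmapped}",
            f"  removed sex chromosome:      {self.n_removed_sexchrom}",
            f"  removed call rate < {self.call_rate_min:g}:    {self.n_removed_callrate}",
            f"  removed MAF < {self.maf_min:g}:           {self.n_removed_maf}",
            f"  removed all-heterozygous:    {self.n_removed_allhet}",
            f"QC retained SNPs: {self.n_retained}",
        ]


def apply_qc(
    geno: GenotypeMatrix,
    maf_min: float = 0.02,
    call_rate_min: float = 0.90,
    sex_labels=DEFAULT_SEX_LABELS,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs; returns the retained matrix and a one-count-per-SNP report.

    Thresholds are strict: a SNP at exactly ``maf_min`` or exactly
    ``call_rate_min`` is retained.
    """
    sex_labels = {str(s) for s in sex_labels}
    chrom = geno.snp_info["chrom"].to_numpy()
    pos = geno.snp_info["pos"].to_numpy()
    d = geno.dosages

    unmapped = (chrom == "0") | (chrom == "") | (pos <= 0)
    sexchrom = np.isin(chrom, sorted(sex_labels)) & ~unmapped

    call_rate = geno.call_rate()
    low_call = (call_rate < call_rate_min) & ~unmapped & ~sexchrom

    maf = geno.maf()
    low_maf = (np.nan_to_num(maf, nan=0.0) < maf_min) & ~unmapped & ~sexchrom & ~low_call

    n_nonmiss = (~np.isnan(d)).sum(axis=0)
    n_het = np.nansum(d == 1, axis=0)
    all_het = (n_nonmiss > 0) & (n_het == n_nonmiss) & ~unmapped & ~sexchrom & ~low_call & ~low_maf

    keep = ~(unmapped | sexchrom | low_call | low_maf | all_het)
    report = QcReport(
        n_input_snps=geno.n_snps,
        n_removed_unmapped=int(unmapped.sum()),
        n_removed_sexchrom=int(sexchrom.sum()),
        n_removed_callrate=int(low_call.sum()),
        n_removed_maf=int(low_maf.sum()),
        n_removed_allhet=int(all_het.sum()),
        n_retained=int(keep.sum()),
        maf_min=maf_min,
        call_rate_min=call_rate_min,
        sex_labels=sorted(sex_labels),
    )
    if report.n_retained == 0:
        raise ValueError(f"no SNPs survive QC; report: {report.to_json()}")
    return geno.subset_snps(keep), report
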