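"""VanRaden method-1 genomic relationship matrix and PCA diagnostics.

G = Z Z' / sum_i 2 p_i (1 - p_i), where Z holds allele counts (0/1/2)
centered by 2 p_i and p_i is the counted-allele frequency estimated from
the sample itself.  Missing dosages are mean-imputed to 2 p_i before
centering, which preserves the zero-column-sum identity of Z (and hence
a zero grand sum of G).  Monomorphic SNPs contribute zero to both the
numerator and the denominator.

In a two-way cross the sample deviates from Hardy-Weinberg proportions,
so the mean self-relationship is below 1 when scaling by the
HWE-expected heterozygosity; this is expected and no rescaling is
applied.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from keelgen.dataio import GenotypeMatrix

__all__ = ["GRM", "PcaResult", "compute_grm", "pca"]


@dataclasses.dataclass
class GRM:
    """Genomic relationship matrix with its VanRaden scaling constant."""

    matrix: np.ndarray
    scale: float
    allele_freqs: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match GRM dimension")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)
        df.to_csv(path, sep="\t", index_label="sample_id")
        return path

    @classmethod
    def from_tsv(cls, path) -> "GRM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(i) for i in df.index]
        # the dense TSV carries no sidecar: scale/freqs are placeholders
        return cls(
            matrix=df.to_numpy(),
            scale=1.0,
            allele_freqs=np.array([]),
            snp_ids=[],
            sample_ids=ids,
        )

    def save(self, prefix) -> tuple[Path, Path]:
        """Binary matrix (.npy) plus JSON sidecar with scale and frequencies."""
        prefix = Path(prefix)
        npy = prefix.with_suffix(".grm.npy")
        sidecar = prefix.with_suffix(".grm.json")
        np.save(npy, self.matrix)
        sidecar.write_text(
            json.dumps(
                {
                    "scale": self.scale,
                    "allele_freqs": np.asarray(self.allele_freqs).tolist(),
                    "snp_ids": list(self.snp_ids),
                    "sample_ids": list(self.sample_ids),
                }
            )
        )
        return npy, sidecar

    @classmethod
    def load(cls, prefix) -> "GRM":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".grm.json").read_text())
        return cls(
            matrix=np.load(prefix.with_suffix(".grm.npy")),
            scale=meta["scale"],
            allele_freqs=np.asarray(meta["allele_freqs"]),
            snp_ids=meta["snp_ids"],
            sample_ids=meta["sample_ids"],
        )


@dataclasses.dataclass
class PcaResult:
    """Top-k principal components of a GRM."""

    scores: np.ndarray  # n x k
    variance_fraction: np.ndarray  # length k, non-increasing

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if (vf < -1e-12).any():
            raise ValueError("variance fractions must be non-negative")
        if vf.size > 1 and np.any(np.diff(vf) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")
        if vf.sum() > 1 + 1e-8:
            raise ValueError("variance fractions must sum to <= 1")


def compute_grm(geno: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM from a dosage matrix.

    Allele frequencies come from non-missing calls of the sample itself;
    missing dosages are imputed to 2p before centering.
    """
    d = geno.dosages
    p = geno.allele_freqs()
    if np.isnan(p).any():
        raise ValueError("SNP with no non-missing calls; run QC first")
    het = 2.0 * p * (1.0 - p)
    scale = float(het.sum())
    if scale <= 0:
        raise ValueError("all SNPs are monomorphic; GRM scale would be 0")
    Z = np.where(np.isnan(d), 0.0, d - 2.0 * p)
    # imputing missing to 2p then centering is the same as centering to 0
    G = (Z @ Z.T) / scale
    G = (G + G.T) / 2.0
    return GRM(
        matrix=G,
        scale=scale,
        allele_freqs=p,
        snp_ids=list(geno.snp_info["snp_id"]),
        sample_ids=list(geno.sample_ids),
    )


def pca(grm: GRM, k: int) -> PcaResult:
    """Top-k eigendecomposition of G; variance fraction = eigenvalue / trace."""
    if k > grm.n:
        raise ValueError(f"k={k} exceeds GRM dimension {grm.n}")
    if not np.isfinite(grm.matrix).all():
        raise ValueError("GRM contains non-finite entries")
    evals, evecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(evals)[::-1][:k]
    evals_k = np.clip(evals[order], 0.0, None)
    trace = float(np.trace(grm.matrix))
    scores = evecs[:, order] * np.sqrt(evals_k)
    return PcaResult(scores=scores, variance_fraction=evals_k / trace)
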