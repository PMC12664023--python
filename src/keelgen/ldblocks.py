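"""Linkage disequilibrium: r2, pruning, D' confidence intervals, blocks.

* ``genotype_r2``: squared Pearson correlation of dosage vectors over
  pairwise-complete individuals (composite LD on unphased data).
* ``ld_prune``: greedy sliding-window pruning; the retained count m
  approximates the number of independent tests for Bonferroni
  thresholds.
* ``em_haplotype_freqs`` / ``dprime_ci``: two-SNP EM over the
  double-heterozygote phase ambiguity, then a Haploview-style D'
  confidence interval from a normalized 101-point likelihood grid.
* ``find_blocks``: Gabriel-style blocks -- a pair is "strong LD" when
  its D' CI lower bound >= 0.60 and upper bound >= 0.90; a candidate
  block's outermost pair must be strong and >= 95% of informative pairs
  inside must be strong; overlaps resolved longest-first.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from keelgen.dataio import GenotypeMatrix

__all__ = [
    "LdPair",
    "HaplotypeBlock",
    "genotype_r2",
    "ld_prune",
    "em_haplotype_freqs",
    "dprime_ci",
    "find_blocks",
    "assign_hits_to_blocks",
]


@dataclasses.dataclass
class LdPair:
    snp_a: str
    snp_b: str
    r2: float
    dprime: float
    dprime_ci_low: float
    dprime_ci_high: float
    n_informative: int


@dataclasses.dataclass
class HaplotypeBlock:
    chrom: str
    start: int
    stop: int
    snp_ids: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError("block start > stop")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.stop


def genotype_r2(dosages_a, dosages_b) -> float:
    """Squared dosage correlation over pairwise-complete individuals.

    Returns NaN when either SNP is monomorphic on the complete set or
    fewer than 10 complete pairs exist.  Invariant to allele flips and
    to swapping the SNPs.
    """
    a = np.asarray(dosages_a, dtype=float).ravel()
    b = np.asarray(dosages_b, dtype=float).ravel()
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 10:
        return float("nan")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(geno: GenotypeMatrix, window_kb: float = 500.0, step_snps: int = 10,
             r2_max: float = 0.2) -> list[str]:
    """Greedy sliding-window LD pruning per chromosome.

    Within each window (SNPs within ``window_kb`` of the anchor SNP),
    while any retained pair has r2 > ``r2_max`` the lower-MAF member of
    the worst pair is removed (ties: the later map position goes).  The
    anchor advances ``step_snps`` retained SNPs at a time, and passes
    repeat until a full pass removes nothing, so no retained pair closer
    than the window span can exceed the threshold.
    """
    maf = geno.maf()
    retained: list[str] = []
    for chrom, idx in geno.snp_info.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        pos = geno.snp_info["pos"].to_numpy()[idx]
        if np.any(np.diff(pos) < 0):
            warnings.warn(f"chromosome {chrom}: positions unsorted; sorting for pruning")
            order = np.argsort(pos, kind="stable")
            idx, pos = idx[order], pos[order]
        alive = np.ones(idx.size, dtype=bool)
        window_bp = window_kb * 1000.0

        def sweep(step: int) -> bool:
            changed = False
            anchor_ptr = 0
            while True:
                alive_idx = np.flatnonzero(alive)
                if anchor_ptr >= alive_idx.size:
                    break
                a0 = alive_idx[anchor_ptr]
                in_win = alive_idx[(pos[alive_idx] >= pos[a0]) & (pos[alive_idx] - pos[a0] <= window_bp)]
                # greedy removal inside the window
                while in_win.size >= 2:
                    sub = geno.dosages[:, idx[in_win]]
                    k = in_win.size
                    worst = (None, r2_max)
                    for i in range(k):
                        for j in range(i + 1, k):
                            r2 = genotype_r2(sub[:, i], sub[:, j])
                            if np.isfinite(r2) and r2 > worst[1]:
                                worst = ((i, j), r2)
                    if worst[0] is None:
                        break
                    i, j = worst[0]
                    gi, gj = in_win[i], in_win[j]
                    mi, mj = maf[idx[gi]], maf[idx[gj]]
                    # remove the lower-MAF member; ties -> later position
                    if mi < mj:
                        drop = gi
                    elif mj < mi:
                        drop = gj
                    else:
                        drop = gj if pos[gj] >= pos[gi] else gi
                    alive[drop] = False
                    changed = True
                    in_win = in_win[in_win != drop]
                anchor_ptr += step
            return changed

        # documented sliding pass, then a step-1 cleanup so no retained
        # within-window pair can exceed the threshold
        while sweep(step_snps):
            pass
        while sweep(1):
            pass
        retained.extend(geno.snp_info["snp_id"].to_numpy()[idx[alive]])
    return retained


def _genotype_table(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over pairwise-complete individuals."""
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok].astype(int), b[ok].astype(int)
    tab = np.zeros((3, 3))
    for ga, gb in zip(a, b):
        tab[ga, gb] += 1
    return tab


def _genotype_probs(h: np.ndarray) -> np.ndarray:
    """3x3 genotype-pair probabilities from haplotype freqs (AB, Ab, aB, ab).

    Alleles: genotype = count of the A/B allele; haplotype pairs unite at
    random (no within-pair dependence beyond the haplotype frequencies).
    """
    pAB, pAb, paB, pab = h
    pa = np.array([pAB + pAb, paB + pab])  # freq of A, a on first SNP
    probs = np.zeros((3, 3))
    # genotype (ga, gb) = counts of allele "1" at each SNP
    hap = {(1, 1): pAB, (1, 0): pAb, (0, 1): paB, (0, 0): pab}
    for (a1, b1), f1 in hap.items():
        for (a2, b2), f2 in hap.items():
            probs[a1 + a2, b1 + b2] += f1 * f2
    return probs


def em_haplotype_freqs(dosages_a, dosages_b, tol: float = 1e-8, max_iter: int = 1000):
    """Two-SNP haplotype frequencies by EM over the phase ambiguity.

    Returns (freqs, converged): freqs = (AB, Ab, aB, ab) summing to 1,
    where A/B denote the counted alleles.  Only the double heterozygote
    is phase-ambiguous; all other genotype pairs count haplotypes
    directly.
    """
    a = np.asarray(dosages_a, dtype=float).ravel()
    b = np.asarray(dosages_b, dtype=float).ravel()
    tab = _genotype_table(a, b)
    n = tab.sum()
    if n < 10:
        raise ValueError("need >= 10 pairwise-complete individuals")

    # fixed (unambiguous) haplotype counts; AB from cell (ga, gb):
    # each individual contributes two haplotypes
    def fixed_counts() -> np.ndarray:
        c = np.zeros(4)  # AB, Ab, aB, ab
        for ga in range(3):
            for gb in range(3):
                cnt = tab[ga, gb]
                if cnt == 0 or (ga == 1 and gb == 1):
                    continue
                # at most one locus heterozygous -> phase is determined;
                # pairing the sorted allele lists yields the two haplotypes
                a_alleles = [1] * ga + [0] * (2 - ga)
                b_alleles = [1] * gb + [0] * (2 - gb)
                for ha, hb in zip(a_alleles, b_alleles):
                    k = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(ha, hb)]
                    c[k] += cnt
        return c

    base = fixed_counts()
    n_dh = tab[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    h = np.full(4, 0.25)
    converged = False
    for _ in range(max_iter):
        if n_dh > 0:
            coup = h[0] * h[3]
            rep = h[1] * h[2]
            denom = coup + rep
            frac = 0.5 if denom == 0 else coup / denom
            extra = np.array([frac, 1 - frac, 1 - frac, frac]) * n_dh
        else:
            extra = np.zeros(4)
        new = (base + extra) / (2.0 * n)
        if np.max(np.abs(new - h)) < tol:
            h = new
            converged = True
            break
        h = new
    return h, converged


def _dprime_from_freqs(h: np.ndarray) -> float:
    pAB, pAb, paB, pab = h
    pA, pB = pAB + pAb, pAB + paB
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax <= 0:
        return float("nan")
    return abs(D) / dmax


def dprime_ci(dosages_a, dosages_b, conf: float = 0.90) -> LdPair:
    """Point D' plus a likelihood-grid confidence interval (Haploview-style).

    The multinomial likelihood of the genotype table is profiled over a
    101-point grid of |D'| in [0, 1] (allele frequencies held at their
    estimates, D signed as the point estimate), normalized to unit mass,
    and the central ``conf`` interval of the cumulative curve is
    reported.
    """
    a = np.asarray(dosages_a, dtype=float).ravel()
    b = np.asarray(dosages_b, dtype=float).ravel()
    tab = _genotype_table(a, b)
    n = tab.sum()
    h, _ = em_haplotype_freqs(a, b)
    pA, pB = h[0] + h[1], h[0] + h[2]
    if pA <= 0 or pA >= 1 or pB <= 0 or pB >= 1:
        return LdPair("", "", float("nan"), float("nan"), float("nan"), float("nan"), int(n))
    D = h[0] - pA * pB
    sign = 1.0 if D >= 0 else -1.0
    if sign > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else float("nan")

    grid = np.linspace(0.0, 1.0, 101)
    logliks = np.full(grid.size, -np.inf)
    for gi, dp in enumerate(grid):
        Dg = sign * dp * dmax
        hf = np.array([
            pA * pB + Dg,
            pA * (1 - pB) - Dg,
            (1 - pA) * pB - Dg,
            (1 - pA) * (1 - pB) + Dg,
        ])
        hf = np.clip(hf, 1e-12, None)
        hf = hf / hf.sum()
        probs = np.clip(_genotype_probs(hf), 1e-300, None)
        logliks[gi] = float((tab * np.log(probs)).sum())
    ll = logliks - logliks.max()
    mass = np.exp(ll)
    mass = mass / mass.sum()
    cdf = np.cumsum(mass)
    alpha = (1.0 - conf) / 2.0
    lo = float(grid[np.searchsorted(cdf, alpha)])
    hi = float(grid[min(np.searchsorted(cdf, 1.0 - alpha), grid.size - 1)])
    r2 = genotype_r2(a, b)
    return LdPair(
        snp_a="", snp_b="", r2=r2, dprime=float(dprime),
        dprime_ci_low=lo, dprime_ci_high=hi, n_informative=int(n),
    )


def find_blocks(geno: GenotypeMatrix, max_kb: float = 5000.0, ci_low_min: float = 0.60,
                ci_high_min: float = 0.90, strong_frac: float = 0.95) -> list[HaplotypeBlock]:
    """Gabriel-style haplotype blocks from D' confidence intervals.

    A pair is strong LD iff ci_low >= ``ci_low_min`` and
    ci_high >= ``ci_high_min``.  A candidate block is a contiguous SNP
    run spanning <= ``max_kb`` whose outermost pair is strong; it is
    accepted when at least ``strong_frac`` of its informative pairs are
    strong.  Overlaps resolve longest-span-first (ties: earlier start).
    Blocks are labeled "chrom_k" per chromosome in map order.
    """
    blocks: list[HaplotypeBlock] = []
    info = geno.snp_info
    for chrom, idx in info.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        pos = info["pos"].to_numpy()[idx]
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        k = idx.size
        cache: dict[tuple[int, int], LdPair] = {}

        def pair(i: int, j: int) -> LdPair:
            key = (i, j)
            if key not in cache:
                try:
                    cache[key] = dprime_ci(geno.dosages[:, idx[i]], geno.dosages[:, idx[j]])
                except ValueError:
                    cache[key] = LdPair("", "", np.nan, np.nan, np.nan, np.nan, 0)
            return cache[key]

        def strong(lp: LdPair) -> bool:
            return (np.isfinite(lp.dprime_ci_low) and lp.dprime_ci_low >= ci_low_min
                    and lp.dprime_ci_high >= ci_high_min)

        candidates = []
        for i in range(k):
            for j in range(i + 1, k):
                if pos[j] - pos[i] > max_kb * 1000.0:
                    break
                outer = pair(i, j)
                if not strong(outer):
                    continue
                n_strong = n_inf = 0
                for ii in range(i, j + 1):
                    for jj in range(ii + 1, j + 1):
                        lp = pair(ii, jj)
                        if np.isfinite(lp.dprime_ci_low):
                            n_inf += 1
                            n_strong += strong(lp)
                if n_inf and n_strong / n_inf >= strong_frac:
                    candidates.append((i, j))

        taken = np.zeros(k, dtype=bool)
        chosen = []
        for i, j in sorted(candidates, key=lambda c: (-(pos[c[1]] - pos[c[0]]), pos[c[0]])):
            if taken[i : j + 1].any():
                continue
            taken[i : j + 1] = True
            chosen.append((i, j))
        for bnum, (i, j) in enumerate(sorted(chosen, key=lambda c: c[0]), start=1):
            blocks.append(
                HaplotypeBlock(
                    chrom=str(chrom),
                    start=int(pos[i]),
                    stop=int(pos[j]),
                    snp_ids=list(info["snp_id"].to_numpy()[idx[i : j + 1]]),
                    label=f"{chrom}_{bnum}",
                )
            )
    return blocks


def assign_hits_to_blocks(hits: pd.DataFrame, blocks: list[HaplotypeBlock]) -> tuple[pd.DataFrame, int]:
    """Map significant/suggestive SNPs onto haplotype blocks.

    Hits inside a block take that block; hits in no block become
    singleton one-SNP intervals.  The labeled table is ordered and
    labeled "chrom_k" in map order per chromosome; the second return
    value is the union SNP count over all labeled intervals.
    """
    assigned: dict[tuple[str, int, int], dict] = {}
    for hit in hits.itertuples(index=False):
        chrom, posn, snp = str(hit.chrom), int(hit.pos), str(hit.snp_id)
        home = next((b for b in blocks if b.contains(chrom, posn)), None)
        if home is None:
            key = (chrom, posn, posn)
            rec = assigned.setdefault(
                key, {"chrom": chrom, "start": posn, "stop": posn, "snp_ids": [snp], "hits": []}
            )
        else:
            key = (home.chrom, home.start, home.stop)
            rec = assigned.setdefault(
                key, {"chrom": home.chrom, "start": home.start, "stop": home.stop,
                      "snp_ids": list(home.snp_ids), "hits": []}
            )
        rec["hits"].append(snp)

    rows = []
    per_chrom: dict[str, int] = {}
    union: set[str] = set()
    for key in sorted(assigned, key=lambda k: (k[0], k[1])):
        rec = assigned[key]
        per_chrom[rec["chrom"]] = per_chrom.get(rec["chrom"], 0) + 1
        label = f"{rec['chrom']}_{per_chrom[rec['chrom']]}"
        union.update(rec["snp_ids"])
        rows.append(
            {
                "block": label,
                "chrom": rec["chrom"],
                "start": rec["start"],
                "stop": rec["stop"],
                "n_snps": len(rec["snp_ids"]),
                "snp_ids": ",".join(rec["snp_ids"]),
                "hit_snps": ",".join(rec["hits"]),
            }
        )
    return pd.DataFrame(rows), len(union)
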