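"""Map haplotype blocks to nearby genes/QTL from a local interval table.

A feature is reported when it intersects the block extended by
``flank_bp`` on each side, with a strict boundary: the gap between
feature and block border must be strictly less than the flank.
"Upstream"/"downstream" are positional (+ reference direction);
feature strand is ignored for distances, and single-bp touching counts
as overlapping.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from keelgen.dataio import IntervalTable
from keelgen.ldblocks import HaplotypeBlock

__all__ = ["OverlapRecord", "genes_near_blocks"]


@dataclasses.dataclass
class OverlapRecord:
    block: str
    feature: str
    chrom: str
    distance: int  # bp gap to the nearer block border; 0 if overlapping
    relation: str  # "overlaps", "upstream" (feature before block) or "downstream"

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if self.relation not in ("overlaps", "upstream", "downstream"):
            raise ValueError(f"bad relation {self.relation!r}")


def genes_near_blocks(
    blocks: list[HaplotypeBlock], intervals: IntervalTable, flank_bp: int = 50_000
) -> list[OverlapRecord]:
    """Features overlapping or within ``flank_bp`` (strict) of each block.

    Output order is (block start, feature start) per chromosome and does
    not depend on the input ordering of blocks or features.
    """
    records: list[OverlapRecord] = []
    feats = sorted(intervals, key=lambda f: (f.chrom, f.start, f.end, f.name))
    for block in sorted(blocks, key=lambda b: (b.chrom, b.start, b.stop)):
        for feat in feats:
            if feat.chrom != block.chrom:
                continue
            if feat.end >= block.start and feat.start <= block.stop:
                distance, relation = 0, "overlaps"
            elif feat.end < block.start:
                distance, relation = block.start - feat.end, "upstream"
            else:
                distance, relation = feat.start - block.stop, "downstream"
            if distance < flank_bp:
                records.append(
                    OverlapRecord(
                        block=block.label or f"{block.chrom}:{block.start}-{block.stop}",
                        feature=feat.name,
                        chrom=feat.chrom,
                        distance=int(distance),
                        relation=relation,
                    )
                )
    return records


def overlaps_to_frame(records: list[OverlapRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records],
                        columns=["block", "feature", "chrom", "distance", "relation"])
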