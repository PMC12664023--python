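"""Map haplotype blocks to nearby genes from a local interval table.

Uses a small synthetic gene set (BED) around two hand-specified blocks
and reports every gene overlapping a block or lying strictly within
50 kb of its borders, with the gap distance and side.
"""

from pathlib import Path
import tempfile

from keelgen import genes_near_blocks
from keelgen.dataio import read_intervals
from keelgen.ldblocks import HaplotypeBlock

blocks = [
    HaplotypeBlock(chrom="20", start=12_269_383, stop=12_367_466,
                   snp_ids=["snpA", "snpB"], label="20_1"),
    HaplotypeBlock(chrom="2", start=126_410_011, stop=126_634_251,
                   snp_ids=["snpC"], label="2_1"),
]

# synthetic gene annotations (BED: 0-based half-open on disk)
bed = "\n".join([
    "20\t12300000\t12320000\tgene_inside",
    "20\t12200000\t12230000\tgene_39kb_upstream",
    "20\t12417467\t12500000\tgene_exactly_50kb_down",  # excluded: gap not < 50 kb
    "2\t126700000\t126720000\tgene_66kb_downstream",   # excluded
    "2\t126380000\t126409000\tgene_1kb_upstream",
]) + "\n"

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "genes.bed"
    path.write_text(bed)
    intervals = read_intervals(path, "BED")

for rec in genes_near_blocks(blocks, intervals, flank_bp=50_000):
    print(f"block {rec.block}: {rec.feature:<24} {rec.relation:<10} gap {rec.distance:>6} bp")
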