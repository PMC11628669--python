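"""Map outlier SNPs to genes within 50 kbp in a GFF3 annotation.

Writes a toy annotation, then queries it: a SNP inside a gene span
reports distance 0; one 10 kbp away is reported with that distance;
anything at or beyond the window is silent.
"""

import tempfile
from pathlib import Path

from karyorda import genes_near, read_annotation

gff = """##gff-version 3
scaffold_1\ttoy\tgene\t100000\t105000\t.\t+\t.\tID=urease_subunit
scaffold_1\ttoy\tgene\t180000\t182000\t.\t-\t.\tID=formyl_transferase
"""
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "toy.gff3"
    path.write_text(gff)
    genes = read_annotation(path)

for pos, label in ((102_500, "inside the urease gene"),
                   (170_000, "10 kbp from the formyl transferase"),
                   (20_000, "beyond every window")):
    hits = genes_near("scaffold_1", pos, genes, window=50_000)
    print(f"SNP @ {pos:>7,} ({label}):")
    for h in hits:
        print(f"   {h.gene_id}: {h.distance:,} bp {h.relation}")
    if not hits:
        print("   no gene within 50 kbp")
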