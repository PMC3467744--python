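"""Parse GFF3 gene models, splice CDS segments out of a genome and
write the features back as GFF3."""

import io

from seqforge import DNA, make_sequence, translate
from seqforge.seqio import extract_spliced, read_gff, write_gff3

genome = make_sequence("ATGAAACCCGGGTTTACGTAGCATCAT", DNA, "chr1")

gff_text = """\
chr1\tdemo\tgene\t1\t21\t.\t+\t.\tID=gene1
chr1\tdemo\tmRNA\t1\t21\t.\t+\t.\tID=tx1;Parent=gene1
chr1\tdemo\tCDS\t1\t6\t.\t+\t0\tParent=tx1
chr1\tdemo\tCDS\t16\t21\t.\t+\t0\tParent=tx1
"""

features = read_gff(io.StringIO(gff_text), dialect="gff3")
cds = [f for f in features if f.type == "CDS"]
spliced = extract_spliced(cds, genome)
print(f"spliced CDS: {spliced}")
print(f"protein:     {translate(spliced, trim_stop=True)}")

print("\nround-tripped GFF3:")
print(write_gff3(features))
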