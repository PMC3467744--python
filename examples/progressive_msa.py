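"""Progressive multiple alignment of four DNA variants: distance
matrix, UPGMA guide tree and the final CLUSTAL block."""

from seqforge.align import (
    GapPenalty,
    SubstitutionMatrix,
    distance_matrix,
    progressive_msa,
    write_alignment,
)

seqs = ["ACGTACGTTT", "ACGTACGT", "ACTTACGTTT", "GCGTACG"]
matrix = SubstitutionMatrix.match_mismatch(1, -1)
gap = GapPenalty(-2, -1)

d = distance_matrix(seqs, matrix, gap)
print("pairwise distances (1 - fractional identity):")
print(d.round(3))

msa = progressive_msa(seqs, matrix, gap)
print(f"\nguide tree: {msa.tree.newick()}")
print(f"sum-of-pairs score: {msa.score}\n")
print(write_alignment(msa, "clustal"))
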