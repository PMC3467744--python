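"""Global, local and anchored linear-memory alignment of two protein
fragments under BLOSUM62."""

from seqforge.align import (
    GapPenalty,
    align_global,
    align_global_linear,
    align_local,
    load_matrix,
    write_alignment,
)

blosum62 = load_matrix("blosum62")
gap = GapPenalty(open=-10, extend=-1)

a, b = "HEAGAWGHEE", "PAWHEAE"

glob = align_global(a, b, blosum62, gap)
print(f"global score {glob.score}:")
print(write_alignment(glob, "fasta"))

loc = align_local(a, b, blosum62, gap)
print(f"local score {loc.score} (substrings start at {loc.starts}):")
print("  " + loc.rows[0])
print("  " + loc.rows[1])

# The linear-memory aligner gives the same global optimum; anchoring
# position 0 of each sequence forces H-P into one column.  An anchored
# optimum can never beat the free one (here it happens to tie it).
lin = align_global_linear(a, b, blosum62, gap)
anchored = align_global_linear(a, b, blosum62, gap, anchors=[(0, 0)])
print(f"linear-memory score {lin.score}, anchored (0,0) score {anchored.score}")
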