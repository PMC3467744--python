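"""Translate an open reading frame, with ambiguity codes and a
bacterial start codon, and inspect all six reading frames."""

from seqforge import DNA, make_sequence, six_frame_translate, translate

orf = make_sequence("TTGAAACGNTGGTAG", DNA, "demo_orf")

# Bacterial code (NCBI table 11): TTG is an initiation codon, so with
# init_met it becomes M.  CGN collapses to R (all four expansions are
# arginine); the trailing TAG stop is trimmed.
peptide = translate(orf, table=11, init_met=True, trim_stop=True)
print(f"{orf.identifier}: {orf} -> {peptide}")

print("\nsix-frame translation (frame: product):")
for frame, product in six_frame_translate(orf, table=11).items():
    print(f"  {frame:+d}: {product}")
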