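"""Indexed lazy FASTA: open a file without loading sequence data, then
read only the slices you touch."""

import tempfile
from pathlib import Path

from seqforge import DNA, make_sequence, subsequence
from seqforge.seqio import open_fasta_lazy, write_fasta

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "contigs.fa"
    contigs = [
        make_sequence("ACGT" * 500, DNA, "contig1"),
        make_sequence("TTGCA" * 300, DNA, "contig2"),
    ]
    write_fasta(contigs, str(path))

    # One indexing pass records byte offsets; symbols stay on disk.
    lazy = open_fasta_lazy(str(path))
    c1 = lazy[0]
    print(f"{c1.identifier}: length {len(c1)} (no sequence loaded yet)")
    window = subsequence(c1, 998, 1010)  # reads ~12 bytes from disk
    print(f"window [998, 1010): {window}")
    print(f"equal to eager copy: {window == subsequence(contigs[0], 998, 1010)}")
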