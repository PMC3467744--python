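"""Decode a Sanger FASTQ read and re-encode it in the Illumina-1.3 and
Solexa conventions, showing how the quality characters change."""

import io

from seqforge.seqio import convert_fastq, read_fastq, write_fastq

sanger_text = "@read1 demo\nACGTACGT\n+\n!I5+I?>I\n"
record = next(read_fastq(io.StringIO(sanger_text), "sanger"))
print(f"Phred qualities: {record.qualities}")

for target in ("illumina13", "solexa"):
    converted = convert_fastq(record, target)
    line = write_fastq([converted], target).splitlines()[3]
    print(f"{target:>11}: {converted.qualities} -> {line!r}")

# Note the Q0 base: Phred 0 maps to the Solexa floor of -5, and the
# sanger->illumina13 re-encoding is a pure +31 character offset.
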