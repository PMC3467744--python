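# Methods

This note records the models behind each subsystem, the defaults and
why they were chosen, the numerical conventions, and what the test
suite's synthetic inputs do and do not establish.

## Sequence model and coordinates

All internal coordinates are 0-based, half-open. GFF's 1-based
inclusive coordinates are converted exactly once, at the I/O boundary
(`extract_spliced` and the GFF writer); nothing else in the library
ever sees 1-based positions. Input is case-insensitive and stored
upper-case canonical; soft-masking semantics are deliberately out of
scope.

Sequences are immutable values over an alphabet; equality is
value-based (equal symbols, equal alphabet), independent of the
storage backend. Eager in-memory storage validates every symbol at
construction; the indexed lazy FASTA backend validates on access, so
opening a file costs only one indexing pass and no sequence bytes are
retained. The two backends are interchangeable by contract, and the
suite probes that contract with a thousand random index/slice reads.
Remote (web-service) storage backends are represented only by the
storage-provider protocol; none is implemented, keeping the package
fully testable offline.

## Translation

Codon tables are total maps from the 64 concrete RNA codons plus a
start-codon set, using the NCBI numbering; tables 1, 2 and 11 ship
built in (standard, vertebrate mitochondrial, bacterial) because they
cover the common nuclear, organellar and prokaryotic cases — the data
structure accepts any other table. The engine normalises DNA to RNA
codons first, so `translate(dna)` and `translate(transcribe(dna))`
are identical by construction.

Degenerate codons are expanded over all concrete codons: one common
amino acid is emitted as itself, disagreement as `X`, and an
all-stop expansion as a stop. This preserves the information a
degenerate base actually carries (e.g. four-fold degenerate family
codons translate exactly) without ever failing on valid IUPAC input.

`init_met` rewrites only the first codon of the frame, matching
initiation semantics, and only on an exact (concrete) start-codon
match. `trim_stop` truncates at the *first* stop, the CDS-oriented
reading of stop trimming; callers who want internal stops visible
leave it off and receive `*` characters. Incomplete trailing codons
are dropped silently, the standard six-frame convention.

## Alignment

**Gap model.** Affine: a run of length L scores `open + L·extend`,
open ≤ 0 charged once per run, end gaps penalized in global mode (the
strict global reading; semi-global modes are out of scope). Scores
are integers, distances reals.

**Determinism.** Traceback ties resolve diagonal > up (gap in the
second sequence) > left, and the same order applies to state
selection, so repeated runs are byte-identical.

**Linear-memory aligner.** The score pass keeps two rows of the
three-state recurrence. The alignment itself is recovered by
divide and conquer: split at the middle row, join either at a node or
inside a vertical gap run spanning the split (adding back the
doubly-charged open), and recurse with boundary flags that let a gap
run continue across a sub-problem edge without re-opening.
Sub-problems at or below 1024 cells fall back to the quadratic DP
with the same boundary flags. The emitted alignment is re-scored
from its rows, which is exact because the join values are computed
from optimal forward/backward quantities. Equivalence with the
quadratic aligner is asserted over 200 random pairs under three gap
settings.

**Anchors.** An anchor `(i, j)` is a single residue-pair constraint.
Because an anchored column interrupts any gap run, the segments
between consecutive anchors are independent sub-alignments and the
decomposition is exact, not heuristic. Anchors must be strictly
increasing in both coordinates; the anchored optimum can never exceed
the free optimum, with equality when an anchor lies on an optimal
path — both facts are asserted against brute-force enumeration.

**Progressive MSA.** Distances are `1 − fractional identity` from
pairwise global alignments (identical residue columns over all
columns). The guide tree is UPGMA — the simplest rooted tree a
progressive merge order needs; ties pick the lowest cluster-index
pair and children are ordered by smallest input index, so the tree is
deterministic. Profiles merge by the same affine DP over columns,
scoring column pairs sum-of-pairs over residue counts with gap
penalties scaled by the number of row pairs affected; gaps inserted
into a profile are never removed ("once a gap, always a gap"). The
*stored* MSA score is defined as the sum-of-pairs score recomputed
from the emitted rows (each row pair projected, double-gap columns
dropped, scored under the affine model), so the reported score is
always consistent with the alignment it describes. With exactly two
sequences the MSA is the optimal pairwise global alignment.

## FASTQ quality encodings

The variant is always an explicit parameter. The three offset/range
conventions (Sanger 33/[0, 93], Solexa 64/[−5, 62], Illumina-1.3
64/[0, 62]) overlap enough that autodetection silently corrupts
qualities, which is worse than asking the caller to say what they
have. Phred↔Solexa conversion uses the exact logistic relations
(`Q_phred = 10·log₁₀(10^(Q_solexa/10) + 1)` and its inverse, Phred 0
pinned to Solexa −5), rounding to the nearest integer with ties away
from zero, then clamping to the target range. Sanger↔Illumina-1.3 is
a pure offset re-encoding and is the identity on Q ∈ [0, 62].
Reading is streaming (constant memory in the number of records);
same-variant write→read round trips are byte-exact.

## GFF dialects

GFF3, GTF and GFF2 are read; GFF3 is the only written dialect.
GFF3 `ID`/`Parent` attributes are resolved into object links after
parsing. Attribute values are percent-escaped on output over the
GFF3 reserved set (`; = & , %` and control characters) only. `CDS`
features require a phase when written, per the format. Tool-specific
attribute quirks beyond standard dialect syntax are not special-cased.
Spliced extraction requires one seqid, one definite strand and
non-overlapping segments, and reverse-complements minus-strand
products.

## Protein properties

Residue masses follow the Expasy residue-mass convention (peptide
mass = Σ residues + one water, average 18.0153 Da / monoisotopic
18.010565 Da). Mass overrides are keyed by residue symbol and affect
every occurrence — per-position modification placement is out of
scope — and they touch mass calculations only, never hydropathy,
instability or charge.

The pKa set is data, not code: published sets disagree and the
computed pI moves with them, so the Bjellqvist-style set common to pI
calculators is the bundled default (N-term 7.5, C-term 3.55, K 10.0,
R 12.0, H 5.98, D 4.05, E 4.45, C 9.0, Y 10.0) and the EMBOSS set is
provided as an alternative; any `PkaSet` can be swapped in. The
isoelectric point is found by bisection on [0, 14] to |charge| < 1e−4
(pH resolved well below that); monotonicity of the charge curve makes
the root unique. No claim is made that these defaults reproduce any
particular web service's output digit for digit.

The instability index uses the full sequence length L as denominator
over the L−1 adjacent dipeptides, the published definition; < 40
classifies as stable. Ambiguous residues (B, Z, J, X) are hard
errors in mass and GRAVY — a silently wrong mass is worse than a
failure — but are skipped with a logged warning in the composition-
based aliphatic index.

All constant tables (masses, hydropathy, the 400-entry dipeptide
instability weights, pKas, extinction coefficients) are cross-checked
in the test suite against independently transcribed copies of the
same published tables; the average-mass comparison allows ~5 mDa for
differing atomic-weight vintages. The monoisotopic ≤ average
invariant holds for the 20 standard residues but *not* for
selenocysteine (selenium's most abundant isotope is heavier than its
mean atomic weight), which is why the check is scoped to the
standard 20.

## What the synthetic inputs do and do not show

All test data is generated: uniform random DNA over `ACGT` (with
IUPAC codes injected for the ambiguity suites), uniform random
peptides over the 20 standard residues, and hand-written miniature
FASTA/FASTQ/GFF fixtures. Problem sizes are chosen so the whole
suite runs in seconds: alignment oracles use >1000 pairs of length
≤ 6 (where exhaustive enumeration is feasible), linear-memory
equivalence uses 200 pairs up to length 80 under three gap settings,
translation uses 500 degenerate strings up to 30 nt, and the MSA
suite uses 50 random triples up to length 30.

Passing these suites establishes the *algorithmic contracts* —
optimality, equivalence, round-trip exactness, invariants — which do
not depend on sequence composition. It does not establish anything
about biological plausibility on real data: random uniform sequences
have no homology structure, so MSA quality on diverged families,
matrix choice, or gap-parameter tuning are not evaluated here.
Progressive alignment is a heuristic; its structural invariants are
verified, not column-level optimality (no iterative refinement or
consistency scoring is attempted).

## Known limitations

- Only NCBI tables 1, 2, 11 are bundled; selenocysteine/pyrrolysine
  recoding is not modelled.
- The DP kernels are pure Python: comfortable to thousands of
  residues, not a vectorized long-read aligner (no banding).
- FASTA lazy indexing uses an internal per-line index, not `.fai`
  files; BAM/SAM, GenBank/EMBL flat files and paired-end semantics
  are out of scope.
- CLUSTAL output is write-only; aligned FASTA is the round-trip
  format.
- No network-backed sequence storage or web-service clients.
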