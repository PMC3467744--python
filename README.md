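# seqforge

A sequence-analysis toolkit for Python: one library covering the
everyday core of sequence bioinformatics, built around a small set of
explicit, testable contracts.

- **Sequence data model** — alphabets with IUPAC ambiguity and
  complement rules; immutable sequences over pluggable storage
  providers, including an indexed *lazy* FASTA backend that reads
  symbols from disk only when touched.
- **Translation engine** — NCBI codon tables (1, 2 and 11 built in),
  all six reading frames, start-codon conversion to Met, stop
  trimming, and expand-and-collapse handling of degenerate codons
  (`CGN` → `R`; disagreeing expansions → `X`).
- **Alignment** — global (Needleman–Wunsch/Gotoh) and local
  (Smith–Waterman) affine-gap pairwise alignment; a linear-memory
  global aligner with divide-and-conquer traceback and user-specified
  anchors; progressive multiple alignment over a UPGMA guide tree;
  NCBI-format substitution matrices (BLOSUM62 and NUC.4.4 bundled);
  aligned-FASTA and CLUSTAL output.
- **Protein properties** — molecular weight (average/monoisotopic,
  with XML-configurable residue-mass overrides for isotope labels and
  PTMs), extinction coefficient, instability index, aliphatic index,
  GRAVY, net charge and isoelectric point, amino-acid composition.
- **I/O** — FASTA (eager and lazy), the three FASTQ quality-encoding
  variants (Sanger, Solexa, Illumina 1.3+) with exact quality-scale
  conversion, and GFF3/GTF/GFF2 feature parsing with spliced-sequence
  extraction and GFF3 writing.

A thin `seqforge` command-line front end (`translate`, `align`,
`msa`, `props`, `fastq-convert`, `gff-extract`) wraps the library for
pipeline use; the primary interface is the Python API, demonstrated
by the scripts in `examples/`.

## The models in brief

**Affine-gap alignment.** A gap of length *L* scores
`open + L·extend` (both ≤ 0), the open charged once per run; end gaps
are penalized in global mode. The three-state Gotoh recurrence over
states (match, gap-in-query, gap-in-target) gives the optimum; the
linear-memory variant computes the same score keeping only two rows
and recovers the path by splitting at the middle row, where the
optimal path crosses either at a node or inside a vertical gap run.
An anchor `(i, j)` forces `s1[i]` and `s2[j]` into one column; since
an anchored column interrupts any gap run, the segments between
anchors are solved independently and exactly.

**Quality scales.** Phred defines `Q = −10·log₁₀(p_error)`; Solexa
uses odds instead of probability, so the exact interconversion is
`Q_phred = 10·log₁₀(10^(Q_solexa/10) + 1)` (and its inverse), with
Phred 0 pinned to the Solexa floor of −5. Sanger and Illumina-1.3
both carry Phred values and differ only in ASCII offset (33 vs 64).

**Peptide properties.** Mass is `Σ residue masses + one water`
(Expasy residue-mass tables). Net charge at a given pH is the
Henderson–Hasselbalch sum over the termini and the D/E/C/Y/H/K/R side
chains; the isoelectric point is its unique zero crossing, found by
bisection on [0, 14]. The instability index is the Guruprasad
dipeptide-weight sum scaled by `10/L`; the aliphatic index is
`X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu)` in mole percent; GRAVY is
the mean Kyte–Doolittle hydropathy.

## A worked example

```python
from seqforge import DNA, make_sequence, translate
from seqforge.align import GapPenalty, align_global, load_matrix
from seqforge.protein import isoelectric_point, molecular_weight

orf = make_sequence("TTGAAACGNTGGTAG", DNA, "orf1")
pep = translate(orf, table=11, init_met=True, trim_stop=True)
print(pep)            # MKRW  (TTG is a bacterial start; CGN collapses to R)

aln = align_global("HEAGAWGHEE", "PAWHEAE", load_matrix("blosum62"),
                   GapPenalty(-10, -1))
print(aln.score)      # 2
print(aln.rows)       # ('HEAGAWGHEE', '---PAWHEAE')

print(round(molecular_weight("MKRW"), 4))    # 619.7827
print(round(isoelectric_point("MKRW"), 2))   # 11.0
```

`MKRW` is the translated peptide: the degenerate codon `CGN` encodes
arginine under every concrete expansion, so no information is lost.
The alignment score of 2 is the optimal global affine-gap score in
BLOSUM62 half-bits; the rows show the three-residue end gap it
required. From the command line the same translation is:

```sh
printf ">orf1\nTTGAAACGNTGGTAG\n" | seqforge translate --table 11 --init-met --trim-stop
```

Each script in `examples/` exercises one capability end to end and
prints a short, annotated result.

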