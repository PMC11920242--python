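# styscreen

Toolkit for designing and analyzing adenine-base-editor (ABE) screens that
tile serine, threonine and tyrosine residues genome-wide, plus the downstream
assays used to validate and interpret the hits.

ABE screens install precise A·T→G·C edits through a protospacer-defined
activity window instead of cutting DNA. Targeting every S/T/Y codon turns a
pooled CRISPR screen into a phospho-site-resolution mutagenesis experiment:
each guide converts one phosphorylatable residue into a fixed missense
variant, and sorting cells on a surface phenotype (for example PD-L1 or
MHC-I levels) reveals which individual residues regulate it. `styscreen`
covers the full loop:

- **`library_design`** — enumerate S/T/Y-targeting guides (20-nt spacer, NGG
  PAM, window positions 4–8) on both strands, predict on-target and bystander
  amino-acid changes, attach internal barcodes (iBARs), add controls.
- **`ibar_screen`** — count sgRNA–iBAR pairs, median-of-ratios normalization,
  per-iBAR log2 fold changes, a variance-trend z statistic with a consistency
  penalty for sign-discordant iBAR triplets, BH correction and signed
  `screen_score` hit calls.
- **`amplicon_edits`** — merge paired amplicon reads, extract the edited
  window by flanking anchors, tabulate per-position base composition and
  translate haplotypes into outcome labels such as `Y514C` or `L512P/S513P`.
- **`phenotype_metrics`** — relative MFI and competitive killing
  sensitivity/resistance indices with closed-form definitions and group tests.
- **`signature_scoring`** — build a weighted expression signature from a
  differential-expression table, score cohort profiles, correlate with immune
  markers and compare responders vs non-responders.
- **`synthetic_data`** — seeded generators for every input above, each
  returning machine-readable ground truth.

## Worked example

Everything below is reproducible; the output shown is what the commands
print.

```bash
$ styscreen simulate proteome --n-genes 2 --seed 7 --out demo
wrote 2 transcripts to demo/proteome.fa

$ styscreen design --cds demo/proteome.fa --out demo/library.tsv --seed 7
wrote 20 guides to demo/library.tsv

$ head -3 demo/library.tsv | cut -f1-8
sublibrary  gene_id  residue  spacer                pam  strand  on_target_change  bystanders
sense       GENE1    T19      TACACTCTATATCAGCCACA  AGG  sense   T19A
sense       GENE1    T67      AAAACCAGTTTGGGGTCTAT  AGG  sense   T67A              S68G
```

Each row is one designable residue: the spacer, its PAM and strand, the
predicted on-target change and any bystander edits inside the window, plus
three iBAR columns. Simulate a sorted screen with 15 planted enrichments and
score it:

```bash
$ cat > demo/sim.yaml <<EOF
n_guides: 2000
n_controls: 200
n_hits_up: 15
effect: 2.0
EOF
$ styscreen simulate screen --config demo/sim.yaml --seed 7 --out demo
wrote counts for 2200 guides to demo/counts.tsv

$ styscreen screen --counts demo/counts.tsv --samples demo/samples.tsv \
      --direction up --out demo/hits.tsv
16 hits of 2200 guides -> demo/hits.tsv
```

`hits.tsv` carries, per guide, the per-iBAR fold changes, the consistency
penalty, the combined z, BH-adjusted p and the signed
`screen_score = ±(−log10 p_adj)`; guides with `|screen_score| > 1` are hits.

Validate an individual hit by amplicon sequencing:

```bash
$ styscreen simulate amplicon --n-reads 5000 --seed 7 --out demo
wrote 5000 read pairs to demo

$ styscreen edits --r1 demo/amplicon_1.fq --r2 demo/amplicon_2.fq \
      --spec demo/amplicon.spec.yaml --out demo/ed
{"n_reads_used": 5000, "n_reads_unlocated": 0, "n_reads_indel": 0, "n_pairs_unmerged": 0}

$ head -4 demo/ed.alleles.tsv
haplotype                       count  fraction  aa_outcome
ATGGAACTGTCGTACAAAGGCTTCGATCTT  2379   0.4758    WT
ATGGAACTGTCGTGCAAAGGCTTCGATCTT  1490   0.2980    Y514C
ATGGAACCGCCGTACAAAGGCTTCGATCTT  983    0.1966    L512P/S513P
```

The planted 30% single edit and 20% co-edit are recovered, labeled in
protein coordinates.

Python API equivalents live under the same names:

```python
from styscreen import design_guides, analyze_screen, killing_sensitivity

killing_sensitivity(25, 50)   # -> 66.67: mutant cleared 67% better than control
```

## Layout

```
src/styscreen/       library modules + click CLI (console script: styscreen)
tests/               pytest suite, incl. brute-force oracles and acceptance tests
scripts/acceptance.py  end-to-end metrics report
docs/methods.md      model definitions, defaults, numerical choices
```
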