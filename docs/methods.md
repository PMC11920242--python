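# Methods

Definitions, defaults and numerical choices for every `styscreen` module.
Units: counts are raw read counts; fold changes are log2; expression is
log2(TPM); percentages of GFP⁺ cells are on 0–100.

## 1. Guide design (`library_design`)

**Editor model.** ABE chemistry converts A→G on the protospacer strand within
an activity window. Defaults (`EditorSpec`): 20-nt protospacer, `NGG` PAM,
window = protospacer positions 4–8, 1-based from the PAM-distal (5') end.
The window is a design decision — ABE window calls vary by construct and
readout — so it is a parameter, with 4–8 (the canonical ABEmax high-activity
window) as the default. Antisense guides edit the template strand, appearing
as T→C in coding coordinates.

**Emission rule.** For each transcript, both the coding context
(5'-flank + CDS + 3'-flank) and its reverse complement are scanned for
spacer+PAM placements. A guide is emitted per (spacer, strand, residue) when
at least one non-empty subset of window adenines lies within an S/T/Y codon
and yields a missense change (different, non-stop amino acid) —
`codon_edit_outcomes` classifies each subset as missense / synonymous /
stop_gain / other.

**Labels.** `on_target_change` (e.g. `Y98C`) is the consequence of editing
all window-editable bases of the target codon — the modal outcome at high
editor activity. Amino-acid changes at *other* codons under the same full
edit are listed in `bystander_changes` (e.g. `L512P` accompanying `S513P`).

**iBARs.** Each guide carries 3 internal barcodes (6-mers, no homopolymer of
length ≥4) drawn deterministically from a seeded generator keyed by the
spacer sequence, so the same spacer gets the same barcodes in every
sublibrary and re-run. Controls (e.g. safe-harbor spacers) are added with
`add_controls` and flagged `is_control`.

## 2. Screen statistic (`ibar_screen`)

Counts are indexed by (spacer, iBAR) × sample. Steps:

1. **Normalization** — median-of-ratios size factors (geometric-mean
   reference over rows positive in all samples; default `pseudocount=0`, so
   a column exactly 2× another gets a size factor exactly 2× as large).
2. **Fold change** — per iBAR, `lfc = log2((t + 1) / (r + 1))` on normalized
   counts (pseudocount 1 here stabilizes low counts).
3. **Variance trend** — control guides are binned into 10 quantile bins of
   reference abundance; within-bin lfc standard deviations define σ(μ) by
   linear interpolation (`np.interp`). Requires ≥20 control guides.
4. **z-scores** — `z = lfc / σ(μ)` per iBAR.
5. **Consistency penalty** — for each guide, `penalty = max(1, var(z, ddof=1))`
   is applied only when the iBAR z's are not all sign-concordant with the
   tested direction; concordant triplets keep penalty 1.
6. **Combination** — `z_combined = Σz / sqrt(n_ibars · penalty)`, one-sided
   normal p-value in the tested direction.
7. **Multiplicity** — Benjamini–Hochberg within each direction;
   `screen_score = ±(−log10 p_adj)` (sign = direction); a guide is a hit iff
   `|screen_score| > 1` (strictly), i.e. p_adj < 0.1.

Guides with fewer than 3 iBARs are scored but flagged (`flagged_few_ibars`).
Enrichment (sorted-high vs reference) and depletion (sorted-low) are two
independent one-directional analyses.

## 3. Amplicon outcomes (`amplicon_edits`)

- **Merging** — mate 2 is reverse-complemented; the overlap maximizing the
  match count with ≥20 bp length and ≤10% mismatches is chosen; overlap
  disagreements resolve toward the higher base quality; pairs with no
  acceptable overlap are dropped and counted.
- **Target extraction** — the in-frame target region is located by its 10-bp
  flanks, each tolerating ≤1 mismatch; ambiguous placements are discarded;
  optional reverse-complement search.
- **Composition** — per-position A/C/G/T fractions over located,
  length-conserved targets only; length-discordant targets are counted as
  indels (reported separately and labeled `indel` in the allele table).
  A→G editing efficiency at a position is its `fG` fraction.
- **Outcome calls** — each observed target haplotype is translated codon by
  codon in coding orientation (reverse-complemented first when the CDS is on
  the '−' strand of the amplicon) and labeled `WT`, `synonymous`, `indel`,
  or slash-joined residue changes in protein coordinates (`L512P/S513P`).

## 4. Phenotype metrics (`phenotype_metrics`)

- `relative_mfi(raw, isotype, control)` = (raw/isotype) / control-ratio;
  control vs itself = 1 by construction.
- Killing indices on %GFP⁺ survivors A (mutant) and B (control):
  `index = 100 · (1 − [A/(100−A)] / [B/(100−B)])` — an odds-ratio form, so
  sensitivity(A=B)=0, sensitivity(0,B>0)=100, sensitivity(25,50)=66.7,
  resistance(75,50)=−200. Sensitivity and resistance share the formula;
  the two names document the direction of the planted expectation.
- `compare_groups` is a two-sided t-test (equal-variance by default, ≥2
  replicates per arm); `significance_stars` maps p to n.s./*/**/***/****
  at 0.05/0.01/0.001/0.0001.

## 5. Signature scoring (`signature_scoring`)

From a differential-expression table, the top `n_top` (default 250) genes by
Wald statistic in each direction are selected; weights are
`k_i = w_i / max|w|` over the selected genes (option `max_signed` divides by
the signed maximum instead). The per-sample score is `S = Σ k_i · X_i` with
`X_i = log2(TPM)`; genes absent from a profile contribute 0 and a
`low_coverage` flag is set when more than half the signature is missing.
Scores are raw weighted sums — no z-scoring by default — so linearity and
scale behavior are exact; standardize across a cohort downstream if needed.

Marker sets: MHC-I = {HLA-A, HLA-B, HLA-C, B2M}, PD-L1 = {CD274},
CTL = {CD8A, CD8B, GZMA, GZMB, PRF1}, matched case-insensitively; marker
scores are within-set means. `correlate_and_compare` reports Pearson r
against markers and a responder (PR/CR) vs non-responder (PD/SD) t-test.

## 6. Synthetic data (`synthetic_data`)

All generators take a `seed` and return ground truth with the data.

- **Toy proteomes** — random CDS from non-stop codons (ATG start, 30-bp
  flanks), rejection-sampled until ≥1 designable guide exists.
- **Screen counts** — defaults are the study conditions the screens model:
  top/bottom **10% gates**, **2 rounds** of sorting, **500 reads/iBAR**,
  **3 iBARs/guide**, NB noise via gamma-Poisson (Var = m + 0.05·m²) on a
  lognormal(σ=1) abundance backbone. Selection multiplies a guide's
  gate-capture odds by 2^effect per round; effect 2 gives expected
  lfc ≈ 2.69 under the defaults.
- **Amplicon reads** — planted haplotype fractions (or independent
  per-position rates), uniform substitution error (default 0.001), 150-bp
  pairs at Q38. `make_demo_amplicon` builds an in-frame target carrying
  L-S-Y codons so single-edit (Y514C) and co-edit (L512P/S513P) shapes are
  exercised.
- **Expression cohorts** — signature genes follow
  `X = baseline + activation·k + N(0, noise_sd)`; background genes are pure
  noise; marker genes optionally co-vary with activation.

**Scope and limitations.** The simulators are calibration instruments, not
biology: no guide-efficiency heterogeneity, no off-target editing, no PCR
jackpotting, no indel byproducts from the editor, no gene-level structure
linking guides. They exist to verify statistical behavior (FDR, power,
rate recovery) under a known truth.

## Numerical notes

- All RNG is `numpy.random.default_rng`; seeds stay below 2^31. iBAR
  assignment keys the generator with (seed, sha256(spacer)[:4]) so
  assignments are order-independent.
- BH correction via `statsmodels.stats.multitest.multipletests`; normal
  tails and t-tests via `scipy.stats`; FASTQ and translation via Biopython.
- `screen_score` is a monotone transform of a step-function (BH) statistic;
  comparisons between guides should use `z_combined` when strict ordering
  at equal adjusted p matters.
- Read merging compares overlaps as uint8 arrays, scanning long overlaps
  first and stopping once no shorter overlap can beat the best match count;
  50,000 pairs merge in seconds.
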