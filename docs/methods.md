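# Methods

## Problem and model

Cis-acting long non-coding RNAs tend to regulate genes near their own
transcription site. The screening model operationalises "near" as a linear
genomic window: an mRNA and a lncRNA on the same chromosome whose gene
spans lie within 50 kb of each other form a candidate HML (hepatic
mRNA–lncRNA) pair. Everything upstream of pairing is candidate selection
(differential expression, coding potential, pathway relevance); everything
downstream is evidence aggregation (network centrality, annotation
funnel) and experimental validation statistics. No mechanism is modelled:
a pair is a hypothesis generator, not a causal claim.

## Coordinate and distance conventions

- Internal coordinates are 0-based half-open. GTF input (1-based
  inclusive) is shifted by −1 on the start at read time and shifted back
  on write; BED input is taken as-is. A round trip through GTF preserves
  the printed coordinates exactly.
- Multi-record genes (exons, transcripts sharing a `gene_id`) are
  collapsed to their min-start/max-end span before any distance is
  computed; the analysis is at gene/locus resolution, not isoform
  resolution.
- Chromosome names are matched after stripping a leading `chr`, so
  Ensembl- and UCSC-style files can be mixed.
- Distance is the boundary gap between collapsed spans: 0 for overlapping
  or abutting loci, otherwise `max(starts) − min(ends)`. It is symmetric,
  strand-blind, and undefined (None) across chromosomes. A TSS-to-TSS mode
  exists for sensitivity analyses but is experimental: it inherits any
  strand-annotation errors, and the primary convention is boundary gap.
- The window comparison is inclusive (distance ≤ window pairs). The
  boundary semantics of "within 50 kb" are not fixed by common usage, so
  the inclusive rule is declared here and an exclusive flag is provided.
- Pairing is many-to-many: one lncRNA may pair with several mRNAs and one
  mRNA with several lncRNAs (the validated set itself contains a gene
  with two paired lncRNAs).

## Screening statistics

**Fold-change filter.** `|log2FC| > t`, default t = 2, strict inequality.
Absolute value is the default because the validated genes include a
downregulated one; a one-sided mode exists. log2 units are assumed for
the input contrast; the threshold is configurable if a source used a
different base. Output order is deterministic (|log2FC| descending, id
ascending).

**Coding-potential screen.** Preference order per candidate: an explicit
score-table label (`coding` removed; `noncoding`/`weak_coding` kept), then
the ORF heuristic on a provided sequence (coding-like if longest
ATG→stop ORF ≥ 300 nt or ≥ 30 % of transcript length, three forward
frames, stop codon included in the length), then retain-with-flag. The
heuristic is a deliberate desk-scale approximation of dedicated
coding-potential calculators: it ignores hexamer composition, conservation
and reverse-strand ORFs, and on short transcripts the 30 % rule is
aggressive. Retaining no-evidence candidates is a design choice: the
screen removes *strong* coding potential; absence of evidence is not
evidence of coding.

**Over-representation.** Upper-tail hypergeometric (one-sided Fisher),
each set intersected with the universe first, k = 0 reported as p = 1.
The universe defaults to all annotated mRNAs and is configurable — the
background of the original web-tool analysis is unknowable, so this is an
explicit substitute. An EASE-style variant (testing k − 1) is available
for closer agreement with the DAVID web tool. Multiple testing:
Benjamini–Hochberg at q = 0.05 by default; the raw p < 0.05 rule is
available by flag. Category tags (carbohydrate/lipid metabolism) propagate
from significant sets to their member genes; a gene in both categories is
the "dual-category" criterion of the funnel.

**Network and hub selection.** STRING-style combined scores (0–1000) are
rescaled to [0, 1]; edges below 0.4 ("medium confidence" — the source
analysis states no cutoff) are dropped. HML pairs contribute unweighted
edges that count toward degree; a PPI-only degree mode exists. Degree
centrality is deg(v)/(n−1). The shortlist funnel filters pair-bearing
mRNAs sequentially — target-pathway membership, dual category (or the
alternative "more than two pathways" reading, both implemented), annotated
paired lncRNA — then ranks by centrality with deterministic tie-breaks
(n_pathways, then id). Filters-then-rank is a declared resolution of an
ambiguous precedence; every stage logs before/after counts so the funnel
is auditable. An empty shortlist is a valid outcome, not an error.

## Validation statistics

- **ΔΔCT.** ΔCT = CT_target − CT_reference per sample; ΔΔCT subtracts the
  *mean* ΔCT of the calibrator (control) group — per-sample calibration is
  not possible across animals; fold = 2^(−ΔΔCT). Folds are invariant to
  any constant CT shift. Amplification efficiency is assumed to be the
  ideal 2 per cycle.
- **ANOVA.** One-way fixed-effects F test on folds across groups; means ±
  SEM (sd/√n). All-constant input degenerates to p = 1 with a warning
  rather than NaN. Pairwise Welch t-tests with BH correction serve as the
  post-hoc — a declared substitute, since the original letter-coded
  contrasts name only "ANOVA".
- **Pearson correlation** between paired mRNA and lncRNA log2 expression
  (−ΔCT) within a group; two-sided p from the t transform with n − 2 df;
  zero-variance input is an error, not a silent NaN.
- **ROC/AUC.** Rank-sum (Mann–Whitney) form with ties counted half;
  95 % CI from a stratified percentile bootstrap (2,000 resamples,
  seeded — the CI method of the source analysis is unstated).
- **HOMA-IR** = insulin(µU/mL) × glucose(mg/dL)/405, positive inputs
  required. A separate converter (default 25 µU per ng) handles ng/mL
  insulin, because published group tables in this field are sometimes in
  ng/mL while the index requires µU/mL; the conversion is never applied
  silently. Indeed, applying the printed formula to typical published
  group values in ng/mL yields a much larger index than the tables print —
  the simulated HOMA-IR summaries reflect the formula, not any such table.
- **Tolerance-test AUC.** Trapezoidal area over the measured span
  (0–120 min at 0/30/60/90/120), total area by default, baseline-subtracted
  (incremental) by flag, in mg/dL·min.

## Synthetic study generator

The generator's defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| n_mrnas / n_lncrnas | 5000 / 236 | catalogue sizes; 236 is the candidate lncRNA pool |
| frac_de | 0.08 | 400 mRNAs pass the fold-change screen |
| n_true_pairs | 10 | planted cis pairs within the window |
| true_pair_max_gap / decoy_min_gap | 40 kb / 60 kb | separability around the 50-kb window |
| funnel 5 → 4 → 3 | n_funnel_* | target-pathway, dual-category, annotated counts |
| group_sizes | 6 per group | Ctrl, HF-Sed, HF-Exe, Diabetic |
| effect_dct / ct_sd | 2.0 / 0.8 cycles | ≈4-fold group shifts, realistic qPCR noise |
| planted_rho | 0.70/0.86/0.76/0.76 | published prediabetic pair correlations |

Genes are laid out in blocks separated by ≥ decoy_min_gap; a planted
pair's lncRNA sits within true_pair_max_gap of its mRNA (a second lncRNA,
when planted, goes upstream). Because decoy_min_gap > window >
true_pair_max_gap, proximity pairing provably recovers exactly the
planted pairs — the construction is the oracle. DE magnitudes are
|N(3, 0.5)| resampled past the threshold (null features resampled below
it), so the planted pass-count is exact; p-values are a monotone transform
of |log2FC|. Expression: reference CT ~ N(15, 0.2); target ΔCT = class
baseline − direction × group multiplier × effect, with group multipliers
(Ctrl 0, HF-Sed 1, HF-Exe −0.3, Diabetic 1.5) encoding the published
pattern — up/down in the sedentary high-fat group, reversed slightly past
control by exercise, amplified in diabetes. Paired lncRNA noise is coupled
to the mRNA's as z_l = ρ·z_m + √(1−ρ²)·ε, so the within-group sample
correlation of −ΔCT concentrates on ρ (and equals 1 exactly at ρ = 1).
Phenotypes use published group means with SDs back-computed from SEMs at
n = 6. Every generator draws from its own seed substream; identical
configs produce byte-identical files.

What the generator does **not** emulate: real microarray effect-size and
noise distributions, correlated DE across linked genes, probe effects,
isoform structure, amplification-efficiency variation, and any real
genome's gene density. Passing tests therefore demonstrate that the
*method* recovers planted structure under its own assumptions — not that
the original biological findings are correct.

## Problem sizes and numerical choices

Recovery and calibration checks run at deliberately chosen sizes: oracle
equivalence on 20 genomes of 500 × 500 features; planted-pair recovery
over 50 seeds; hypergeometric exactness exhaustively for all N ≤ 30 (to
1e-12, integer-arithmetic oracle); null calibration with 1,000 replicate
draws at large parameters (where the discrete p-value distribution is
dense enough for a KS uniformity check to be meaningful); correlation
recovery at n = 500 within the 3(1−ρ²)/√n sampling bound, and the
study-condition direction/significance pattern at n = 30 per group over
100 seeds. The n = 6 preset is reported descriptively — at six animals
per group, correlation estimates are intrinsically unstable, which the
worked example shows honestly. Ties in ranking are always broken
deterministically (documented secondary keys), and degenerate inputs
(zero variance, empty shortlist, all-tied scores) have defined behaviour.

## Known limitations

- Boundary-gap proximity ignores strand, TADs and 3D contacts; "50 kb"
  between gene boundaries is one of several defensible conventions
  (boundaries vs midpoints vs TSSs) and is declared, not derived.
- The ORF heuristic is a coarse stand-in for model-based coding-potential
  scoring and should not be used where a score table is available.
- The enrichment universe, correction procedure and EASE behaviour are
  substitutes for an unknowable web-tool configuration.
- The 2^(−ΔΔCT) model assumes perfect amplification efficiency and a
  stable reference gene.
- Degree centrality is the only hub statistic, by design; mixing
  unweighted pairing edges with thresholded PPI edges makes the centrality
  scale depend on the pair set.
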