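# Methods

## Scores and rules

**Fold-change screen.** For a miRNA expression row `x` over the 12
tissues, the single-tissue fold in tissue *t* is
`x_t / mean(x over the other 11 tissues)`; a call is made when the fold
reaches the threshold (default 80). The denominator is the arithmetic mean
of the other tissues, not the median or a trimmed mean. When no single
tissue passes and dual calls are enabled (`max_tissues = 2`, the default),
the two highest-expressing tissues are called jointly iff
`min(top-2) / mean(remaining 10)` reaches the same threshold. The dual
rule exists because a strictly single-tissue 80-fold criterion cannot, by
construction, call a miRNA that splits its expression between two tissues
(each tissue's own fold is diluted by the other's high value); the top-2
variant is the minimal extension that preserves the single-tissue
semantics as a special case. At most one call is made per miRNA; all-zero
rows are skipped with a warning. The looser 20-fold convention used elsewhere in the
literature is available by passing `fold_threshold=20` — the threshold is a
parameter, not a constant.

**TSPV / TSVT.** With `f_b = (x_b + ε) / Σ(x + ε)` the expression
fraction in tissue *b*, `TSVT_b = log2(f_b)` and `TSPV = Σ_b TSVT_b`.
Logs are base 2: only base 2 reproduces the uniform-expression maximum
`12·log2(1/12) = −43.0196`, the score's defining anchor. Every TSVT is
≤ 0, `Σ_b 2^TSVT_b = 1`, and the score is invariant to rescaling the row.
The pseudocount ε defaults to `1e-9 × row sum` and is applied only when a
cell is zero (log2(0) is undefined); positive rows are scored exactly.
TSVT > −2.5 (strict) flags the entity as specific in a tissue. TSPV
categories use half-open bins: medium `[−120, −80)`, low `[−80, −60)`,
non-tissue-specific `[−60, 0]`; "high" covers everything below −120,
including values under the nominal −160 edge, since lower TSPV only means
stronger specificity (near-zero cells can push TSPV far below −160).

**Clusters.** Per (chromosome, strand), loci are sorted by start and
chained while the inter-locus gap `next.start − current_end` (floored at 0
for overlaps; `current_end` is the running maximum end) is ≤ 10,000 bp.
Gaps of exactly 10,000 join. Singletons are not clusters. The caller is
invariant to input order and to uniform translation of coordinates.

**TSS and promoters.** TSS priority: experimental table → the cluster's
5′-most coordinate (span start on +, span end on −) → the locus's own 5′
coordinate. Promoters are strand-aware: `[tss−5000, tss+1000)` on +,
`[tss−1000, tss+5000)` on −. "Upstream" follows the transcribed strand;
the window definition itself says nothing about strand, but a TSS implies
transcription directionality, and a strand-blind window would
place 5/6 of the window downstream of minus-strand genes. Windows are
clamped at chromosome edges rather than discarded (a clamped promoter
still has most of its sequence). All coordinates are 0-based half-open
(BED convention), so abutting intervals do not overlap and a 1-bp overlap
is the minimum that counts.

**Scan.** A TF→miRNA relation is a deduplicated (TF, promoter-owner) pair
supported by ≥ 1 binding site overlapping the promoter by ≥ `min_overlap_bp`
(default 1); site multiplicity is kept as an edge attribute, because the
interesting count is regulatory relations (pairs), not sites. The
implementation uses per-chromosome interval trees; tests compare it
against a brute-force all-pairs oracle at 10⁴ × 10⁴ scale.

**Binding profile.** The 6-kb TSS-relative window is cut into 200-bp bins
(30 bins). A site increments **every** bin it overlaps — a site spanning k
bins counts k times — and each tissue's bin counts are divided by that
tissue's total site count and scaled to percent. Percentages can therefore
sum above 100; counting per overlapped bin is deliberate — it is what
makes wide sites visible in several bins. Offsets are transcription-oriented (they run against the genome on
the minus strand). Tissues with zero sites are returned as flagged
all-zero rows, not dropped.

**Tissue occurrence.** In which tissues can a TF→miRNA relation occur?
The inputs carry only one per-tissue signal for a TF — its expression — so
the rule is parametric: the relation occurs in tissue *t* when the TF's
copy number there is strictly above `presence_threshold` (default 0). The
histogram bins relations by occurrence count; a 0 bin holds relations of
TFs expressed nowhere so that the histogram always conserves the number of
scored edges.

**Targets.** Verified-first: if a miRNA has any experimentally verified
targets, exactly those are used and predictions are ignored; otherwise
predicted targets with total context score strictly below −0.3 are used
(−0.31 passes, −0.30 does not — the cutoff is printed as a strict
inequality). The verified branch is unaffected by the cutoff, and the
operation is idempotent.

**Enrichment.** Per tissue *t*, the 2×2 table crosses membership in *t*'s
target set against the specific-in-*t* gene label over the background
universe; Fisher's exact test is two-sided by default (the more
conservative choice when no direction is pre-registered; one-sided
"greater" is an option), via `scipy.stats.fisher_exact`. Significance is
flagged on raw p-values at 0.05; Benjamini–Hochberg adjusted values across the 12
tissues are reported alongside for rigor. A per-tissue 2×2 design was
chosen over pairwise tissue comparisons (the phrase "between 12 tissues"
is ambiguous); the pairwise variant is deliberately not implemented.
Tests pin the p-values to an exact rational-arithmetic hypergeometric
enumeration oracle at 1e-10.

**Network.** TF→miRNA, TF→gene and miRNA⊣gene edges are directed; PPI
edges are semantically undirected and stored once. TF→gene edges are
produced in-repo by reusing the promoter construction + scan on gene TSSs
with the same 5 kb/1 kb window, replacing the external regulatory-domain
assignment step with the identical geometric rule. TF→miRNA and
miRNA⊣gene edges are attributed to the miRNA's specific tissue(s);
TF→gene and PPI edges are tissue-agnostic by default (no per-tissue
signal attaches to them directly; an expression-presence filter could be
layered on), so they appear in every per-tissue
view — per-tissue graphs are always edge-subsets of the "all" graph. An
entity typed both miRNA and TF/gene across layers is an error; a TF that
is also a target gene or PPI protein keeps type `tf`.

## Synthetic data

The generators are pure functions of `FixtureConfig`; identical configs
give identical outputs (independent seed streams per generator, so the
three fixtures can be generated in any order).

* **Genome**: one synthetic chromosome (20 Mb default) — cluster and
  promoter logic is chromosome-local, so multiple chromosomes add no
  coverage. Cluster blocks of `cluster_size` same-strand loci with
  intra-gaps ≤ 2 kb; blocks separated by > 50 kb, so the 10-kb caller
  recovers exactly the planted clusters. Defaults (10 clusters of 3 among
  60 miRNAs) put half of all miRNAs in clusters, matching the roughly
  half-clustered structure of the real catalog. TFBS widths are uniform
  in [50, 400) bp (ChIP-seq peak scale, wide enough to span bin
  boundaries); per-promoter site counts are Poisson (rate 3), offsets
  drawn 70/30 from a near-TSS mode (σ = 300 bp around −150) and a distal
  mode at −3.5 kb (σ = 200 bp), mimicking the proximal enrichment plus
  secondary upstream mode seen in real occupancy profiles; 200 background
  sites are scattered uniformly.
* **Expression**: multiplicative log-normal noise (σ = 0.3) around a
  common baseline keeps all values positive; a planted entity's home
  value is set *exactly* to `planted_ts_fold × mean(others)` (fold 100 by
  default, above the 80 screen), so fold recovery is arithmetic, not
  statistical. One TF row is exactly constant — the uniform-TSPV control.
* **Targets**: each gene is labelled specific in one uniform tissue with
  probability 0.6; each tissue's 200 targets are sampled without
  replacement with genes labelled in that tissue weighted by
  `enrichment_effect` (5 by default). At effect 1 targeting is
  independent of labels — the null used to calibrate the Fisher test's
  type-I error (empirically ≈ 0.04 at the 0.05 level over 500 null
  fixtures; slightly conservative, as expected for an exact test on
  discrete tables). Planted miRNAs are wholly verified-evidence or wholly
  predicted-evidence so that verified-first selection recovers the
  planted sets exactly; chaff predictions above the −0.3 cutoff exercise
  the filter.

What the fixtures do **not** emulate: real genome sequence, motif
content, hairpin structure, inter-tissue expression correlation,
cell-line heterogeneity of ChIP-seq peaks, or the curation biases of real
target databases. Passing tests therefore demonstrate the correctness of
the rules and statistics, not the biological accuracy of any particular
real-data result.

## Problem sizes in the test suite

Scan-oracle equivalence runs at 10⁴ promoters × 10⁴ sites; the Fisher
oracle enumerates every table with total ≤ 14 and several hundred random
tables with margins ≤ 50; the null type-I simulation uses 500 fixtures of
2,000 genes × 200 targets per tissue; the power check uses 100 fixtures at
effect 5. These sizes make the full suite run in a couple of minutes while
leaving the statistical assertions well-powered.

## Known limitations

* Binding-profile percentages are per-bin ratios, not a distribution;
  they need not sum to 100.
* The dual-tissue screen is a design extension (see above); curated call
  lists can be supplied downstream to bypass screening entirely.
* Pairwise-tissue Fisher comparisons are not implemented.
* The pipeline assumes all inputs share one genome assembly; there is no
  liftover.
* The curated catalog's heart row yields 7/10 clustered miRNAs while its
  brain row yields 4/28; the two rows' clustering levels differ sharply
  and only the recomputed per-tissue fractions are asserted anywhere.
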