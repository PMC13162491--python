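# Methods

This note records the models implemented by `colonyevo`, their assumptions,
the defaults that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely open.

## Mutation classes and site counting

Single-base substitutions are binned into six unordered base-pair classes
(AT→CG, AT→GC, AT→TA, CG→GC, CG→TA, GC→TA). The binning is strand-symmetric:
a substitution and its complement (A→C and T→G; C→T and G→A; C→A and G→T ...)
fall in the same class, so observed counts are independent of which strand a
variant caller reports.

Substitution *opportunities* are enumerated exhaustively: for every
nucleotide of every CDS and each of its three alternative bases, the affected
codon is translated before and after the change. A synonymous change
increments the class total Sᵢ, any amino-acid-changing or stop-gaining
change increments Nᵢ. This yields the conservation identity
Σᵢ(Sᵢ+Nᵢ) = 3 × counted coding length, which is asserted as an invariant.

Counting conventions (all recorded in the table's `options` field):

- **Genetic code**: NCBI translation table 11 (bacterial), configurable;
  the organisms of interest are enterobacteria.
- **Start codons** are translated like any other codon: site counting
  concerns substitution effects, not initiation.
- **Terminal stop codons** are excluded by default. When included
  (`include_terminal_stop=True`), stop→stop counts as synonymous and
  stop→sense as non-synonymous. Exclusion is the conventional choice; the
  flag exists because the alternative is defensible and the difference is
  three sites per gene.
- **Overlapping CDS**: each genomic site is counted once per CDS context,
  matching the per-gene semantics of "possible sites".
- **Ambiguity codes** (N, ...) cannot be classified; the position is skipped
  and tallied in `skipped_positions`.
- **Coordinates**: external formats keep their native 1-based inclusive
  conventions (GFF3, GenBank, Genome Diff); reported positions are 1-based.

Effect classification is cross-checked in the test suite against an
independent oracle that mutates every position and re-translates the whole
CDS with Biopython, with exact equality required on all twelve table entries.

## Ka/Ks estimators

With observed per-class counts sᵢ (synonymous) and nᵢ (non-synonymous,
nonsense included) and site totals Sᵢ, Nᵢ:

| estimator | formula |
|---|---|
| crude | Σnᵢ / Σsᵢ |
| uncorrected per-site | (Σnᵢ/ΣNᵢ) / (Σsᵢ/ΣSᵢ) |
| corrected via synonymous sites | Σnᵢ / Σᵢ(Nᵢ·sᵢ/Sᵢ) |
| corrected via non-synonymous sites | Σᵢ(Sᵢ·nᵢ/Nᵢ) / Σsᵢ |

All four are point estimators over the whole catalog (no per-gene values, no
alignment-based codon models, no multiple-hit correction — the method is
count-based against a fixed reference). Sums run over all six classes;
classes with zero counts contribute zero.

Degenerate classes: a class with Sᵢ = 0 has necessarily sᵢ = 0 and its
0/0 term in the synonymous-site correction is dropped and recorded in
`excluded_classes`; analogously for Nᵢ = 0 in the non-synonymous-site
correction. A positive count in a zero-opportunity class means the counts
and the site table describe different genomes and raises.

An optional bootstrap (off by default, `fit(bootstrap=B)`) resamples the
observed mutations with replacement and reports percentile intervals; the
headline outputs are point values. Ratios are printed to two decimals;
machine outputs keep full precision.

### Small-sample behaviour and the recovery benchmark

Under the generative model below, both corrected estimators target the
selection parameter ω exactly *in expected counts*. Applied to a single
small catalog they are ratio estimators and inherit the usual O(1/m) Jensen
bias: at 50 mutations per catalog the per-replicate estimates run ~5–6%
high (measured over 200 replicates). The recovery benchmark therefore
averages the per-class counts over replicates before forming the ratio —
the consistent replicate-mean estimate — and compares its deviation from ω
with the Monte-Carlo standard error of the replicate distribution. Measured
at the benchmark conditions (12-CDS genome, 10:1 transition-biased
spectrum, 200 replicates × 50 mutations): corrected estimators 0.99–1.06 at
ω = 1 and 0.30 at ω = 0.3, while the crude ratio sits near the
spectrum-weighted ΣN/ΣS (≈ 2.2–2.3) and the uncorrected per-site ratio is
biased in the opposite direction (≈ 0.69). Users applying the corrected
estimators to catalogs of ~15–50 mutations should expect the same few-percent
upward bias; it is a property of the formula, not of this implementation.

## Mutation catalogs

The catalog layer consumes variant-caller output; it never calls variants.
Two dialects are read and written:

- A minimal subset of the breseq Genome Diff format: mutational entries
  SNP → SNS, INS → insertion, DEL → deletion (typed `large_deletion` at
  ≥ 100 bp), MOB → IS insertion. AMP and unknown entry types are skipped
  with a logged warning and a tally; evidence lines (RA/JC/MC/UN) are
  ignored. GD SNP lines do not carry the reference base; annotation fills
  and verifies it.
- A flat TSV with header `isolate, position, type, ref, alt, element, size,
  genes, region, effect, seqid, is_mediated`.

Coding effects are filled by `annotate_effects`, strand-aware (for
minus-strand CDS the alternative base is complemented before codon
substitution). A recorded reference base that disagrees with the reference
genome is an **error**, not a warning: silently mis-annotated effects would
corrupt Ka/Ks downstream. IS-mediated large deletions keep
`is_mediated=True` so "IS-mediated event" tallies can include them alongside
IS insertions; both the insertion-only and the mediated-inclusive counts are
derivable from the summary.

A *distinct mutational event* is a unique (contig, position, type, change)
tuple; the same event observed in several isolates counts once toward the
event total and once per isolate in the per-isolate counts.

The observed crude ratio of a catalog can differ depending on whether
nonsense and missense totals are taken from the effect breakdown or from a
separately stated non-synonymous total; the package always reports the
counts it derived (`tally_spectrum`) and leaves externally printed totals to
the caller.

## Competition analysis

CIC = (A_mutant/A_reference) / CIC_pa with CIC_pa the **arithmetic** mean of
control-pair ratios (the assay's stated convention). Colonies with a zero
focal-strain measurement get CIC = 0 and are excluded from log-scale tests
with an explicit exclusion count — never silently dropped.

Inference is on log₂ ratios: mean, SD, t = mean/(SD/√n), df = n−1, two-sided
p from the t distribution; fold change 2^mean; Wilcoxon signed-rank
two-sided p as a robustness check (exact null for n ≤ 25 without ties,
normal approximation with continuity correction otherwise; zero differences
dropped per the Wilcoxon convention). Zero log-scale variance is flagged
degenerate and no p is reported. For direct pairwise competitions the same
machinery runs on per-colony log₂(a/b), with mean ± SD of both strains
reported on the original scale alongside (the compositional-data
convention: test on the unconstrained scale, describe on the original one).

Known interaction: the arithmetic-mean normaliser and the geometric-mean
fold estimator disagree by a factor exp(−(σ·ln2)²/2) under multiplicative
lognormal noise with log₂-scale SD σ — about 1% at the assay-scale σ = 0.22,
about 6% at σ = 0.5. At realistic noise this is negligible; at high noise,
fold-change recovery saturates short of the true ratio by this factor.

## Association statistics

Spearman rank correlation uses average ranks for ties and the conventional
t approximation t = r_s√((n−2)/(1−r_s²)), df = n−2 for the two-sided p — the
behaviour of standard statistical software at the study-scale n = 24, where
the approximation's type-I error is within Monte-Carlo error of nominal
(checked by permutation in the test suite). An exact permutation option
exists for n ≤ 10. Missing values are excluded pairwise with reported
counts. Welch's t (two-sided, Welch–Satterthwaite df, reported to one
decimal) compares log₂-transformed trait values between groups; positivity
is enforced before the transform.

## Gene-set enrichment

Exact hypergeometric upper tail P[X ≥ k] for an overlap of k genes between
a module of n and a target set of K genes in a universe of N, accumulated
via log-sum-exp so p-values down to ~1e-300 are representable. Expected
overlap n·K/N and fold k/expected are reported with the p-value. The
universe is a required explicit input and is never inferred from the union
of the two sets: the result is sensitive to N and a silently inferred
universe invites overstatement. Enrichment (upper tail) is the default; a
depletion tail is available behind a flag. No multiple-testing machinery is
included — this is a single-comparison tool.

## Synthetic-data generators

All generators are deterministic under one global seed, expanded into fixed
per-generator substreams, and emit files that round-trip through the
package's readers.

- **Genomes**: `num_cds` CDS (default 40, lengths uniform over 150–900 nt in
  codon steps, GC 0.51 — enterobacterial scale, desk-sized) placed with
  random spacers on one contig, on both strands; each CDS starts ATG, ends
  with a stop, contains no internal stop.
- **Mutation catalogs**: proposals (position, alternative base) drawn with
  probability ∝ the class weight βᵢ of the substitution; synonymous
  proposals always accepted, non-synonymous accepted with probability ω;
  emission continues until `n_mutations` (default 50, the replicate size of
  the recovery benchmark) are accepted; the generator records its true
  per-class counts for oracle checks. Because the proposal distribution is
  exactly the class-weighted opportunity measure, E[sᵢ] ∝ βᵢSᵢ and
  E[nᵢ] ∝ ωβᵢNᵢ, making ω the exact target of the corrected estimators.
- **Competition**: reference measurement lognormal around a 20 mm² baseline;
  focal measurement = ρ·b·2^ε with ε ~ Normal(0, σ²), σ = 0.22 and
  n = 4 colonies + 4 controls by default (assay-scale effect/noise/size);
  controls use ρ = 1; a proportion modality normalises pairs to sum to one.
- **Gene sets**: universe of N = 4175, targets K = 713, module n = 243 by
  default (study-scale set sizes; N chosen as a round enterobacterial
  gene-universe scale). With planted fold φ = 1 the module is a simple
  random sample — the exact hypergeometric null; otherwise the number of
  target genes in the module is Binomial(n, φK/N) clipped to feasibility,
  giving expected overlap φ·nK/N.

What the generators do **not** emulate: read-level sequencing error and
variant-calling uncertainty, IS transposition mechanics and hotspots,
spatial colony structure, linkage between mutations within an isolate, and
transcriptome structure. Passing recovery and calibration tests therefore
demonstrates correctness of the estimators and tests under their stated
sampling models, not robustness to upstream artefacts in real data.

## Test-suite conventions and problem sizes

Simulation-backed tests run at fixed seeds with desk-scale problem sizes:
12-CDS genomes for estimator recovery (200 replicates × 50 mutations),
2,000 simulated 4-colony experiments for t-test calibration, 10,000
permutations at n = 24 for Spearman calibration, exhaustive enumeration up
to N = 15 for the hypergeometric oracle, and 200 random CDS up to 300 nt
for the site-counting oracle. Calibration assertions use binomial 99%
bands; recovery assertions use Monte-Carlo 95% intervals as described
above. The discrete hypergeometric p-value is calibrated through the
standard randomised-p construction (P[X > k] + U·P[X = k]), since the raw
upper tail of a discrete statistic is superuniform by construction.

## Known limitations

- No per-gene or alignment-based dN/dS; the estimators are global and
  reference-anchored, appropriate for sparse catalogs from short
  experiments, not for divergent sequence comparisons.
- Frameshift consequences, regulatory effects and RNA genes are out of
  scope; indels and IS events enter tallies but not the Ka/Ks counts.
- The corrected estimators' few-percent small-sample bias (above) applies
  to any single catalog of tens of mutations.
- The printed t statistic of a published mean ± SD pair cannot always be
  reproduced from those two numbers; the package reports the
  formula-consistent t = mean/(SD/√n) and does not attempt to match
  externally printed statistics.
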