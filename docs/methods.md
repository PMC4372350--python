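# Methods

## Problem and model

The package labels every residue of a protein sequence as CRITICAL or
NONCRITICAL, where the critical region (core) of an antimicrobial peptide
is the shortest experimentally supported segment retaining activity. The
training signal comes from *nested families*: sets of ≥ 2 sequences
related by substring containment. The core of a family is its shortest
member, required to be a substring of every other member and 7–40 residues
long; families whose candidate core falls outside that range, or that have
no member contained in all others, are rejected with a typed reason
(`TOO_SHORT`, `TOO_LONG`, `NO_COMMON_MEMBER`). Labels are marked on the
carrier (the longest member). When the core occurs more than once in the
carrier, the leftmost occurrence is labeled and a warning records the
multiplicity — a deterministic choice; the alternative (labeling every
occurrence) would break the one-contiguous-run invariant that the
evaluation assumes. Ties for the longest member are broken by
lexicographically smallest id. All coordinates are 0-based, half-open.

Family construction takes the connected components of the containment
relation and keeps those containing a member that is a substring of all
others; remaining sequences are reported as orphans. Grouping is
order-invariant. Sequences containing nonstandard letters (B, J, O, U, Z —
normalized to X) stay parseable but are excluded from family building,
since the model's alphabet is the 20 canonical residues.

Representative selection (for low-redundancy datasets) is greedy
incremental clustering by decreasing length: a carrier joins the first
cluster whose seed it matches at more than the identity threshold (default
0.70), else founds a new cluster; seeds are returned. Identity is matched
residues divided by the length of the shorter sequence, with matches taken
as the better of the best gapless diagonal and a gap-tolerant
maximal-matches global alignment.

## Observation channels

Eight per-residue categorical tracks feed the CRF. All are pure functions
of sequence plus configuration.

| channel | alphabet | construction | key defaults |
|---|---|---|---|
| PRIMARY | 20 letters | the residue | — |
| SS | H/E/C | external per-residue prediction, or built-in fallback | window 5 |
| DOMAIN | IN/OUT | union of supplied conserved-domain intervals | all OUT if none |
| ALIGN | IN/OUT | coverage by accepted gapless BLOSUM62 hits | norm. score ≥ 2.5, run ≥ 7 |
| AMPA | IN/OUT | runs of low windowed bactericidal propensity | window 7, threshold 0.225, min stretch 4 |
| AGGR | IN/OUT | aggregation hot spots on windowed propensity | ladder 5/7/9/11, threshold −0.02, min run 5, proline breaks |
| CHARGE | LEADING/POSITIVE/NONPOSITIVE | net charge of the N-mer ending at the residue | N = 7 |
| AMPH | IN/OUT | membership in a high-moment window | window 10, 100°, μH ≥ 0.35 |

Net charge is count(K, R) − count(D, E); histidine is not counted positive
by default (`count_his_positive` flips this for sensitivity analysis). The
first N−1 positions of the charge track carry the LEADING symbol because
no full window ends there.

The hydrophobic moment of a window of length N is
μH = (1/N)·|Σₙ Hₙ e^(i n δ)|, n = 0…N−1, with δ = 100° per residue for an
α-helix and Hₙ the Eisenberg consensus hydrophobicity. The AMPH cutoff
0.35 is a conventional amphipathic-helix threshold on that scale; the
upstream tool reports a moment but no binarization cutoff, so the value is
explicit configuration. μH is invariant under sequence reversal (the sum
conjugates), which the tests assert to 1e−12.

The gapless search scans every query × core diagonal for maximal runs in
which each aligned pair scores ≥ 0 under BLOSUM62 (loaded from Biopython's
packaged NCBI matrix); a run's raw score is the sum of pair scores and its
normalized score is raw/length, the ranking key. Implementation detail:
the core database is concatenated with sentinel separators that score −1
against everything, so run bookkeeping is a single vectorized recurrence
over query rows instead of a per-diagonal loop; results are identical to
the brute-force all-offsets scan (asserted on random instances).
Acceptance thresholds for the ALIGN track (normalized score ≥ 2.5 over ≥ 7
residues) discard short incidental runs whose per-residue scores are
inflated; both are configuration.

The continuous profiles (AMPA, AGGR, AMPH) are binarized to IN/OUT because
the CRF consumes categorical observations; the IN regions are the
segments the respective tools would report. Windowed means at the sequence
ends use truncated windows. The built-in secondary-structure fallback is a
deliberately simple propensity smoother (window-averaged Chou–Fasman helix
and sheet propensities; H when the helix average exceeds 1.0 and
dominates, E when the sheet average does, else C). It is lower fidelity
than a neural predictor and exists so the pipeline runs self-contained;
external per-residue predictions are used when supplied and are validated
for length.

All propensity scales ship as plain-text files with provenance headers
(`eisenberg.scale`, `ampa_pv.scale`, `aggrescan_a3v.scale`); no network
access occurs anywhere.

## The CRF

Labels are ordered (CRITICAL, NONCRITICAL); a virtual BEGIN label anchors
transitions at position 0 and there is no explicit END state, keeping Z
exact while matching the common toolkit treatment. Feature templates use
the CRF++-style U/B grammar over the eight track columns at offsets −2…+2
(the size-5 window). Every distinct instantiated observation pattern is
paired with every label (state features) or with every label bigram
including BEGIN (transition features). Out-of-range offsets produce
explicit boundary tokens (`_B-1_`, `_B+1_`, …) so the model sees begin/end
context rather than truncated windows.

Two template sets are packaged: `default` (all 8 channels × 5 offsets,
a PRIMARY residue bigram at offsets −1/0, and the pure label-transition
feature) and `reduced` (full window on PRIMARY, focus position only for
the derived channels). The reduced set trains several times faster and is
the default for the moderate corpus sizes used in the shipped evaluations;
both files are plain text and swappable.

Inference is exact: forward–backward and Viterbi in log space with
max-shifted log-sum-exp. Viterbi ties resolve toward the first label in
the declared order, applied consistently in the backtrace (so an all-zero
model yields an all-CRITICAL path, a documented convention rather than an
accident). Training minimizes the negative conditional log-likelihood plus
Σλ²/(2σ²) (default σ² = 10; the regularization constant of the original
toolkit is not documented, so it is explicit configuration) with SciPy's
L-BFGS-B. The objective is convex; weights start at zero and no randomness
enters training, so identical inputs give bit-identical models. The
gradient is model-expected minus empirical feature counts plus λ/σ²,
verified against central finite differences (relative error < 1e−5) and,
for the normalization itself, against exhaustive enumeration of all 2ⁿ
labelings for n ≤ 12 (|Δ log Z| < 1e−8). The whole training corpus is
padded into batched arrays (pattern-id tensors per sequence) so each
objective evaluation is a handful of vectorized recurrences; per-cell
scatter uses bincount.

Model files are versioned text (label order, templates, pattern strings,
`repr`-formatted weights) and round-trip bit-exactly. Patterns unseen at
training time score zero at prediction.

## Evaluation protocol

Residue-level confusion counts take CRITICAL as positive. Metrics:
sensitivity TP/(TP+FN), specificity TN/(FP+TN), accuracy (TP+TN)/total
(all reported as percentages), and MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)
(TN+FP)(TN+FN)). When a marginal is zero the MCC denominator vanishes; the
conventional value 0 is returned with a `degenerate_mcc` flag.

Cross-validation splits *families* across folds (sizes differ by ≤ 1,
deterministic in the seed, invariant to input order), never residues or
carriers of one family — residue-level splitting would leak near-duplicate
context. Confusion counts are pooled over folds and the metrics computed
once, because single summary numbers per configuration are wanted;
per-fold rows are retained so the averaged view stays recoverable. The
ALIGN channel is recomputed per fold against the training-fold core
database only: a held-out carrier must not be allowed to align against its
own family's core. The ablation harness reuses the per-fold tracks across
all nine configurations (full set plus each single-channel removal, the
removal implemented by dropping every template referencing the channel).

## Synthetic families

The generator emulates the statistical structure the labeler needs, not
microbiology. A core is drawn with length uniform in [7, 40]; residues are
placed on an ideal helical wheel (360/3.6 = 100° per residue, random
starting phase): positions facing one side take hydrophobic residues
(L/I/F/V/A/W/G), the other side takes K or R with probability 0.45 (K:R ≈
60:40) and otherwise polar residues with glycine enriched and D/E/M nearly
absent. This yields cores that are cationic (mean net charge ≈ +4 at
typical lengths), periodically amphipathic, and glycine-rich. Flanks are
drawn from a packaged background frequency table (Swiss-Prot average
composition) with 15% extra acidic mass mixed in, making the background
predominantly neutral/acidic. Families have 2–4 members: the core itself
plus extensions embedding the core exactly once between random flanks of
5–30 residues; member lengths are kept distinct so the carrier is
unambiguous, and a family is redrawn if its core appears inside another
family's members (which would merge containment components). A boundary
bias mode tilts the joint distribution of the (P(−1), P1) pair toward
(R, G) by rejection sampling, giving that cell a 2×2 odds ratio equal to
the configured value exactly.

One RNG stream (`numpy.random.default_rng(seed)`) drives a whole corpus;
the manifest records the configuration and per-family truth, and identical
seeds reproduce byte-identical corpora.

What the generator does **not** emulate: homology between families (each
family is independent, so the ALIGN channel carries less information than
it would on a real redundant collection), realistic secondary-structure
labels (the SS track comes from the fallback predictor), domain
annotations (DOMAIN is uninformative without external input), sequencing
noise, or any activity values. Passing tests therefore demonstrate that
the machinery is correct and that the labeler recovers planted signal of
realistic shape — not field performance on real AMP collections.

## Boundary coupling

For each labeled carrier with a non-empty flank on the requested side, the
analysis takes the residue pair across the core boundary (N side: last
flank residue and first core residue; C side: last core residue and first
residue after the core; terminal cores are skipped for that side). The
20×20 cell for pair (a, b) gets log((obs + c)/(exp + c)), natural log,
where exp is the product of the observed marginal frequencies times the
number of boundaries. The pseudocount c defaults to the mean count per
cell (n/400, floored at 0.5): a flat sub-count pseudocount lets cells with
expected counts below one reach |log-odds| > 1 by sampling noise alone and
dominate the ranking, while shrinkage on the scale of the average cell
keeps the ranking governed by well-supported cells and still vanishes in
relative terms as n grows. A flat pseudocount remains available as an
explicit argument. Note the statistic measures departure from
independence: if *every* boundary were the same pair, the marginals alone
would explain the cell and its log-odds would be 0 — enrichment is only
visible against mixed boundaries.

The background population for the descriptive distributions is the full
carrier by default (switchable to non-critical residues only). The
amphipathicity distribution summarizes each population by the mean
windowed moment over all full windows — a coherently periodic segment
scores high even though any long carrier contains some amphipathic
stretch; a maximum-over-windows statistic would be monotone under
inclusion and could never separate a core from its own carrier.

## Problem sizes in the shipped evaluations

The packaged evaluations use corpus sizes at which the measured quantities
are stable: 300 families (10-fold CV and ablation, reduced templates,
≤ 60 L-BFGS iterations per fold), 1000 families for core-recovery rates,
and 2000 boundaries for the coupling analysis. The acceptance script
derives independent sub-seeds from its `--seed` argument for each stage.

## Known limitations

- The secondary-structure fallback is a propensity smoother; on real data
  an external per-residue predictor should be supplied.
- The AMPA/AGGRESCAN/moment binarizations follow the cited tools'
  published defaults but are approximations of those tools' full output
  conventions (e.g., truncated rather than undefined end windows).
- Greedy identity clustering matches the common tool's convention
  (identity over the shorter length, length-sorted seeds) but is not a
  re-implementation of its word-filter heuristics.
- The CRF is first-order linear-chain; long-range label dependencies are
  only captured through observation windows.
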