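# Methods

## Model and procedure

`grnrewire` treats a gene-regulatory network as a directed bipartite-ish
graph from TF *families* to target genes.  The evidence for an edge is
physical and local: an open-chromatin peak that (a) is annotated to the
target gene and (b) contains a binding-motif occurrence for the family.
Condition labels on edges come from the differential status of their
supporting peaks, so "rewiring" between two conditions reduces to set
differences of (family, gene) keys.

The stages, their contracts, and the defaults that matter:

### Peak union and counts

Peaks from all samples are extended and merged per chromosome
(overlapping *or book-ended* extended intervals merge, the usual genome-
arithmetic convention).  Two extension conventions are supported and tied
to the `mode` switch so that per-assay defaults are never mixed silently:

| mode  | extension            | fold threshold k |
|-------|----------------------|------------------|
| dnase | interval ends ±200 bp| 3                |
| chip  | summit ±100 bp       | 2                |
| atac  | interval ends ±200 bp| 2                |

A merged peak's summit is the summit of the member with the highest raw
count (leftmost on ties — deterministic and count-justified); member ids
are kept as provenance and per-sample counts are summed.  Peaks with fewer
than `min_summit_reads = 10` reads at the summit are removed ("less than",
so exactly 10 is kept).  Tags-per-million normalization divides by the
supplied library total when given, else by the per-sample sum over the
union (in which case normalized values sum to 1e6 by construction); the
divisor used is reported.

The differential rule is a plain pseudocounted fold change on per-condition
means: `fold = (mean_A + c)/(mean_B + c)`, specific-to-A iff `fold ≥ k`,
specific-to-B iff `fold ≤ 1/k`.  The pseudocount defaults to `c = 1`
(in the counting units actually compared): zero-denominator peaks are
otherwise undefined, and `c = 0` reproduces the raw ratio when wanted.
Replicates are averaged arithmetically.  Both normalized and raw counts can
drive the rule — published analyses of this kind have used either — and
neither is privileged.

### Annotation

HiC first: a peak overlapping (≥1 bp) a promoter-capture link's anchor is
assigned that link's gene; all overlapping links count, so a peak can feed
several genes.  The whole peak interval is tested, not just the summit,
because anchors are typically wide restriction fragments.  Every remaining
peak falls back to the closest TSS by |summit − TSS|, ties broken by
lexicographically smallest gene id; there is no distance cap by default (an
optional cap yields explicit "unassigned" labels).  The two methods
partition the peak set and every peak ends up assigned.

### Motif scanning

PWMs are stored as per-position base probabilities.  A pseudo-frequency
(default 0.01) is added to every raw matrix entry before column
normalization, which keeps log-odds finite for zero counts.  Scores are
`Σᵢ log₂(pᵢ(bᵢ)/q(bᵢ))` against a background `q` (uniform by default; a
genome-composition background can be computed from the supplied FASTA).
Both strands are scanned — the reverse strand scores the reverse complement
— and windows containing N are skipped.  A window is reported at
`score ≥ threshold_fraction × max_score` with `threshold_fraction = 0.8` by
default (per-motif thresholds of the common external scanners are not
published; 0.8 of the maximum achievable log-odds is a conventional,
configurable choice).  Same-position opposite-strand duplicates collapse to
the better strand; distinct positions are all kept, since edge inference
only needs presence, not masking.

Enrichment of a motif in a foreground peak set against a disjoint
background uses peak-level presence (≥1 occurrence) and the upper-tail
hypergeometric p-value of drawing the foreground from the pooled universe.
Paired-motif spacing collects |centerA − centerB| over all cross pairs
within each shared peak (centers are `floor((start+end)/2)`); a best-pair
mode keeps only the top-scoring occurrence of each motif per peak.  Whether
published spacing analyses used all pairs or best pairs is generally not
stated; all-pairs is the default here.

### Network assembly and statistics

Edge identity is the (family, gene) pair — multiple supporting peaks
aggregate into one edge, with per-peak provenance retained.  An edge's
condition is the common label of its supporting peaks; mixed or unchanged
support yields "shared".  A condition network contains its specific plus
shared edges, and `compare_networks` returns gained = B∖A and lost = A∖B
with per-family tallies and an optional TF-only target filter.  Self-edges
(a family's motif in a peak annotated to one of its own members) are kept
and flagged — autoregulation is biologically meaningful — with configurable
removal.

TF families are grouped by shared motif; the source-node representative is
the member with the highest expression (lexicographic on ties; absent
members count as zero with a warning).  The pipeline uses the mean of the
two condition values for this selection, since a single-patient expression
value is not available for synthetic two-condition data.

Module overlap tests are one-sided upper-tail hypergeometric:
`p = P(X ≥ overlap)`, `X ~ Hypergeom(N, |A|, |B|)`.  The universe defaults
to the genes of the expression table and is configurable — published
analyses rarely state their universe, and the p-value depends on it.
Expression gene lists use a fold-change ≥ 2 filter when only raw tables are
given; a precomputed DE table additionally applies adjusted p < 0.1 (the
model-based testing that produces adjusted p-values is upstream of this
package).  A disease-specificity filter keeps genes strictly >2-fold above
a reference tissue in ≥ `min_samples` samples.

### Density matrices

Rows are peaks ranked by descending fold change (ties by peak id); columns
are fixed bins (default 2,000 bp window, 10 bp bins) across
[summit − window/2, summit + window/2), summing a per-bp coverage track;
positions beyond chromosome ends contribute zero.  Because this package
consumes per-peak counts rather than per-bp pileups, the pipeline derives a
coverage track by spreading each union peak's normalized mean count
uniformly over its interval; any externally computed per-bp track can be
substituted through the library call.

## The synthetic landscape

The generator emulates the *shape* of a two-condition accessibility
experiment, not its full biology.  What it plants:

- a random genome (default 2 × 2 Mb, GC 0.41 — human-like);
- 1,000 non-overlapping peaks of 400 bp.  Peaks are placed ≥ 2× the
  maximum union extension apart so that union construction can never merge
  two planted peaks — this keeps truth bookkeeping exact;
- a truth network of `round(edge_density × families × genes)` edges
  (default 150), each realized by a dedicated supporting peak carrying an
  exact consensus instance of the family's motif (length 10, placed on a
  random strand inside the peak);
- condition specificity: `rewired_fraction` of edges (default 0.3) are
  split between gained (B-only) and lost (A-only); their supporting peaks
  get mean `depth × planted_fold_change` (default 100 × 4) in their
  condition and `depth` in the other.  An additional 10% of non-edge
  peaks per direction are specific decoys, so differential calling is
  exercised on peaks that carry no motif;
- HiC links for `hic_link_fraction` of peaks (anchor inset inside the
  peak, promoter at the target's TSS); the rest of the truth edges run
  through closest-TSS fallback, which constrains those targets to be the
  supporting peak's closest gene by construction;
- counts: negative binomial with `variance = μ + μ²/size`
  (`size = nb_dispersion`, default 10 — moderately overdispersed, as peak
  counts typically are); `nb_dispersion = inf` is the zero-noise sentinel
  that makes counts exactly `round(μ)`;
- expression: uniform log2 baselines, family representatives planted
  strictly highest in their family, targets of condition-specific edges
  shifted by `log2(planted_fold_change)` in their condition, Gaussian
  log2-scale noise (default sd 0.25).

Two constructions deserve emphasis because the exact-recovery guarantee
depends on them.  First, family consensi are drawn pairwise-distinct
(Hamming ≥ 4, including against reverse complements, no palindromes), and
any *accidental* exact match of a consensus elsewhere in the random genome
is mutated away ("scrubbing").  With near-consensus PWMs under pseudo-count
0.01, a single mismatch costs ~10 bits out of ~20, so any scan threshold
fraction above ~0.6 admits only exact consensus matches — exact-string
scrubbing therefore guarantees that a scan finds all planted instances and
nothing else.  Second, TF member genes receive expression values but no
TSS, so the closest-TSS fallback can only target catalog genes and planted
truth never collides with family membership (self-edges are tested through
the inference API directly instead).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level noise and mappability artifacts,
peak-calling uncertainty, overlapping or nested regulatory elements,
degenerate motif matches and motif families with correlated PWMs,
cross-sample HiC transfer error, replicate structure, and trans effects on
expression.  Recovery at zero noise demonstrates the pipeline's logic is
exact; the noisy defaults demonstrate robustness margins (a planted 4-fold
change sits comfortably above the 3-fold rule), not performance on patient
data.

## Numerical choices

- Coordinates are 0-based half-open throughout (BED convention); 1-based
  sources are converted at the boundary.  Summits are absolute coordinates
  so they survive merging.
- Writers sort stably and format numbers at 6 significant digits, so equal
  objects produce byte-identical files; run manifests record SHA-256
  checksums.
- The scanner accumulates window scores position by position in a fixed
  order, so its scores are bit-identical to a sequential brute-force sum;
  the maximum score uses the same order.  Uniform PWMs (max score 0) report
  every window at threshold 1.0 by the ≥ comparison.
- Ties everywhere break deterministically (lexicographic gene/peak ids,
  leftmost summit), and all randomness flows through one integer seed per
  landscape (`numpy.random.default_rng` with per-stage substreams), so
  identical parameters and seed give byte-identical outputs.
- Fixture presets: `tiny` (1 × 200 kb, 2 families, 20 genes, 60 peaks) for
  fast round trips, `demo` (2 × 2 Mb, 5 families, 200 genes, 1,000 peaks)
  for full-scale runs; both use the zero-noise sentinels so pipeline output
  is exactly comparable to the packaged truth.  The demo's scan threshold is
  0.9.  These sizes keep a complete end-to-end run in seconds on one CPU
  while still exercising every stage at realistic peak density.

## Known limitations

- The pipeline consumes per-peak counts; it does not compute coverage from
  alignments (density matrices use the uniform spread described above
  unless a real track is supplied).
- Motif scanning is single-PWM log-odds with 0-order backgrounds; no
  dinucleotide models, no de-novo discovery, no motif clustering.
- Differential calling is the fold rule by design; model-based testing
  (e.g. empirical-Bayes moderated fits) is upstream and enters only through
  precomputed DE tables.
- Hypergeometric overlap p-values are as good as the universe choice,
  which is explicit and configurable for that reason.
- `compare_networks` counts one connection per (family, gene) pair;
  per-peak multiplicities are available in edge provenance but do not
  change the counts.
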