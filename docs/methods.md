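# Methods

`tcrepspec` implements an analysis pipeline for epitope-specific T-cell
receptor (TCR) β-chain repertoires: it turns the tabular output of
sorted-cell TCR sequencing into a per-epitope clonotype database,
characterizes that database (publicity across donors, CDR3 similarity
clusters, V/J gene usage), trains per-epitope specificity classifiers
calibrated against a bulk background, and uses both the database and the
classifiers to annotate independent patient repertoires and relate the
diversity of epitope-specific clusters to clinical group. This note records
the model assumptions, the defaults that matter, and the numerical choices.

## Parsing and quality control

All analyses operate on the β chain only. A clonotype is (CDR3 amino-acid
sequence, V gene, J gene, read count, donor). Input dialects: MiXCR clone
export, AIRR Rearrangement, and this package's `simple` TSV; all
tab-delimited and gzip-transparent.

QC rejects a record at the first failing rule, in order:

1. **Anchor rule** — the CDR3 must start with the conserved cysteine and end
   with the conserved phenylalanine. This is enforced literally: a
   tryptophan terminus (permitted by IMGT junction nomenclature) is treated
   as a failure, because the filter is defined on C…F framing.
2. **Alphabet rule** — any character outside the 20 standard residues
   (stop `*`, `X`, `_`, lowercase) rejects the record.
3. **Orphon rule** — records whose V or J gene is on the orphon list
   (germline segments outside the canonical TRB locus) are rejected. The
   orphon list is data, not code: a default IMGT-style list ships in
   `resources.py` and every entry point accepts an override. Because
   published orphon inventories differ in detail, orphon-rejection counts on
   real data are reproducible only relative to a stated list.
4. **Missing-gene rule** — blank V/J fields reject the record (counted
   separately in the parse report so that output + rejections = input holds
   exactly).

Gene fields are tokenized by splitting on commas (first listed gene wins),
stripping parenthesized alignment scores, and dropping the `*allele`
suffix. Zero-padded gene dialects (`TRBV07-03`) are unified with plain ones
(`TRBV7-3`) internally; outputs keep the focal set's spelling. Missing read
counts default to 1 (required by the ratio and dedup rules below) and are
logged.

## Database construction

Sorted runs from multiple epitopes share donor material, so one CDR3 can
appear under several sorting epitopes. Disambiguation uses read counts:
for each ambiguous CDR3 the highest read count per epitope is taken
(replicate runs for the same donor and epitope are merged with counts
summed first), and the ratio between the two most abundant epitopes
decides — at least 100 assigns the CDR3 to the dominant epitope, anything
below removes the CDR3 entirely. Ties give ratio 1 and removal. When more
than two epitopes are involved, only the top two counts enter the ratio.
Control sorts against irrelevant epitopes participate in disambiguation
(absorbing promiscuous clones) but never enter the final database.

Within an epitope, training sets are collapsed to one record per CDR3,
keeping the V/J pair with the highest read count; exact ties break on
lexicographically smallest (V, J) so results are order-independent.

**Publicity** is judged on CDR3 identity alone (V/J ignored): a sequence is
public when observed in at least two donors. The histogram of
donors-per-public-CDR3 is reported alongside the per-CDR3 table.

## CDR3 similarity clustering

Two CDR3s are joined by an edge when they have equal length and Hamming
distance exactly 1 (the distance is undefined across lengths, so no
cross-length edges exist). Clusters are connected components of size ≥ 2 —
exactly the operational definition "each member differs in one amino acid
from at least one other member". Single-linkage components are used rather
than any second-stage supercluster refinement; published cluster counts
from tools with extra refinement stages can therefore differ by a few
clusters. The graph is built in O(n·L) expected time by hashing each
sequence once per position with that position deleted; the suite checks
edge-set equality against a quadratic all-pairs oracle. Cluster identifiers
are the lexicographically smallest member, making output order-independent.

Per-cluster position-frequency matrices are exported as L×20 row-stochastic
tables (rows = positions), the orientation sequence-logo tools consume.

## V/J usage enrichment

Usage is counted over unique TCRs (unique CDR3+V+J combinations), never
read counts. For each gene with at least 2 focal occurrences a two-sided
Fisher exact test compares focal vs background occurrence; genes below the
minimum are reported untested. Benjamini–Hochberg correction is applied per
gene class (V or J) and epitope, over tested genes only; significance is
q < 0.05, with direction labelled by the odds ratio (enriched = significant
and OR > 1). Family-level analysis rolls genes up to IMGT subgroups (symbol
truncated before the subfamily hyphen) before testing.

The test-calibration check resamples focal sets (n = 500) from the
empirical gene law of a fixed background table (n = 10,000 over 12 roughly
equal-usage genes; expected focal counts ≈ 40 per gene) and measures the
per-gene rejection rate at α = 0.05 over 1,000 replicates. With counts of
this size the discreteness of the exact test keeps the achieved size
slightly conservative (≈ 0.035–0.05), inside the nominal ± 0.02 band; with
much rarer genes the exact test would be more conservative still.

## Specificity models and the baseline prediction rate

Per epitope, a random forest (100 trees by default, seeded) is trained on
epitope-specific CDR3s versus negatives sampled without replacement from a
bulk background pool at a 5:1 negative:positive ratio (the ratio is a
package default, configurable; it stabilizes cross-validated metrics under
class imbalance). Pool entries matching a positive CDR3 are excluded.

The **encoding** is owned by this package (`anchored-physchem-1`): anchors
are dropped, the inner sequence fills an 18-slot frame from both ends
(middle slots zero = gap), each slot carrying four z-scored residue
descriptors (Kyte–Doolittle hydrophobicity, charge, volume, Grantham
polarity), plus one length feature — 73 features for any CDR3 of length
5–20. A single substitution changes only one slot's features; sequences
shorter than 5 are rejected.

Evaluation is stratified 5-fold cross-validation reporting balanced
accuracy at the 0.5 vote threshold, AUROC and average precision
(mean ± SD), with pooled out-of-fold ROC and precision–recall curve points
exported. The final model is refit on all data.

**Calibration**: the fitted model scores `n_background` TCRs (100,000 by
default, drawn from the pool excluding training negatives when the pool
allows) and freezes the sorted score array. The baseline prediction rate of
a query is the fraction of background scores greater than or equal to its
score (inclusive comparison); a query passes at the default threshold of
0.01% when at most 10 of 100,000 background TCRs score as high. BPR is
monotone non-increasing in the raw score, and training → prediction is
bit-reproducible for a fixed seed.

Cross-validated metrics of any re-implementation depend on the encoding and
hyperparameters, so published point values from other tools are treated as
a performance regime, not bit targets; the suite instead requires AUROC
≥ 0.9 on motif-implanted synthetic positives and a shuffled-label AUROC
indistinguishable from 0.5.

## Cohort annotation and cluster-diversity association

Each individual's samples are merged into a single repertoire of unique
CDR3s (counts summed, highest-count V/J retained); repertoire size is the
number of unique clonotypes. Specific TCRs are identified by (a) exact
CDR3 look-up against the database — which by construction cannot find
unseen sequences — and (b) model prediction at the BPR threshold; the two
sets are unioned on CDR3. Summary tables report counts and frequencies
(percent of repertoire size, 3 decimals); frequencies are recomputed from
their own counts as an internal consistency check on every output.

All individuals' unique CDR3s are then pooled and jointly clustered.
Clusters containing at least one identified specific CDR3 are annotated
with their group composition: member-CDR3 counts per clinical group. A
CDR3 observed in individuals of several groups counts toward each such
group, so group columns can sum to slightly more than cluster size when
groups share sequences; on sharing-free data row sums equal cluster size.
The association between clinical group and cluster membership uses the
2×K contingency of member counts for the two compared groups over the K
annotated clusters (Pearson chi-squared, no continuity correction; a
warning is raised when expected counts fall below 5, which is routine at
these sizes). On the published seven-cluster composition this construction
reproduces the reported statistic and p-value exactly, which is why it was
chosen over presence/absence alternatives.

## Synthetic data generator

The generator produces every input shape the pipeline consumes, with
ground-truth bookkeeping for parameter-recovery tests. Defaults are the
study conditions used throughout the tests and the acceptance script:

* **Sorted runs** — 12 donors per epitope, 150 clones per run at 90% sort
  purity. Each epitope's repertoire is a mixture of 60 motif families
  (family 0 is the configured consensus; the rest are fresh anchored draws
  of nearby length, with mildly heavy-tailed family weights); each clone
  perturbs its family consensus at 15% per inner position, creating
  Hamming-1 neighbourhoods. A single family per epitope would collapse each
  epitope into one giant component; the mixture reproduces the observed
  fragmentation into many small clusters. Specific clones are copied into
  another donor with probability 0.15 (publicity), and 5% of clones leak
  into a second sort with their count divided by a lognormal ratio
  (median ≈ 8), so most contaminants fall below the ratio-100 rule and are
  removed.
* **Background pools** — anchor-constrained random CDR3s: length
  categorical on 8–20 with mode 13–15, inner residues from a
  glycine/serine-rich composition, V/J symbols from a shipped functional
  TRB gene list with rank-weighted usage, zipf(a = 2) read counts. No
  V(D)J recombination model is simulated; the anchored-draw background is
  sufficient for every property the pipeline tests and keeps the package
  dependency-free. A `corrupt_fraction` knob injects malformed records for
  QC testing; otherwise all output passes QC with zero rejections.
* **Cohorts** — 3 healthy / 3 complete remission / 3 relapse repertoires
  with sizes in the few-hundred-to-few-thousand range. Planted specific
  clones descend from per-group seed CDR3s drawn from the database: exact
  seed copies (look-up hits) at ~0.4% of repertoire size for patients and
  0.1% for healthy, plus 1-mutation variants (model/cluster hits). The
  relapse group's plants descend from 1 seed family, remission's from 7 —
  the concentrated-versus-spread contrast the association test must
  detect.

What the generator does **not** emulate: generation-probability structure
of real V(D)J recombination (so absolute publicity levels are set by the
sharing knob, not convergent recombination), HLA restriction, clonal
abundance correlations between individuals, and the background similarity
of real bone-marrow repertoires (random backgrounds are nearly
Hamming-disjoint, so cohort-wide clustered fractions are far lower than in
real cohorts; planted families dominate the annotated clusters). Passing
tests therefore demonstrate correctness of the pipeline's rules and
recoverability of planted structure, not biological realism of the
background.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full pipeline at the
default conditions above (≈ 4,200 sorted records per epitope set, ≈ 1,400
unique database CDR3s per epitope, 25,000-TCR background pool, 10,000-TCR
BPR calibration sample, 1,000 calibration replicates, 200 association-power
replicates). These sizes give stable statistics while keeping a complete
run in tens of seconds; `n_background` = 100,000 (the production default)
is used automatically when a larger pool is supplied.

## Known limitations

* Exact-count reproduction of published database statistics requires the
  original deposited runs; the pipeline reads their table formats directly,
  but no downloads ship with the package.
* The orphon list is configurable data; counts of orphon rejections depend
  on the list chosen.
* Cross-validated classifier metrics depend on the encoding; only regime
  properties are asserted.
* The chi-squared association is asymptotic; with the small per-cluster
  counts typical of annotated clusters, expected counts below 5 are routine
  and flagged, and an exact/permutation alternative may be preferable for
  very small tables.
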