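# Methods

This note documents the models, numerical choices, and open design
decisions behind each stage of the pipeline, and what the synthetic-data
generators do and do not emulate.

## Spectral-count quantification

A peptide-spectrum-match table maps each peptide (distinct amino-acid
sequence, irrespective of charge or modification) to a set of protein
accessions and a spectrum count per MS run. Per protein and run we report:

- **SPC** — spectra of all matching peptides, shared or not;
- **uSPC** — spectra of peptides matching only that protein;
- **adjSPC** — uSPC plus shares of each shared peptide's spectra, split
  among its accessions in proportion to their uSPC *in that run*. When
  every accession of a shared peptide has zero uSPC in a run, the spectra
  are split equally; this keeps the per-run spectra balance exact
  (Σ adjSPC = Σ spectra, enforced to 1e-9 in tests).
- **NadjSPC** — adjSPC divided by the run's total adjSPC over retained
  proteins (or by a bait set's adjSPC in bait-normalised mode), so
  Σ NadjSPC = 1 per run.

Apportionment is computed per run rather than on pooled counts: unique-count
proportions can differ between runs, and per-run values keep NadjSPC well
defined for each acquisition.

**Discard rule.** A protein whose total uSPC is zero and whose every
peptide is shared with some protein that does have unique evidence is
considered redundant and discarded; apportionment is then re-run on the
reduced accession sets so the retained partners absorb the shared spectra.
Re-apportionment (rather than freezing the first pass) is a deliberate
choice: it preserves the spectra balance among retained proteins.

**Family grouping.** Proteins are linked when the shared fraction of
*either* protein's own matched-peptide set strictly exceeds the threshold
(default 0.80); connected components become families. The asymmetric
either-direction test makes a strict subset always group with its superset,
which matches the intended family semantics; exactly 80% does not group.
Grouping is computed once on the pooled dataset. Family quantities are the
member sums; the label is the member with the highest total uSPC,
ties broken by accession order.

## Enrichment statistics

Technical runs are summed to bioreplicate level before any ratio, because
reproducibility is counted in bioreplicates. Per bioreplicate *b*,

    ratio_b = max(NadjSPC_TRAP,b, ε) / max(NadjSPC_WT,b, ε),  ε = 1e-5,

and the reported ratio is the arithmetic mean over bioreplicates where the
protein was observed in either genotype. The floor applies to both sides so
a protein absent from WT gets a large but finite ratio. "Observed in a
TRAP bioreplicate" means any nonzero spectral evidence in that biorep's
summed runs.

**Resampling significance.** The test needs a null standard deviation per
protein. We fit the variance–mean trend across all proteins and conditions:
per protein and condition, the replicate mean and sample sd are computed;
pairs with positive mean are sorted by log10 mean and cut into equal-count
bins (bin count = clip(n/20, 5, 30)); a cubic is fit through the per-bin
medians of log10 mean and log10 sd. Two numerical details matter:

- the sample sd of k replicates is median-biased low
  (median = σ·sqrt(med(χ²_{k−1})/(k−1)), ≈ 0.83σ at k = 3); we divide this
  factor out per condition, otherwise the null is anti-conservative by
  roughly a factor 1.2 in σ and the type-I rate nearly doubles;
- predictions clamp log10(mean) to the observed range and floor the
  predicted sd at one tenth of the smallest nonzero observed sd, so the
  cubic cannot be extrapolated or collapse to zero variance.

Given the fit, the observed statistic is d = mean(TRAP) − mean(WT); the
null resamples both condition's replicate sets from Normal(m₀, σ(m₀)) with
m₀ the pooled mean, and p = (1 + #{|d*| ≥ |d|}) / (iterations + 1)
(two-sided, add-one so p > 0; default 20,000 iterations, explicit seed,
bit-for-bit reproducible). On data generated from this model class the
fraction of null p < 0.05 sits within [0.03, 0.07] and the p distribution
passes a KS uniformity check; on overdispersed count data the raw p-values
are moderately anti-conservative, which is why the candidate filter does
not rely on them alone.

**Candidate filter.** avg ratio ≥ 3 AND ≥ 2 of 3 TRAP bioreplicates AND
TRAP adjSPC ≥ 18 AND ≥ 3 distinct peptides. The packaged 59-row published
candidate table (transcribed to TSV, checksum-guarded) passes this filter
in full, partitions into 54 rows at p < 0.05 (remainder < 0.1), and counts
15/22/10/12 across the DNA–RNA / metabolism / proteostasis / unknown
function bins — these are regression anchors in the test suite. Printed
p-values of 0.00000 are floored at the smallest p attainable with 20,000
iterations (1/20001).

## Evolutionary rate covariation

A gene's per-species rate is its **terminal branch length**. This choice is
robust to gene-tree/species-tree discordance and needs no internal-branch
reconciliation; the cost is that deep coevolution signal on internal
branches is invisible. Normalisation divides each species column by its
across-gene mean (removing species effects such as generation time), then
each gene row by its own mean (removing gene-wide rate differences);
species observed in fewer than 3 genes are dropped. Because the species
means are plain averages, a few genes with extreme rate dispersion can
contaminate them — ERC should be run with many genes so the mean is stable
(the test suite demonstrates the failure mode at 4 genes).

Pairs need ≥ 8 shared species (t-test with ≥ 6 df); Pearson r with the
two-sided t p-value; Benjamini–Hochberg across all valid pairs (verified
against a literal step-up implementation). Network edges default to
FDR-adjusted p < 0.05; raw-p networks are available behind a flag.

**Duplication calling** uses the species-overlap rule on rooted trees: an
internal node is a duplication iff two of its child subtrees share a
species. No bootstrap-guided rearrangement is attempted; a multifurcating
root is rejected as unrooted.

## Coexpression networks

Inputs are per-bait ranked lists of (gene, LS) capped at 100 entries; LS is
treated as an opaque monotonic coexpression score. Edges are undirected and
deduplicated across directions keeping the maximum LS (the two directed
scores of near-symmetric mutual-rank lists rarely differ). Ties at rank k
break lexicographically, which keeps top-k lists size-exact and
deterministic. The combined builder unions top-20 and LS ≥ 6 edges, then
removes non-bait nodes with pre-filter degree < 2 in a single pass (not
iteratively); baits survive only with ≥ 1 remaining edge. In the network
statistics, edges between two baits count toward both bait classes, so
average connectivity is (edges_CLP + edges_trapped)/nodes; this matches the
convention in which the two class counts exceed the unique edge count.

## Synthetic data

The generators are pure functions of a seeded configuration.

**PSM counts** emulate the 2-genotype × 3-bioreplicate × 3-technical-run
design. Protein abundances are log-normal (median 15 expected spectra per
protein per run, log-sd 1.2 — a deep affinity-enrichment run of ~2,000
proteins); planted enriched proteins are multiplied by the effect size
(default 5) in TRAP; per-bioreplicate biological noise has CV 0.2; each
protein carries 3–30 peptides, a configurable fraction shared within
consecutive-protein homolog families; counts are negative binomial with
dispersion 0.1 (variance μ + 0.1μ², the overdispersion typical of spectral
counts; Poisson is available for calibration work). Not emulated: peptide
ionisation chemistry, contaminants, decoys, and inter-run alignment — so a
passing recovery test demonstrates the statistical pipeline, not search
engine behaviour.

**Gene trees** start from a packaged synthetic 20-taxon species tree
(`species_tree_20taxa.nwk`; tips S01..S20). Terminal branch lengths follow
L_s · r_g · exp(strength·scale·z_s + σ·ε) with a standard-normal latent z
shared within each planted coevolving pair; scale = 0.6 bounds the shared
log-dispersion at full strength and σ = 0.15 is the per-branch noise.
These defaults keep rate dispersion in the realistic range where Pearson
correlation retains power; a planted pair at the default strength 0.8 has
log-scale correlation ≈ 0.91. The duplicate-and-diverge mode replaces one
random node per affected gene with two diverged copies of its subtree and
logs the duplication by the tip set beneath the inserted node.

**Coexpression lists** place baits (plus a few background genes) into
modules sharing a latent factor (within-module correlation 0.8) over 200
expression samples among 4,000 background genes. Pairwise Pearson
similarities below a Bonferroni-calibrated noise floor get the bottom rank;
mutual ranks (geometric mean of the two directed ranks) map to
LS = log((1−q)/q), q = MR/(N+1), clipped to [−9, 10], with sub-floor pairs
compressed strictly below on [−10, −9.1] so ranked lists are tie-free. The
calibration makes a null dataset produce an (near-)empty LS ≥ 6 network
while in-module edges land just above 6 — the threshold semantics the
downstream builders consume. Absolute LS values are not calibrated to any
real coexpression database.

## Problem sizes used in checks

Oracle equality for apportionment runs 200 random instances of ≤ 50
proteins; the significance-null calibration uses 2,000 proteins at 2,000
iterations; end-to-end recovery averages 8 seeded datasets of 2,040
proteins with 40 planted five-fold enrichments (recovery ≥ 90%, ≤ 2 false
positives on average); the ERC null uses 1,000 independent pairs and
planted-pair recovery 10 pairs among 200 genes. These sizes give stable
statistics while keeping a full run of the suite under a minute.

## Known limitations

- The resampling significance test is a reconstruction of an unpublished
  tool described only at the level of "cubic fit, adaptive binning, 20,000
  iterations"; published p-values are not expected to reproduce exactly.
- Rate covariation from terminal branches cannot reproduce results computed
  with a different rate projection, and the mean-based normalisation is
  sensitive to extreme genes (see above).
- Network reproduction of archived coexpression databases requires the
  archived per-bait lists themselves; the package reproduces the builders'
  semantics and verifies them against set-theoretic oracles instead.
- The discard and grouping rules operate on the peptide-accession bipartite
  structure only; they cannot recover proteins whose unique evidence was
  lost upstream of the count table.
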