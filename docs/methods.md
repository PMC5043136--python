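# Methods

`duphist` reconstructs the duplication history of a gene family across
several related genomes: which members arose by whole-genome/segmental
duplication (S/WGD) versus tandem duplication, when the large-scale events
happened (via synonymous distance), and which descendants of each ancestral
locus each species has retained, lost, or repurposed. Every stage is
validated against a synthetic-genome simulator that plants known events, so
the whole pipeline is testable without downloading genome annotations.

## The simulator

`simulate.build_ancestral_genome` lays out `n_chromosomes ×
genes_per_chromosome` protein-coding genes (random sense-codon bodies, ATG
start, single stop, 6–9 exons with 80–400 bp introns, intergenic gaps
2–6 kb), flagging `family_founder_count` genes — on distinct chromosomes
where possible — as the focal family. Defaults are desk-scale (2 chromosomes
× 30–40 genes, 2 founders, genes 150–250 codons): large enough that 50-gene
flanking windows and block statistics behave as on real annotations, small
enough that a full multi-species study runs in seconds to minutes on one CPU.

**Divergence model.** `evolve_cds_pair(cds, target_ks, target_omega, seed)`
plants substitutions directly: the number of synonymous events is
Poisson(`target_ks` × S) and the number of nonsynonymous events
Poisson(`target_omega` × `target_ks` × N), with S and N the NG86 site counts
of the input. Each event picks uniformly among the currently available
single-nucleotide changes of its class; stop-creating changes are never
available, so length and reading frame are preserved. Because events land
uniformly per site, the NG86 estimator with Jukes–Cantor correction is an
approximately unbiased estimator of the targets at moderate divergence
(measured: mean estimated Ks 0.506 at target 0.5 over replicates; mean ω
0.203 at target 0.2). Above Ks ≈ 2 the estimator approaches the Jukes–Cantor
saturation bound (pS = 3/4) and individual pair estimates become noisy or
undefined; block dating uses medians over many pairs precisely to absorb
this.

**Events.** `apply_wgd` duplicates every chromosome, retains each duplicate
gene independently with the given retention rate (losses are recorded; the
ancestral copy is never removed), and diverges retained duplicates at the
event's target Ks. `apply_tandem_array` inserts diverged copies downstream
of a gene at a controlled nearest-boundary spacing with a controlled number
of intervening background genes, shifting downstream coordinates.
`speciate` derives a descendant species by diverging every gene. Gene loss
applies to duplicates by default; `apply_gene_loss` can also remove
ancestral loci to emulate ancient losses. A truth table (TSV) records every
event, and `CladeSimulation.lineage` additionally records speciation edges so
a pair of genes can be assigned its true divergence event (the oldest
duplication edge on the copy-tree path between them).

**What the simulator does not emulate:** intron/intergenic sequence content
(coordinates only), inversions and translocations, codon-usage bias, rate
variation among sites and lineages, and fragmented or mis-annotated gene
models. Passing tests therefore demonstrate correctness of the algorithms
under clean annotations and homogeneous divergence, not robustness to the
assembly and annotation artifacts of real genome projects.

## Homology and pair calling

All-vs-all search uses exact local alignment (Biopython `PairwiseAligner`)
on CDS nucleotide sequences. Default scoring is match +2, mismatch −1, gap
open 20, gap extend 10 (a length-L gap costs 20 + 10·L):

* a local alignment extends while its expected per-column score is positive;
  with mismatch −1 that holds down to 1/3 identity, so duplicates from
  ancient events (pair Ks 1.5–2.3, nucleotide identity ~45–55%) produce
  full-length alignments, where the classic BLASTN −3 mismatch would cut
  detection off near 60% identity;
* unrelated sequences (~25% identity) drift negative, and the heavy gap
  costs stop random pairs from stitching matches into long fake alignments
  (duplicates of coding sequence rarely gain indels, so real pairs pay
  almost no gap cost);
* the reporting floor (score ≥ 100) sits several-fold above the measured
  random-pair score tail at these catalog sizes, so the hit list is
  effectively free of unrelated pairs.

The quadratic scan is prescreened by normalized protein edit distance
(edlib) between the two translations: measured on simulated data, unrelated
proteins sit near 0.84 while duplicates stay below ~0.70 out to Ks ≈ 3, so
the default cutoff 0.75 skips essentially all unrelated pairs and essentially
no related ones. The prescreen and all scoring parameters are arguments.

Calling rules are literal: paralogs require identity strictly > 40% and
alignment strictly > 300 bp within one species; orthologs are reciprocal
best hits (ties broken by identity, then gene id) with both alignments
≥ 300 bp. Identity counts identical columns over all alignment columns,
gap columns included.

## Ka/Ks (NG86)

Pairs are aligned at the protein level (global, BLOSUM62, gap 10/1), the
alignment is back-translated onto the CDSs (gap columns dropped and
counted), and Ka/Ks is computed by Nei–Gojobori (1986) counting: per-codon
synonymous sites as the synonymous fraction of non-stop single-nucleotide
changes at each position; differences partitioned by averaging over all
substitution orders, excluding pathways through stop codons (if every
pathway passes a stop, the differences are split equally); Jukes–Cantor
correction of both proportions. Proportions ≥ 3/4 leave the rate undefined
and flagged (`ks_saturated`), never silently dropped. ω = Ka/Ks classifies
selection: < 0.5 strong purifying, [0.5, 1) relaxed purifying, = 1 (tol
1e−9) neutral, > 1 positive. NG86 with equal pathway weights is the fully
specifiable baseline; maximum-likelihood estimators are out of scope.

## Microsynteny, tandem rule, groups

A duplicated region is called for a homologous family pair when at least 3
of the 50 upstream/downstream neighbors of the two anchors also form
homologous pairs. Flank matching is greedy one-to-one by descending
alignment score (a single promiscuous flanking gene cannot satisfy the rule
alone); flank homology uses a relaxed floor (identity > 40%, alignment
> 150 bp) because background genes can be shorter than family genes. Synteny
quality = 2 × matches / (total genes in both segments) × 100, the anchor
pair counting as a match.

Tandem duplication: same chromosome, both family members, nearest span
boundaries ≤ 60 kb apart, and ≤ 5 annotated non-family gene loci strictly
between (family genes in between extend the chain instead). Pairs are merged
transitively into maximal clusters. When a pair satisfies both the tandem
rule and a block, tandem wins — the two expansion classes are reported as
disjoint.

Ancestral-locus groups are the connected components of the graph whose edges
are block anchor pairs (within- and cross-species), labeled "A", "B", … by
decreasing size with lexicographic tie-break, so labels are independent of
block input order.

## Dating and retention

A block is dated by the median Ks over its anchor pair and flank pairs
(saturated pairs excluded; a block with no defined Ks is flagged undated).
Each species carries named era intervals; a within-species block is assigned
to the interval containing its median, else left unassigned — values outside
all intervals are reported, not forced. The shipped rosid-like configuration
places intervals around the published medians (salicoid p 0.27 and γ 1.54 in
*Populus*; α 0.86 and merged β/γ 2.0 in *Arabidopsis*; γ 1.22 in *Vitis*,
1.76 in *Carica*); since only medians, not boundaries, are published, the
intervals pad midway between neighboring eras and are fully configurable
(YAML round-trip via `EraConfig`). The *Vitis* γ interval starts at 0.9 so
that a Ks ≈ 0.83 pair — reported in the literature as a more recent event —
stays unassigned while γ block medians near 1.0 are captured.

The retention matrix has one row per ancestral-locus group and, per species,
one duplicate slot per expected post-benchmark copy. Slot multiplicities are
an explicit per-species config value (default 4:2:1:1 for an
*Arabidopsis*/*Populus*/*Vitis*/*Carica*-like clade measured against the
shared triplication) because multiplicities compound multiplicatively across
successive WGDs. Cells hold a retained family gene, an "N" locus (a
collinear block counterpart that is no longer a family member — found by
running the block detector between family genes and their non-family
homologs), or "lost". The multiplicity report gives observed retained counts,
expected counts (rows × slots), their ratio, and family-size ratios against a
benchmark species, rounded to two decimals.

For simulated clades the era intervals are derived from the planted design:
the ancient band must absorb compounded divergence — event Ks plus
speciation divergence on both copies plus any later private WGD
(1.5 + 0.2 + 0.6 ≈ 2.3 in the default design) — and Jukes–Cantor noise near
saturation, hence a deliberately wide [1.05, 3.5]; the recent band
[0.05, 0.8] brackets the 0.3 target. These bands were fixed from this
arithmetic, not tuned.

## Phylogeny

Protein distances default to the p-distance with pairwise gap deletion;
Poisson correction (−ln(1−p)) is a flag. Multiple alignments come from
biotite's progressive aligner when not supplied. Neighbor joining is the
standard Q-matrix agglomeration with deterministic tie-breaking (sorted
label pairs), negative branch estimates clamped to zero and counted, and the
final three-way join closed-form; it reconstructs additive matrices exactly
(topology and lengths, tol 1e−9). Bootstrap resamples alignment columns with
replacement and reports, per internal edge, the percentage of replicate NJ
trees containing the same bipartition. Subfamily membership (e.g. the 9-/13-
positional-specificity split of lipoxygenases) is a user-supplied label or,
by convention, the two sides of the deepest split; `clade_mean_distance`
then gives mean within-subfamily distances, flagging singletons.

## Numerical and design notes

* Determinism: every stochastic routine takes a seed (or NumPy Generator);
  identical configuration + seed gives byte-identical exported files.
* Thresholds at boundaries follow the stated strictness exactly: paralog
  identity > 40 and length > 300 are strict; ortholog length ≥ 300 is not.
* Degenerate inputs raise typed errors (invalid codons, empty alignments,
  asymmetric distance matrices, unknown genes/species) rather than returning
  sentinel values; undefined quantities (saturated Ks, singleton subfamily)
  are returned as `None` with a flag.
* Problem sizes in the shipped study and validation runs: clades of 4
  species × 2 chromosomes × 30 genes, 20 replicate seeds for recovery rates,
  100 pairs × 1000 codons for estimator recovery, 50 random 8-taxon trees
  for NJ — sizes chosen so each run completes in minutes on one CPU while
  keeping binomial noise on the measured rates small.

## Known limitations

* Single best local alignment per pair (no multi-HSP tiling); no E-values.
* NG86 only; near saturation (pair Ks ≳ 2) estimates are noisy and rates can
  be undefined — medians over blocks mitigate, single pairs do not.
* The block detector anchors on family genes and their flanks only; it is a
  microsynteny caller, not a genome-wide collinearity chainer.
* Era assignment is an interval lookup on one number; overlapping real eras
  (e.g. β vs γ in *Arabidopsis*) cannot be separated and are modeled merged.
* The simulator's clean annotations overstate real-data performance (see
  simulator section).
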