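# Methods

This note documents the statistical procedures implemented in
`chipcompendium`, the parameters that matter, what the synthetic data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Coordinates and interval algebra

All coordinates are BED-convention 0-based half-open `[start, end)`.  Two
intervals overlap iff they share at least one base; book-ended intervals do
not.  Strand is metadata only — no overlap computation consults it.  Union
("atomic") regions are the maximal merged intervals of all peaks across all
samples; a region is occupied by a sample iff one of its peaks shares >= 1 bp
with it.  Duplicate identical peaks within one sample file are collapsed on
read, as they are almost always file artifacts.

## The randomisation null

The single null model used for pairwise overlap significance, genomic-context
expectations and CpG preference is a length-preserving, within-chromosome
uniform relocation of each peak: a peak of length `L` on a chromosome of
length `C` receives a uniform start on `[0, C - L]`.  Keeping the chromosome
preserves per-chromosome peak composition, the least-assuming choice; shuffled
peaks may overlap one another.  All empirical p-values use the add-one
estimator `p = (#null >= obs + 1)/(n + 1)`, whose floor is `1/(n + 1)`.

For pairwise overlap, the statistic is directional: `obs(i, j)` counts peaks
of sample *i* overlapping >= 1 peak of *j*, and the null re-shuffles sample
*i*.  The occupancy-correlation matrix (Pearson over binary occupancy
columns) is symmetric with unit diagonal and is what the clustering consumes
by default.  Clustering is average-linkage agglomeration on `1 - r` via
scipy; for fixed input the merge order and leaf order are deterministic.

Defaults: 1000 randomisations for dedicated pairwise significance, 100 for
compendium-wide matrices (a pragmatic runtime/precision trade-off; `p` floors
at ~0.01 then, which is adequate for a heatmap classification).

## Promoters, genes, and TF loci

A peak or region is *promoter* iff it overlaps `TSS +- 1 kb` for any gene.
The window is symmetric because directionality adds an assumption the
underlying classification does not need; the window size is exposed.

Nearest-gene assignment anchors on the peak midpoint (robust to peak width)
and minimises distance to annotated TSSs, breaking exact ties towards the
lexicographically smallest gene id so results are order-independent.  Signed
distances are negative upstream in the gene's reading direction.

TF-locus enrichment asks whether transcription-factor gene loci carry more
peaks than expected *given gene length*.  Genes are binned into gene-length
quantiles (default 20 bins; use fewer when genes are scarce — a bin holding
TF genes but no non-TF genes is a hard error rather than a silent bias); each
of `n_resample` (default 10,000) rounds redraws, per bin, as many non-TF
genes as the bin has TF genes and records their mean peak count.  This
resampling correction is transparent and assumption-light compared to a
regression adjustment; the p-value is one-sided (TF mean above the
length-matched null).

The promoter->enhancer dependence check partitions genes by promoter-peak
presence and compares mean enhancer-peak counts by label permutation
(two-sided, 10,000 permutations).

## Multiplicity and conservation

Region multiplicity counts *distinct factors* bound, not samples, so a
factor assayed in many cell types is not over-weighted.  Strata above a cap
(default 8) pool into a top bin against sparse tails.  Per-stratum overlap
fractions with conserved-region or validated-enhancer tracks carry exact
(Clopper-Pearson) binomial CIs; empty strata report missing, never zero.

The trend test reports the stratum-level Spearman correlation between
multiplicity and overlap fraction, but the permutation p-value uses the
region-level Spearman between per-region multiplicity and the binary overlap
flag, recomputed under permutations of the flags.  The stratum-level
statistic cannot be tested this way: with `k` strata the smallest achievable
two-sided permutation p is `2/k!` (0.083 for four strata), while the
region-level statistic has per-region resolution and is exactly what
permuting region labels randomises.

## Motif scanning and enrichment

PFMs (JASPAR format, read via Biopython) are scored as log-odds after adding
a pseudocount of 0.25 to every cell, against a background mononucleotide
composition (default: the scanned sequences' own composition; uniform in the
simulator's genome).  A window is a hit when its score reaches
`threshold_fraction` (default 0.85) of the maximum achievable score; both
strands are scanned; `N` contributes zero log-odds.  Raising the threshold
can only remove hits.  Consensus motifs (used for trimers) are matched
exactly against their IUPAC codes.

Enrichment uses the *presence* statistic — the number of peaks containing at
least one hit — which is robust to homopolymer pileups, compared against 100
random genomic sequence sets of identical count and per-sequence lengths
(positions uniform over the genome, nothing excluded by default).
Benjamini-Hochberg control is applied across motifs within a sample; a motif
is *enriched* at q <= 0.05 and fold >= 1.5 over the null mean.  Promoter- and
enhancer-specific motifs are those enriched in exactly one of the two peak
classes when the procedure is run per class.

The add-one empirical p of a small count statistic is discrete and
conservative by construction; result objects expose the null tail counts so
calibration diagnostics can use the tie-randomised p, which is exactly
Uniform(0,1) when the observed set is exchangeable with the null sets.

## Genomic context and CpG islands

Each peak's midpoint receives exactly one of nine categories with fixed
precedence Promoter > 5'UTR > 3'UTR > Exon > Intron > LTR > SINE > LINE >
Intergenic.  Midpoint assignment guarantees a partition (category counts sum
to peak counts); genic features outrank repeats, mirroring common annotation
practice.  Because the gene table carries no CDS, the UTR stand-ins are the
first/last 200 bp of the terminal exons, reading-direction aware.  Expected
category fractions come from the shuffle null (they sum to 1 by
construction); two-sided binomial tests use the expected fraction as success
probability, BH-corrected across the nine categories.  The CpG test is
empirical (shuffle-based) rather than parametric because island coverage is
blocky; samples are labelled Prefer/Avoid at two-sided p <= 0.05 and Neutral
otherwise.

## Motif-pair spacing

For peaks co-bound by two factors, one gap is contributed per peak from the
best-scoring anchor hit and best-scoring partner hit (ties to the leftmost
position in the anchor frame).  The gap counts bases strictly between the
anchor end and the partner start, measured in the anchor hit's reading frame
(negative-strand anchors mirror the peak), so abutment is gap 0 and a
one-base overlap is gap -1 — the convention under which overlapping joint
elements of the CANNTGGAW type read as "-1 bp".  Reverse-complementing every
input sequence leaves the histogram unchanged.  Gaps outside
`[-partner length, max_gap]` (default max 50 bp) are tallied out-of-range.

Preferred gaps are detected against a null that keeps each peak's anchor
fixed and re-places the partner uniformly among the positions whose gap
falls inside the declared range — conditioning on the range is required
because the observed histogram only tallies in-range gaps; without it the
null is systematically thinner than the observation and the test is
anticonservative.  Per-gap add-one p-values are BH-corrected across the gap
range; a gap is called at q <= 0.05 with >= 10 observations.  `n_null`
defaults to 2000 because the smallest achievable q is
`(#gaps)/(n_null + 1)`; 1000 rounds would leave the floor above 0.05 for the
default 59-gap range and no call could ever be made.

The trimer scan runs the same machinery between a sample's designated
primary motif and all 64 trimers (exact match, both strands), in
lexicographic order.  The replication filter keeps (anchor, partner, gap)
triples whose gap (+- 1 bp) is enriched in at least two distinct samples.

## Gene-set enrichment and lineage priming

Functional enrichment is an upper-tail hypergeometric test on GMT-style gene
sets with BH correction — a deliberate, reproducible, offline replacement
for web-service annotation tools.  The default universe is all annotated
genes (a flag restricts it to genes with >= 1 peak).  The lineage-priming
analysis takes >= 3 samples of one factor, partitions their union regions
into Venn membership cells separately for promoters and enhancers, maps each
cell's regions to nearest genes, and tests each cell's gene list; priming
shows up as marker sets enriched in the progenitor-with-lineage-A cell but
not the progenitor-with-lineage-B cell, and vice versa.

## The synthetic compendium generator

The generator emulates, with known ground truth, every statistical structure
the analyses assume.  Defaults define the study conditions:

* genome: 3 chromosomes x 300 kb, i.i.d. uniform sequence; 60 non-overlapping
  genes (3-8 kb, three exons) spread over the whole chromosome via a
  Dirichlet allocation of intergenic gaps so no gene owns an outsized
  nearest-gene territory; CpG islands (G+C 0.65, 500 bp) at 60 % of TSSs;
  24 repeats per chromosome cycling LINE/SINE/LTR; 20 % of genes flagged TF.
* 420 latent regulatory regions (200 bp, pairwise disjoint), 30 % promoters
  slotted within +-1 kb of TSSs, 70 % enhancers placed away from all
  promoter windows and thinned so regions whose *nearest* gene is a TF gene
  occur at 3x density — exact under the nearest-TSS assignment rule the
  analyses use.
* 12 samples = 4 factors x 3 cell types.  Each sample binds promoters with
  probability 0.8, enhancers owned by its repertoire with 0.7, and all other
  enhancers with 0.05.  The first factor is Pu.1-like: its repertoire is a
  factor-specific enhancer set shared across its three cell-type samples.
* peak lengths: normal(200, 40) clipped at 50 bp, centred on the latent
  region with +-30 bp jitter.
* planted motifs (sharp PFMs; insertion sites sampled from the column
  distributions, random strand, uniform offset): an ETS-like motif in the
  Pu.1 repertoire and one motif per cell type's enhancers, each at
  probability 0.6, plus two never-planted decoys in the library.
* one planted composite: GATA-motif anchor and E-box partner at a 9 bp gap
  in 40 % of the regions co-bound by the two GATA-factor samples.
* conservation: region-level probability by distinct-factor multiplicity
  {1: 0.05, 2: 0.15, 3: 0.30, 4: 0.50}; validated enhancers at half those
  rates.

All randomness flows from one seeded generator with a fixed sample order, so
bundles are byte-reproducible.  What the generator does **not** emulate:
realistic nucleotide composition or repeat sequences, read-level noise, peak
callers' width/score behaviour, chromatin domains, or the scale of real
compendia (hundreds of thousands of regions).  Passing tests on this
substrate demonstrate correctness and calibration of the procedures under
their stated assumptions — not performance on real data.  One visible
divergence: with dense shared promoter binding over a small genome, over
half of all synthetic peaks are promoter peaks, a far larger share than in
real compendia, where distal peaks dominate.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed; derived seeds come from
`numpy.random.SeedSequence`.  The pipeline manifest records the seed, all
parameters, and SHA-256 checksums of inputs and outputs; identical config
and seed reproduce identical bytes.  Default problem sizes (12 samples,
~2,000 peaks, 100-2000 resampling rounds per test) keep a full synthetic
pipeline run around half a minute on one CPU; all sizes are exposed in the
run config for larger studies.

## Known limitations

* The pairwise overlap statistic is directional; only the correlation matrix
  is symmetric.  Region-count-based variants can be derived from the union
  occupancy if needed.
* Empirical p-values are bounded below by `1/(n + 1)`; extremely small
  p-values require proportionally many randomisations.
* Best-hit-per-peak spacing ignores secondary motif instances; peaks with
  many true composite copies contribute once.
* Midpoint-based category assignment undercounts long peaks spanning several
  features — by design, to keep the nine categories a partition.
* The hypergeometric gene-set test treats genes as exchangeable and ignores
  gene length and term redundancy.
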