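# Methods

This note documents the statistical procedures, the conventions chosen where
several are defensible, and what the synthetic validation does and does not
establish.

## Motif similarity and subclassing

A motif is a 4×w column-stochastic matrix over A, C, G, T. The similarity of
two motifs is the maximum, over all ungapped offsets with at least
`min_overlap` (default 4) overlapping columns and over the
reverse-complement orientation of the second motif (on by default), of the
Pearson correlation between the two flattened 4×L overlapping sub-matrices.
Offsets at which either sub-matrix is constant have undefined correlation
and are skipped. The measure is symmetric and lies in [−1, 1].

TFs are clustered hierarchically (average linkage; configurable) on the
distance 1 − r. The subclass count k is chosen by the elbow rule: using rows
of the similarity matrix as Euclidean feature vectors, k is the smallest
cluster count whose within-cluster sum of squares is below 10% of the WSS of
the single unpartitioned cluster. WSS(n) = 0, so a qualifying k always
exists; ties resolve to the smallest k. Subclasses with fewer than 5 members
are kept in the partition but flagged excluded, and take no part in TSDS
scoring. The feature space for WSS and the linkage method are package
conventions — the clustering criterion itself does not prescribe them — and
both are exposed as parameters.

Merged subclass motifs anchor on the member with the highest total
information content; other members align at their best offset/orientation.
The merge averages position-wise over the columns covered by **every**
member (this makes two offset-shifted copies merge to exactly their
overlap); if that intersection is empty — possible with many noisy members —
the merge falls back, with a warning, to averaging over covering members on
the reference's footprint.

Motif-diversity reporting uses the interquartile range of off-diagonal
similarities with linear-interpolation (type-7) quartiles, and Spearman
correlation of IQR against group size; with constant IQRs the correlation is
undefined and reported as absent.

## TSDS scoring

Each alignment column c receives three scores across the retained
subclasses (gaps ignored throughout; a subclass entirely gapped at c is
omitted from that column's statistics):

* **RE(c)** — mean over subclasses of the Kullback–Leibler divergence
  (base 2) of the subclass residue distribution from the whole-family
  distribution. Frequencies use a pseudocount of λ = 0.5 per residue class
  (so 20λ added to each denominator), which keeps the divergence finite;
  λ = 0 reproduces textbook values on pure columns (two pure subclasses at
  50/50 give exactly 1 bit).
* **ED(c)** — mean pairwise Euclidean distance between subclass mean
  physicochemical vectors, using the five Atchley factors per amino acid
  (polarity/accessibility, secondary-structure propensity, size,
  codon composition, charge).
* **ER(c)** — ratio of expected between-subclass to within-subclass residue
  substitution distance, where the substitution distance is 1 minus
  min-max-normalized BLOSUM62 similarity. Expectations are plug-in
  (cᵀDc/n², ordered pairs, self-pairs included): this convention makes
  subclasses with identical residue compositions score exactly 1, which a
  finite-sample distinct-pair mean cannot do. A small ε = 1e-9 in numerator
  and denominator keeps the ratio defined for invariant compositions.

The combined statistic is the equal-weight mean of the three scores'
column-wise z-scores. Columns whose non-gap residues are 100% identical
(and all-gap columns) are excluded before scoring — they cannot carry
subclass information.

Significance comes from permuting the TF → subclass labels (preserving each
column's residue composition, unlike residue shuffling) and recomputing the
combined statistic: p(c) = (1 + #{permuted ≥ observed})/(n_perm + 1).
Columns with raw p < 0.1 are TSDSs; BH-adjusted p-values are emitted
alongside for users who prefer a multiplicity-corrected call, but the
default call uses raw p to match the stated 0.1 rule.

## Coevolution

For each retained column pair (columns with gap fraction > 0.25 or zero
diversity are dropped), using only sequences ungapped at both columns
(per-pair N; pairs with fewer than 2 co-observations are missing):

* **MI** in bits: Σ p(a,b) log₂[p(a,b)/(p(a)p(b))].
* **MIp**: MI − APC, APC(i,j) = MI(i,·)·MI(j,·)/⟨MI⟩, with off-diagonal row
  means and the grand mean over off-diagonal pairs.
* **OMES**: Σ (N_obs − N_exp)²/N with N_exp(a,b) = nᵢ(a)·nⱼ(b)/N.
* **SCA**: Frobenius norm over residue pairs of φᵢᵃφⱼᵇ(f_ij^ab − fᵢᵃfⱼᵇ),
  with conservation weights φ = |ln[f̃(1−q)/((1−f̃)q)]|, f̃ = (1−λ)f + λq,
  uniform background q = 1/20, regularization λ = 0.03.

No redundancy-based sequence weighting is applied — many coevolution tools
reweight similar sequences, but the combination scheme here operates on the
raw per-pair frequencies, and the synthetic generator produces unweighted
i.i.d. rows. Per-method scores are min-max rescaled to [0, 1],
quantile-normalized across the four methods (ties receive the average of
their tied ranks' reference values), and averaged. Candidate pairs are the
top decile per method — top-k with k = ⌊0.10·m⌋ and ties at the k-th score
included, which on 100 distinct scores selects exactly the 10 pairs scoring
≥ 91. CRPs are candidates shared by ≥ 2 methods. Method agreement is the
Jaccard coefficient of candidate sets.

## Network analysis

The CRP graph (columns as nodes, CRPs as edges) is partitioned by greedy
modularity maximization (Clauset–Newman–Moore); on graphs of ≤ 8 nodes the
greedy partition is within 0.05 of the exhaustive optimum in testing. The
TSDS-clustering test permutes TSDS labels over nodes (not degree-preserving
rewiring — the question is about labels, not topology) with the intra-TSDS
edge fraction as statistic. CRP classification by endpoint TSDS membership
uses exact count ratios (intra/between/extra sum to 1 by construction).
Sequence separation uses the strict |i − j| > 5 rule; block crossing treats
an endpoint outside every supplied block as out-of-block (documented
convention — intervals are user-supplied data; the default heuristic splits
the alignment at columns with gap fraction > 0.5). The motif-similarity
comparison groups TFs by their **ordered** residue pair at the two columns,
weights each ≥2-member group's mean pairwise motif similarity by its share
of eligible TFs, and compares CRP vs non-CRP score distributions with a
Welch t-test (at most 500 seeded-sampled non-CRP pairs in the pipeline, for
runtime). FDR control is Benjamini–Hochberg.

## Structures

Complexes must parse from PDB format, have resolution strictly better than
4 Å (the record is required unless explicitly overridden), and contain both
protein and DNA (residue names DA/DC/DG/DT/DU) chains. Waters and
heteroatoms are excluded; disordered atoms contribute their
highest-occupancy conformer; all remaining atoms, including hydrogens if
present, participate in minima. Distances are the minimum Euclidean
atom–atom distance; where a column maps to residues in several chains the
minimum over chains is taken (conservative for interface proximity).
Column → residue mapping tries exact substring search, then global alignment
(BLOSUM62, gap open −11 / extend −1, free end gaps), keeping only columns
aligned to identical residues and refusing mappings under 60% identity.
An f-CRP has max(d_i, d_j) > 10 Å to the nearest DNA atom, strict
inequality. FoldX is never executed: the package writes `individual_list`
mutation lines (`RA49G;`) after checking the wild-type against the
structure, and parses replicate ΔΔG tables, averaging the (by default 5)
replicates and flagging means > 2 kcal/mol as binding-disrupting.

Note that PDB text carries 3 decimal places and parsed coordinates are
single-precision, so round-tripped geometry is reproducible to ~1e-3 Å;
exactness claims (1e-9 Å) apply to the distance computation on parsed
coordinates.

## Synthetic families

The generator's defaults describe the validation world: 60 TFs × 40
columns × 3 subclasses, background columns i.i.d. uniform over a
configurable alphabet subset (default all 20 residues), TSDS columns with
one subclass-specific residue each and a 5% within-subclass substitution
rate, covarying pairs driven by a fixed random alphabet bijection applied
with probability ρ (so at ρ = 1 the pair's MI equals the first column's
entropy), and per-TF PWMs drawn column-wise from Dirichlet(α·template + 1)
with α = 50. Subclass templates (width 8, one 0.85-dominant base per
column) are rejection-sampled until all pairwise template similarities are
≤ 0.5 under the same offset/orientation-searched measure used downstream:
random short consensus sequences share 4-mers often enough that, without
this, "distinct subclasses" would not actually be distinct.

What a green synthetic run establishes: the chain of estimators recovers
planted partitions, columns, and pairs at the stated noise levels, the
permutation nulls are calibrated, and the statistics agree with independent
brute-force enumeration. What it does not establish: behavior under
phylogenetic correlation between sequences (rows here are exchangeable; real
family alignments are not, and MIp's APC is the only background correction
applied), realistic gap structure, alignment error, or motif-database noise.

## Numerical conventions

* Permutation p-values use the +1 convention, so p ∈ [1/(n_perm+1), 1].
* z-scores with zero column-spread are set to 0 (degenerate score vector).
* Min-max rescaling of a constant vector returns zeros.
* Similarity of motifs with constant overlap at every offset is NaN with a
  warning.
* All randomness flows from a single integer seed per run
  (numpy `default_rng`); identical configuration and seed give
  byte-identical reports.
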