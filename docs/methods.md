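# Methods

## The problem and the data

Serum antibodies select binders from a random 12mer peptide display library;
sequencing the bound peptides yields, per biospecimen, a large set of unique
12-residue amino-acid reads (order 1e6 in production screens).  Linear
epitopes surface in these data as short motifs — 5 to 6 residues is the
typical linear paratope contact — that recur across reads far more often
than the sample's amino-acid composition predicts.  The package turns such
read sets into proteome-wide antigen rankings for a case cohort T against a
control cohort U.

## Model

**Enrichment.**  Each unique 12mer is decomposed into its 8 constituent
5mers and 7 constituent 6mers.  For sample S and kmer x,

    E_S(x) = n_S(x) / e_S(x),      e_S(x) = N_S (L - k + 1) ∏_i p_i

where `n_S(x)` is the number of unique 12mers containing x at least once,
`N_S` the number of unique 12mers, `L = 12`, and `p_i` the proportion of
x's i-th letter among all residues of all reads of S.  `N_S` counts unique
reads: duplicate reads carry no information after selection and
amplification, and uniqueness makes `N_S` consistent with the definition of
`n_S`.  Only observed kmers are materialized; an unobserved kmer has E = 0.

**Control normalization.**  For every kmer, the control cohort defines a
vector C of enrichment values, one per control, with absence contributing
E = 0.  A sample's normalized enrichment is the z-score
F = (E − mean(C)) / sd(C).  The sample standard deviation (n−1) is used, so
that normalizing the controls against their own background standardizes
each non-degenerate kmer exactly (mean 0, sd 1); the population convention
is available via `ddof=0`.

**Degenerate-sd floor.**  sd(C) can be zero or tiny (kmers seen in no or
one control).  The effective sd is floored at the 1st percentile of the
strictly positive sds of the background, computed **per k**.  A pooled
floor would be wrong here: expected counts — and with them the scale of
enrichment values and their sds — differ between 5mers and 6mers by roughly
the alphabet size, so a pooled 1st percentile sits at the 5mer scale and
leaves 6mers effectively unfloored.  At desk-scale read depths that turns
every case-observed 6mer unseen in the controls into an enormous z-score —
an artifact that advantages cases systematically, because a control's own
kmers are by construction inside the background while a case's are not.
With the per-k floor such a singleton normalizes to roughly the same
z-scale as a singleton inside the background.  The floor is overridable
(scalar or per-k mapping).

**Protein score.**  For protein p of length `len(p)` and window width w,

    P(s,p) = max_i  Σ_{k∈{5,6}}  Σ_{j=i}^{min(i+w, len(p)−k)}  G_S(kmer(j,k,p))

with G either raw E or normalized F (default F).  Window starts run over
`[0, len(p)−5]`; the argmax (smallest index on ties) is the reported
epitope location `P_loc`.  Kmers absent from the sample's table contribute
the value of E = 0 under the chosen mode; windows covering non-standard
proteome letters (X/U/B/Z) contribute 0, since such kmers cannot occur in a
standard-letter peptide library.  The default w = 5 makes the window of
w+1 6mers span w + 6 = 11 residues, the length reported for dominant
epitopes.

**Cohort statistics.**  Per protein, case scores A(p) are compared with
control scores B(p) by:

- *Outlier sum* O(p) (Tibshirani & Hastie): pool A and B, standardize by
  the pooled median and 1.4826-scaled MAD, and sum the case values strictly
  above the fence q75 + IQR of the standardized pool (linear-interpolation
  quartiles).  It is sensitive to strong signal present in only a subset of
  cases, where rank tests lose power.
- *Permutation null*: 1,000 uniform case/control relabellings preserving
  group sizes.  The joint standardization and the fence depend only on the
  pooled multiset, which relabelling never changes, so the null is computed
  as subset sums of the once-standardized pool — exactly equivalent to
  recomputing the full statistic per permutation, and two orders of
  magnitude faster.  The z-score of the observed statistic against the
  permutation mean/sd is mapped to a one-sided upper-tail normal p-value
  (the statistic only detects case-upward outliers).
- Mann-Whitney U (one-sided, case > control; exact for small tie-free
  groups, tie-corrected normal approximation otherwise), two-sample KS on
  scores, KS on epitope locations (locational conservation), and Hedges' g
  with the small-sample correction J = 1 − 3/(4(n₁+n₂) − 9).
- Benjamini-Hochberg FDR over all tested proteins on the outlier-sum
  p-values; the output table is ranked by this q-value, then by z.

Per-protein permutation streams derive from `(seed, rank of protein id)`,
and group vectors are sorted before testing, so results are invariant to
the order of proteins and of manifest rows.  Proteins scoring zero in both
cohorts are reported with p = 1 rather than dropped.

**Dominant epitopes.**  Case samples with score above a threshold (default
6) contribute their argmax location; locations are clustered by single
linkage with gap ≤ w, and each cluster reports the 11-residue peptide at
its modal location with its supporting sample count.

## Synthetic data generator

`generate_cohort` emulates the *structure* of a screened cohort: every
sample is a set of unique 12mers with i.i.d. letters from a configurable
composition (uniform by default; an NNK-degeneracy-biased preset is
provided), and a `prevalence` fraction of case samples carries planted
reads — a `plant_rate` fraction of their reads contains a contiguous
fragment (≥ 5 residues) of a chosen 11-residue epitope at a random offset
with random flanks.  Decoy proteins are i.i.d. sequences from the same
composition.  Everything is reproducible bit-for-bit from one seed, and
generated manifests use relative paths so equal-seed cohorts are
byte-identical wherever they are written.

What the generator does **not** emulate: sequencing error, PCR and library
construction bias, inter-sample depth variation, polyspecific/mimotope
binding, correlated kmer backgrounds from real immune repertoires, and
conformational epitopes.  Passing tests on these data therefore demonstrate
the statistical machinery — enrichment arithmetic, normalization identities,
null calibration, signal recovery and ranking — not performance on real
screens.

**Problem sizes.**  The shipped study conditions are 20 cases vs 50
controls, 2e4 unique reads per sample, 201 proteins of 300 residues, plant
rate 0.02, prevalence 0.5.  At this depth a planted protein is recovered at
rank 1 with its dominant epitope on the planted interval.  These sizes are
deliberate desk-scale surrogates for production screens (≥ 1e6 reads,
21,057 proteins, 1,157 controls); kmer occupancy is far sparser here, which
is exactly why the per-k sd floor matters (see above).

## Calibration and power experiments

**Null surrogate.**  Null per-protein scores are modeled as i.i.d. draws
from a right-skewed distribution (χ² with 3 df).  The windowed-max score of
a null sample is a maximum of many weakly dependent window sums, so its
distribution is right-skewed with a heavy upper tail; a symmetric surrogate
(e.g. normal) is unrealistic and also breaks the uniformity of the
outlier-sum p-value, because light tails leave the statistic at exactly
zero for most null cohorts (an atom the normal-tail p cannot spread out).
Under the χ²₃ null with 20 vs 50 samples and 1,000 permutations, the
one-sided p-value is approximately uniform (KS distance ≈ 0.06–0.08) and
the type-I error at α = 0.05 is ≈ 0.05–0.08 across seeds — mildly
anti-conservative, a known consequence of applying a normal tail to a
skewed permutation null; see Limitations.

**Power curves.**  `power_curve` perturbs the case score vector of one
protein and recomputes the outlier-sum permutation statistics against
untouched controls: magnitude points multiply the case vector by factors in
[0.1, 2]; prevalence points resample it with replacement from its "high"
(> 6) and "low" (≤ 6; ties go low) pools, each position independently high
with the target probability, aggregated over 1,000 resamples (median and
interquartile band of p — the resample count follows the original
experimental design; the spread across resamples is the reason a single
resample is not reported).  The shipped base vectors are synthetic: a χ²₃
null plus a Normal(12, 2) signal component in half of 20 cases, against 400
controls.  The control cohort is kept an order of magnitude larger than the
case cohort on purpose: the outlier-sum fence is computed from the pooled
sample, so when cases are a large fraction of the pool (e.g. 20 vs 50) a
high-prevalence signal drags the fence upward and power *falls* again at
prevalence → 1.  With a small case fraction — the regime these experiments
model — significance is monotone in both magnitude and prevalence
(Spearman ρ > 0.98 on the shipped grids).

## Numerical choices

- MAD scale constant 1.4826; quartiles by linear interpolation (both
  configurable at the module level).
- MAD = 0 (more than half the pooled values identical) is floored at a
  machine-epsilon-scale value so standardized values stay finite; with all
  values equal the outlier sum is exactly 0.
- Permutation null sd uses ddof = 1; a null with zero spread is flagged
  degenerate and reported with p = 1.
- Argmax ties break to the smallest index; ranking ties break by z, then
  protein id — all output is deterministic given inputs and seed.
- Floats are serialized with 12 significant digits (`%.12g`); tables
  round-trip losslessly for strings and integers and to working precision
  for floats.
- Proteins shorter than 5 residues score 0 at location 0.

## Limitations

- The normal-tail p-value on the permutation z is mildly anti-conservative
  for small cohorts (observed type-I ≈ 0.05–0.08 at nominal 0.05); with
  1,000 permutations an empirical p could not resolve below 1e-3, which is
  why the z/normal route exists, but p-values within ~2× of nominal should
  not be over-read.
- The outlier sum is blind to signal present in essentially *all* cases
  when cases are a sizable fraction of the pooled sample (fence chasing);
  use Mann-Whitney/KS alongside it in balanced designs.
- Desk-scale read depths leave kmer space sparse; enrichment values are
  then dominated by presence/absence and the per-k sd floor becomes
  load-bearing.  At production depths (≥ 1e6 reads, ≥ 100s of controls)
  the floor rarely binds.
- One protein = one score: multi-epitope composite scoring and motif-based
  (rather than exact-kmer) aggregation are out of scope.
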