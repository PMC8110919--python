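# piwas

Proteome-wide discovery of candidate antibody antigens from random-peptide
serology screens.

Serum antibodies select binders out of a random 12mer peptide display
library; sequencing the bound peptides gives, per biospecimen, a large set
of unique 12-residue amino-acid reads.  Linear epitopes show up in these
data as 5–6 residue motifs that recur far more often than the sample's
amino-acid composition predicts.  `piwas` turns per-sample read sets plus a
proteome FASTA into a ranked table of candidate antigens for a case cohort
against a control cohort, with per-sample epitope locations — the
protein-level analog of a genome-wide association scan, for the immune
repertoire.

## The statistic

For each sample S, every unique 12mer is decomposed into its 5mers and
6mers, and each kmer gets an enrichment

    E_S(kmer) = n_S(kmer) / e_S(kmer),
    e_S(kmer) = N_S (L − k + 1) ∏ᵢ pᵢ

(`n_S` = unique 12mers containing the kmer, `N_S` = unique reads, `L` = 12,
`pᵢ` = letter proportions in S).  Enrichments are z-normalized per kmer
against a control cohort, `F = (E − μ_C)/σ_C`, tiled onto every protein,
and smoothed with a sliding window: the protein score is

    P(s,p) = maxᵢ Σ_{k∈{5,6}} Σ_{j=i}^{min(i+w, len(p)−k)} G_S(kmer(j,k,p))

with `G = F` (or raw `E`), default window `w = 5`, so the reported epitope
under the maximal window spans 11 residues.  Per protein, case scores are
compared with control scores by the outlier-sum statistic (with a
1,000-permutation null, z-scored and mapped to a one-sided normal-tail
p-value), Mann-Whitney U, Kolmogorov-Smirnov on scores and on epitope
locations, and Hedges' g; proteins are ranked by Benjamini-Hochberg FDR of
the outlier-sum p across the proteome.  The outlier sum is the headline
statistic because autoantibody signal is typically strong but present in
only a subset of cases — exactly the regime where rank tests lose power.

A simulation layer generates synthetic screens with planted epitopes at
configurable magnitude (`plant_rate`) and prevalence, and reproduces
magnitude/prevalence power experiments on per-protein score vectors.
See `docs/methods.md` for the full model, defaults and limitations.

## Worked example

Generate a small synthetic screen (5 cases vs 10 controls, 5,000 unique
reads per sample, 31 proteins; an 11-residue epitope planted into 5% of the
reads of 60% of the cases) and run the full pipeline:

```sh
piwas simulate cohort --out-dir cohort --n-cases 5 --n-controls 10 \
    --reads-per-sample 5000 --n-decoys 30 --plant-rate 0.05 \
    --prevalence 0.6 --seed 42

cat > run.yaml <<EOF
proteome: cohort/proteome.fasta
manifest: cohort/manifest.tsv
out_dir: out
n_perm: 1000
seed: 42
EOF

piwas run --config run.yaml
# ranked 31 proteins; top hit SYN0000 (outlier-sum FDR 0.0961)
```

The top of `out/protein_stats.tsv`:

| protein_id | outlier_sum | os_z | os_p    | os_fdr | dominant_epitopes | dominant_locs |
|------------|-------------|------|---------|--------|-------------------|---------------|
| SYN0000    | 2205.04     | 2.74 | 0.0031  | 0.096  | TVDNDQGQRSD;SKVQCYSSDLI | 150;0   |

SYN0000 is the protein the generator planted, and `TVDNDQGQRSD` at
position 150 is exactly the planted 11-residue epitope.  The per-sample
scores behind that row (`out/scores.tsv`) show why the outlier sum finds
it: the three planted case samples score ~3,650 while the two unplanted
cases and all ten controls stay below 10 — a strong signal in a *subset*
of cases.  At this desk scale the FDR stays modest (31 proteins, 5 cases);
deeper cohorts drive it down sharply.

Each stage is also available separately (`piwas enrich`, `piwas
background`, `piwas score`, `piwas stats`, `piwas simulate power`), and the
whole pipeline can be driven from Python via `piwas.analyze_cohort` /
`piwas.run_pipeline`.

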