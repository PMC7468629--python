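# aimpanel

Statistical evaluation of biallelic InDel ancestry-informative-marker (AIM)
panels, and biogeographic ancestry inference from them, in one tested Python
package. Given a samples × loci insertion-dosage genotype table with
population labels it computes:

- **Forensic parameters** per locus: insertion/deletion allele frequencies,
  matching probability (MP), power of discrimination (PD), polymorphic
  information content (PIC), power of exclusion (PE), typical paternity index
  (TPI), observed/expected heterozygosity (Nei's unbiased estimator), exact
  or chi-square Hardy–Weinberg tests with Bonferroni correction
  (`popgen_core`).
- **Differentiation statistics**: Weir–Cockerham θ (per locus and
  ratio-of-sums multilocus), Rosenberg's informativeness for assignment
  *I*ₙ with its per-population divergence (PSD) decomposition, Nei's
  *D*_A distance, and counts of loci above an F_st threshold
  (`differentiation`).
- **Ancestry classification**: Snipper-style naive-Bayes assignment under
  HWE genotype probabilities with smoothed training frequencies, and proper
  leave-one-out cross-validation producing an origin × assigned confusion
  matrix (`ancestry_classify`).
- **Admixture inference**: EM maximum-likelihood fitting of the standard
  admixture likelihood (individual ancestry proportions Q, cluster allele
  frequencies P) with seeded restarts, supervised per-individual and pooled
  group-level Q estimation against fixed reference frequencies, and
  second-difference (ΔK) model selection across K (`admixture_model`).
- **Ordination and trees**: genotype PCA (centered or frequency-standardized),
  Torgerson classical MDS of any distance matrix, and deterministic
  Saitou–Nei neighbor joining with Newick export (`ordination_tree`,
  `io_formats`).
- **Synthetic data**: seeded Balding–Nichols simulation of divergent
  continental groups plus per-allele-copy admixed groups with known ancestry
  vectors, so every stage is testable offline (`synthetic_data`).

The package ships the published per-locus reference statistics of a 39-locus
AIM-InDel panel typed in 509 individuals
(`src/aimpanel/data/panel_reference_stats.csv`), which the test-suite and the
acceptance script reproduce from first principles.

## Input format

A TSV with header `sample  population  <locus_1> ... <locus_L>` and cells
`0/1/2` (insertion dosage), `II/ID/DD`, or `./.` for missing, mixed freely.
A VCF importer for biallelic indel records is provided
(`aimpanel.io_formats.read_vcf_biallelic_indels`); dosage counts the longer
allele of REF/ALT.

## CLI

```sh
panel simulate --out world.tsv --seed 1          # synthetic 5-continent world
panel forensic world.tsv --out forensic.csv
panel fst world.tsv --out fst.csv                # add --per-locus for locus table
panel classify world.tsv --loocv --out confusion.csv
panel admixture world.tsv -k 3 --out q.csv
panel deltak world.tsv --out deltak.csv
panel pca world.tsv --out pca.csv
panel mds world.tsv --out mds.csv
panel njtree world.tsv --out tree.nwk
panel run-all world.tsv --out results/ --seed 1 --target-group TARGET
```

`run-all` executes the whole sequence (forensic → informativeness → F_st →
LOOCV → admixture + ΔK → supervised target components → PCA/MDS/NJ tree) and
writes a `manifest.json` with artifact paths, seed, config echo and timings.
Loci can be dropped from the cross-population stages only via
`--exclude-locus`, mirroring panels whose reference data lack a locus.

## Conventions

- Dosage counts the **insertion** allele; deletion frequency is `1 − p`.
- Missing genotypes are excluded locus-wise from counts; the classifier
  skips missing loci; PCA mean-imputes per locus.
- Expected heterozygosity uses the small-sample correction
  `(2n/(2n−1))·2pq`; the exact HWE test is the conditional enumeration test.
- Weir–Cockerham θ is reported unclamped (clamp flag available); multilocus
  θ is the ratio-of-sums estimator.
- EM admixture: uncorrelated frequencies, P clipped to `[1e−6, 1−1e−6]`,
  cluster labels aligned across runs by greedy P-correlation matching.
- Naive-Bayes training frequencies use a Jeffreys-style pseudo-count
  (s = 0.5 per allele, configurable); equal class priors; argmax ties break
  lexically.
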