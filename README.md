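# ppientropy

Per-patient Shannon-entropy analysis of protein–protein-interaction (PPI)
subnetworks built from up-regulated genes, for systems-biology and
precision-oncology researchers who want a network-level readout of tumor
complexity from paired tumor/control RNA-seq.

## The method

For each patient with a paired tumor and control sample:

1. **Differential expression.** Subtract the control expression vector from
   the tumor vector over the shared gene universe (RSEM-normalized values,
   negative differentials retained).
2. **Up-regulation call.** Form the relative-frequency histogram of the
   differentials, transform each frequency by `y' = log10(y + 1)`, and
   least-squares fit a Gaussian `A·exp(−(x−μ)²/2σ²)` to the transformed
   bulk. Genes whose differential strictly exceeds the one-tail cut
   `μ + σ·z(1−α)` (α = 0.05, `z(0.95)` = 1.6449) are called up-regulated.
3. **Subnetwork induction.** Map the called genes to UniProtKB accessions
   and keep every interactome edge with both endpoints in that set
   (isolated proteins are dropped).
4. **Entropy.** Summarise the subnetwork by the Shannon entropy of its
   degree distribution, in bits:

   `H = − Σ_k p(k) · log2 p(k)`

   where `p(k)` is the fraction of subnetwork nodes with degree `k`. H
   depends only on proportions, never on network size.
5. **Hub-removal null.** Compare the entropy after deleting the top-5
   degree hubs against an empirical null of 1,000 random 5-node removals;
   the one-sided pseudo-count p-value locates the hub attack in the null's
   left tail.

At cohort level, the mean subnetwork entropy of each cancer type is
regressed on its Kaplan–Meier 5-year survival rate (`100·S(1825 days)`).
The fitted line evaluated at 100% survival defines an entropy goal; for
each patient, the top-20 baseline hubs are removed cumulatively and the
number of targets prescribed is the smallest n whose post-removal entropy
reaches the goal. Cohort entropy heterogeneity is tested with
Kruskal–Wallis plus pairwise Mann–Whitney tests under Holm correction.

A synthetic-data generator (scale-free interactome, planted degree-biased
up-regulation, entropy-linked censored survival) emits the exact file
formats the readers consume, so the whole pipeline is testable without any
download.

## Worked example

```
ppientropy simulate --seed 5 --out data/ --n-proteins 1000 --n-genes 1000 \
    --cohorts 4 --patients-per-cohort 10
ppientropy cohort --expression data/expression.tsv \
    --sample-sheet data/sample_sheet.tsv --mapping data/mapping.tsv \
    --interactome data/interactome.mitab --clinical data/clinical.tsv \
    --seed 5 --out run/
ppientropy report --run-dir run/
```

prints

```
Kruskal-Wallis chi2 = 11.894, df = 3, p = 0.00775
entropy ~ survival: Y = -0.0033X + 1.215 (r = -0.66, p = 0.341)
100%-survival entropy goal: 0.881 bits
targets ~ survival: slope -0.0142 (r = -0.75)
notice: cohort C1: below-30 paired patients (10)
...
```

Reading the output: the four synthetic cancer types differ significantly
in mean subnetwork entropy (Kruskal–Wallis p ≈ 0.008); entropy falls by
about 0.0033 bits per percentage point of 5-year survival (with only 4
cohorts the slope is not yet significant, hence p = 0.34); a tumor whose
entropy exceeds 0.881 bits needs at least one hub inactivated to reach the
entropy associated with 100% survival; and cohorts with poorer survival
need more targets on average (negative targets-vs-survival slope). The
below-30 notices flag cohorts smaller than the minimum recommended for
stable cohort statistics. Per-patient detail lands in `run/patients.tsv`
(up-regulated counts, subnetwork size, entropy, top hubs, null-test p,
target count) with full hub rankings in `run/patients.json` and cumulative
removal trajectories in `run/target_plans.json`.

The same analysis runs on real inputs: a TCGA RNASeqV2-style expression
TSV, a patient/tumor/control sample sheet, a GeneSymbol→UniProtKB mapping
TSV, a PSI-MITAB interactome (e.g. IntAct's `intact-micluster.txt`), and a
TCGA-CDR-style clinical table with `OS`/`OS.time` columns.

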