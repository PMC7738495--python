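# consortia

Minimal microbial consortium prediction from binary protein-family profiles.

Culture collections are most useful when a small, defined subset of isolates
("minimal consortium") captures as much as possible of the functional
potential of the microbiome it models.  `consortia` implements that design
problem for the common setting where genomes and metagenomes are reduced to
presence/absence sets of protein families (Pfam-style identifiers), plus the
cohort statistics that go with it:

* **Selection** — for each metagenome *M*, isolates from a reference panel
  are added greedily by the score `S(C) = |C ∩ M| − λ·|C \ M|` (matches minus
  λ-weighted mismatches of the pooled consortium profile, λ = 1 by default;
  λ = 0 is classic greedy maximum coverage).  The community size per sample
  is the knee of the cumulative functional-coverage curve — the point at
  maximum perpendicular distance from the first-to-last chord.
* **Cohort aggregation** — per-species selection prevalence (overall and per
  sample group) and median picking rank; the "core consortium" is every
  species selected in >50% of samples of at least one group.
* **Group separation** — PERMANOVA-style pseudo-F on the Jaccard distance
  matrix of the profiles, with label permutation (exact enumeration on small
  designs).
* **Host ecology** — per-sample cultured fraction from a set of taxa matched
  to isolates, Kruskal–Wallis host comparison, and host-enrichment calls
  (detected in ≥20% of target-host samples and higher median abundance than
  every other host by one-sided Wilcoxon rank-sum, Benjamini–Hochberg
  adjusted p < 0.05).
* **Synthetic data** — generators for reference panels, metagenome cohorts
  with planted communities and false-present/false-absent noise, and
  host-labelled abundance tables with planted enrichment, so every stage can
  be validated against known ground truth.

See `docs/methods.md` for the model details, parameter defaults, and what
the synthetic validation does and does not demonstrate.

## Worked example

Simulate a 15-genome panel and a 12-sample cohort in two groups with
group-private family content, then run the pipeline:

```sh
cat > params.yaml <<'YAML'
panel: {n_genomes: 15, n_families: 600, core_fraction: 0.25, accessory_prob: 0.25}
n_samples: 12
community_size: [5, 8]
fp_rate: 0.01
fn_rate: 0.02
groups: {CN: 6, DK: 6}
group_private_families: 40
YAML

consortia simulate cohort --params params.yaml --seed 11 --out-prefix demo
consortia select --panel demo.panel.tsv --metagenomes demo.cohort.tsv \
    --lambda 1.0 --tolerance 0.05 --out selections.json
consortia aggregate --selections selections.json --groups demo.groups.tsv \
    --threshold 0.5 --out summary.tsv
consortia grouptest --profiles demo.cohort.tsv --groups demo.groups.tsv \
    --permutations 999 --seed 1 --out grouptest.json
```

which prints

```
12 samples × 680 families
selected communities for 12 samples -> selections.json
1 core genomes (prevalence > 50%, any_group) -> summary.tsv
pseudo-F = 7.351, p = 0.002165 -> grouptest.json
```

The first sample's record in `selections.json` shows a coverage curve
`[0.477, 0.636, 0.745, 0.829, 0.88, 0.919, 0.93]` with `knee_k = 4`: the
fourth pick is where marginal coverage gain drops off, so its minimal
community is the first four ranked genomes `G013, G001, G003, G015`.  The
summary row for the core genome reads

```
genome_id  n_selected_total  prevalence_total  median_rank  prevalence_CN  prevalence_DK  core
     G001                 5          0.416667          2.0       0.166667       0.666667  True
```

G001 makes the community in 67% of DK samples (median rank 2), crossing the
>50%-in-one-group rule even though its cohort-wide prevalence is 42%.  The
group test's pseudo-F of 7.35 with p ≈ 0.002 confirms that the two groups'
functional profiles separate — driven by the 40 group-private families the
simulation planted.

The same functions are importable directly
(`from consortia import select_minimal_community, host_enrichment, ...`);
the CLI is a thin layer over them.

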