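# cosegsel

Co-segregation analysis of bulk-segregant RNA-seq and label-free
proteomics, for nominating insect effector candidates.

## The problem

Aphids secrete salivary effector proteins into host plants; some subvert
host immunity (virulence), others are recognised by host resistance genes
(avirulence). Comparing a virulent and an avirulent aphid genotype directly
confounds the causative genes with thousands of unrelated expression
differences between divergent genetic backgrounds. When virulence
segregates as a single dominant Mendelian locus in an F1 cross, bulked
segregant analysis (BSA) breaks that confound: pool the most virulent and
the most avirulent F1 siblings, and background differences — segregating
independently of the virulence locus — average out of the pooled
transcriptomes while locus-linked differences persist. Intersecting the
resulting gene lists with saliva and salivary-gland proteomes filters
candidates down to proteins whose expression *co-segregates* with the
phenotype and which are demonstrably secreted.

`cosegsel` is for researchers running (or evaluating) such a design: it
implements the phenotyping, the count-based differential-expression engine,
the Perseus-style proteome quantitation, the evidence-intersection filter,
and a synthetic generator of the whole F1 multi-omics world with known
ground truth.

## What is implemented

* **Phenotyping** — virulence index VI = log2(mean survivors out of 5 ×
  nymphs + 1); strict-threshold VIR/AVR classification (VI > 4 / < 2 on
  A17, > 5 / < 4.5 on the resistant NIL); 5-day confirmation screen;
  cross-host Pearson correlation; selection of the two 22-clone bulks.
* **RNA-seq DE** — TMM normalisation (matches edgeR's factors to 1e-6 on a
  frozen fixture), TMM-FPKM, moderated method-of-moments NB dispersion, a
  conditional NB exact test on group-summed pseudo-counts (reduces exactly
  to the conditional binomial test at φ = 0), Benjamini–Hochberg FDR, calls
  at |log2FC| > 2 and FDR < 0.05.
* **Proteomics** — MaxQuant protein-groups parsing; decoy/contaminant
  filtering; log2 transform; MNAR downshift imputation
  (Normal(μ − 2.1σ, (0.1σ)²) over all measured values); Welch SSDA test at
  p ≤ 0.05; signed relative fold change (|RFC| ≥ 1); exclusive-detection
  calls (all replicates of one genotype, none of the other); Venn and
  annotation summaries.
* **Integration** — gene × dataset evidence matrix over saliva, salivary
  gland, parental heads, parental bodies and F1 pools; the candidate rule
  (≥ 3 datasets, or F1 plus ≥ 1 other); direction-conflict detection;
  corroboration rates; hypergeometric / Wallenius category enrichment.
* **Simulator** — Mendelian F1 cross (dominant `Vv` × `vv`, 1:1
  segregation, hybrid-marker verification), plant-level phenotype assays,
  NB count matrices with virulence-linked and background cis-effects,
  log-normal proteomes with abundance-dependent dropout, all with ground
  truth for parameter-recovery testing.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Run the full synthetic workflow at its default scale (78 F1 clones, bulks
of 22, 2,000 genes with 200 background-divergent and 10 virulence-linked,
800-protein panels with 20 truly absent):

```sh
cosegsel run-all --seed 1 --out run1
```

prints

```
run complete; manifest at run1/manifest.json
  parent_head_R: 90 up-VIR, 117 up-AVR
  parent_head_S: 90 up-VIR, 117 up-AVR
  parent_body: 90 up-VIR, 118 up-AVR
  F1_body: 3 up-VIR, 7 up-AVR
```

This is the design's signature result: the parental whole-body contrast
calls 208 genes (the 200 divergent-background genes plus the 10 linked
genes, minus a few low-expression misses), while the bulked-F1 contrast
calls only 10 — and those 10 are exactly the virulence-locus-linked genes,
the background having averaged out of the pools. The head contrasts repeat
the parental comparison on both host genotypes (host effects are off by
default, so R and S agree).

`run1/` then contains every intermediate table (phenotypes, virulence
calls with bulk membership, count matrices, per-contrast DE tables, SSDA
and exclusive-protein tables, the evidence matrix, the candidate list, and
enrichment tables), each headed by a comment naming its generating stage,
plus `manifest.json` with parameters and per-table checksums — rerunning
with the same seed reproduces the tables byte-for-byte. In this run the
candidate filter retains 84 genes; the first line of `run1/candidates.tsv`:

```
id	side	n_datasets	rule
GENE_00006	AVR	5	both
```

a virulence-locus-linked gene supported in all five datasets on the AVR
side — the synthetic analogue of a top effector candidate.

Individual stages are available as `cosegsel simulate | phenotype | de |
proteomics | integrate`, each reading and writing plain tab-separated
tables, and as library functions (`cosegsel.rnaseq.de_test`,
`cosegsel.proteomics.ssda_ttest`, ...).

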