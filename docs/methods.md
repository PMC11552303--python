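# Methods

`cosegsel` implements a co-segregation analysis for nominating insect
effector candidates: bulked-segregant RNA-seq of an F1 aphid population
segregating for a dominant virulence locus, label-free quantitative
proteomics of saliva and salivary glands, and an evidence-intersection
filter over the resulting gene lists. A synthetic multi-omics generator
reproduces the statistical structure of the experimental design so that
every stage can be exercised, and its parameter-recovery behaviour measured,
without any external data.

## The genetic model

Virulence on resistant *Medicago truncatula* hosts (carrying the *RAP1*
resistance locus) is controlled by a single biallelic locus with a fully
dominant allele `V`. The virulent parent is heterozygous `Vv` — the only
configuration that yields the observed 1:1 segregation when crossed to an
avirulent `vv` parent — and each F1 clone draws its genotype independently
with P(`Vv`) = 1/2. Neutral marker loci carry parent-private allele pairs;
a true hybrid therefore has exactly one allele from each parent at every
locus, which is the check `verify_f1` applies (any single contaminated
locus fails a clone). Incomplete penetrance can be introduced through the
survival probabilities but is off by default.

## Phenotyping

Each clone × host assay infests five nymphs on each of ten plants and
scores plant-level survivors and nymph production ten days later. The
virulence index is

    VI = log2(mean survivors out of 5 × nymphs produced + 1)

Both factors are per-plant means by default; a clone-total nymph variant is
exposed because the index's printed definition does not fix the statistic.
Classification uses strict inequalities — VIR: VI > 4 (A17) and > 5
(RNIL); AVR: VI < 2 (A17) and < 4.5 (RNIL); boundary values stay
unclassified — with the laxer RNIL cutoffs reflecting that host's slightly
weaker resistance. A five-day confirmation screen (four plants × five
aphids; survival fraction = survivors / 20) confirms VIR above 80% survival
on both hosts and AVR below 20% (A17) and 70% (RNIL), with an override
flag for clones that survive but barely grow. Bulks take the `k = 22`
most extreme confirmed clones per class by A17 index, with deterministic
tie-breaking (RNIL index, then clone id) so reruns select identical bulks.

In the simulator, survivors are Binomial(5, p) per plant and nymphs are
negative binomial around the configured fecundity (forced to zero when no
aphid survives — dead clones cannot reproduce). Defaults: p = 0.9 / 0.05
for `Vv` / `vv` on resistant hosts (fecundity 30 / 1), and virulent-class
parameters for every clone on susceptible hosts (p = 0.95, fecundity 30),
so both genotypes perform identically where the resistance locus is absent.
The generator gives every clone of a genotype the same assay parameters —
no clone-level random effect — so simulated populations separate more
cleanly, and the cross-host index correlation runs higher (≈ 0.99), than a
real F1 population; passing phenotyping tests demonstrate threshold logic
and parameter recovery, not robustness to continuous phenotypic variation.

## Expression model and differential expression

Each gene has a baseline relative abundance (log-normal, σ = 1.2).
Virulence-locus-linked genes (default 10) shift by ±4 log2 units with any
`V` allele (dominant coding, random direction per gene). Background genes
(default 200) carry a divergent cis-allele private to the virulent parent
that segregates independently of `V`; roughly half the clones in any F1
pool inherit it, so pooled means equalise while the parental contrast
retains the full shift — the mechanism that makes bulked-segregant
filtering work. A pool's expected expression is the arithmetic mean of its
member clones' normalised expression (equal aphid numbers pool transcripts
approximately additively). Counts are gamma-Poisson with dispersion φ
(default 0.1; Poisson at 0) around library-size-scaled means; library
sizes vary uniformly ±15% around 500,000. Desk-scale sizes — 2,000 genes,
500k-read libraries — keep the full suite and the acceptance run inside a
few minutes while preserving per-gene counts (~250) comparable to a
genome-scale experiment's mid-expressed genes.

The DE engine is a from-scratch implementation of the classic count
workflow:

* **TMM normalisation.** Reference = sample whose upper-quartile count
  fraction is closest to the mean fraction; per sample, M and A values over
  genes positive in both libraries are trimmed (30% two-sided on M, 5% on
  A, rank-based with average ties) and the factor is 2^(precision-weighted
  mean M) with delta-method weights; factors are rescaled to geometric mean
  one. Agreement with the reference implementation is pinned to 1e-6 on a
  frozen fixture.
* **FPKM** uses the effective (TMM-scaled) library size:
  `count × 1e9 / (length × lib × factor)`; heatmap exports are
  log2(FPKM + 1), gene-wise zero-centred.
* **Dispersion** is method-of-moments per gene, `max(0, (s² − μ)/μ²)` on
  counts rescaled to the geometric-mean library size with variance pooled
  over within-group residuals, shrunk toward the genome-wide median with a
  prior weight of 10 residual df — enough to stabilise 3–5-replicate
  designs without erasing per-gene signal.
* **Exact test.** Counts are rescaled to the common (geometric-mean)
  effective library size, rounded to pseudo-counts and summed per group.
  A sum of n i.i.d. NB(μ, φ) is exactly NB(nμ, φ/n), so conditional on the
  total the split follows the normalised product of the two group-sum
  pmfs with means proportional to replicate numbers; the two-sided p sums
  all splits no more likely than the observed one (with a 1e-10 relative
  tolerance on pmf ties). At φ = 0 this reduces exactly to the conditional
  binomial test, which is the oracle the tests enumerate. This group-sum
  conditional test was chosen over a quasi-likelihood GLM because every
  contrast in the design is two-group, and because it admits a brute-force
  oracle.
* **Calls.** log2FC is computed on group-mean CPM with a prior count of
  0.5 on both means; genes with zero counts across a contrast are dropped
  before Benjamini–Hochberg correction (they are untestable and only
  inflate m); a call requires |log2FC| > 2 and FDR < 0.05, strictly. No
  low-expression CPM filter is applied by default (one is available), since
  the exact test is already conservative at low counts.

Simulated effects are ±4 log2 units so that true signals clear the
|log2FC| > 2 call threshold with margin; under the null the exact test's
p < 0.05 rate calibrates to ~5–6% at φ = 0.1, n = 5.

## Proteomics

MaxQuant-style protein-group tables ("LFQ intensity <sample>" columns,
0/empty = not detected, "+" flags for reverse / contaminant / site-only
entries) are filtered, log2-transformed and imputed: each missing cell is
drawn from Normal(μ − 2.1σ, (0.1σ)²), where μ and σ summarise **all**
measured values (global scope; a per-sample mode is available). The
downshift treats missingness as abundance-dependent (MNAR): missing
signals are most plausibly low-abundance ones. SSDA testing is a Welch
two-sample t-test per protein at p ≤ 0.05 with no multiple-testing
correction — deliberately mirroring standard practice for these small
panels; a BH-corrected mode sits behind a flag. Degenerate zero-variance
proteins are handled explicitly (p = 1 when both groups are constant and
equal; an `exactly_separated` flag instead of a spurious p = 0 otherwise).
Relative fold change is computed on un-logged group means of imputed LFQ
with the signed-reciprocal convention (A/B when A ≥ B, else −B/A), so
|RFC| ≥ 1 and the sign names the more abundant group. Exclusive proteins —
detected in all replicates of one genotype, none of the other, before
imputation — are the qualitative complement to SSDA. PCA runs on imputed
intensities by default (unimputed is exposed). Percentage summaries round
half away from zero, and "percent shared" is reported against the union
and against both totals, since quoted fractions vary in their denominator.

The simulated proteome panel comprises the products of the first 800 genes
(linked genes are placed inside this panel — effector candidates are, by
construction, expressed where proteomics can see them). Log2 intensities
are Gaussian (replicate SD 0.3) around protein × genotype means drawn from
N(25, 2); linked-gene proteins shift 2 log2 units in their transcript
direction, 80 further proteins shift in either direction, and 20 are truly
absent from one genotype. A cell drops out with probability
logistic((midpoint − x) · slope).

**Calibrating the detection limit.** The dropout midpoint and slope control
how often a protein present in both genotypes is, by chance, detected in
all four replicates of one and none of the other — a false "exclusive"
call. A limit inside the abundance distribution (midpoint 2 SD below the
mean location, shallow slope) produced such coincidences at a rate that
overwhelmed the 20 true absences; a steep slope at the same midpoint was
worse, turning every differential protein that straddles the limit into a
deterministic false exclusive. The defaults therefore place the limit in
the far tail (midpoint 19 ≈ 3 SD below the protein-mean location) with a
steep transition (slope 3 per log2 unit, matching the ~1–2 log2-unit
detection transition of real LFQ data), giving an expected false-exclusive
rate well under one per run against 20 true absences. The pipeline's
saliva layer shifts the midpoint up by +3, producing the sparser detection
(~10% missing) characteristic of saliva samples relative to gland tissue.
Consequences for interpretation: exclusive-call precision near 1.0 on
defaults shows the rule recovers truth when detection is reliable; it does
not bound the false-exclusive rate of real data whose detection limit cuts
into the abundance distribution.

## Integration

Five datasets feed a gene × dataset evidence matrix — saliva, salivary
gland, parental heads, parental bodies, bulked F1 bodies — with cell states
absent / up_VIR / up_AVR / present_undirected. For proteome datasets
"represented" means detected or differentially abundant (directed calls
take precedence over presence); for transcriptome datasets it means
DE-called only. Identifier unification is an explicit input map; unmapped
ids are reported, never silently dropped (orthology inference is out of
scope — the simulator uses protein ids identical to gene ids).

The candidate filter keeps genes non-absent in at least three datasets,
plus every gene shared between the F1 transcriptome and at least one other
dataset. A candidate's side is VIR or AVR only when every directed cell
agrees; mixed-direction genes are labelled conflicts and listed separately,
as are parent-vs-F1 opposite-direction genes with their pattern
(VIRparent/AVRF1 or AVRparent/VIRF1). Undirected presence never creates a
conflict. Corroboration rates (members of a focal directed set that are
directed in ≥ 1 other dataset) and annotation fractions (secretion-signal
%, non-annotated %) round half away from zero. "Non-annotated" means a
descriptor carrying no functional information: hypothetical /
uncharacterized / predicted protein, bare NA, or a bare genome-project
accession.

Category enrichment is a one-sided hypergeometric tail (exact against
brute-force enumeration on all universes ≤ 25 in the tests); supplying
per-gene bias weights switches to Wallenius' noncentral hypergeometric
with the term's mean-weight odds, a single-odds approximation to full
length-bias correction (which is out of scope). Strict mode requires
BH-FDR < 0.05; lenient mode requires at least two DE genes in the term and
raw p < 0.05, the exploratory setting for small gene sets.

## Pipeline and reproducibility

`run_all` executes simulate → phenotype → bulk selection → DE (four
contrasts: parental heads on resistant and susceptible hosts, parental
bodies, F1 pools) → proteomics (saliva, salivary gland) → integration. All
randomness flows from one seed through named substreams (stream name
CRC32-hashed into the spawn key), so any stage rerun alone reproduces its
draws, and a full rerun is byte-identical (checksums in the manifest).
Every output table begins with a comment line naming its generating stage
and parameters. A stage failure halts the run with the stage name; partial
outputs are retained.

## Known limitations

* No sequence-level simulation (reads, peptides, genomes), recombination
  maps, epistasis, or parent-of-origin effects; one virulence locus only.
* Host-genotype effects on aphid expression default to off (configurable),
  so simulated head contrasts across hosts are null by construction.
* Phenotypes lack clone-level random effects (see Phenotyping above).
* The proteome detection limit sits in the abundance tail by default (see
  the calibration note above).
* Enrichment ignores ontology DAG structure; terms are flat gene sets.
* The NB exact test enumerates all splits of a gene's pseudo-count total,
  which is quadratic in expression for extremely deep libraries; at the
  default library sizes this is negligible.
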