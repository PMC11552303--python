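"""Synthetic F1 cross with linked multi-omics readouts.

This module builds a miniature version of the experimental system the rest of
the package analyses: two divergent clonal aphid parents (one virulent, one
avirulent on resistant *Medicago* hosts), an F1 population segregating 1:1
for a single dominant virulence locus, per-clone phenotype assays, bulked and
parental RNA-seq count matrices, and label-free proteome intensity tables
with abundance-dependent (MNAR) dropout.

The generator exists so that every downstream stage — virulence indexing,
bulk selection, TMM/NB differential expression, downshift imputation,
evidence integration — can be exercised end to end with known ground truth
and no external data.

Model sketch
------------
* One biallelic virulence locus; the VIR parent is heterozygous ``Vv`` (the
  only configuration compatible with 1:1 segregation from a cross against a
  ``vv`` parent), ``V`` fully dominant.
* Neutral marker loci are heterozygous in both parents with parent-private
  allele symbols, so a true F1 carries exactly one allele from each parent
  at every locus (the hybrid check).
* Expression: each gene has a baseline relative abundance. "Linked" genes
  are cis-regulated by the virulence locus (any ``V`` shifts the mean by
  ``effect_log2fc``). "Background" genes carry a divergent cis-allele private
  to the VIR parent that segregates independently of ``V``; in an F1 pool
  roughly half the clones carry it, so pooled means equalise while the
  parental contrast keeps the full shift. Counts are negative-binomial
  (gamma-Poisson) around library-size-scaled means.
* Proteomes: log2 intensities are Gaussian around protein x genotype means;
  a cell is observed with probability ``1 - logistic((midpoint - x) * slope)``
  so that low-abundance signals drop out preferentially; a configured subset
  of proteins is truly absent in one genotype (ground-truth "exclusive"
  candidates).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SimConfig",
    "ParentalGenome",
    "F1Clone",
    "make_parents",
    "simulate_cross",
    "verify_f1",
    "simulate_phenotypes",
    "GeneModel",
    "CountSample",
    "simulate_counts",
    "ProteinSample",
    "simulate_intensities",
    "write_counts_tsv",
    "write_protein_groups_tsv",
    "write_phenotypes_tsv",
]

#: host genotype -> resistance class (R carries the resistance locus, S lacks it)
HOST_CLASS = {"A17": "R", "RNIL": "R", "SNIL": "S", "DZA": "S"}


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


def _default_survival() -> dict[tuple[str, str], float]:
    return {
        ("Vv", "R"): 0.90,
        ("vv", "R"): 0.05,
        ("Vv", "S"): 0.95,
        ("vv", "S"): 0.95,
    }


def _default_fecundity() -> dict[tuple[str, str], float]:
    return {
        ("Vv", "R"): 30.0,
        ("vv", "R"): 1.0,
        ("Vv", "S"): 30.0,
        ("vv", "S"): 30.0,
    }


@dataclass
class SimConfig:
    """All parameters of the synthetic F1 multi-omics world.

    Defaults mirror the experimental design: 78 screened F1 clones, 7 microsatellite
    marker loci, bulks of 22, 4 proteome replicates per genotype, and a
    dominant virulence locus segregating 1:1.
    """

    n_f1: int = 78
    n_markers: int = 7
    n_genes: int = 2000
    n_background_de: int = 200
    n_linked: int = 10
    effect_log2fc: float = 4.0
    dispersion: float = 0.1
    lib_size_mean: int = 500_000
    lib_size_jitter: float = 0.15
    n_proteins: int = 800
    n_protein_de: int = 80
    n_absent: int = 20
    protein_effect_log2: float = 2.0
    protein_rep_sd: float = 0.3
    protein_mean_loc: float = 25.0
    protein_mean_scale: float = 2.0
    missing_logistic_midpoint: float = 19.0
    missing_logistic_slope: float = 3.0
    survival_probs: Mapping[tuple[str, str], float] = field(default_factory=_default_survival)
    fecundity_mean: Mapping[tuple[str, str], float] = field(default_factory=_default_fecundity)
    nymph_dispersion: float = 0.3
    n_host_responsive: int = 0
    host_effect_log2fc: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_f1", "n_markers", "n_genes", "n_background_de", "n_linked",
                     "n_proteins", "n_protein_de", "n_absent", "n_host_responsive"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.n_background_de + self.n_linked > self.n_genes:
            raise ConfigError("n_background_de + n_linked exceeds n_genes")
        if self.dispersion < 0 or self.nymph_dispersion < 0:
            raise ConfigError("dispersions must be >= 0")
        if self.lib_size_mean <= 0:
            raise ConfigError("lib_size_mean must be positive")
        if not 0.0 <= self.lib_size_jitter < 1.0:
            raise ConfigError("lib_size_jitter must lie in [0, 1)")
        for key, p in self.survival_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"survival probability out of [0,1] for {key}: {p}")
        for key, m in self.fecundity_mean.items():
            if m < 0:
                raise ConfigError(f"fecundity mean negative for {key}: {m}")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream so each stage is independently reproducible.

        The stream name is hashed (CRC32, stable across runs and platforms)
        into the spawn key, so adding streams never perturbs existing ones.
        """
        key = zlib.crc32(stream.encode())
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )


@dataclass(frozen=True)
class ParentalGenome:
    """A clonal parent: VIR carries the dominant virulence allele ``V`` once."""

    label: str  # "VIR" or "AVR"
    alleles: tuple[tuple[str, str], ...]  # per marker locus
    virulence_genotype: str  # "Vv" or "vv"


@dataclass(frozen=True)
class F1Clone:
    """One F1 progeny clone.

    ``alleles`` holds, per marker locus, (allele from VIR parent, allele from
    AVR parent). ``background_dosage`` is the per-background-gene indicator of
    having inherited the VIR parent's divergent cis-allele (dominant coding).
    """

    id: str
    alleles: tuple[tuple[str, str], ...]
    virulence_genotype: str
    background_dosage: tuple[int, ...] = ()

    @property
    def has_v(self) -> bool:
        return "V" in self.virulence_genotype


def make_parents(config: SimConfig) -> tuple[ParentalGenome, ParentalGenome]:
    """Construct VIR and AVR parents with parent-private marker alleles."""
    vir_alleles = tuple((f"L{i}.V1", f"L{i}.V2") for i in range(config.n_markers))
    avr_alleles = tuple((f"L{i}.A1", f"L{i}.A2") for i in range(config.n_markers))
    vir = ParentalGenome("VIR", vir_alleles, "Vv")
    avr = ParentalGenome("AVR", avr_alleles, "vv")
    return vir, avr


def simulate_cross(config: SimConfig) -> list[F1Clone]:
    """Draw ``n_f1`` true hybrid clones; P(Vv) = 1/2 independently per clone."""
    rng = config.rng("cross")
    vir, avr = make_parents(config)
    clones: list[F1Clone] = []
    width = max(3, len(str(max(config.n_f1, 1))))
    for i in range(config.n_f1):
        alleles = tuple(
            (vir.alleles[m][rng.integers(2)], avr.alleles[m][rng.integers(2)])
            for m in range(config.n_markers)
        )
        genotype = "Vv" if rng.random() < 0.5 else "vv"
        dosage = tuple(int(x) for x in rng.integers(0, 2, size=config.n_background_de))
        clones.append(F1Clone(f"F1_{i:0{width}d}", alleles, genotype, dosage))
    return clones


def verify_f1(
    clone: F1Clone,
    parents: tuple[ParentalGenome, ParentalGenome],
    marker_loci: Sequence[int] | None = None,
) -> bool:
    """Hybrid check: at every marker locus, one allele from each parent.

    Mirrors microsatellite verification of progeny: a selfed or contaminant
    clone fails at any locus where both alleles trace to a single parent.
    """
    vir, avr = parents
    if marker_loci is None:
        marker_loci = range(len(clone.alleles))
    for locus in marker_loci:
        if locus < 0 or locus >= len(clone.alleles) or locus >= len(vir.alleles):
            raise KeyError(f"unknown marker locus {locus}")
        a, b = clone.alleles[locus]
        vir_set, avr_set = set(vir.alleles[locus]), set(avr.alleles[locus])
        if not ((a in vir_set and b in avr_set) or (b in vir_set and a in avr_set)):
            return False
    return True


def simulate_phenotypes(
    clones: Sequence[F1Clone],
    config: SimConfig,
    hosts: Sequence[str] = ("A17", "RNIL"),
    n_plants: int = 10,
    n_infested: int = 5,
    day: int = 10,
) -> pd.DataFrame:
    """Plant-level survival/fecundity assay for each clone x host.

    Per plant: ``survivors ~ Binomial(n_infested, p(genotype, host class))``
    and, when any survive, ``nymphs ~ NB(fecundity_mean, nymph_dispersion)``;
    dead plants produce zero nymphs. ``Vv`` clones use virulent parameters on
    resistant hosts (complete dominance); every clone uses virulent-class
    parameters on susceptible hosts.
    """
    rng = config.rng("phenotypes")
    records = []
    for clone in clones:
        for host in hosts:
            host_class = HOST_CLASS.get(host)
            if host_class is None:
                raise ConfigError(f"unknown host genotype {host!r}")
            genotype = clone.virulence_genotype if host_class == "R" else "Vv"
            key = (genotype, host_class)
            if key not in config.survival_probs or key not in config.fecundity_mean:
                raise ConfigError(f"missing phenotype parameters for {key}")
            p = config.survival_probs[key]
            mu = config.fecundity_mean[key]
            for plant in range(1, n_plants + 1):
                survivors = int(rng.binomial(n_infested, p))
                if survivors == 0 or mu == 0:
                    nymphs = 0
                else:
                    nymphs = int(_nb_draw(rng, np.array([mu]), config.nymph_dispersion)[0])
                records.append((clone.id, host, plant, survivors, nymphs, day))
    return pd.DataFrame(
        records, columns=["clone", "host", "plant", "survivors", "nymphs", "day"]
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mean + phi * mean**2 (Poisson when phi=0)."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


@dataclass(frozen=True)
class GeneModel:
    """Fixed per-world gene parameters shared by every count sample."""

    gene_ids: tuple[str, ...]
    gene_lengths: np.ndarray  # bp
    baseline: np.ndarray  # unnormalised relative abundance
    linked_idx: np.ndarray
    background_idx: np.ndarray
    host_responsive_idx: np.ndarray
    linked_sign: np.ndarray = field(default_factory=lambda: np.array([]))
    background_sign: np.ndarray = field(default_factory=lambda: np.array([]))

    def truth(self) -> pd.DataFrame:
        """Ground-truth labels for test assertions."""
        label = np.array(["null"] * len(self.gene_ids), dtype=object)
        label[self.background_idx] = "background"
        label[self.linked_idx] = "linked"
        label[self.host_responsive_idx] = "host_responsive"
        return pd.DataFrame({"gene": list(self.gene_ids), "label": label})


def build_gene_model(config: SimConfig) -> GeneModel:
    """Draw baselines, lengths and the linked/background gene assignment.

    Linked (virulence-locus cis-regulated) genes are placed inside the first
    ``n_proteins`` gene indices so their products can also surface in the
    simulated proteomes — effector candidates are, by construction, expressed
    where the proteomics can see them.
    """
    rng = config.rng("genes")
    gene_ids = tuple(f"GENE_{i:05d}" for i in range(config.n_genes))
    lengths = rng.integers(300, 5001, size=config.n_genes)
    baseline = rng.lognormal(mean=0.0, sigma=1.2, size=config.n_genes)
    panel = min(config.n_proteins, config.n_genes) or config.n_genes
    linked = rng.choice(panel, size=min(config.n_linked, panel), replace=False)
    remaining = np.setdiff1d(np.arange(config.n_genes), linked)
    background = rng.choice(remaining, size=config.n_background_de, replace=False)
    rest = np.setdiff1d(remaining, background)
    n_host = min(config.n_host_responsive, rest.size)
    host_resp = rng.choice(rest, size=n_host, replace=False) if n_host else np.array([], dtype=int)
    linked, background = np.sort(linked), np.sort(background)
    # cis effects point either way: divergence, not uniform upregulation
    linked_sign = rng.choice([-1.0, 1.0], size=linked.size)
    background_sign = rng.choice([-1.0, 1.0], size=background.size)
    return GeneModel(gene_ids, lengths, baseline, linked, background,
                     np.sort(host_resp), linked_sign, background_sign)


@dataclass(frozen=True)
class CountSample:
    """One RNA-seq library.

    ``source`` is ``"VIR_parent"``, ``"AVR_parent"``, or a tuple of
    :class:`F1Clone` (a bulked pool). ``group`` is the contrast label the DE
    module will see; ``host_class`` only matters when host-responsive genes
    are configured.
    """

    sample_id: str
    source: str | tuple[F1Clone, ...]
    group: str
    host_class: str = "R"


def _expression_vector(model: GeneModel, config: SimConfig, has_v: bool,
                       background_dosage: np.ndarray, host_class: str) -> np.ndarray:
    rel = model.baseline.copy()
    if has_v:
        rel[model.linked_idx] *= 2.0 ** (config.effect_log2fc * model.linked_sign)
    rel[model.background_idx] *= 2.0 ** (
        config.effect_log2fc * model.background_sign * background_dosage)
    if host_class == "R" and model.host_responsive_idx.size:
        rel[model.host_responsive_idx] *= 2.0 ** config.host_effect_log2fc
    return rel / rel.sum()


def source_expression(model: GeneModel, config: SimConfig,
                      source: str | tuple[F1Clone, ...], host_class: str = "R") -> np.ndarray:
    """Expected relative expression of a parent, clone or pool (sums to 1).

    A pool's expectation is the arithmetic mean of its member clones'
    normalised expression: pooling equal aphid numbers pools transcripts
    approximately additively.
    """
    ones = np.ones(config.n_background_de)
    zeros = np.zeros(config.n_background_de)
    if source == "VIR_parent":
        return _expression_vector(model, config, True, ones, host_class)
    if source == "AVR_parent":
        return _expression_vector(model, config, False, zeros, host_class)
    if isinstance(source, str):
        raise ConfigError(f"unknown count source {source!r}")
    if len(source) == 0:
        raise ConfigError("pool with zero member clones")
    members = [
        _expression_vector(model, config, c.has_v, np.asarray(c.background_dosage, float),
                           host_class)
        for c in source
    ]
    rel = np.mean(members, axis=0)
    return rel / rel.sum()


def simulate_counts(
    sample_design: Sequence[CountSample],
    config: SimConfig,
    model: GeneModel | None = None,
    rng: np.random.Generator | None = None,
):
    """NB count matrix for a design of parental and pooled-F1 libraries.

    Returns a :class:`cosegsel.rnaseq.CountMatrix`. Library sizes vary
    uniformly within ±15% of ``lib_size_mean``; counts are gamma-Poisson with
    dispersion ``config.dispersion`` (Poisson when 0).
    """
    from .rnaseq import CountMatrix  # local import to avoid a cycle

    if model is None:
        model = build_gene_model(config)
    if rng is None:
        rng = config.rng("counts")
    cols = {}
    groups = {}
    for s in sample_design:
        rel = source_expression(model, config, s.source, s.host_class)
        j = config.lib_size_jitter
        lib = config.lib_size_mean * rng.uniform(1.0 - j, 1.0 + j)
        cols[s.sample_id] = _nb_draw(rng, lib * rel, config.dispersion).astype(np.int64)
        groups[s.sample_id] = s.group
    counts = pd.DataFrame(cols, index=list(model.gene_ids))
    return CountMatrix(
        counts=counts,
        gene_lengths=pd.Series(model.gene_lengths, index=list(model.gene_ids)),
        sample_groups=pd.Series(groups),
    )


@dataclass(frozen=True)
class ProteinModel:
    """Per-world protein parameters: means per genotype plus truth labels."""

    protein_ids: tuple[str, ...]
    mean_vir: np.ndarray  # log2 scale
    mean_avr: np.ndarray
    truth: pd.DataFrame  # protein, label in {null, de_vir, de_avr, absent_in_AVR, absent_in_VIR}


def build_protein_model(config: SimConfig, model: GeneModel | None = None) -> ProteinModel:
    """Protein panel = products of the first ``n_proteins`` genes.

    Linked genes (all inside the panel) are differentially abundant in the
    direction of the virulence allele; a further random subset carries a
    background-biotype abundance shift; ``n_absent`` proteins are truly absent
    from one genotype, split evenly.
    """
    rng = config.rng("proteins")
    if model is None:
        model = build_gene_model(config)
    n = min(config.n_proteins, config.n_genes)
    protein_ids = tuple(model.gene_ids[i] for i in range(n))
    base = rng.normal(config.protein_mean_loc, config.protein_mean_scale, size=n)
    mean_vir = base.copy()
    mean_avr = base.copy()
    label = np.array(["null"] * n, dtype=object)

    in_panel = model.linked_idx < n
    linked = model.linked_idx[in_panel]
    l_sign = model.linked_sign[in_panel] if model.linked_sign.size else np.ones(linked.size)
    # protein abundance tracks the transcript direction of linked genes
    mean_avr[linked[l_sign > 0]] -= config.protein_effect_log2
    mean_vir[linked[l_sign < 0]] -= config.protein_effect_log2
    label[linked[l_sign > 0]] = "de_vir"
    label[linked[l_sign < 0]] = "de_avr"

    pool = np.setdiff1d(np.arange(n), linked)
    n_de = min(config.n_protein_de, pool.size)
    de = rng.choice(pool, size=n_de, replace=False)
    half = n_de // 2
    mean_avr[de[:half]] -= config.protein_effect_log2
    label[de[:half]] = "de_vir"
    mean_vir[de[half:]] -= config.protein_effect_log2
    label[de[half:]] = "de_avr"

    pool = np.setdiff1d(pool, de)
    n_abs = min(config.n_absent, pool.size)
    absent = rng.choice(pool, size=n_abs, replace=False)
    a_half = n_abs // 2
    mean_avr[absent[:a_half]] = -np.inf  # absent in AVR -> VIR-exclusive
    label[absent[:a_half]] = "absent_in_AVR"
    mean_vir[absent[a_half:]] = -np.inf
    label[absent[a_half:]] = "absent_in_VIR"

    truth = pd.DataFrame({"protein": list(protein_ids), "label": label})
    return ProteinModel(protein_ids, mean_vir, mean_avr, truth)


@dataclass(frozen=True)
class ProteinSample:
    sample_id: str
    genotype: str  # "VIR" or "AVR"


def default_protein_design(n_reps: int = 4) -> list[ProteinSample]:
    """4 replicates per genotype, the standard quantitative proteome design."""
    return [ProteinSample(f"VIR_{i + 1}", "VIR") for i in range(n_reps)] + [
        ProteinSample(f"AVR_{i + 1}", "AVR") for i in range(n_reps)
    ]


def simulate_intensities(
    sample_design: Sequence[ProteinSample] | None,
    config: SimConfig,
    protein_model: ProteinModel | None = None,
    gene_model: GeneModel | None = None,
    rng: np.random.Generator | None = None,
):
    """Label-free proteome with MNAR dropout.

    Returns ``(IntensityMatrix, truth)``. Each observed cell is
    ``Normal(mean, protein_rep_sd)`` on the log2 scale; a cell goes missing
    with probability ``logistic((midpoint - x) * slope)``, so low-abundance
    signals drop out preferentially. Truly-absent proteins are missing in all
    replicates of the affected genotype.
    """
    from .proteomics import IntensityMatrix  # local import to avoid a cycle

    if sample_design is None:
        sample_design = default_protein_design()
    if protein_model is None:
        protein_model = build_protein_model(config, gene_model)
    if rng is None:
        rng = config.rng("intensities")
    n = len(protein_model.protein_ids)
    cols = {}
    groups = {}
    for s in sample_design:
        if s.genotype not in ("VIR", "AVR"):
            raise ConfigError(f"protein sample genotype must be VIR/AVR, got {s.genotype!r}")
        mean = protein_model.mean_vir if s.genotype == "VIR" else protein_model.mean_avr
        x = np.where(np.isfinite(mean), rng.normal(mean, config.protein_rep_sd), -np.inf)
        z = (config.missing_logistic_midpoint - x) * config.missing_logistic_slope
        p_missing = np.where(np.isfinite(x), expit(z), 1.0)
        missing = rng.random(n) < p_missing
        vals = np.where(missing, np.nan, 2.0 ** x)
        cols[s.sample_id] = vals
        groups[s.sample_id] = s.genotype
    intensities = pd.DataFrame(cols, index=list(protein_model.protein_ids))
    flags = pd.DataFrame(
        False,
        index=list(protein_model.protein_ids),
        columns=["reverse", "contaminant", "identified_by_site"],
    )
    matrix = IntensityMatrix(intensities=intensities, flags=flags,
                             sample_groups=pd.Series(groups))
    return matrix, protein_model.truth


_FAMILIES = (
    "aminopeptidase N",
    "angiotensin converting enzyme",
    "glutathione S-transferase",
    "peroxidase-like",
    "regucalcin-like",
    "cathepsin B",
    "glucose dehydrogenase",
)


def make_annotations(config: SimConfig, model: GeneModel | None = None) -> pd.DataFrame:
    """Synthetic gene annotation table: description, secretion flag, family.

    Effector-plausible genes (virulence-locus linked) are biased toward
    secretion signals and missing annotations, echoing how real candidate
    lists look; everything else gets either a named enzyme family or a
    generic descriptor.
    """
    if model is None:
        model = build_gene_model(config)
    rng = config.rng("annotations")
    n = config.n_genes
    desc = np.empty(n, dtype=object)
    family = np.empty(n, dtype=object)
    secreted = np.zeros(n, dtype=bool)
    fam_draw = rng.integers(0, len(_FAMILIES), size=n)
    for i in range(n):
        u = rng.random()
        if u < 0.15:
            desc[i] = f"uncharacterized protein LOC1{i:08d}"
            family[i] = "unknown"
        elif u < 0.22:
            desc[i] = "hypothetical protein"
            family[i] = "unknown"
        elif u < 0.45:
            family[i] = _FAMILIES[fam_draw[i]]
            desc[i] = family[i]
        else:
            desc[i] = f"conserved protein {i}"
            family[i] = "other"
        secreted[i] = rng.random() < 0.15
    for i in model.linked_idx:
        secreted[i] = rng.random() < 0.6
        if rng.random() < 0.5:
            desc[i] = f"uncharacterized protein LOC2{i:08d}"
            family[i] = "unknown"
    return pd.DataFrame(
        {"description": desc, "secreted": secreted, "family": family},
        index=list(model.gene_ids),
    )


# ---------------------------------------------------------------------------
# Plain-text writers (tab-separated dialects consumed by downstream modules)
# ---------------------------------------------------------------------------

def write_counts_tsv(cm, path) -> None:
    """gene_id, length, then one integer column per sample."""
    out = pd.DataFrame({"gene_id": cm.counts.index, "length": cm.gene_lengths.values})
    out = pd.concat([out.set_index("gene_id"), cm.counts], axis=1)
    out.to_csv(path, sep="\t", index_label="gene_id")


def write_protein_groups_tsv(im, path) -> None:
    """MaxQuant protein-groups dialect: 'LFQ intensity <sample>' columns,
    missing encoded as 0, '+' convention for Reverse / Potential contaminant."""
    out = pd.DataFrame(index=im.intensities.index)
    out.index.name = "Protein IDs"
    for col in im.intensities.columns:
        out[f"LFQ intensity {col}"] = im.intensities[col].fillna(0.0)
    out["Reverse"] = np.where(im.flags["reverse"], "+", "")
    out["Potential contaminant"] = np.where(im.flags["contaminant"], "+", "")
    out["Only identified by site"] = np.where(im.flags["identified_by_site"], "+", "")
    out.to_csv(path, sep="\t")


def write_phenotypes_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)
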