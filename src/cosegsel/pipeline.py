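"""End-to-end orchestration of the co-segregation workflow.

One structured configuration drives: synthetic cross -> phenotyping ->
bulk selection -> differential expression (parental heads on resistant and
susceptible hosts, parental bodies, bulked F1 pools) -> proteomics (saliva
and salivary gland) -> evidence integration. Every intermediate table is
written as tab-separated text with a header comment naming its generating
stage and parameters, plus a manifest with checksums, so a rerun with the
same seed reproduces byte-identical numeric tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import integration, phenotyping, proteomics, rnaseq, simcross
from .proteomics import ImputationParams
from .simcross import CountSample, SimConfig

__all__ = ["RunConfig", "run_all", "PipelineStageError"]

log = logging.getLogger("cosegsel")


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a full run needs: simulation world, thresholds, output dir."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: Path = Path("cosegsel_run")
    k: int = 22
    lfc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    alpha: float = 0.05
    imputation: ImputationParams = field(default_factory=ImputationParams)
    n_body_reps: int = 5
    n_head_reps: int = 3
    nymph_stat: str = "mean"
    override_avr: tuple[str, ...] = ()
    saliva_midpoint_shift: float = 3.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_block = raw.pop("sim", {})
        for key in ("survival_probs", "fecundity_mean"):
            if key in sim_block:  # YAML maps "Vv,R" -> value
                sim_block[key] = {tuple(k.split(",")): v for k, v in sim_block[key].items()}
        imp_block = raw.pop("imputation", {})
        cfg = cls(sim=SimConfig(**sim_block), imputation=ImputationParams(**imp_block),
                  **{k: v for k, v in raw.items() if k != "out_dir"})
        if "out_dir" in raw:
            cfg.out_dir = Path(raw["out_dir"])
        return cfg

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(self, sim=dataclasses.replace(self.sim, seed=seed))


def _write(df: pd.DataFrame, path: Path, stage: str, params: dict,
           index: bool = True) -> None:
    header = "# stage=%s %s\n" % (stage, " ".join(f"{k}={v}" for k, v in params.items()))
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _directed(de_table: pd.DataFrame) -> dict[str, str]:
    """DE call table -> id -> VIR/AVR (group A is always the VIR-side group)."""
    out = {}
    for gid, row in de_table.iterrows():
        if row["call"] == "up_A":
            out[gid] = "VIR"
        elif row["call"] == "up_B":
            out[gid] = "AVR"
    return out


def run_all(config: RunConfig) -> dict:
    """Execute the whole workflow; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    manifest: dict = {"seed": sim.seed, "parameters": {
        "k": config.k, "lfc": config.lfc_threshold, "fdr": config.fdr_threshold,
        "alpha": config.alpha, "downshift": config.imputation.downshift,
        "width": config.imputation.width, "scope": config.imputation.scope,
        "sim": {k: str(v) for k, v in dataclasses.asdict(sim).items()},
    }, "tables": {}, "summary": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                result = fn()
            except Exception as exc:  # halt with stage name, keep partial outputs
                raise PipelineStageError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return deco

    @stage("simulate_cross")
    def clones():
        return simcross.simulate_cross(sim)

    @stage("phenotype")
    def calls():
        idx = simcross.simulate_phenotypes(clones, sim, hosts=("A17", "RNIL"))
        conf = simcross.simulate_phenotypes(clones, sim, hosts=("A17", "RNIL"),
                                            n_plants=4, day=5)
        _write(idx, out / "phenotypes_day10.tsv", "phenotype", {"day": 10}, index=False)
        _write(conf, out / "phenotypes_day5.tsv", "phenotype", {"day": 5}, index=False)
        table = phenotyping.make_calls(idx, conf, override_avr=config.override_avr,
                                       nymph_stat=config.nymph_stat)
        return table

    @stage("select_bulks")
    def bulks():
        vir_bulk, avr_bulk = phenotyping.select_bulks(calls, k=config.k)
        table = calls.copy()
        table["bulk"] = [
            "VIR" if c in vir_bulk else ("AVR" if c in avr_bulk else "")
            for c in table["clone"]
        ]
        _write(table, out / "virulence_calls.tsv", "phenotype",
               {"k": config.k, "nymph_stat": config.nymph_stat}, index=False)
        return vir_bulk, avr_bulk

    vir_bulk, avr_bulk = bulks
    by_id = {c.id: c for c in clones}

    @stage("simulate_counts")
    def count_matrices():
        model = simcross.build_gene_model(sim)
        heads = []
        for host_cls, host_tag in (("R", "R"), ("S", "S")):
            for g, src in (("VIR", "VIR_parent"), ("AVR", "AVR_parent")):
                for r in range(1, config.n_head_reps + 1):
                    heads.append(CountSample(f"head_{g}_{host_tag}_{r}", src,
                                             f"{g}head{host_tag}", host_cls))
        body = []
        vir_pool = tuple(by_id[c] for c in vir_bulk)
        avr_pool = tuple(by_id[c] for c in avr_bulk)
        for r in range(1, config.n_body_reps + 1):
            body.append(CountSample(f"body_VIRp_{r}", "VIR_parent", "VIRparent"))
            body.append(CountSample(f"body_AVRp_{r}", "AVR_parent", "AVRparent"))
            body.append(CountSample(f"body_VIRf1_{r}", vir_pool, "VIRF1pool"))
            body.append(CountSample(f"body_AVRf1_{r}", avr_pool, "AVRF1pool"))
        cm_heads = simcross.simulate_counts(heads, sim, model,
                                            rng=sim.rng("counts_heads"))
        cm_body = simcross.simulate_counts(body, sim, model,
                                           rng=sim.rng("counts_body"))
        simcross.write_counts_tsv(cm_heads, out / "counts_heads.tsv")
        simcross.write_counts_tsv(cm_body, out / "counts_body.tsv")
        return model, cm_heads, cm_body

    model, cm_heads, cm_body = count_matrices

    contrasts = {
        "parent_head_R": (cm_heads, "VIRheadR", "AVRheadR"),
        "parent_head_S": (cm_heads, "VIRheadS", "AVRheadS"),
        "parent_body": (cm_body, "VIRparent", "AVRparent"),
        "F1_body": (cm_body, "VIRF1pool", "AVRF1pool"),
    }

    @stage("differential_expression")
    def de_tables():
        tables = {}
        for name, (cm, a, b) in contrasts.items():
            res = rnaseq.de_test(cm, a, b, lfc_threshold=config.lfc_threshold,
                                 fdr_threshold=config.fdr_threshold)
            _write(res, out / f"de_{name}.tsv", "de",
                   {"contrast": f"{a}_vs_{b}", "lfc": config.lfc_threshold,
                    "fdr": config.fdr_threshold})
            tables[name] = res
        heat = rnaseq.zero_centred_log_fpkm(cm_body)
        de_any = sorted(set().union(*[
            set(t.index[t["call"] != "ns"]) for t in tables.values()]))
        _write(heat.loc[[g for g in de_any if g in heat.index]],
               out / "heatmap_zero_centred_tmm_fpkm.tsv", "de", {"matrix": "body"})
        coords, var_frac = rnaseq.pca_summary(rnaseq.tmm_fpkm(cm_body).T)
        coords["variance_fraction"] = list(var_frac) + [float("nan")] * \
            (len(coords) - len(var_frac))
        _write(coords, out / "pca_body.tsv", "de", {"matrix": "body"})
        return tables

    @stage("proteomics")
    def proteome():
        pm = simcross.build_protein_model(sim, model)
        sg_matrix, truth = simcross.simulate_intensities(
            None, sim, pm, model, rng=sim.rng("intensities_sg"))
        saliva_cfg = dataclasses.replace(
            sim, missing_logistic_midpoint=sim.missing_logistic_midpoint
            + config.saliva_midpoint_shift)
        sal_matrix, _ = simcross.simulate_intensities(
            None, saliva_cfg, pm, model, rng=sim.rng("intensities_saliva"))
        simcross.write_protein_groups_tsv(sg_matrix, out / "proteinGroups_salivary_gland.tsv")
        simcross.write_protein_groups_tsv(sal_matrix, out / "proteinGroups_saliva.tsv")
        _write(truth.set_index("protein"), out / "protein_truth.tsv", "simulate", {})

        results = {}
        for tissue, mat in (("salivary_gland", sg_matrix), ("saliva", sal_matrix)):
            logm = proteomics.filter_and_log(mat)
            imput = proteomics.impute_missing(
                logm, config.imputation,
                rng=sim.rng(f"impute_{tissue}"))
            ssda = proteomics.ssda_ttest(imput, mat.sample_groups, alpha=config.alpha)
            _write(ssda, out / f"ssda_{tissue}.tsv", "proteomics",
                   {"tissue": tissue, "alpha": config.alpha,
                    "downshift": config.imputation.downshift,
                    "width": config.imputation.width})
            excl = proteomics.exclusive_proteins(mat)
            det = mat.intensities.notna()
            detected = {
                g: set(det.index[det[mat.samples_in(g)].any(axis=1)])
                for g in ("VIR", "AVR")
            }
            summary = proteomics.proteome_summary(detected["VIR"], detected["AVR"])
            results[tissue] = {"ssda": ssda, "exclusive": excl,
                               "detected": detected, "summary": summary}
            _write(pd.DataFrame(sorted((p, g) for g, s in excl.items() for p in s),
                                columns=["protein", "genotype"]),
                   out / f"exclusive_{tissue}.tsv", "proteomics",
                   {"tissue": tissue}, index=False)
        return results

    @stage("integrate")
    def evidence():
        annotations = simcross.make_annotations(sim, model)
        _write(annotations, out / "annotations.tsv", "simulate", {})
        directed = {
            "parent_head": _directed(de_tables["parent_head_R"]),
            "parent_body": _directed(de_tables["parent_body"]),
            "F1_body": _directed(de_tables["F1_body"]),
        }
        for tissue, ds in (("saliva", "saliva"), ("salivary_gland", "salivary_gland")):
            ssda = proteome[tissue]["ssda"]
            calls_t = {p: row["higher_in"] for p, row in ssda[ssda["ssda"]].iterrows()}
            for g, prots in proteome[tissue]["exclusive"].items():
                for p in prots:
                    calls_t.setdefault(p, g)
            directed[ds] = calls_t
        presence = {
            "saliva": set().union(*proteome["saliva"]["detected"].values()),
            "salivary_gland": set().union(*proteome["salivary_gland"]["detected"].values()),
        }
        matrix = integration.build_evidence(directed, presence)
        _write(matrix, out / "evidence_matrix.tsv", "integrate", {})
        candidates = integration.table1_filter(matrix)
        _write(candidates, out / "candidates.tsv", "integrate",
               {"rule": "three_plus_or_f1_plus_one"}, index=False)
        conflicts = integration.direction_conflicts(matrix)
        _write(conflicts, out / "direction_conflicts.tsv", "integrate", {}, index=False)

        saliva_ssda = set(directed["saliva"])
        corrob = None
        if saliva_ssda:
            corrob = integration.corroboration_rate(
                saliva_ssda,
                [set(directed[d]) for d in ("salivary_gland", "parent_head",
                                            "parent_body", "F1_body")])
        categories = {
            fam: set(annotations.index[annotations["family"] == fam])
            for fam in annotations["family"].unique() if fam not in ("other", "unknown")
        }
        universe = set(annotations.index)
        enrich = {}
        for side, key in (("VIR", "up_A"), ("AVR", "up_B")):
            de_set = set(de_tables["parent_body"].index[
                de_tables["parent_body"]["call"] == key])
            if de_set:
                tab = integration.category_enrichment(de_set, universe, categories,
                                                      mode="lenient")
                _write(tab, out / f"enrichment_parent_body_{side}.tsv", "integrate",
                       {"mode": "lenient", "side": side}, index=False)
                enrich[side] = tab
        return matrix, candidates, conflicts, corrob

    matrix, candidates, conflicts, corrob = evidence

    manifest["summary"] = {
        "n_clones": len(clones),
        "n_confirmed_VIR": int(((calls["class"] == "VIR") & calls["confirmed"]).sum()),
        "n_confirmed_AVR": int(((calls["class"] == "AVR") & calls["confirmed"]).sum()),
        "de_counts": {
            name: {"up_VIR": int((t["call"] == "up_A").sum()),
                   "up_AVR": int((t["call"] == "up_B").sum())}
            for name, t in de_tables.items()
        },
        "proteome": {t: proteome[t]["summary"] for t in proteome},
        "n_candidates": int(len(candidates)),
        "n_conflicts": int(len(conflicts)),
        "saliva_corroboration": corrob,
    }
    for p in sorted(out.glob("*.tsv")):
        manifest["tables"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
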