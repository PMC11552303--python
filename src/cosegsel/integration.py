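"""Multi-omics evidence integration and candidate filtering.

Five datasets feed the evidence matrix: saliva and salivary-gland proteomes
(detection and/or differential abundance), head and whole-body parental
transcriptome contrasts, and the bulked-F1 whole-body contrast. A gene's
cell per dataset is one of absent / up_VIR / up_AVR / present_undirected
(undirected = detected in a proteome without a significant abundance call).

Candidates are genes represented in at least three datasets, plus every gene
shared between the F1 transcriptome and at least one other dataset — the F1
rule is what turns background biotype divergence into a co-segregation
filter. Direction conflicts between parental and F1 contrasts are listed
separately rather than discarded.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .proteomics import round_half_away
from .rnaseq import bh_fdr

__all__ = [
    "DATASETS",
    "ABSENT",
    "UP_VIR",
    "UP_AVR",
    "PRESENT",
    "build_evidence",
    "table1_filter",
    "direction_conflicts",
    "corroboration_rate",
    "annotation_fractions",
    "is_non_annotated",
    "category_enrichment",
]

DATASETS = ("saliva", "salivary_gland", "parent_head", "parent_body", "F1_body")
ABSENT, UP_VIR, UP_AVR, PRESENT = "absent", "up_VIR", "up_AVR", "present_undirected"
_DIRECTED = (UP_VIR, UP_AVR)


class EvidenceIntegrityError(ValueError):
    """Contradictory directed calls for one id within one dataset."""


def build_evidence(
    de_tables: Mapping[str, Iterable],
    presence_sets: Mapping[str, Iterable[str]] | None = None,
    id_map: Mapping[str, str] | None = None,
    datasets: Sequence[str] = DATASETS,
) -> pd.DataFrame:
    """Assemble the gene x dataset evidence matrix.

    ``de_tables[dataset]`` is an iterable of ``(id, side)`` pairs (or a
    mapping id -> side) with side in {"VIR", "AVR"}; ``presence_sets`` holds
    undirected detections (saliva/salivary-gland proteomes). ``id_map``
    translates dataset-local ids into the unified namespace; ids it cannot
    map are collected and reported via a warning, never silently dropped.
    Directed calls take precedence over presence; contradictory directed
    calls within one dataset raise :class:`EvidenceIntegrityError`.
    """
    presence_sets = presence_sets or {}
    unmapped: set[str] = set()

    def unify(raw: str) -> str | None:
        if id_map is None:
            return raw
        if raw in id_map:
            return id_map[raw]
        unmapped.add(raw)
        return None

    cells: dict[str, dict[str, str]] = {}
    for ds in datasets:
        pairs = de_tables.get(ds, {})
        items = pairs.items() if isinstance(pairs, Mapping) else pairs
        for raw, side in items:
            if side not in ("VIR", "AVR"):
                raise ValueError(f"side must be VIR or AVR, got {side!r}")
            gid = unify(raw)
            if gid is None:
                continue
            state = UP_VIR if side == "VIR" else UP_AVR
            prev = cells.setdefault(gid, {}).get(ds)
            if prev in _DIRECTED and prev != state:
                raise EvidenceIntegrityError(
                    f"{gid} called both directions in dataset {ds}")
            cells[gid][ds] = state
        for raw in presence_sets.get(ds, ()):
            gid = unify(raw)
            if gid is None:
                continue
            cells.setdefault(gid, {}).setdefault(ds, PRESENT)
    if unmapped:
        warnings.warn(f"{len(unmapped)} ids could not be mapped: "
                      f"{sorted(unmapped)[:10]}...", stacklevel=2)
    matrix = pd.DataFrame(ABSENT, index=sorted(cells), columns=list(datasets))
    for gid, row in cells.items():
        for ds, state in row.items():
            matrix.loc[gid, ds] = state
    return matrix


def table1_filter(matrix: pd.DataFrame, f1_dataset: str = "F1_body") -> pd.DataFrame:
    """Candidate list: >= 3 datasets, or F1 plus at least one other.

    ``side`` is VIR/AVR when every directed cell agrees, else "conflict".
    The rule column records which clause admitted the gene.
    """
    records = []
    for gid, row in matrix.iterrows():
        non_absent = row[row != ABSENT]
        n = len(non_absent)
        three_plus = n >= 3
        f1_rule = (row.get(f1_dataset, ABSENT) != ABSENT) and n >= 2
        if not (three_plus or f1_rule):
            continue
        directed = set(non_absent[non_absent.isin(_DIRECTED)])
        if directed == {UP_VIR}:
            side = "VIR"
        elif directed == {UP_AVR}:
            side = "AVR"
        elif not directed:
            side = "undirected"
        else:
            side = "conflict"
        rule = "both" if (three_plus and f1_rule) else \
            ("three_plus" if three_plus else "f1_plus_one")
        records.append((gid, side, n, rule))
    return pd.DataFrame(records, columns=["id", "side", "n_datasets", "rule"])


def direction_conflicts(matrix: pd.DataFrame, parent_dataset: str = "parent_body",
                        f1_dataset: str = "F1_body") -> pd.DataFrame:
    """Genes whose parental and F1 whole-body directions oppose each other.

    Undirected presence never creates a conflict. The pattern label names
    which side each generation favoured (e.g. ``VIRparent/AVRF1``).
    """
    rows = []
    for gid, row in matrix.iterrows():
        p, f = row.get(parent_dataset), row.get(f1_dataset)
        if {p, f} == {UP_VIR, UP_AVR}:
            pattern = "VIRparent/AVRF1" if p == UP_VIR else "AVRparent/VIRF1"
            rows.append((gid, pattern))
    return pd.DataFrame(rows, columns=["id", "pattern"])


def corroboration_rate(focal_set: Iterable[str],
                       other_sets: Sequence[Iterable[str]]) -> tuple[int, int, int]:
    """How many focal directed calls recur in at least one other dataset.

    Returns ``(k, n, percent)`` with the percentage rounded half away from
    zero — the convention used for every printed fraction here.
    """
    focal = set(focal_set)
    if not focal:
        raise ValueError("focal set must be nonempty")
    union = set().union(*[set(s) for s in other_sets]) if other_sets else set()
    k = len(focal & union)
    return k, len(focal), round_half_away(100.0 * k / len(focal))


_NON_ANNOT = re.compile(
    r"^(hypothetical protein\b|uncharacterized protein\b|predicted protein\b|"
    r"na$|-*\s*na\s*-*$|acypi\d+$)",
    re.IGNORECASE,
)


def is_non_annotated(description: str | float | None) -> bool:
    """True for descriptors carrying no functional information.

    Covers hypothetical/uncharacterized/predicted proteins, bare NA entries,
    and bare genome-project accessions (ACYPIxxxxxx with nothing else).
    """
    if description is None or (isinstance(description, float) and np.isnan(description)):
        return True
    text = str(description).strip().strip("-–—").strip()
    if not text:
        return True
    return bool(_NON_ANNOT.match(text))


def annotation_fractions(id_set: Iterable[str], annotations: pd.DataFrame) -> dict:
    """Secreted % and non-annotated % of a gene/protein set.

    ``annotations`` is indexed by id with a boolean ``secreted`` column and a
    ``description`` column; an id missing from the table is an error (ids may
    be annotated *as unknown*, but must be present).
    """
    ids = list(id_set)
    missing = [i for i in ids if i not in annotations.index]
    if missing:
        raise KeyError(f"ids without annotation rows: {missing[:10]}")
    if not ids:
        return {"n": 0, "secreted_pct": 0, "non_annotated_pct": 0}
    sub = annotations.loc[ids]
    n_sec = int(sub["secreted"].astype(bool).sum())
    n_na = int(sub["description"].map(is_non_annotated).sum())
    return {
        "n": len(ids),
        "secreted_pct": round_half_away(100.0 * n_sec / len(ids)),
        "non_annotated_pct": round_half_away(100.0 * n_na / len(ids)),
    }


def category_enrichment(
    de_set: Iterable[str],
    universe: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    mode: str = "strict",
    bias_weights: Mapping[str, float] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation test per category term.

    One-sided hypergeometric tail by default; when per-gene ``bias_weights``
    are supplied (e.g. transcript lengths), Wallenius' noncentral
    hypergeometric with the term's mean-weight odds approximates a
    selection-bias-corrected test. ``strict`` mode keeps terms at BH-FDR <
    alpha; ``lenient`` keeps terms with at least two DE genes and raw p <
    alpha (the exploratory mode for small gene sets).
    """
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    universe = set(universe)
    de = set(de_set)
    if not de <= universe:
        raise ValueError("de_set must be a subset of the universe")
    N, n_de = len(universe), len(de)
    rows = []
    for term, members in categories.items():
        term_univ = set(members) & universe
        K = len(term_univ)
        if K == 0:
            warnings.warn(f"term {term!r} has no overlap with the universe; skipped",
                          stacklevel=2)
            continue
        k = len(term_univ & de)
        if bias_weights is None:
            p = float(stats.hypergeom.sf(k - 1, N, K, n_de))
        else:
            w = pd.Series(bias_weights)
            inside = w.reindex(list(term_univ)).mean()
            outside_ids = list(universe - term_univ)
            outside = w.reindex(outside_ids).mean() if outside_ids else inside
            odds = float(inside / outside) if outside > 0 else 1.0
            p = float(stats.nchypergeom_wallenius.sf(k - 1, N, K, n_de, odds))
        rows.append((term, k, K, p))
    out = pd.DataFrame(rows, columns=["term", "n_de_in_term", "n_term", "p_value"])
    if out.empty:
        out["fdr"] = out["enriched"] = []
        return out
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    if mode == "strict":
        out["enriched"] = out["fdr"] < alpha
    else:
        out["enriched"] = (out["n_de_in_term"] >= 2) & (out["p_value"] < alpha)
    return out.sort_values("p_value").reset_index(drop=True)
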