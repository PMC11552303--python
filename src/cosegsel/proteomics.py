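"""Label-free proteome quantitation in the Perseus style.

Input is a MaxQuant-style protein-groups table of LFQ intensities for four
replicates per genotype. The workflow: drop decoy/contaminant/site-only
entries, log2-transform, impute missing values from a downshifted narrow
normal (missingness here is abundance-dependent, so missing cells are best
explained as low-abundance signals), Welch-test each protein at p <= 0.05
(no multiple-testing correction, matching common practice for these small
panels; a BH mode is available), and report signed relative fold changes
plus exclusive-detection calls and Venn-style proteome summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rnaseq import bh_fdr, pca_summary

__all__ = [
    "IntensityMatrix",
    "ImputationParams",
    "read_protein_groups",
    "filter_and_log",
    "impute_missing",
    "ssda_ttest",
    "rfc",
    "exclusive_proteins",
    "proteome_summary",
    "round_half_away",
]


@dataclass
class IntensityMatrix:
    """Proteins x samples LFQ intensities (NaN = not detected) plus flags."""

    intensities: pd.DataFrame
    flags: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        vals = self.intensities.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("present intensities must be strictly positive")
        for col in ("reverse", "contaminant", "identified_by_site"):
            if col not in self.flags.columns:
                self.flags[col] = False
        missing = [s for s in self.intensities.columns if s not in self.sample_groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.intensities.columns if self.sample_groups[s] == group]


def read_protein_groups(path, sample_groups: pd.Series | dict | None = None) -> IntensityMatrix:
    """Parse the MaxQuant protein-groups dialect.

    Intensity columns are named ``LFQ intensity <sample>``; 0 or empty means
    not detected; ``Reverse`` / ``Potential contaminant`` / ``Only identified
    by site`` use the "+" convention. When ``sample_groups`` is omitted the
    group is the sample name up to the last underscore (the simulator's
    convention, e.g. ``VIR_1`` -> ``VIR``).
    """
    df = pd.read_csv(path, sep="\t", index_col="Protein IDs", comment="#")
    lfq_cols = [c for c in df.columns if c.startswith("LFQ intensity ")]
    if not lfq_cols:
        raise ValueError("no 'LFQ intensity <sample>' columns found")
    intens = df[lfq_cols].apply(pd.to_numeric, errors="coerce")
    intens.columns = [c[len("LFQ intensity "):] for c in lfq_cols]
    intens = intens.where(intens > 0)  # 0 / empty -> missing

    def plus(col: str) -> pd.Series:
        if col in df.columns:
            return df[col].fillna("").astype(str).str.strip() == "+"
        return pd.Series(False, index=df.index)

    flags = pd.DataFrame({
        "reverse": plus("Reverse"),
        "contaminant": plus("Potential contaminant"),
        "identified_by_site": plus("Only identified by site"),
    })
    if sample_groups is None:
        sample_groups = {s: s.rsplit("_", 1)[0] for s in intens.columns}
    return IntensityMatrix(intens, flags, pd.Series(sample_groups))


@dataclass
class ImputationParams:
    """Downshifted-normal imputation parameters, in units of the measured SD."""

    downshift: float = 2.1
    width: float = 0.1
    scope: str = "global"  # or "per_sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")
        if self.scope not in ("global", "per_sample"):
            raise ValueError("scope must be 'global' or 'per_sample'")


def filter_and_log(matrix: IntensityMatrix) -> pd.DataFrame:
    """Drop flagged proteins and log2-transform; NaN marks missing cells."""
    bad = matrix.flags[["reverse", "contaminant", "identified_by_site"]].any(axis=1)
    kept = matrix.intensities.loc[~bad.reindex(matrix.intensities.index, fill_value=False)]
    return np.log2(kept)


def impute_missing(log_matrix: pd.DataFrame, params: ImputationParams | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Replace missing cells with draws that mimic low-abundance signals.

    Each missing cell is drawn from ``Normal(mu - downshift * sd,
    (width * sd)^2)`` where mu and sd summarise the measured values in scope
    (all measured values by default; per-sample optionally). Measured cells
    are never altered.
    """
    params = params or ImputationParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    out = log_matrix.copy()
    if params.scope == "global":
        vals = out.to_numpy(dtype=float)
        measured = vals[~np.isnan(vals)]
        if measured.size == 0:
            raise ValueError("no measured values to anchor imputation")
        mu, sd = measured.mean(), measured.std(ddof=0)
        mask = out.isna()
        draws = rng.normal(mu - params.downshift * sd, params.width * sd,
                           size=int(mask.values.sum()))
        arr = out.to_numpy(dtype=float)
        arr[mask.to_numpy()] = draws
        return pd.DataFrame(arr, index=out.index, columns=out.columns)
    for col in out.columns:
        series = out[col]
        measured = series.dropna()
        if measured.empty:
            raise ValueError(f"sample {col!r} has no measured values")
        mu, sd = measured.mean(), measured.std(ddof=0)
        n_missing = int(series.isna().sum())
        out.loc[series.isna(), col] = rng.normal(
            mu - params.downshift * sd, params.width * sd, size=n_missing)
    return out


def rfc(mean_a: float, mean_b: float) -> float:
    """Signed relative fold change of two raw-scale group means.

    Returns A/B when A >= B, else -(B/A); magnitude is always >= 1 and the
    sign points at the group with the higher abundance.
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("group means must be positive on the raw scale")
    return mean_a / mean_b if mean_a >= mean_b else -(mean_b / mean_a)


def ssda_ttest(
    log_matrix: pd.DataFrame,
    groups: pd.Series | dict,
    group_a: str = "VIR",
    group_b: str = "AVR",
    alpha: float = 0.05,
    correct: bool = False,
) -> pd.DataFrame:
    """Welch two-sample t-test per protein on (imputed) log2 intensities.

    A protein is SSDA when p <= alpha (uncorrected by default; ``correct``
    switches to BH-FDR <= alpha). Output includes the log2 difference, the
    signed RFC of the raw-scale group means, volcano coordinates, and an
    ``exactly_separated`` flag for the degenerate zero-variance case where
    the t statistic is unbounded.
    """
    groups = pd.Series(groups)
    cols_a = [c for c in log_matrix.columns if groups[c] == group_a]
    cols_b = [c for c in log_matrix.columns if groups[c] == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    A = log_matrix[cols_a].to_numpy(dtype=float)
    B = log_matrix[cols_b].to_numpy(dtype=float)
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("missing values present: impute before testing")

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance rows trip scipy's precision warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    var0 = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    separated = var0 & (mean_a != mean_b)
    p = np.where(var0 & ~separated, 1.0, p)
    p = np.where(separated, 0.0, p)

    diff = mean_a - mean_b
    rfc_vals = np.array([rfc(2.0 ** a, 2.0 ** b) for a, b in zip(mean_a, mean_b)])
    sig = (bh_fdr(np.clip(p, np.nextafter(0, 1), 1.0)) <= alpha) if correct else (p <= alpha)
    res = pd.DataFrame({
        "log2fc": diff,
        "rfc": rfc_vals,
        "p_value": p,
        "neg_log10_p": -np.log10(np.clip(p, 1e-300, None)),
        "ssda": sig,
        "higher_in": np.where(diff >= 0, group_a, group_b),
        "exactly_separated": separated,
    }, index=log_matrix.index)
    return res


def exclusive_proteins(matrix: IntensityMatrix, group_a: str = "VIR",
                       group_b: str = "AVR") -> dict[str, set[str]]:
    """Proteins detected in every replicate of one genotype and none of the other.

    Detection is presence before imputation — these calls are the qualitative
    complement to the quantitative SSDA analysis.
    """
    bad = matrix.flags[["reverse", "contaminant", "identified_by_site"]].any(axis=1)
    intens = matrix.intensities.loc[~bad.reindex(matrix.intensities.index, fill_value=False)]
    det = intens.notna()
    cols_a = [c for c in intens.columns if matrix.sample_groups[c] == group_a]
    cols_b = [c for c in intens.columns if matrix.sample_groups[c] == group_b]
    all_a, none_b = det[cols_a].all(axis=1), ~det[cols_b].any(axis=1)
    all_b, none_a = det[cols_b].all(axis=1), ~det[cols_a].any(axis=1)
    return {
        group_a: set(intens.index[all_a & none_b]),
        group_b: set(intens.index[all_b & none_a]),
    }


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-fraction rule)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def proteome_summary(detected_a: set[str], detected_b: set[str],
                     label_a: str = "VIR", label_b: str = "AVR") -> dict:
    """Venn counts and percentage conventions for two detection sets.

    Because a "percent shared" can be quoted against the union or either
    set's total, all three conventions are reported explicitly.
    """
    shared = detected_a & detected_b
    union = detected_a | detected_b
    uniq_a, uniq_b = detected_a - detected_b, detected_b - detected_a

    def pct(k: int, n: int) -> int:
        return round_half_away(100.0 * k / n) if n else 0

    return {
        f"n_{label_a}": len(detected_a),
        f"n_{label_b}": len(detected_b),
        "n_shared": len(shared),
        f"n_unique_{label_a}": len(uniq_a),
        f"n_unique_{label_b}": len(uniq_b),
        f"pct_unique_{label_a}": pct(len(uniq_a), len(detected_a)),
        f"pct_unique_{label_b}": pct(len(uniq_b), len(detected_b)),
        "pct_shared_of_union": pct(len(shared), len(union)),
        f"pct_shared_of_{label_a}": pct(len(shared), len(detected_a)),
        f"pct_shared_of_{label_b}": pct(len(shared), len(detected_b)),
    }


def proteome_pca(imputed_log: pd.DataFrame):
    """Sample-space PCA on imputed log2 intensities (values already logged)."""
    return pca_summary(imputed_log.T, log=False)
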