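"""Count-based differential expression for two-group contrasts.

The engine mirrors the classic count workflow: trimmed-mean-of-M-values
(TMM) normalisation, TMM-normalised FPKM reporting, moderated
method-of-moments negative-binomial dispersion estimation, a conditional
exact test on group-summed pseudo-counts, Benjamini-Hochberg FDR, and the
standard call thresholds (|log2FC| > 2, FDR < 0.05).

Every contrast in the design — parental heads on resistant or susceptible
hosts, parental whole bodies, bulked F1 pools — is a two-group comparison,
which is why a conditional exact test (rather than a GLM) is the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "tmm_factors",
    "tmm_fpkm",
    "cpm",
    "estimate_dispersion",
    "nb_exact_test",
    "exact_nb_pvalue",
    "bh_fdr",
    "call_de",
    "de_test",
    "pca_summary",
    "zero_centred_log_fpkm",
]


@dataclass
class CountMatrix:
    """Genes x samples integer counts with gene lengths and group labels."""

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        missing = [s for s in self.counts.columns if s not in self.sample_groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    def samples_in(self, *groups: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_groups[s] in groups]

    @classmethod
    def from_tsv(cls, path, sample_groups: pd.Series | dict) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        lengths = df.pop("length")
        return cls(df, lengths, pd.Series(sample_groups))


def tmm_factors(
    counts: pd.DataFrame | CountMatrix,
    ref_sample: str | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors.

    Reference defaults to the sample whose upper-quartile count fraction is
    closest to the mean of those fractions. Per sample, M (log-ratio) and A
    (log-abundance) values over genes positive in both sample and reference
    are trimmed two-sided (30% on M, 5% on A) and the factor is two to the
    precision-weighted mean of retained M values, with delta-method weights.
    Factors are rescaled to geometric mean 1, so ``lib_size * factor`` is the
    effective library size.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    data = counts.to_numpy(dtype=float)
    lib = data.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with all-zero counts")
    f75 = np.percentile(data, 75, axis=0) / lib
    if ref_sample is None:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_sample)
    ref = data[:, ref_idx]
    n_ref = lib[ref_idx]

    factors = np.empty(data.shape[1])
    for j in range(data.shape[1]):
        factors[j] = _tmm_pair(data[:, j], ref, lib[j], n_ref, logratio_trim, sum_trim)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, sum_trim: float) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return 1.0
    o, r = obs[both], ref[both]
    log_r = np.log2((o / n_obs) / (r / n_ref))
    abs_e = (np.log2(o / n_obs) + np.log2(r / n_ref)) / 2.0
    # delta-method asymptotic variance of M; weights are its inverse
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return 2.0 ** f


def effective_lib_sizes(cm: CountMatrix, factors: pd.Series | None = None) -> pd.Series:
    if factors is None:
        factors = tmm_factors(cm)
    return cm.counts.sum(axis=0) * factors


def tmm_fpkm(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """fpkm[g, s] = count * 1e9 / (length_bp * effective library size)."""
    eff = effective_lib_sizes(cm, factors)
    return cm.counts * 1e9 / np.outer(cm.gene_lengths.values, eff.values)


def cpm(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million of the effective (TMM-scaled) library size."""
    eff = effective_lib_sizes(cm, factors)
    return cm.counts * 1e6 / eff.values


def zero_centred_log_fpkm(cm: CountMatrix, factors: pd.Series | None = None,
                          offset: float = 1.0) -> pd.DataFrame:
    """log2(TMM-FPKM + offset), gene-wise mean-centred: the heatmap matrix."""
    lf = np.log2(tmm_fpkm(cm, factors) + offset)
    return lf.sub(lf.mean(axis=1), axis=0)


def estimate_dispersion(
    cm: CountMatrix,
    groups: pd.Series | None = None,
    factors: pd.Series | None = None,
    prior_df: float = 10.0,
    user_phi: float | None = None,
) -> pd.Series:
    """Per-gene NB dispersion, moderated toward the genome-wide median.

    Raw estimates are method-of-moments, ``max(0, (s2 - mean) / mean^2)``, on
    counts rescaled to a common library size, with the variance pooled over
    within-group residuals. They are shrunk toward the median raw estimate
    with a prior weight of ``prior_df`` residual degrees of freedom — enough
    to stabilise 3-5 replicate designs without swamping real per-gene signal.
    """
    groups = cm.sample_groups if groups is None else groups
    eff = effective_lib_sizes(cm, factors)
    common = np.exp(np.mean(np.log(eff)))
    y = cm.counts * (common / eff)

    labels = groups.reindex(y.columns)
    resid_df = 0
    ss = np.zeros(y.shape[0])
    mu = y.mean(axis=1).to_numpy()
    for g in labels.unique():
        cols = [c for c in y.columns if labels[c] == g]
        if len(cols) < 2:
            continue
        sub = y[cols].to_numpy()
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        resid_df += len(cols) - 1
    if resid_df == 0:
        if user_phi is None:
            raise ValueError("no replicated group: supply user_phi")
        return pd.Series(user_phi, index=cm.counts.index, name="dispersion")
    s2 = ss / resid_df
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / mu**2), np.nan)
    med = float(np.nanmedian(raw)) if np.isfinite(np.nanmedian(raw)) else 0.0
    raw = np.where(np.isnan(raw), med, raw)
    phi = (prior_df * med + resid_df * raw) / (prior_df + resid_df)
    return pd.Series(phi, index=cm.counts.index, name="dispersion")


def exact_nb_pvalue(a: int, t: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p for the split (a, t - a) of total t.

    Group sums of ``n`` i.i.d. NB(mu, phi) variables are NB(n*mu, phi/n), so
    conditioned on the total ``t`` the split follows the normalised product
    of the two group-sum pmfs with means proportional to replicate numbers.
    The p-value sums the probabilities of all splits no more likely than the
    observed one. With phi = 0 this reduces to the binomial conditional test
    Binomial(t, n_a / (n_a + n_b)).
    """
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    if phi <= 1e-12:
        logpr = stats.binom.logpmf(k, t, n_a / (n_a + n_b))
    else:
        mu = t / (n_a + n_b)
        size_a, size_b = n_a / phi, n_b / phi
        logpr = stats.nbinom.logpmf(k, size_a, size_a / (size_a + n_a * mu)) + \
            stats.nbinom.logpmf(t - k, size_b, size_b / (size_b + n_b * mu))
    pr = np.exp(logpr - logpr.max())
    total = pr.sum()
    p = pr[pr <= pr[a] * (1.0 + 1e-10)].sum() / total
    return float(min(1.0, max(p, np.nextafter(0, 1))))


def nb_exact_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    phi: pd.Series | np.ndarray | float,
    lib_sizes_a: np.ndarray,
    lib_sizes_b: np.ndarray,
) -> pd.Series:
    """Per-gene exact-test p-values for two replicate groups.

    Counts are first scaled to a common effective library size (the geometric
    mean over all samples) and rounded to pseudo-counts, then summed within
    groups; the conditional NB test runs on the group sums with the per-gene
    dispersion reduced by the replicate numbers (see :func:`exact_nb_pvalue`).
    """
    if counts_a.empty or counts_b.empty:
        raise ValueError("both groups must contain samples")
    libs = np.concatenate([np.asarray(lib_sizes_a, float), np.asarray(lib_sizes_b, float)])
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    common = np.exp(np.mean(np.log(libs)))
    pa = np.rint(counts_a.to_numpy(float) * (common / np.asarray(lib_sizes_a, float)))
    pb = np.rint(counts_b.to_numpy(float) * (common / np.asarray(lib_sizes_b, float)))
    a = pa.sum(axis=1).astype(np.int64)
    b = pb.sum(axis=1).astype(np.int64)
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    if isinstance(phi, pd.Series):
        phi_arr = phi.reindex(counts_a.index).to_numpy(float)
    else:
        phi_arr = np.broadcast_to(np.asarray(phi, float), a.shape)
    if (phi_arr < 0).any():
        raise ValueError("dispersion must be >= 0")
    pvals = np.array([
        exact_nb_pvalue(int(ai), int(ai + bi), n_a, n_b, float(ph))
        for ai, bi, ph in zip(a, b, phi_arr)
    ])
    return pd.Series(pvals, index=counts_a.index, name="p_value")


def bh_fdr(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values (monotonicity enforced)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, lfc_threshold: float = 2.0,
            fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Annotate a results table with up_A / up_B / ns calls (strict cutoffs)."""
    out = results.copy()
    up_a = (out["log2fc"] > lfc_threshold) & (out["fdr"] < fdr_threshold)
    up_b = (out["log2fc"] < -lfc_threshold) & (out["fdr"] < fdr_threshold)
    out["call"] = np.where(up_a, "up_A", np.where(up_b, "up_B", "ns"))
    return out


def de_test(
    cm: CountMatrix,
    group_a: str,
    group_b: str,
    lfc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    prior_count: float = 0.5,
    prior_df: float = 10.0,
    user_phi: float | None = None,
    min_cpm: float | None = None,
) -> pd.DataFrame:
    """Full two-group contrast: normalise, estimate dispersion, test, call.

    Genes with zero counts across the contrast's samples are excluded before
    FDR correction (they are untestable and would only inflate m). An
    optional CPM floor is available but off by default. log2FC is computed on
    group-mean CPM with a prior count of ``prior_count`` added to both means.
    """
    cols_a = cm.samples_in(group_a)
    cols_b = cm.samples_in(group_b)
    if not cols_a or not cols_b:
        raise ValueError(f"no samples for contrast {group_a} vs {group_b}")
    sub = CountMatrix(
        cm.counts[cols_a + cols_b],
        cm.gene_lengths,
        cm.sample_groups[cols_a + cols_b],
    )
    factors = tmm_factors(sub)
    eff = effective_lib_sizes(sub, factors)
    keep = sub.counts.sum(axis=1) > 0
    if min_cpm is not None:
        keep &= (cpm(sub, factors) >= min_cpm).any(axis=1)
    counts = sub.counts.loc[keep]

    try:
        phi = estimate_dispersion(sub, factors=factors, prior_df=prior_df,
                                  user_phi=user_phi).loc[keep]
    except ValueError:
        if user_phi is None:
            raise
        phi = pd.Series(user_phi, index=counts.index)

    p = nb_exact_test(counts[cols_a], counts[cols_b], phi,
                      eff[cols_a].to_numpy(), eff[cols_b].to_numpy())
    c = cpm(sub, factors).loc[keep]
    mean_a = c[cols_a].mean(axis=1)
    mean_b = c[cols_b].mean(axis=1)
    log2fc = np.log2((mean_a + prior_count) / (mean_b + prior_count))
    res = pd.DataFrame({
        "gene": counts.index,
        "log2fc": log2fc.values,
        "p_value": p.values,
        "fdr": bh_fdr(p.values),
        "mean_expression": ((mean_a + mean_b) / 2).values,
        "dispersion": phi.values,
    }).set_index("gene")
    return call_de(res, lfc_threshold, fdr_threshold)


def pca_summary(matrix: pd.DataFrame, log: bool = True, offset: float = 1.0,
                n_components: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA of an expression matrix (samples x features).

    Features are log2(value + offset) then mean-centred per feature, matching
    the log2 zero-centred convention used for the expression heatmaps.
    Returns (coordinates indexed by sample, variance fractions).
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    if log:
        X = np.log2(X + offset)
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(X):
        raise ValueError("constant matrix has no principal components")
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=matrix.index, columns=cols), \
        pca.explained_variance_ratio_
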