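"""Virulence phenotyping: indices, classification, confirmation, bulk selection.

Clones are assayed on two resistant host genotypes (A17 and a resistant
near-isogenic line, RNIL). The virulence index combines survival and
reproduction::

    VI = log2(mean survivors out of 5 x nymphs produced + 1)

Clones are called virulent (VIR) when VI > 4 on A17 and > 5 on RNIL, and
avirulent (AVR) when VI < 2 on A17 and < 4.5 on RNIL — the RNIL cutoffs are
laxer because its resistance is slightly weaker. Calls are re-checked by a
shorter 5-day survival screen before clones enter the 22-clone bulks used
for bulked-segregant RNA-seq.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "virulence_index",
    "classify_clone",
    "confirmation_screen",
    "host_correlation",
    "select_bulks",
    "virulence_table",
    "make_calls",
]

# strict-threshold defaults (index scale is log2)
VI_THRESHOLDS = {
    "A17": {"vir": 4.0, "avr": 2.0},
    "RNIL": {"vir": 5.0, "avr": 4.5},
}
CONFIRM_THRESHOLDS = {"vir": 0.8, "avr_A17": 0.2, "avr_RNIL": 0.7}


def virulence_index(mean_survivors: float, nymphs: float) -> float:
    """log2(mean_survivors * nymphs + 1); zero whenever either factor is zero."""
    if mean_survivors < 0 or nymphs < 0:
        raise ValueError("virulence_index arguments must be nonnegative")
    if mean_survivors > 5:
        raise ValueError("mean_survivors cannot exceed 5 (5 nymphs infested)")
    return math.log2(mean_survivors * nymphs + 1.0)


def classify_clone(vi_a17: float, vi_rnil: float,
                   thresholds: dict | None = None) -> str:
    """Strict-inequality call: 'VIR', 'AVR', or 'unclassified' at boundaries."""
    if not (math.isfinite(vi_a17) and math.isfinite(vi_rnil)):
        raise ValueError("virulence indices must be finite")
    th = thresholds or VI_THRESHOLDS
    if vi_a17 > th["A17"]["vir"] and vi_rnil > th["RNIL"]["vir"]:
        return "VIR"
    if vi_a17 < th["A17"]["avr"] and vi_rnil < th["RNIL"]["avr"]:
        return "AVR"
    return "unclassified"


def confirmation_screen(surv_a17: float, surv_rnil: float, candidate_class: str,
                        override_avr: bool = False) -> bool:
    """5-day survival re-check of a provisional call.

    VIR confirmed when survival exceeds 80% on both hosts; AVR confirmed when
    survival falls below 20% on A17 and 70% on RNIL, or when ``override_avr``
    marks a clone that survives but barely grows.
    """
    for f in (surv_a17, surv_rnil):
        if not 0.0 <= f <= 1.0:
            raise ValueError("survival fractions must lie in [0, 1]")
    if candidate_class == "VIR":
        return surv_a17 > CONFIRM_THRESHOLDS["vir"] and surv_rnil > CONFIRM_THRESHOLDS["vir"]
    if candidate_class == "AVR":
        return override_avr or (
            surv_a17 < CONFIRM_THRESHOLDS["avr_A17"]
            and surv_rnil < CONFIRM_THRESHOLDS["avr_RNIL"]
        )
    raise ValueError(f"confirmation_screen needs a VIR/AVR candidate, got {candidate_class!r}")


def host_correlation(vi_pairs: Iterable[tuple[float, float]]) -> tuple[float, float]:
    """Pearson correlation of per-clone indices across the two resistant hosts."""
    pairs = np.asarray(list(vi_pairs), dtype=float)
    if pairs.shape[0] < 3:
        raise ValueError("need at least 3 clone index pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one host's indices")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def virulence_table(records: pd.DataFrame, nymph_stat: str = "mean") -> pd.DataFrame:
    """Per clone x host virulence index from plant-level assay records.

    ``nymph_stat`` selects whether the nymph factor is the per-plant mean
    (default) or the clone total.
    """
    if nymph_stat not in ("mean", "total"):
        raise ValueError("nymph_stat must be 'mean' or 'total'")
    rows = []
    for (clone, host), grp in records.groupby(["clone", "host"], sort=True):
        ms = grp["survivors"].mean()
        ny = grp["nymphs"].mean() if nymph_stat == "mean" else grp["nymphs"].sum()
        rows.append((clone, host, ms, ny, virulence_index(ms, ny)))
    return pd.DataFrame(rows, columns=["clone", "host", "mean_survivors", "nymphs", "vi"])


def make_calls(
    index_records: pd.DataFrame,
    confirmation_records: pd.DataFrame | None = None,
    override_avr: Sequence[str] = (),
    nymph_stat: str = "mean",
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Full call table: indices on both hosts, class, and confirmation status.

    ``confirmation_records`` are day-5 plant-level survival counts; their
    survival fraction is aphids alive over aphids infested (5 per plant).
    Clones without confirmation data keep ``confirmed = False`` unless the
    class screen is skipped entirely (``confirmation_records is None``), in
    which case provisional calls stand.
    """
    vt = virulence_table(index_records, nymph_stat=nymph_stat)
    wide = vt.pivot(index="clone", columns="host", values="vi")
    if not {"A17", "RNIL"}.issubset(wide.columns):
        raise ValueError("index records must cover hosts A17 and RNIL")
    calls = pd.DataFrame({
        "clone": wide.index,
        "vi_A17": wide["A17"].values,
        "vi_RNIL": wide["RNIL"].values,
    })
    calls["class"] = [
        classify_clone(a, r, thresholds) for a, r in zip(calls.vi_A17, calls.vi_RNIL)
    ]
    overrides = set(override_avr)
    if confirmation_records is None:
        calls["confirmed"] = calls["class"] != "unclassified"
    else:
        surv = (
            confirmation_records.groupby(["clone", "host"])
            .apply(lambda g: g["survivors"].sum() / (5.0 * len(g)), include_groups=False)
            .unstack()
        )
        confirmed = []
        for clone, cls in zip(calls.clone, calls["class"]):
            if cls == "unclassified" or clone not in surv.index:
                confirmed.append(False)
                continue
            confirmed.append(
                confirmation_screen(
                    surv.loc[clone, "A17"], surv.loc[clone, "RNIL"], cls,
                    override_avr=clone in overrides,
                )
            )
        calls["confirmed"] = confirmed
    calls["override_avr"] = [c in overrides for c in calls.clone]
    return calls.reset_index(drop=True)


class BulkSelectionError(RuntimeError):
    """Not enough confirmed clones of a class to fill a bulk."""


def select_bulks(calls: pd.DataFrame, k: int = 22) -> tuple[list[str], list[str]]:
    """The k most extreme confirmed clones per class, by A17 index.

    VIR bulk takes the highest ``vi_A17`` (ties: higher ``vi_RNIL``, then
    clone id); AVR bulk the lowest (ties: lower ``vi_RNIL``, then id).
    """
    vir = calls[(calls["class"] == "VIR") & calls["confirmed"]]
    avr = calls[(calls["class"] == "AVR") & calls["confirmed"]]
    for name, grp in (("VIR", vir), ("AVR", avr)):
        if len(grp) < k:
            raise BulkSelectionError(
                f"need {k} confirmed {name} clones, have {len(grp)} (short by {k - len(grp)})"
            )
    vir_bulk = (
        vir.sort_values(["vi_A17", "vi_RNIL", "clone"], ascending=[False, False, True])
        .head(k)["clone"].tolist()
    )
    avr_bulk = (
        avr.sort_values(["vi_A17", "vi_RNIL", "clone"], ascending=[True, True, True])
        .head(k)["clone"].tolist()
    )
    return vir_bulk, avr_bulk
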