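"""Paired comparison of two drying treatments, stratified by preparation.

For each element, concentrations under treatment A (towel-dried) and
treatment B (further heat-gun-dried) are compared with a two-sided paired
Wilcoxon signed-rank test, run separately within the raw and cooked strata.
Zero differences are dropped before ranking. The exact null distribution is
used for n <= 25 nonzero differences (enumerated over sign assignments, with
midranks for tied magnitudes); larger samples use the normal approximation
with continuity correction. Elements that read zero in every sample of a
stratum are reported with an all-zero flag instead of a p-value. No
multiple-testing correction is applied by default; Holm adjustment is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

FLAG_OK = ""
FLAG_ALL_ZERO = "all_zero"        # every value in the stratum is zero ("*")
FLAG_ZERO_DIFFS = "zero_diffs"    # A and B identical: no nonzero differences
FLAG_INSUFFICIENT = "insufficient_pairs"

EXACT_MAX_N = 25


@dataclass
class PairedTreatmentTable:
    """Element concentrations under two treatments, paired by sample id."""

    treatment_a: pd.DataFrame
    treatment_b: pd.DataFrame
    strata: pd.Series

    def __post_init__(self) -> None:
        if not self.treatment_a.index.equals(self.treatment_b.index):
            raise ValueError("treatment tables must pair by sample id")
        if not self.treatment_a.columns.equals(self.treatment_b.columns):
            raise ValueError("treatment tables must share the element roster")
        if not self.treatment_a.index.equals(self.strata.index):
            raise ValueError("strata must be indexed by the same sample ids")

    @property
    def elements(self) -> list[str]:
        return list(self.treatment_a.columns)

    def stratum_labels(self) -> list[str]:
        return list(pd.unique(self.strata))

    def to_csv(self, path: str | Path) -> Path:
        a = self.treatment_a.copy()
        a.insert(0, "treatment", "A")
        b = self.treatment_b.copy()
        b.insert(0, "treatment", "B")
        long = pd.concat([a, b])
        long.insert(0, "stratum", pd.concat([self.strata, self.strata]).values)
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        long.to_csv(path, na_rep="NA")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedTreatmentTable":
        long = pd.read_csv(path, index_col=0, na_values=["NA"])
        a = long[long["treatment"] == "A"].drop(columns=["treatment", "stratum"])
        b = long[long["treatment"] == "B"].drop(columns=["treatment", "stratum"])
        strata = long.loc[long["treatment"] == "A", "stratum"]
        strata.name = "preparation"
        return cls(treatment_a=a, treatment_b=b.loc[a.index], strata=strata)


def exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p-value by enumeration over sign flips.

    Uses midranks for tied magnitudes (doubled to stay integral) and a
    dynamic-programming convolution over the 2^n equally likely sign
    assignments. Two-sided p = min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w2 = int(round(2.0 * ranks[d > 0].sum()))
    r2 = np.round(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= 2.0**n
    p_low = float(counts[: w2 + 1].sum())
    p_high = float(counts[w2:].sum())
    return min(1.0, 2.0 * min(p_low, p_high))


def _wilcoxon_pair(a: np.ndarray, b: np.ndarray) -> tuple[float | None, str]:
    """Two-sided paired signed-rank p-value for one element in one stratum."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        return None, FLAG_ZERO_DIFFS
    if nz.size < 2:
        return None, FLAG_INSUFFICIENT
    if nz.size <= EXACT_MAX_N:
        return exact_signed_rank_p(nz), FLAG_OK
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=True, alternative="two-sided",
        method="approx",
    )
    return float(res.pvalue), FLAG_OK


def paired_wilcoxon_by_element(
    pairs: PairedTreatmentTable,
    stratum: str,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-element paired Wilcoxon tests within one stratum.

    Returns a frame with columns element, n_pairs, p_value, flag,
    significant. Elements all-zero in the stratum carry the all-zero flag and
    no p-value.
    """
    mask = (pairs.strata == stratum).to_numpy()
    if mask.sum() < 2:
        raise ValueError(f"stratum {stratum!r} has fewer than 2 pairs")
    a = pairs.treatment_a.loc[mask]
    b = pairs.treatment_b.loc[mask]
    rows = []
    for el in pairs.elements:
        av = a[el].to_numpy(dtype=float)
        bv = b[el].to_numpy(dtype=float)
        if np.all(av == 0) and np.all(bv == 0):
            rows.append({"element": el, "n_pairs": int(mask.sum()), "p_value": np.nan,
                         "flag": FLAG_ALL_ZERO, "significant": False})
            continue
        p, flag = _wilcoxon_pair(av, bv)
        rows.append(
            {
                "element": el,
                "n_pairs": int(mask.sum()),
                "p_value": np.nan if p is None else p,
                "flag": flag,
                "significant": bool(p is not None and p < alpha),
            }
        )
    out = pd.DataFrame(rows)
    if holm:
        out = _holm_adjust(out, alpha)
    return out


def _holm_adjust(result: pd.DataFrame, alpha: float) -> pd.DataFrame:
    out = result.copy()
    valid = out["p_value"].notna()
    p = out.loc[valid, "p_value"].to_numpy()
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    out.loc[valid, "p_holm"] = adj
    out.loc[valid, "significant"] = adj < alpha
    return out


def moisture_table(pairs: PairedTreatmentTable, alpha: float = 0.05) -> pd.DataFrame:
    """Element x stratum p-value table; '*' marks all-zero strata."""
    cols: dict[str, list[str]] = {}
    for stratum in pairs.stratum_labels():
        res = paired_wilcoxon_by_element(pairs, stratum, alpha=alpha)
        rendered = []
        for _, row in res.iterrows():
            if row["flag"] == FLAG_ALL_ZERO:
                rendered.append("*")
            elif pd.isna(row["p_value"]):
                rendered.append("NA")
            else:
                rendered.append(f"{row['p_value']:.4f}")
        cols[f"p_{stratum}"] = rendered
    return pd.DataFrame({"element": pairs.elements, **cols})
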