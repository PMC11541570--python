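"""Differential intronic-APA calling.

Two modes mirror the two experimental designs the workflow supports:

* pairwise (cell-line, few replicates): expression sums per condition are
  cast to integer pseudo-counts and tested with a 2x2 Pearson chi-square;
  an event is significant at p < 0.05 with |delta TR| > 0.1.
* cohort (tumor vs normal, many samples): per-gene two-sample t-test on TR
  values, significant at p < 0.01; direction by the sign of the mean
  difference.

The 80% conservation rule then asks, per gene, what fraction of case
samples lie strictly beyond the reference (normal-tissue mean TR) in the
called direction; an event is cohort-conserved at fraction >= 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

CASE_ENRICHED = "CASE_ENRICHED"
CONTROL_ENRICHED = "CONTROL_ENRICHED"


@dataclass
class ApaCallSet:
    """Per-gene differential-APA results for one contrast."""

    contrast_id: str
    table: pd.DataFrame  # index gene_id; columns p_value, mean_tr_case,
    #                      mean_tr_control, delta_tr, direction, significant,
    #                      and optionally conserved_fraction, conserved
    excluded: dict[str, str] = field(default_factory=dict)

    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table.significant])

    def conserved_genes(self) -> list[str]:
        if "conserved" not in self.table:
            return []
        return list(self.table.index[self.table.conserved.fillna(False)])


def pairwise_chisq(
    apa_case: float, fl_case: float, apa_control: float, fl_control: float
) -> tuple[float, bool]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table
    [[apa_case, fl_case], [apa_control, fl_control]].

    Inputs are expression sums; they are rounded to integer pseudo-counts.
    Returns ``(p_value, degenerate)``; a zero row or column margin is
    degenerate and yields p = 1.
    """
    table = np.round(
        np.array([[apa_case, fl_case], [apa_control, fl_control]], dtype=float)
    )
    if (table < 0).any():
        raise ValueError("negative counts in chi-square table")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0, True
    _stat, p, _dof, _exp = stats.chi2_contingency(table, correction=False)
    return float(p), False


def call_pairwise(
    tr_case: pd.Series,
    tr_control: pd.Series,
    p_values: pd.Series,
    contrast_id: str = "pairwise",
    alpha: float = 0.05,
    min_delta: float = 0.1,
) -> ApaCallSet:
    """Dichotomous pairwise calls: significant iff p < alpha and |dTR| > min_delta.

    Genes with a missing TR in either condition are excluded and recorded.
    """
    excluded = {}
    rows = {}
    for gene in p_values.index:
        tc, tn = tr_case.get(gene, np.nan), tr_control.get(gene, np.nan)
        if np.isnan(tc) or np.isnan(tn):
            excluded[gene] = "missing TR"
            continue
        delta = tc - tn
        rows[gene] = {
            "p_value": p_values[gene],
            "mean_tr_case": tc,
            "mean_tr_control": tn,
            "delta_tr": delta,
            "direction": CASE_ENRICHED if delta > 0 else CONTROL_ENRICHED,
            "significant": bool(p_values[gene] < alpha and abs(delta) > min_delta),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return ApaCallSet(contrast_id, table, excluded)


def cohort_test(
    tr_case: np.ndarray | pd.Series,
    tr_control: np.ndarray | pd.Series,
    equal_var: bool = False,
) -> Optional[dict]:
    """Unpaired two-sample t-test on per-sample TR values (Welch by default).

    Returns ``{"p_value", "mean_case", "mean_control"}`` over non-missing
    values, or None when a group has fewer than 2 non-missing values or the
    test statistic is undefined (both groups constant).
    """
    a = np.asarray(tr_case, dtype=float)
    b = np.asarray(tr_control, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return None
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(res.pvalue):
        return None
    return {
        "p_value": float(res.pvalue),
        "mean_case": float(a.mean()),
        "mean_control": float(b.mean()),
    }


def call_cohort(
    tr_case: pd.DataFrame,
    tr_control: pd.DataFrame,
    contrast_id: str = "cohort",
    alpha: float = 0.01,
    equal_var: bool = False,
) -> ApaCallSet:
    """Cohort-mode calls over a genes x samples TR matrix pair."""
    excluded = {}
    rows = {}
    common = tr_case.index.intersection(tr_control.index)
    for gene in common:
        res = cohort_test(tr_case.loc[gene], tr_control.loc[gene],
                          equal_var=equal_var)
        if res is None:
            excluded[gene] = "insufficient or degenerate TR values"
            continue
        delta = res["mean_case"] - res["mean_control"]
        rows[gene] = {
            "p_value": res["p_value"],
            "mean_tr_case": res["mean_case"],
            "mean_tr_control": res["mean_control"],
            "delta_tr": delta,
            "direction": CASE_ENRICHED if delta > 0 else CONTROL_ENRICHED,
            "significant": bool(res["p_value"] < alpha),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return ApaCallSet(contrast_id, table, excluded)


def conservation_filter(
    tr_case: pd.DataFrame,
    tr_reference: pd.DataFrame | pd.Series,
    side: str = "above",
    threshold: float = 0.8,
    center: str = "mean",
) -> pd.DataFrame:
    """Fraction of case samples strictly beyond the reference center, per gene.

    ``tr_reference`` may be a genes x samples matrix (its per-gene mean or
    median over non-missing values is the reference) or a precomputed
    per-gene Series.  Ties count for neither side.  Genes whose reference is
    all-missing are dropped.  Returns a frame with columns
    ``conserved_fraction`` and ``conserved``.
    """
    if side not in ("above", "below"):
        raise ValueError("side must be 'above' or 'below'")
    if isinstance(tr_reference, pd.DataFrame):
        ref = (tr_reference.median(axis=1) if center == "median"
               else tr_reference.mean(axis=1))
    else:
        ref = tr_reference
    common = tr_case.index.intersection(ref.index[ref.notna()])
    case = tr_case.loc[common]
    refv = ref.loc[common]
    vals = case.to_numpy(dtype=float)
    r = refv.to_numpy(dtype=float)[:, None]
    nonmiss = ~np.isnan(vals)
    beyond = (vals > r) if side == "above" else (vals < r)
    beyond &= nonmiss
    n = nonmiss.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n > 0, beyond.sum(axis=1) / np.maximum(n, 1), np.nan)
    out = pd.DataFrame(
        {"conserved_fraction": frac, "conserved": frac >= threshold}, index=common
    )
    return out[~out.conserved_fraction.isna()]


def annotate_conservation(
    calls: ApaCallSet,
    tr_case: pd.DataFrame,
    tr_control: pd.DataFrame,
    threshold: float = 0.8,
    center: str = "mean",
) -> ApaCallSet:
    """Attach conservation fractions to a cohort call set, per call direction.

    CASE_ENRICHED genes are checked for case samples above the control
    reference; CONTROL_ENRICHED genes for case samples below it.
    """
    above = conservation_filter(tr_case, tr_control, "above", threshold, center)
    below = conservation_filter(tr_case, tr_control, "below", threshold, center)
    frac = pd.Series(np.nan, index=calls.table.index)
    for gene in calls.table.index:
        src = above if calls.table.at[gene, "direction"] == CASE_ENRICHED else below
        if gene in src.index:
            frac[gene] = src.at[gene, "conserved_fraction"]
    calls.table["conserved_fraction"] = frac
    calls.table["conserved"] = (
        calls.table.significant & (frac >= threshold)
    ).fillna(False)
    return calls


@dataclass
class FrequencyProfile:
    """Cross-cancer event occurrence bookkeeping."""

    table: pd.DataFrame  # index gene_id; columns occurrence, cancers (tuple),
    #                      sides (tuple aligned with cancers), category

    def events_in_at_least(self, k: int) -> list[str]:
        return list(self.table.index[self.table.occurrence >= k])


def frequency_profile(callsets: dict[str, ApaCallSet]) -> FrequencyProfile:
    """Profile conserved events across cancer types.

    Per event (gene), records the set of cancers where it is conserved, the
    side per cancer (tumor = CASE_ENRICHED, normal = CONTROL_ENRICHED), the
    occurrence count, and a category: ``tumor_only``, ``normal_only`` or
    ``mixed``.
    """
    rows: dict[str, dict] = {}
    for cancer, cs in sorted(callsets.items()):
        if "conserved" not in cs.table:
            continue
        conserved = cs.table[cs.table.conserved.fillna(False)]
        for gene, row in conserved.iterrows():
            side = "tumor" if row.direction == CASE_ENRICHED else "normal"
            rec = rows.setdefault(gene, {"cancers": [], "sides": []})
            rec["cancers"].append(cancer)
            rec["sides"].append(side)
    out = {}
    for gene, rec in rows.items():
        sides = set(rec["sides"])
        category = ("mixed" if len(sides) == 2
                    else "tumor_only" if sides == {"tumor"} else "normal_only")
        out[gene] = {
            "occurrence": len(rec["cancers"]),
            "cancers": tuple(rec["cancers"]),
            "sides": tuple(rec["sides"]),
            "category": category,
        }
    table = pd.DataFrame.from_dict(out, orient="index")
    if not table.empty:
        table = table.sort_values("occurrence", ascending=False)
    return FrequencyProfile(table)
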