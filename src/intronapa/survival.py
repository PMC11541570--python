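"""TR-based prognostic modeling.

The prognostic pipeline screens features (variance filter, then a log-rank
test on training samples dichotomized at their training median), fits an
elastic-net-penalized Cox proportional-hazards model on the training set,
computes the prognostic index PI = sum_i beta_i x_i on held-out samples,
splits them into equal-size high/low risk groups by ordered PI, and
evaluates the split with Kaplan-Meier curves and a log-rank test.

Gene-expression and TR feature blocks can be analyzed separately or
concatenated (after per-block variance filtering) to test whether the two
data modalities carry complementary prognostic signal.  A t-test top-k
selector supports the phenotype-classification harness (SVM + AUC over
repeated splits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

log = logging.getLogger(__name__)


@dataclass
class ClinicalTable:
    """Per-sample survival data: time >= 0, event in {0, 1}."""

    frame: pd.DataFrame  # index sample_id; columns time, event (+ phenotypes)

    def __post_init__(self):
        if (self.frame["time"] < 0).any():
            raise ValueError("negative survival times")
        if not self.frame["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")

    @property
    def time(self) -> pd.Series:
        return self.frame["time"]

    @property
    def event(self) -> pd.Series:
        return self.frame["event"]

    def loc(self, samples) -> "ClinicalTable":
        return ClinicalTable(self.frame.loc[samples])


@dataclass
class RiskModel:
    selected_features: list[str]
    beta: pd.Series
    prognostic_index: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    risk_group: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    logrank_p: Optional[float] = None

    def compute_pi(self, X: pd.DataFrame) -> pd.Series:
        """PI = sum_i beta_i x_i — the linear component of the Cox model."""
        return X[self.beta.index] @ self.beta


def variance_filter(matrix: pd.DataFrame, threshold: float) -> list[str]:
    """Features (rows) with sample variance (ddof=1) >= threshold.

    Default thresholds used in this workflow: 1 for gene expression, 0.01
    for TR.
    """
    v = matrix.var(axis=1, ddof=1)
    return list(matrix.index[v >= threshold])


def train_test_split_samples(
    samples: Sequence[str], test_fraction: float = 0.2, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Deterministic 80/20 sample split (seeded permutation)."""
    rng = np.random.default_rng(seed)
    samples = list(samples)
    order = rng.permutation(len(samples))
    n_test = int(round(test_fraction * len(samples)))
    test = sorted(samples[i] for i in order[:n_test])
    train = sorted(samples[i] for i in order[n_test:])
    return train, test


def logrank_screen(
    features: pd.DataFrame,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    train_samples: Optional[Sequence[str]] = None,
) -> list[str]:
    """Select features whose median-dichotomized groups differ by log-rank
    p < alpha on the training samples.

    Each feature (row) is split at its training median; samples at the
    median go to the low group.  Features yielding a group with zero events
    or an empty group are skipped with a warning.
    """
    cols = list(train_samples) if train_samples is not None else list(features.columns)
    clin = clinical.frame.loc[cols]
    selected = []
    for feat in features.index:
        x = features.loc[feat, cols].astype(float)
        med = x.median()
        high = x > med
        if high.sum() == 0 or (~high).sum() == 0:
            log.warning("feature %s: degenerate dichotomization; skipped", feat)
            continue
        t, e = clin["time"], clin["event"]
        if e[high.values].sum() == 0 or e[(~high).values].sum() == 0:
            log.warning("feature %s: a group has zero events; skipped", feat)
            continue
        res = logrank_test(t[high.values], t[(~high).values],
                           e[high.values], e[(~high).values])
        if res.p_value < alpha:
            selected.append(feat)
    return selected


def fit_cox_elastic_net(
    X: pd.DataFrame,
    clinical: ClinicalTable,
    alpha: float = 0.01,
    l1_ratio: float = 0.5,
    standardize: bool = True,
) -> RiskModel:
    """Fit an elastic-net-penalized Cox model (samples x features).

    ``alpha`` is the overall penalty strength and ``l1_ratio`` the L1 mixing
    (1 = lasso, 0 -> ridge-dominant).  Coefficients are reported on the
    original covariate scale.  Raises on non-convergence with diagnostics.
    """
    samples = list(X.index)
    y = Surv.from_arrays(
        event=clinical.frame.loc[samples, "event"].astype(bool).to_numpy(),
        time=clinical.frame.loc[samples, "time"].to_numpy(),
    )
    Xv = X.to_numpy(dtype=float)
    mean = Xv.mean(axis=0)
    sd = Xv.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    if standardize:
        Xv = (Xv - mean) / sd_safe
    # sksurv's l1_ratio must be > 0; treat ridge-dominant requests as small L1
    l1 = max(l1_ratio, 1e-3)
    model = CoxnetSurvivalAnalysis(
        alphas=[alpha], l1_ratio=l1, fit_baseline_model=False, max_iter=200000
    )
    try:
        model.fit(Xv, y)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise RuntimeError(
            f"Cox elastic-net failed to converge: n={Xv.shape[0]}, "
            f"p={Xv.shape[1]}, alpha={alpha}, l1_ratio={l1}: {exc}"
        ) from exc
    coef = model.coef_.ravel()
    if standardize:
        coef = coef / sd_safe
    beta = pd.Series(coef, index=X.columns)
    return RiskModel(selected_features=list(X.columns), beta=beta)


def risk_groups(
    pi: pd.Series, clinical: ClinicalTable
) -> tuple[pd.Series, dict[str, KaplanMeierFitter], float]:
    """Split ordered PI into equal-size high/low risk groups and evaluate.

    With odd n the median sample joins the low-risk group.  Ties straddling
    the split are broken deterministically by sample id (the sort is stable
    on (PI, sample_id)).  Returns (labels, KM fits per group, log-rank p).
    """
    idx = np.lexsort((pi.index.to_numpy(), pi.to_numpy()))
    order = pi.iloc[idx]
    n = len(order)
    n_low = n - n // 2  # odd n: extra sample to low risk
    labels = pd.Series("high", index=order.index, dtype=object)
    labels.iloc[:n_low] = "low"
    labels = labels.loc[pi.index]

    clin = clinical.frame.loc[pi.index]
    fits = {}
    for grp in ("low", "high"):
        mask = (labels == grp).to_numpy()
        kmf = KaplanMeierFitter(label=grp)
        kmf.fit(clin["time"][mask], clin["event"][mask])
        fits[grp] = kmf
    hi, lo = (labels == "high").to_numpy(), (labels == "low").to_numpy()
    res = logrank_test(
        clin["time"][hi], clin["time"][lo], clin["event"][hi], clin["event"][lo]
    )
    return labels, fits, float(res.p_value)


def integrate_covariates(
    expression: pd.DataFrame,
    tr: pd.DataFrame,
    var_threshold_expr: float = 1.0,
    var_threshold_tr: float = 0.01,
) -> pd.DataFrame:
    """Concatenate GE and TR blocks (features x samples) after per-block
    variance filtering, namespaced as GE:/TR: to keep features disjoint.

    Raises on sample mismatch, listing the difference.
    """
    if list(expression.columns) != list(tr.columns):
        only_e = set(expression.columns) - set(tr.columns)
        only_t = set(tr.columns) - set(expression.columns)
        raise ValueError(
            f"sample mismatch between blocks: only-expression={sorted(only_e)}, "
            f"only-TR={sorted(only_t)}"
        )
    e = expression.loc[variance_filter(expression, var_threshold_expr)]
    t = tr.loc[variance_filter(tr, var_threshold_tr)]
    e = e.rename(index=lambda g: f"GE:{g}")
    t = t.rename(index=lambda g: f"TR:{g}")
    return pd.concat([e, t], axis=0)


def ttest_top_k(
    features: pd.DataFrame,
    labels: pd.Series,
    k: int = 100,
    train_samples: Optional[Sequence[str]] = None,
) -> list[str]:
    """Top-k features by two-sample t-test p-value on a binary phenotype.

    Screening uses training samples only.  If k exceeds the feature count
    all features are returned with a warning; k=0 returns the empty list.
    """
    if k == 0:
        return []
    cols = list(train_samples) if train_samples is not None else list(features.columns)
    y = labels.loc[cols]
    groups = y.unique()
    if len(groups) != 2:
        raise ValueError(f"labels must be binary, got {sorted(map(str, groups))}")
    a = features.loc[:, [c for c in cols if y[c] == groups[0]]].to_numpy(float)
    b = features.loc[:, [c for c in cols if y[c] == groups[1]]].to_numpy(float)
    res = stats.ttest_ind(a, b, axis=1)
    p = pd.Series(res.pvalue, index=features.index).fillna(1.0)
    if k >= len(p):
        log.warning("ttest_top_k: k=%d exceeds feature count %d", k, len(p))
        return list(p.index)
    return list(p.nsmallest(k).index)


def prognostic_pipeline(
    features: pd.DataFrame,
    clinical: ClinicalTable,
    seed: int = 0,
    screen_alpha: float = 0.05,
    penalty_alpha: float = 0.01,
    l1_ratio: float = 0.5,
    test_fraction: float = 0.2,
) -> Optional[RiskModel]:
    """End-to-end prognosis: split, screen, fit, PI, risk groups, log-rank.

    ``features`` is features x samples (already variance-filtered when
    applicable).  Returns None when the screen selects nothing.
    """
    train, test = train_test_split_samples(features.columns, test_fraction, seed)
    kept = logrank_screen(features, clinical, screen_alpha, train)
    if not kept:
        return None
    model = fit_cox_elastic_net(
        features.loc[kept, train].T, clinical.loc(train), penalty_alpha, l1_ratio
    )
    pi = model.compute_pi(features.loc[kept, test].T)
    labels, _fits, p = risk_groups(pi, clinical.loc(test))
    model.prognostic_index = pi
    model.risk_group = labels
    model.logrank_p = p
    return model
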