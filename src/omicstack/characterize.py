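"""Clinical and molecular characterization of the discovered subgroups.

Two pieces stay in the core pipeline: a k-group log-rank test (with
Kaplan-Meier curve coordinates) comparing survival across clusters, and
differential-feature selection — one-way ANOVA per feature across clusters,
one-vs-rest Welch t-tests per cluster, Benjamini-Hochberg correction within
datatype, and a joint q-value / log2 fold-change threshold. The selected
features define the input dimensions of the subgroup classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import OmicsLayer, SurvivalTable

#: datatypes whose fold change is a ratio of means (with pseudo-count);
#: bounded/real-valued datatypes use a plain mean difference instead
RATIO_FC_DATATYPES = ("F1", "F2")


@dataclass
class DEResult:
    """Differential-expression verdict for one feature."""

    feature_id: str
    datatype: str
    anova_p: float
    anova_q: float
    log2fc: dict[int, float]          # per-cluster effect vs rest
    pairwise_p: dict[int, float]      # one-vs-rest Welch t-test p per cluster
    selected: bool
    assigned_cluster: int | None      # cluster with the largest |effect|

    @property
    def max_abs_log2fc(self) -> float:
        return max(abs(v) for v in self.log2fc.values())


def logrank_test(surv: SurvivalTable):
    """k-group log-rank test across cluster labels, plus KM curve coordinates.

    Returns ``(chi2, p_value, curves)`` where curves maps cluster ->
    DataFrame with columns ``time`` and ``survival`` (the KM step function).
    The statistic has k-1 degrees of freedom.
    """
    if surv.cluster is None:
        raise ValueError("survival table carries no cluster labels")
    groups = np.unique(surv.cluster)
    if len(groups) < 2:
        raise ValueError("log-rank test requires at least two clusters")
    if surv.event.sum() == 0:
        raise ValueError("all samples censored: log-rank test undefined")

    res = multivariate_logrank_test(surv.time, surv.cluster, surv.event)
    curves: dict[int, pd.DataFrame] = {}
    for g in groups:
        mask = surv.cluster == g
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[mask], surv.event[mask])
        sf = kmf.survival_function_
        curves[int(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return float(res.test_statistic), float(res.p_value), curves


def _welch_onevsrest(x_in: np.ndarray, x_out: np.ndarray) -> float:
    if len(x_in) < 2 or len(x_out) < 2:
        return 1.0
    if np.std(x_in) == 0 and np.std(x_out) == 0:
        return 1.0 if np.mean(x_in) == np.mean(x_out) else 0.0
    t = stats.ttest_ind(x_in, x_out, equal_var=False)
    p = float(t.pvalue)
    return 1.0 if np.isnan(p) else p


def differential_features(
    layer: OmicsLayer | pd.DataFrame,
    labels: np.ndarray,
    datatype: str | None = None,
    q_max: float = 0.01,
    log2fc_min: float = 5.0,
    pseudo_count: float = 1.0,
    two_sided_fc: bool = True,
) -> list[DEResult]:
    """Per-feature ANOVA + one-vs-rest Welch t-tests with BH correction.

    Fold change is ``log2((mean_in + c) / (mean_rest + c))`` for ratio-scale
    datatypes (F1/F2) and a plain mean difference for bounded or already
    log-like datatypes (F3/F4). BH runs within the datatype over the ANOVA
    p-values. A feature is selected when ``q <= q_max`` and the magnitude
    of its largest per-cluster effect reaches ``log2fc_min`` (set
    ``two_sided_fc=False`` for the one-sided reading).
    """
    if isinstance(layer, OmicsLayer):
        values, fids, dtype = layer.values, layer.feature_ids, layer.datatype
    else:
        values = np.asarray(layer, dtype=float)
        fids = list(layer.columns) if isinstance(layer, pd.DataFrame) else [
            f"f{j}" for j in range(values.shape[1])
        ]
        dtype = datatype or "F1"
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    if min((labels == c).sum() for c in clusters) < 2:
        raise ValueError("every cluster needs at least two samples")
    use_ratio = dtype in RATIO_FC_DATATYPES

    n_feat = values.shape[1]
    anova_p = np.ones(n_feat)
    fcs: list[dict[int, float]] = []
    pair_ps: list[dict[int, float]] = []
    masks = {int(c): labels == c for c in clusters}

    for j in range(n_feat):
        col = values[:, j]
        groups = [col[m] for m in masks.values()]
        if np.ptp(col) == 0:  # constant feature: never significant
            anova_p[j] = 1.0
        else:
            f = stats.f_oneway(*groups)
            anova_p[j] = 1.0 if np.isnan(f.pvalue) else float(f.pvalue)
        fc: dict[int, float] = {}
        pp: dict[int, float] = {}
        for c, m in masks.items():
            x_in, x_out = col[m], col[~m]
            if use_ratio:
                fc[c] = float(
                    np.log2((x_in.mean() + pseudo_count) / (x_out.mean() + pseudo_count))
                )
            else:
                fc[c] = float(x_in.mean() - x_out.mean())
            pp[c] = _welch_onevsrest(x_in, x_out)
        fcs.append(fc)
        pair_ps.append(pp)

    anova_q = multipletests(anova_p, method="fdr_bh")[1]
    out: list[DEResult] = []
    for j, fid in enumerate(fids):
        effects = fcs[j]
        assigned = max(effects, key=lambda c: abs(effects[c]))
        magnitude = abs(effects[assigned]) if two_sided_fc else max(effects.values())
        selected = bool(anova_q[j] <= q_max and magnitude >= log2fc_min)
        out.append(
            DEResult(
                feature_id=fid,
                datatype=dtype,
                anova_p=float(anova_p[j]),
                anova_q=float(anova_q[j]),
                log2fc=effects,
                pairwise_p=pair_ps[j],
                selected=selected,
                assigned_cluster=int(assigned) if selected else None,
            )
        )
    return out


def select_subgroup_features(
    results: list[DEResult], q_max: float = 0.01, log2fc_min: float = 5.0,
    two_sided_fc: bool = True,
) -> dict[str, list[str]]:
    """Features passing both thresholds, grouped by datatype.

    An empty selection for a datatype is allowed (the classifier for that
    datatype is simply skipped); re-applies the thresholds so callers can
    tighten or relax them after the tests were run.
    """
    chosen: dict[str, list[str]] = {}
    for r in results:
        magnitude = (
            r.max_abs_log2fc if two_sided_fc else max(r.log2fc.values())
        )
        if r.anova_q <= q_max and magnitude >= log2fc_min:
            chosen.setdefault(r.datatype, []).append(r.feature_id)
    return chosen


def de_table(results: list[DEResult]) -> pd.DataFrame:
    """Flatten DE results into the TSV-friendly table layout."""
    rows = []
    for r in results:
        row = {
            "feature_id": r.feature_id,
            "datatype": r.datatype,
            "anova_p": r.anova_p,
            "anova_q": r.anova_q,
            "selected": r.selected,
            "assigned_cluster": r.assigned_cluster,
        }
        for c, v in sorted(r.log2fc.items()):
            row[f"log2fc_c{c}"] = v
        for c, v in sorted(r.pairwise_p.items()):
            row[f"pairwise_p_c{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
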