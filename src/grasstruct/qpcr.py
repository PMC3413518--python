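"""Efficiency-normalized relative quantification of qPCR Cq tables.

The per-gene amplification efficiency E is fitted from a standard curve
of serial dilutions, E = 10^(-1/slope) with slope from the least-squares
regression of Cq on log10(template amount).  Target abundance relative
to a reference gene is the normalized ratio

    ratio = E_t^(-CqT) / E_r^(-CqR)

and with two reference genes the final ratio is the geometric mean of
the per-reference ratios.  Fold changes are expressed relative to the
untreated control condition; significance over time points is assessed
by one-way ANOVA (computed from the between/within mean squares) with
pairwise two-sample t-tests at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EfficiencyFit",
    "AnovaResult",
    "fit_efficiency",
    "normalized_ratio",
    "replicate_ratios",
    "fold_change_table",
    "anova_pairwise",
]


@dataclass(frozen=True)
class EfficiencyFit:
    gene: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame
    degenerate: bool = False


def fit_efficiency(dilutions, gene: str = "") -> EfficiencyFit:
    """Fit E = 10^(-1/slope) from (log10 dilution, Cq) standard-curve points."""
    pts = np.asarray(list(dilutions), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (log10 dilution, Cq) points")
    res = stats.linregress(pts[:, 0], pts[:, 1])
    if res.slope >= 0:
        raise ValueError(f"non-negative standard-curve slope ({res.slope:.3g}): assay failure")
    return EfficiencyFit(
        gene=gene,
        slope=res.slope,
        intercept=res.intercept,
        efficiency=10.0 ** (-1.0 / res.slope),
        r_squared=res.rvalue**2,
    )


def normalized_ratio(cq_target: float, cq_refs, e_target: float, e_refs) -> float:
    """E_t^(-CqT) / E_r^(-CqR); multiple references combine by geometric mean."""
    if np.isscalar(cq_refs):
        cq_refs = [cq_refs]
    if np.isscalar(e_refs):
        e_refs = [e_refs] * len(cq_refs)
    if len(cq_refs) != len(e_refs) or not cq_refs:
        raise ValueError("need one efficiency per reference Cq")
    for e in [e_target, *e_refs]:
        if e <= 1:
            raise ValueError("amplification efficiencies must exceed 1")
    if any(c is None or (isinstance(c, float) and math.isnan(c)) for c in cq_refs):
        raise ValueError("missing reference Cq")
    target = e_target ** (-cq_target)
    per_ref = [target / (e ** (-c)) for c, e in zip(cq_refs, e_refs)]
    return float(np.exp(np.mean(np.log(per_ref))))


_CONDITION = ["tissue", "treatment", "time_h"]


def replicate_ratios(table: pd.DataFrame, efficiencies: dict[str, float]) -> pd.DataFrame:
    """Per-replicate normalized ratios for every target row of a Cq table.

    The table holds one row per (gene, tissue, treatment, time_h,
    replicate) with columns ``role`` in {target, reference} and ``Cq``.
    Each target replicate is normalized against the reference-gene Cq
    values of the same condition and replicate.
    """
    required = {"gene", "role", "Cq", "replicate", *_CONDITION}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Cq table lacks columns {sorted(missing)}")
    if (table.Cq <= 0).any():
        raise ValueError("Cq values must be positive")
    refs = table[table.role == "reference"]
    targets = table[table.role == "target"]
    ref_lookup = refs.set_index(_CONDITION + ["replicate", "gene"]).Cq.sort_index()
    rows = []
    for r in targets.itertuples(index=False):
        key = (r.tissue, r.treatment, r.time_h, r.replicate)
        try:
            ref_cqs = ref_lookup.loc[key]
        except KeyError:
            raise ValueError(f"no reference Cq for condition {key}") from None
        ratio = normalized_ratio(
            r.Cq,
            list(ref_cqs.values),
            efficiencies[r.gene],
            [efficiencies[g] for g in ref_cqs.index],
        )
        rows.append(
            {"gene": r.gene, "tissue": r.tissue, "treatment": r.treatment,
             "time_h": r.time_h, "replicate": r.replicate, "ratio": ratio}
        )
    out = pd.DataFrame(rows)
    return out.sort_values(list(out.columns[:-1])).reset_index(drop=True)


def fold_change_table(
    table: pd.DataFrame,
    efficiencies: dict[str, float],
    control: dict | None = None,
    mode: str = "per_replicate",
) -> pd.DataFrame:
    """Fold changes of every gene x condition versus the untreated control.

    ``control`` selects the control rows within each gene x tissue x
    treatment group (default ``{"time_h": 0}``).  With
    ``mode="per_replicate"`` ratios are computed per replicate and then
    averaged; ``mode="mean_cq"`` averages Cq values first.  Reported per
    condition: mean ratio, fold change (condition mean / control mean)
    and mean +/- SD of the replicate-level fold changes.
    """
    control = {"time_h": 0} if control is None else control
    if mode == "mean_cq":
        keys = ["gene", "role", *_CONDITION]
        table = table.groupby(keys, as_index=False).agg(Cq=("Cq", "mean")).assign(replicate=1)
    elif mode != "per_replicate":
        raise ValueError(f"unknown mode {mode!r}")
    ratios = replicate_ratios(table, efficiencies)
    out = []
    for (gene, tissue, treatment), grp in ratios.groupby(["gene", "tissue", "treatment"], sort=True):
        mask = np.ones(len(grp), dtype=bool)
        for col, val in control.items():
            mask &= (grp[col] == val).to_numpy()
        ctrl = grp[mask]
        if ctrl.empty:
            raise ValueError(f"no control replicates for {gene}/{tissue}/{treatment}")
        ctrl_mean = ctrl.ratio.mean()
        for time_h, sub in grp.groupby("time_h", sort=True):
            folds = sub.ratio.to_numpy() / ctrl_mean
            out.append(
                {"gene": gene, "tissue": tissue, "treatment": treatment, "time_h": time_h,
                 "n": len(sub), "mean_ratio": sub.ratio.mean(),
                 "fold_change": sub.ratio.mean() / ctrl_mean,
                 "fold_sd": folds.std(ddof=1) if len(folds) > 1 else 0.0}
            )
    return pd.DataFrame(out)


def anova_pairwise(groups: dict, alpha: float = 0.05, correction: str | None = None) -> AnovaResult:
    """One-way ANOVA across groups plus pairwise two-sample t-tests.

    The F statistic is computed from the between- and within-group mean
    squares.  ``correction="bonferroni"`` rescales the pairwise alpha by
    the number of comparisons; the default leaves them uncorrected.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >=2 groups with >=2 replicates each")
    n_total = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    degenerate = False
    if ms_within == 0:
        if ms_between == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p, degenerate = float("inf"), 0.0, True
    else:
        f_stat = ms_between / ms_within
        p = float(stats.f.sf(f_stat, df_b, df_w))
    n_pairs = df_b * (df_b + 1) // 2
    pair_alpha = alpha / n_pairs if correction == "bonferroni" else alpha
    rows = []
    for (la, a), (lb, b) in combinations(zip(labels, arrays), 2):
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t, tp = (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
        else:
            t, tp = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {"group1": la, "group2": lb, "t": float(t), "p": float(tp),
             "significant": bool(tp <= pair_alpha)}
        )
    return AnovaResult(f_stat, p, df_b, df_w, pd.DataFrame(rows), degenerate)
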