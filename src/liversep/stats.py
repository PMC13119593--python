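"""Group comparisons and diagnostic-accuracy analysis for staging biomarkers.

Implements the evaluation battery used for fibrosis staging metrics:
Mann-Whitney U tests (exact or continuity-corrected normal p), empirical
ROC curves with AUC and Youden-index operating point, Spearman rank
correlation against ordinal histology stage, and the cohort-level staging
report comparing F0-1 / F2-3 / F4 groups, the treatment-relevant F0-2 vs
F3-4 split, and paramagnetic levels across iron-grade groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RocResult", "mann_whitney", "roc_analysis", "spearman_rho",
           "staging_report", "METRIC_COLUMNS"]

#: Report metrics, in the presentation order of the staging table.
METRIC_COLUMNS = [
    ("chi_neg_abs_opt", "|chi-| (optimized r) (ppm)"),
    ("r2s", "R2* (s^-1)"),
    ("chi_pos_opt", "|chi+| (optimized r) (ppm)"),
    ("chi_neg_abs_def", "|chi-| (default r) (ppm)"),
    ("pdff", "PDFF (%)"),
    ("chi_pos_def", "|chi+| (default r) (ppm)"),
    ("chi", "chi (ppm)"),
]


@dataclass
class RocResult:
    """ROC summary: AUC, Mann-Whitney p, Youden cutoff and operating point."""

    auc: float
    p_value: float
    cutoff: float
    sensitivity: float      # percent
    specificity: float      # percent
    fpr: np.ndarray
    tpr: np.ndarray
    direction: int          # +1: larger score = positive class

    @property
    def youden_j(self) -> float:
        return (self.sensitivity + self.specificity) / 100.0 - 1.0


def mann_whitney(group_a, group_b, method: str = "normal"):
    """Two-sided Mann-Whitney U test.

    U counts pairs (a, b) with a > b plus half-ties (so U/(n1*n2) is the
    probability-of-superiority / AUC).  ``method='normal'`` uses the
    large-sample approximation mu = n1*n2/2, sigma^2 = n1*n2*(n1+n2+1)/12
    with a 0.5 continuity correction; ``method='exact'`` enumerates the
    tie-free permutation null.

    Returns (U, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    u = float(np.sum(a[:, None] > b[None, :])
              + 0.5 * np.sum(a[:, None] == b[None, :]))
    n1, n2 = a.size, b.size
    if method == "normal":
        mu = n1 * n2 / 2.0
        sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        z = (abs(u - mu) - 0.5) / sigma
        z = max(z, 0.0)
        p = 2.0 * sps.norm.sf(z)
    elif method == "exact":
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return u, float(min(p, 1.0))


def roc_analysis(scores, labels, method: str = "normal") -> RocResult:
    """Empirical ROC of a scalar metric against a binary group label.

    AUC is the rank (Mann-Whitney) statistic U/(n1*n2); the p-value is
    the two-sided Mann-Whitney p on the same two groups.  The operating
    cutoff maximizes the Youden index J = sens + spec - 1 over all
    thresholds, ties resolving to the lower cutoff.  If the positive
    class scores lower, the direction is flipped (recorded) so AUC >= 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    pos, neg = s[y == 1], s[y == 0]
    u, p = mann_whitney(pos, neg, method=method)
    auc = u / (pos.size * neg.size)
    direction = 1
    if auc < 0.5:
        direction, s = -1, -s
        pos, neg = -pos, -neg
        u, p = mann_whitney(pos, neg, method=method)
        auc = u / (pos.size * neg.size)

    # threshold sweep over midpoints between adjacent unique scores
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cuts = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    sens = np.array([(pos >= c).mean() for c in cuts])
    spec = np.array([(neg < c).mean() for c in cuts])
    fpr, tpr = 1.0 - spec, sens
    order = np.argsort(fpr, kind="stable")
    j = sens + spec - 1.0
    best = int(np.argmax(j))          # argmax takes the first = lowest cutoff
    cutoff = float(cuts[best]) * direction
    return RocResult(auc=float(auc), p_value=p, cutoff=cutoff,
                     sensitivity=float(100 * sens[best]),
                     specificity=float(100 * spec[best]),
                     fpr=fpr[order], tpr=tpr[order], direction=direction)


def spearman_rho(x, y) -> float:
    """Tie-aware Spearman rank correlation (Pearson on mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _group_sel(stages, group):
    return np.isin(np.asarray(stages), group)


def staging_report(table: pd.DataFrame, metrics=None,
                   method: str = "normal") -> dict:
    """Full staging analysis of a cohort metrics table.

    ``table`` needs ``fibrosis_stage`` plus metric columns (see
    :data:`METRIC_COLUMNS`); ``iron_grade`` enables the iron comparison.
    Returns dict with:

    * ``roc`` — one row per metric for the F0-2 vs F3-4 split: AUC,
      p, Youden cutoff, sensitivity/specificity (the treatment-decision
      table layout);
    * ``group_comparisons`` — pairwise Mann-Whitney p for F0-1 vs F2-3
      and F2-3 vs F4 per metric;
    * ``spearman`` — rho of each metric against ordinal stage;
    * ``iron`` — |chi+| comparisons across no-iron / I0-1 / I2-3 groups
      (when iron grades are present).
    """
    if metrics is None:
        metrics = [(c, lbl) for c, lbl in METRIC_COLUMNS if c in table.columns]
    missing = [c for c, _ in metrics if c not in table.columns]
    if missing:
        raise KeyError(f"metric column(s) missing from cohort table: {missing}")
    stages = table["fibrosis_stage"].to_numpy()

    roc_rows, cmp_rows, rho_rows = [], [], []
    adv = _group_sel(stages, (3, 4)).astype(int)   # F3-4 vs F0-2
    for col, label in metrics:
        vals = table[col].to_numpy(dtype=float)
        uninformative = np.unique(vals).size < 2
        if uninformative:
            roc_rows.append({"parameter": label, "auc": 0.5, "p_value": 1.0,
                             "cutoff": float(vals[0]), "sensitivity": 100.0,
                             "specificity": 0.0, "uninformative": True})
        else:
            rr = roc_analysis(vals, adv, method=method)
            roc_rows.append({"parameter": label, "auc": round(rr.auc, 2),
                             "p_value": _round_sig(rr.p_value, 2),
                             "cutoff": rr.cutoff,
                             "sensitivity": rr.sensitivity,
                             "specificity": rr.specificity,
                             "uninformative": False})
        for pair_name, g_lo, g_hi in [("F0-1 vs F2-3", (0, 1), (2, 3)),
                                      ("F2-3 vs F4", (2, 3), (4,))]:
            lo = vals[_group_sel(stages, g_lo)]
            hi = vals[_group_sel(stages, g_hi)]
            u, p = mann_whitney(hi, lo, method=method)
            cmp_rows.append({"parameter": label, "comparison": pair_name,
                             "U": u, "p_value": _round_sig(p, 2)})
        if not uninformative and np.unique(stages).size > 1:
            rho_rows.append({"parameter": label,
                             "spearman_rho": spearman_rho(vals, stages)})

    out = {"roc": pd.DataFrame(roc_rows),
           "group_comparisons": pd.DataFrame(cmp_rows),
           "spearman": pd.DataFrame(rho_rows)}

    if "iron_grade" in table.columns:
        grades = table["iron_grade"].astype(str).to_numpy()
        groups = {"none": grades == "none",
                  "I0-1": np.isin(grades, ["0", "0-1", "1"]),
                  "I2-3": np.isin(grades, ["2", "2-3", "3"])}
        chip_col = "chi_pos_opt" if "chi_pos_opt" in table.columns else None
        iron_rows = []
        if chip_col:
            vals = table[chip_col].to_numpy(dtype=float)
            for (na, nb) in [("none", "I0-1"), ("I0-1", "I2-3")]:
                ga, gb = vals[groups[na]], vals[groups[nb]]
                if ga.size and gb.size:
                    u, p = mann_whitney(gb, ga, method=method)
                    iron_rows.append({"comparison": f"{na} vs {nb}",
                                      "U": u, "p_value": _round_sig(p, 2)})
        out["iron"] = pd.DataFrame(iron_rows)
    return out


def _round_sig(p: float, sig: int) -> float:
    if p <= 0:
        return 0.0
    from math import floor, log10
    return round(p, -int(floor(log10(abs(p)))) + (sig - 1))
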