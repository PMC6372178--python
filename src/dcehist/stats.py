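"""Zonal group statistics: paired comparisons, Gleason correlation, ROC.

Reproduces the study design: within each prostate zone, cancer and benign
ROIs form within-patient pairs, so every histogram parameter is compared
with the Wilcoxon signed-rank test; parameters significant at the 10 mm
ROI diameter go on to ROC analysis with a Youden-index operating point,
and (for cancer ROIs) Spearman correlation against the Gleason score.

Raw p-values only, matching the original analysis; an optional
Benjamini-Hochberg FDR column is available as a clearly marked extension.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError
from .io import FEATURE_NAMES, ZONE_LABELS, FeatureRecord, records_to_frame

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedComparison:
    """Cancer-vs-benign group summary for one parameter/zone/map/diameter."""

    zone: str
    map_name: str
    diameter_mm: float
    parameter: str
    cancer_mean: float
    cancer_sd: float
    benign_mean: float
    benign_sd: float
    n_pairs: int
    wilcoxon_p: float


@dataclass(frozen=True)
class RocResult:
    """ROC analysis of one parameter at the Youden-index threshold.

    ``direction`` records the discriminating polarity: ``"high"`` when
    cancer takes larger values than benign tissue, ``"low"`` otherwise
    (AUC is always oriented >= 0.5). Sensitivity, specificity and accuracy
    are percentages at the reported threshold.
    """

    threshold: float
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    direction: str


@dataclass(frozen=True)
class SpearmanResult:
    """Spearman correlation of one parameter with the Gleason score."""

    zone: str
    map_name: str
    parameter: str
    rho: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (Wilcoxon's rule); the exact null
    distribution is used for n <= 25 without ties in the absolute
    differences, otherwise the tie-corrected normal approximation with
    continuity correction. All differences zero returns p = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"paired vectors differ in length: {x.size} vs {y.size}")
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", correction=True, method=method)
    return float(res.pvalue)


def spearman_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation and its p-value.

    A constant input leaves rho undefined: returns (nan, nan) with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"vectors differ in length: {x.size} vs {y.size}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def auc_rank_sum(positive: np.ndarray, negative: np.ndarray) -> float:
    """AUC via the rank-sum (Mann-Whitney) formulation with half credit
    for ties; NOT oriented (may be < 0.5)."""
    positive = np.asarray(positive, dtype=float)
    negative = np.asarray(negative, dtype=float)
    pooled = np.concatenate([positive, negative])
    ranks = sps.rankdata(pooled)
    n_pos, n_neg = positive.size, negative.size
    r_pos = ranks[:n_pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_with_youden(cancer_values: np.ndarray, benign_values: np.ndarray) -> RocResult:
    """ROC analysis with the Youden-index operating point.

    AUC comes from the rank-sum formulation (ties credited 1/2) and is
    oriented so AUC >= 0.5; the discriminating polarity is recorded in
    ``direction``. Candidate thresholds are midpoints between adjacent
    distinct pooled values; the threshold maximizing
    J = sensitivity + specificity - 1 is returned (ties broken by higher
    sensitivity, then lower threshold).
    """
    cancer = np.asarray(cancer_values, dtype=float)
    benign = np.asarray(benign_values, dtype=float)
    if cancer.size == 0 or benign.size == 0:
        raise ValidationError("both groups must be non-empty")

    distinct = np.unique(np.concatenate([cancer, benign]))
    if distinct.size == 1:
        warnings.warn("both groups constant and equal: AUC = 0.5", stacklevel=2)
        v = float(distinct[0])
        # every case called positive: sensitivity 100, specificity 0
        acc = 100.0 * cancer.size / (cancer.size + benign.size)
        return RocResult(threshold=v, auc=0.5, sensitivity=100.0, specificity=0.0,
                         accuracy=acc, direction="high")

    auc = auc_rank_sum(cancer, benign)
    direction = "high" if auc >= 0.5 else "low"
    if direction == "low":
        auc = 1.0 - auc

    thresholds = 0.5 * (distinct[:-1] + distinct[1:])
    best: tuple[float, float, float, float] | None = None  # (J, sens, -thr marker handled below)
    best_row = None
    for thr in thresholds:
        if direction == "high":
            tp = np.count_nonzero(cancer >= thr)
            tn = np.count_nonzero(benign < thr)
        else:
            tp = np.count_nonzero(cancer <= thr)
            tn = np.count_nonzero(benign > thr)
        sens = 100.0 * tp / cancer.size
        spec = 100.0 * tn / benign.size
        j = sens + spec - 100.0
        key = (j, sens, -thr)
        if best is None or key > best:
            best = key
            acc = 100.0 * (tp + tn) / (cancer.size + benign.size)
            best_row = (float(thr), sens, spec, acc)
    assert best_row is not None
    thr, sens, spec, acc = best_row
    return RocResult(threshold=thr, auc=float(auc), sensitivity=sens, specificity=spec,
                     accuracy=acc, direction=direction)


# ---------------------------------------------------------------------------
# Full-grid summary
# ---------------------------------------------------------------------------


def _paired_frame(df: pd.DataFrame, zone: str, map_name: str, diameter: float) -> pd.DataFrame:
    """Wide frame of complete within-patient pairs; one row per patient,
    columns ``(parameter, group)`` with group in {cancer, benign}."""
    cancer_label, benign_label = ZONE_LABELS[zone]
    sub = df[(df["map"] == map_name) & (df["diameter_mm"] == diameter)]
    cancer = sub[sub["label"] == cancer_label].set_index("patient_id")
    benign = sub[sub["label"] == benign_label].set_index("patient_id")
    common = cancer.index.intersection(benign.index)
    dropped = len(set(cancer.index).symmetric_difference(set(benign.index)))
    if dropped:
        logger.info(
            "zone %s %s %.3g mm: dropped %d unpaired record(s)", zone, map_name, diameter, dropped
        )
    wide = pd.concat(
        {
            "cancer": cancer.loc[common, list(FEATURE_NAMES)],
            "benign": benign.loc[common, list(FEATURE_NAMES)],
        },
        axis=1,
    )
    return wide


def summarize_tables(
    records: list[FeatureRecord],
    alpha: float = 0.05,
    roc_diameter_mm: float = 10.0,
    fdr: bool = False,
    gleason_coding: str = "sum",
) -> dict:
    """Compute the full statistics grid from per-ROI feature records.

    For every (zone, map, diameter, parameter): group mean(SD) over
    complete within-patient pairs and the Wilcoxon signed-rank p. For
    parameters with p < ``alpha`` at ``roc_diameter_mm``: ROC with Youden
    threshold (on the same records) and Spearman correlation of the cancer
    ROIs' parameter with the Gleason score (``gleason_coding``: ``"sum"``
    uses the score as recorded, ``"grade_group"`` maps sums 6,7,8,9,10 to
    ISUP-like ordinal groups 1,2,4,5,5 — the 3+4 / 4+3 distinction is not
    recoverable from sums).

    Returns a JSON-ready dict with keys ``comparisons``, ``roc``,
    ``spearman`` and ``meta``.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValidationError("no feature records to summarize")
    zones = [z for z in ("TZ", "PZ") if df["label"].isin(ZONE_LABELS[z]).any()]
    maps = [m for m in ("MWS", "DPS") if (df["map"] == m).any()]
    diameters = sorted(df["diameter_mm"].unique())

    comparisons: list[dict] = []
    roc_rows: list[dict] = []
    spearman_rows: list[dict] = []

    for zone in zones:
        for map_name in maps:
            for diameter in diameters:
                wide = _paired_frame(df, zone, map_name, diameter)
                if wide.empty:
                    continue
                for param in FEATURE_NAMES:
                    x = wide[("cancer", param)].to_numpy(dtype=float)
                    y = wide[("benign", param)].to_numpy(dtype=float)
                    ok = ~(np.isnan(x) | np.isnan(y))
                    n_dropped = int((~ok).sum())
                    if n_dropped:
                        logger.info(
                            "%s %s %.3g mm %s: dropped %d pair(s) with missing values",
                            zone, map_name, diameter, param, n_dropped,
                        )
                    x, y = x[ok], y[ok]
                    if x.size == 0:
                        continue
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        p = wilcoxon_signed_rank(x, y) if x.size >= 2 else float("nan")
                    comparisons.append(
                        {
                            "zone": zone,
                            "map": map_name,
                            "diameter_mm": float(diameter),
                            "parameter": param,
                            "cancer_mean": float(np.mean(x)),
                            "cancer_sd": float(np.std(x, ddof=1)) if x.size > 1 else float("nan"),
                            "benign_mean": float(np.mean(y)),
                            "benign_sd": float(np.std(y, ddof=1)) if y.size > 1 else float("nan"),
                            "n_pairs": int(x.size),
                            "wilcoxon_p": p,
                        }
                    )
                    # ROC + Spearman restricted to the protocol's ROC diameter
                    if diameter == roc_diameter_mm and np.isfinite(p) and p < alpha:
                        roc = roc_with_youden(x, y)
                        roc_rows.append(
                            {
                                "zone": zone,
                                "map": map_name,
                                "diameter_mm": float(diameter),
                                "parameter": param,
                                "threshold": roc.threshold,
                                "auc": roc.auc,
                                "sensitivity": roc.sensitivity,
                                "specificity": roc.specificity,
                                "accuracy": roc.accuracy,
                                "direction": roc.direction,
                            }
                        )
                        sp = _spearman_vs_gleason(
                            df, zone, map_name, diameter, param, gleason_coding
                        )
                        if sp is not None:
                            spearman_rows.append(sp)

    if fdr:
        pvals = np.array([c["wilcoxon_p"] for c in comparisons])
        finite = np.isfinite(pvals)
        adj = np.full(pvals.shape, np.nan)
        if finite.any():
            adj[finite] = sps.false_discovery_control(pvals[finite], method="bh")
        for c, q in zip(comparisons, adj):
            c["wilcoxon_p_fdr_extension"] = float(q)

    return {
        "comparisons": comparisons,
        "roc": roc_rows,
        "spearman": spearman_rows,
        "meta": {
            "alpha": alpha,
            "roc_diameter_mm": roc_diameter_mm,
            "gleason_coding": gleason_coding,
            "fdr_extension": fdr,
            "n_records": int(len(records)),
        },
    }


_GRADE_GROUP = {6: 1, 7: 2, 8: 4, 9: 5, 10: 5}


def _spearman_vs_gleason(
    df: pd.DataFrame, zone: str, map_name: str, diameter: float, param: str, coding: str
) -> dict | None:
    if "gleason" not in df.columns:
        return None
    cancer_label = ZONE_LABELS[zone][0]
    sub = df[
        (df["label"] == cancer_label)
        & (df["map"] == map_name)
        & (df["diameter_mm"] == diameter)
        & df["gleason"].notna()
        & df[param].notna()
    ]
    if len(sub) < 4:
        return None
    gleason = sub["gleason"].to_numpy(dtype=float)
    if coding == "grade_group":
        gleason = np.array([_GRADE_GROUP[int(g)] for g in gleason], dtype=float)
    elif coding != "sum":
        raise ValidationError(f"unknown gleason coding {coding!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = spearman_corr(sub[param].to_numpy(dtype=float), gleason)
    return {
        "zone": zone,
        "map": map_name,
        "parameter": param,
        "rho": rho,
        "p": p,
        "n": int(len(sub)),
    }


# ---------------------------------------------------------------------------
# Table mirrors
# ---------------------------------------------------------------------------


def comparison_tables(report: dict) -> dict[str, pd.DataFrame]:
    """Mirror the report as publication-style tables.

    Returns one wide cancer/benign/p table per zone (rows = parameters,
    columns = map x diameter), one ROC table per zone, and a Spearman
    table.
    """
    out: dict[str, pd.DataFrame] = {}
    comp = pd.DataFrame(report["comparisons"])
    if not comp.empty:
        for zone, sub in comp.groupby("zone"):
            pivot = sub.pivot_table(
                index="parameter",
                columns=["map", "diameter_mm"],
                values=["cancer_mean", "cancer_sd", "benign_mean", "benign_sd", "wilcoxon_p"],
                sort=False,
            )
            pivot = pivot.reindex(list(FEATURE_NAMES))
            out[f"comparison_{zone}"] = pivot
    roc = pd.DataFrame(report["roc"])
    if not roc.empty:
        for zone, sub in roc.groupby("zone"):
            out[f"roc_{zone}"] = sub.drop(columns="zone").reset_index(drop=True)
    sp = pd.DataFrame(report["spearman"])
    if not sp.empty:
        out["spearman"] = sp.reset_index(drop=True)
    return out
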