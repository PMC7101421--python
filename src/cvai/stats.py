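"""Evaluation statistics: correlation, Mann-Whitney U, ROC/AUC.

The analysis battery around the binarisation pipeline: per-group summaries
of CVAI, correlations of CVAI against choroidal thickness / age /
refractive error, a normal-vs-CSC group comparison (Mann-Whitney U), and
ROC curves for classifying "thick choroid" at fixed thickness cut-offs
(250, 300, 350 um) using CVAI as the score. Because CVAI falls as the
choroid thickens, CVAI predicts a thick choroid with *lower* values; the
``score_direction`` argument makes that orientation explicit everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import DegenerateStatisticError, ParameterError

DEFAULT_THRESHOLDS_UM = (250.0, 300.0, 350.0)

HIGHER_IS_POSITIVE = "higher_is_positive"
LOWER_IS_POSITIVE = "lower_is_positive"
_DIRECTIONS = (HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE)


@dataclass
class EyeRecord:
    """One eye's row in the evaluation: measurements plus derived scores."""

    eye_id: str
    group: str
    choroidal_thickness_um: float
    age_years: float
    sere_dioptre: float
    cvai: float | None = None
    predicted_thickness_um: float | None = None

    def __post_init__(self) -> None:
        if self.choroidal_thickness_um <= 0:
            raise ParameterError("choroidal thickness must be positive")
        if self.cvai is not None and not (0 <= self.cvai <= 1):
            raise ParameterError("cvai must lie in [0, 1]")


@dataclass
class ROCResult:
    """One ROC curve: operating points, trapezoidal AUC, class sizes."""

    threshold_um: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value.

    Pearson uses the t approximation for the p-value; Spearman uses the
    exact/approximate rank method. Zero variance in either variable is a
    degenerate input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ParameterError("correlation requires at least 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ParameterError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticError("zero variance in one of the variables")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ParameterError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``U = min(U_a, U_b)`` (the smaller of the two one-sided
    statistics). The p-value is exact (full null enumeration) when
    ``len(a) + len(b) <= 12`` and there are no ties, and otherwise uses the
    normal approximation with tie correction (no continuity correction, so
    identical samples give p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    return u, float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# dichotomisation and ROC
# ---------------------------------------------------------------------------

def dichotomise(records, threshold_um: float) -> np.ndarray:
    """Label eyes as thick choroid: positive iff thickness >= threshold."""
    frame = _records_frame(records)
    thickness = frame["choroidal_thickness_um"].to_numpy(dtype=float)
    if np.isnan(thickness).any():
        raise ParameterError("thickness missing for some records")
    return thickness >= float(threshold_um)


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    score_direction: str = HIGHER_IS_POSITIVE,
    threshold_um: float = float("nan"),
) -> ROCResult:
    """ROC curve over all distinct score thresholds, trapezoidal AUC.

    Ties contribute half, so the AUC equals the Mann-Whitney pair statistic
    U / (n_pos * n_neg). With ``lower_is_positive`` the score is negated
    before sweeping (the CVAI orientation for predicting thick choroid).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ParameterError("scores and labels must be 1-D and of equal length")
    if score_direction not in _DIRECTIONS:
        raise ParameterError(f"score_direction must be one of {_DIRECTIONS}")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateStatisticError("both classes must be present for a ROC curve")
    s = scores if score_direction == HIGHER_IS_POSITIVE else -scores
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), s, drop_intermediate=False)
    return ROCResult(
        threshold_um=float(threshold_um),
        fpr=fpr,
        tpr=tpr,
        auc=float(_sk_auc(fpr, tpr)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

def _round_floats(obj, sig: int = 6):
    """Round floats to ``sig`` significant digits (stable report bytes
    without flattening small p-values to zero)."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    return obj


def evaluate_cohort(
    records,
    thresholds_um: Sequence[float] = DEFAULT_THRESHOLDS_UM,
    score_direction: str = LOWER_IS_POSITIVE,
    correlation_method: str = "pearson",
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full evaluation battery on a cohort with CVAI populated.

    Per group: mean +/- SD of CVAI; CVAI-vs-thickness, CVAI-vs-age and
    CVAI-vs-refraction correlations; normal-vs-CSC Mann-Whitney on CVAI;
    per-threshold ROC/AUC of CVAI against "thick choroid"; and, when
    predictions are present, the predicted-vs-true thickness correlation.
    When ``out_dir`` is given the report is written as ``report.json`` plus
    one ROC-point CSV per group and threshold; re-running on the same input
    yields byte-identical files.
    """
    frame = _records_frame(records)
    if "cvai" not in frame.columns or frame["cvai"].isna().any():
        raise ParameterError("cvai must be populated for every record")

    report: dict = {"n": int(len(frame)), "groups": {}, "roc": {}, "comparison": {}}
    roc_points: dict[str, pd.DataFrame] = {}

    for group, sub in frame.groupby("group", sort=True):
        cvai = sub["cvai"].to_numpy(dtype=float)
        entry: dict = {
            "n": int(len(sub)),
            "cvai_mean": float(cvai.mean()),
            "cvai_sd": float(cvai.std(ddof=1)) if len(sub) > 1 else 0.0,
            "correlations": {},
        }
        for label, col in (
            ("thickness", "choroidal_thickness_um"),
            ("age", "age_years"),
            ("sere", "sere_dioptre"),
        ):
            coef, p = correlation(sub[col], cvai, method=correlation_method)
            rho, p_s = correlation(sub[col], cvai, method="spearman")
            entry["correlations"][f"cvai_vs_{label}"] = {
                "pearson_r" if correlation_method == "pearson" else correlation_method: coef,
                "p": p,
                "spearman_rho": rho,
                "spearman_p": p_s,
            }
        if "predicted_thickness_um" in sub.columns and sub["predicted_thickness_um"].notna().all():
            coef, p = correlation(
                sub["choroidal_thickness_um"], sub["predicted_thickness_um"],
                method=correlation_method,
            )
            entry["predicted_vs_true"] = {"r": coef, "p": p}

        report["groups"][group] = entry
        roc_entry = {}
        for thr in thresholds_um:
            labels = dichotomise(sub, thr)
            if labels.all() or not labels.any():
                roc_entry[f"{thr:g}"] = None  # one class only at this cut-off
                continue
            roc = roc_auc(cvai, labels, score_direction, threshold_um=thr)
            roc_entry[f"{thr:g}"] = {
                "auc": roc.auc, "n_pos": roc.n_pos, "n_neg": roc.n_neg,
            }
            roc_points[f"roc_{group}_{thr:g}um"] = pd.DataFrame(
                {"fpr": roc.fpr, "tpr": roc.tpr}
            )
        report["roc"][group] = roc_entry

    groups_present = set(frame["group"])
    if {"normal", "csc"} <= groups_present:
        u, p = mann_whitney_u(
            frame.loc[frame["group"] == "normal", "cvai"],
            frame.loc[frame["group"] == "csc", "cvai"],
        )
        report["comparison"]["cvai_normal_vs_csc"] = {"U": u, "p": p}

    report = _round_floats(report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        for name, pts in roc_points.items():
            pts.to_csv(out / f"{name}.csv", index=False, float_format="%.6f")
        _write_plots(frame, roc_points, out)
    return report


def _write_plots(frame: pd.DataFrame, roc_points: dict, out: Path) -> None:
    """Scatter (CVAI vs thickness) and ROC plots, one PNG per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for group, sub in frame.groupby("group", sort=True):
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(sub["choroidal_thickness_um"], sub["cvai"], s=12, alpha=0.7)
        ax.set_xlabel("choroidal thickness (um)")
        ax.set_ylabel("CVAI")
        ax.set_title(f"{group} (n={len(sub)})")
        fig.tight_layout()
        fig.savefig(out / f"scatter_{group}.png", dpi=100)
        plt.close(fig)

        curves = {k: v for k, v in roc_points.items() if k.startswith(f"roc_{group}_")}
        if curves:
            fig, ax = plt.subplots(figsize=(4, 4))
            for name, pts in sorted(curves.items()):
                ax.plot(pts["fpr"], pts["tpr"], label=name.rsplit("_", 1)[-1])
            ax.plot([0, 1], [0, 1], "k--", lw=0.8)
            ax.set_xlabel("false positive rate")
            ax.set_ylabel("true positive rate")
            ax.set_title(f"ROC, {group}")
            ax.legend(title="cut-off")
            fig.tight_layout()
            fig.savefig(out / f"roc_{group}.png", dpi=100)
            plt.close(fig)
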