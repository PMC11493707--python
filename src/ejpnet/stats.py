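"""Cohort statistics: LLD substitution, ROI averaging, Spearman correlation.

Hormone assays differ between the two menstrual-cycle phases, so readings
below the lower limit of detection (LLD) receive phase-specific fixed
substitutes before any statistics: follicular (FOL) estradiol 22 pg/mL and
progesterone 0.05 ng/mL; luteal (LUT) estradiol 10 pg/mL (about half the
20 pg/mL LLD) and progesterone 0.05 ng/mL.  Per-ROI image metrics are
averaged to one value per sample, and hormone-metric association is
assessed with Spearman's rank correlation — mid-ranks for ties, an
exhaustive permutation p-value for small n, the large-sample t
approximation otherwise, and no multiple-comparison correction by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "HormoneRecord",
    "CorrelationResult",
    "LLD_SUBSTITUTES",
    "LLD_LIMITS",
    "substitute_lld",
    "average_rois",
    "spearman",
    "correlate_cohort",
    "IMAGE_METRICS",
]

PHASES = ("FOL", "LUT")

#: Assay lower limits of detection: (phase, hormone) -> limit.
LLD_LIMITS: dict[tuple[str, str], float] = {
    ("FOL", "estradiol"): 22.0,  # pg/mL
    ("FOL", "progesterone"): 0.05,  # ng/mL
    ("LUT", "estradiol"): 20.0,
    ("LUT", "progesterone"): 0.09,
}

#: Fixed substitute assigned to below-LLD readings before statistics.
LLD_SUBSTITUTES: dict[tuple[str, str], float] = {
    ("FOL", "estradiol"): 22.0,
    ("FOL", "progesterone"): 0.05,
    ("LUT", "estradiol"): 10.0,
    ("LUT", "progesterone"): 0.05,
}

#: Per-ROI image metrics that get averaged per sample and correlated.
IMAGE_METRICS = (
    "mfi_epithelium",
    "mfi_intermediate",
    "height_um",
    "pct_accessible",
    "pct_intact",
)

#: Exhaustive permutation p-values up to this n; t approximation beyond.
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class HormoneRecord:
    """Per-sample plasma hormone readings with censoring flags."""

    sample_id: str
    phase: str
    estradiol_pg_ml: float
    progesterone_ng_ml: float
    estradiol_below_lld: bool = False
    progesterone_below_lld: bool = False

    def __post_init__(self) -> None:
        if self.estradiol_pg_ml <= 0 or self.progesterone_ng_ml <= 0:
            raise ValueError("hormone values must be positive")


@dataclass(frozen=True)
class CorrelationResult:
    """One Spearman correlation between a hormone and an image metric."""

    x_name: str
    y_name: str
    rho: float
    p_value: float
    n: int


def substitute_lld(
    record: HormoneRecord,
    substitutes: Mapping[tuple[str, str], float] | None = None,
) -> HormoneRecord:
    """Replace below-LLD hormone values with the phase-specific substitute.

    Detected values pass through unchanged; the operation is idempotent.
    """
    if record.phase not in PHASES:
        raise ValueError(f"unknown phase {record.phase!r}; expected one of {PHASES}")
    subs = LLD_SUBSTITUTES if substitutes is None else substitutes
    changes: dict[str, float] = {}
    if record.estradiol_below_lld:
        changes["estradiol_pg_ml"] = subs[(record.phase, "estradiol")]
    if record.progesterone_below_lld:
        changes["progesterone_ng_ml"] = subs[(record.phase, "progesterone")]
    return replace(record, **changes) if changes else record


def substitute_lld_frame(hormones: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`substitute_lld` over a hormone table."""
    out = hormones.copy()
    for phase in PHASES:
        for hormone, col in (("estradiol", "estradiol_pg_ml"), ("progesterone", "progesterone_ng_ml")):
            sel = (out["phase"] == phase) & out[f"{hormone}_below_lld"].astype(bool)
            out.loc[sel, col] = LLD_SUBSTITUTES[(phase, hormone)]
    return out


def average_rois(per_roi_metrics: pd.DataFrame, metrics: Sequence[str] | None = None) -> pd.DataFrame:
    """Average per-ROI metrics to one row per sample.

    Unweighted arithmetic mean per metric; the ROI count is recorded in an
    ``n_rois`` column.  A metric missing (NaN) in some ROI is averaged
    over the ROIs where it is present, with a warning.
    """
    if "sample_id" not in per_roi_metrics.columns:
        raise ValueError("per-ROI table needs a sample_id column")
    if metrics is None:
        metrics = [m for m in IMAGE_METRICS if m in per_roi_metrics.columns]
        if not metrics:
            metrics = [
                c
                for c in per_roi_metrics.columns
                if c not in ("sample_id", "roi_id", "channel")
                and pd.api.types.is_numeric_dtype(per_roi_metrics[c])
            ]
    missing = per_roi_metrics[list(metrics)].isna()
    if missing.to_numpy().any():
        warnings.warn(
            "missing per-ROI metric values; sample means use available ROIs only",
            stacklevel=2,
        )
    grouped = per_roi_metrics.groupby("sample_id", sort=True)
    out = grouped[list(metrics)].mean()
    out["n_rois"] = grouped.size()
    return out.reset_index()


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(rx @ ry) / denom


def spearman(
    x: Iterable[float],
    y: Iterable[float],
    p_method: str = "auto",
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """Spearman rank correlation with a small-sample exact p-value.

    rho is the Pearson correlation of mid-ranks (ties get average ranks).
    The two-sided p-value is exhaustive over all n! permutations when
    ``p_method='exact_permutation'`` (or ``'auto'`` with n <= 9), and the
    t approximation with n-2 degrees of freedom otherwise.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_rho(rx, ry)

    if p_method == "auto":
        p_method = "exact_permutation" if n <= EXACT_PERMUTATION_MAX_N else "large_sample"
    if p_method == "exact_permutation":
        if n > EXACT_PERMUTATION_MAX_N:
            raise ValueError(f"exact permutation limited to n <= {EXACT_PERMUTATION_MAX_N}")
        perms = np.array(list(permutations(range(n))), dtype=np.intp)
        ryc = ry - ry.mean()
        rxc = rx - rx.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        rhos = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif p_method == "large_sample":
        if abs(rho) >= 1.0:
            p = np.finfo(float).tiny
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        p = min(max(p, np.finfo(float).tiny), 1.0)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")

    return CorrelationResult(x_name=x_name, y_name=y_name, rho=rho, p_value=p, n=n)


def correlate_cohort(
    samples: pd.DataFrame,
    hormones: Sequence[str] = ("estradiol_pg_ml", "progesterone_ng_ml"),
    metrics: Sequence[str] | None = None,
    p_method: str = "auto",
) -> pd.DataFrame:
    """Correlate each hormone with each image metric across samples.

    ``samples`` is a per-sample table (one row per sample, hormone columns
    already LLD-substituted, metric columns ROI-averaged).  Pairs with a
    missing member are dropped pairwise; a pair with fewer than three
    complete observations is skipped with a warning.  Returns a tidy frame
    with columns hormone, metric, rho, p, n.
    """
    if metrics is None:
        metrics = [m for m in IMAGE_METRICS if m in samples.columns]
    rows = []
    for hormone in hormones:
        for metric in metrics:
            pair = samples[[hormone, metric]].dropna()
            if len(pair) < 3:
                warnings.warn(
                    f"skipping {hormone} vs {metric}: only {len(pair)} complete pairs",
                    stacklevel=2,
                )
                continue
            try:
                res = spearman(
                    pair[hormone], pair[metric], p_method=p_method, x_name=hormone, y_name=metric
                )
            except ValueError:
                warnings.warn(
                    f"skipping {hormone} vs {metric}: correlation undefined "
                    "(constant values, e.g. all below LLD)",
                    stacklevel=2,
                )
                continue
            rows.append(
                {"hormone": hormone, "metric": metric, "rho": res.rho, "p": res.p_value, "n": res.n}
            )
    return pd.DataFrame(rows, columns=["hormone", "metric", "rho", "p", "n"])
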