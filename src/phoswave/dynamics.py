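"""Fold-change / Welch-t differential calling, transition classes, scaling.

The calling rule: a feature is significantly different in a comparison when
its replicate-median fold change exceeds the threshold (default 1.5, or is
below its reciprocal) and the two-sided Welch t-test on the per-replicate
intensities gives p below alpha (default 0.05).  Comparisons in which one
side is entirely undetected (zero) and the other detected may satisfy the
fold-change criterion by rule ("zero rescue"); their infinite fold changes
are imputed by substituting the smallest nonzero value of the whole
filtered dataset and recomputing.

With two replicates these t-tests are statistically degenerate (df <= 2);
they are implemented exactly as stated, with deterministic conventions for
zero-variance groups: p = 1 when the means are also equal, p = 0 otherwise.
No multiple-testing correction enters the category assignment; a
Benjamini-Hochberg column is reported for information only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mq_io import SampleDesign

log = logging.getLogger(__name__)

DEFAULT_TIMEPOINTS = (0, 45, 60, 75, 90, 105, 120, 135, 150, 165)

CATEGORIES = ("increased", "decreased", "no_change")


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and anchors of the differential analysis.

    ``metaphase_I`` / ``metaphase_II`` are the 75 and 120 min anchors of
    the metaphase-to-anaphase transition analysis (135 min is the anaphase
    II peak, so the timepoint just before it serves as metaphase II).
    ``fc_clamp_display`` bounds fold changes for display only and never
    affects calls.
    """

    fc_threshold: float = 1.5
    alpha: float = 0.05
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    metaphase_I: int = 75
    metaphase_II: int = 120
    fc_clamp_display: tuple[float, float] = (0.2, 2.2)
    fc_mode: str = "paired"  # or "pooled"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for anchor in (self.metaphase_I, self.metaphase_II):
            if anchor not in self.timepoints:
                raise ValueError(f"anchor {anchor} not in timepoints")
        if self.fc_mode not in ("paired", "pooled"):
            raise ValueError("fc_mode must be 'paired' or 'pooled'")


@dataclass(frozen=True)
class Comparison:
    """A named reference-vs-test contrast over channel groups.

    ``ref_channels`` and ``test_channels`` are ordered by replicate; when
    their lengths match, fold changes are computed replicate-paired.
    """

    label: str
    ref_channels: tuple[str, ...]
    test_channels: tuple[str, ...]


def dataset_minimum(matrix: pd.DataFrame) -> float:
    """Smallest nonzero value of the (filtered) dataset, for imputation."""
    vals = matrix.to_numpy(dtype=float)
    pos = vals[np.isfinite(vals) & (vals > 0)]
    if pos.size == 0:
        raise ValueError("dataset has no nonzero values")
    return float(pos.min())


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, df, two-sided p).

    Zero-variance conventions: equal means -> (0, nan, 1); unequal means
    with zero standard error -> (+/-inf, nan, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return 0.0, float("nan"), 1.0
        log.debug("zero standard error with unequal means: p = 0 convention")
        return float(np.sign(diff)) * float("inf"), float("nan"), 0.0
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _welch_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Welch p-values (same conventions as :func:`welch_t`)."""
    na, nb = A.shape[1], B.shape[1]
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    diff = A.mean(axis=1) - B.mean(axis=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1)
                         + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    return p


def replicate_fold_change(
    ref: Sequence[float],
    test: Sequence[float],
    dataset_min: float,
) -> tuple[float, bool]:
    """Median of per-replicate test/ref ratios with zero imputation.

    Any zero among the paired values is first replaced by the smallest
    nonzero value of the whole dataset, then the per-replicate ratios and
    their median are recomputed; the imputed flag records whether a
    substitution occurred.  With two replicates the median equals the mean
    of the two ratios.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.size == 0 or ref.shape != test.shape:
        raise ValueError("ref and test must be nonempty and replicate-matched")
    imputed = bool((ref == 0).any() or (test == 0).any())
    ref2 = np.where(ref == 0, dataset_min, ref)
    test2 = np.where(test == 0, dataset_min, test)
    return float(np.median(test2 / ref2)), imputed


# ---------------------------------------------------------------------------
# Comparison constructors
# ---------------------------------------------------------------------------


def _strain_tp_channels(design: SampleDesign, strain: str, tp: int,
                        enrichment: str) -> tuple[str, ...]:
    chans = []
    for rep in design.replicates:
        c = design.channels(enrichment=enrichment, strain=strain,
                            replicate=rep, timepoint=tp)
        chans.extend(c)
    return tuple(chans)


def timecourse_comparisons(
    design: SampleDesign, strain: str, enrichment: str,
    reference_tp: int | None = None,
) -> list[Comparison]:
    """Each post-reference timepoint versus the reference (default t0)."""
    tps = design.timepoints
    ref_tp = tps[0] if reference_tp is None else reference_tp
    if ref_tp not in tps:
        raise ValueError(f"unknown reference timepoint {ref_tp}")
    ref = _strain_tp_channels(design, strain, ref_tp, enrichment)
    return [
        Comparison(
            label=f"{strain}:t{ref_tp}-vs-t{tp}",
            ref_channels=ref,
            test_channels=_strain_tp_channels(design, strain, tp, enrichment),
        )
        for tp in tps if tp != ref_tp
    ]


def strain_comparisons(
    design: SampleDesign, ref_strain: str, test_strain: str, enrichment: str,
) -> list[Comparison]:
    """Matched-timepoint contrasts between two strains."""
    return [
        Comparison(
            label=f"{ref_strain}-vs-{test_strain}@t{tp}",
            ref_channels=_strain_tp_channels(design, ref_strain, tp,
                                             enrichment),
            test_channels=_strain_tp_channels(design, test_strain, tp,
                                              enrichment),
        )
        for tp in design.timepoints
    ]


def arrest_comparison(
    design: SampleDesign, ref_strain: str, test_strain: str, enrichment: str,
) -> Comparison:
    """Single contrast over all replicates of two arrested strains."""
    return Comparison(
        label=f"{ref_strain}-vs-{test_strain}",
        ref_channels=tuple(design.channels(enrichment=enrichment,
                                           strain=ref_strain)),
        test_channels=tuple(design.channels(enrichment=enrichment,
                                            strain=test_strain)),
    )


def metaphase_comparisons(
    design: SampleDesign, strain: str, enrichment: str, anchor_tp: int,
) -> list[Comparison]:
    """The metaphase anchor versus each later timepoint."""
    if anchor_tp not in design.timepoints:
        raise ValueError(f"anchor timepoint {anchor_tp} not in design")
    ref = _strain_tp_channels(design, strain, anchor_tp, enrichment)
    return [
        Comparison(
            label=f"{strain}:t{anchor_tp}-vs-t{tp}",
            ref_channels=ref,
            test_channels=_strain_tp_channels(design, strain, tp, enrichment),
        )
        for tp in design.timepoints if tp > anchor_tp
    ]


# ---------------------------------------------------------------------------
# Differential calling
# ---------------------------------------------------------------------------


def call_differential(
    matrix: pd.DataFrame,
    comparisons: Sequence[Comparison],
    config: AnalysisConfig,
    dataset_min: float | None = None,
) -> pd.DataFrame:
    """Per feature x comparison fold-change/t calls.

    Returns a long table with columns feature, comparison, median_fc,
    p_value, q_value (BH, informational), category, zero_rescue, imputed,
    zeros_in_test_groups.
    """
    if dataset_min is None:
        dataset_min = dataset_minimum(matrix)
    thr = config.fc_threshold
    frames = []
    for comp in comparisons:
        for chans in (comp.ref_channels, comp.test_channels):
            missing = [c for c in chans if c not in matrix.columns]
            if missing:
                raise ValueError(
                    f"comparison {comp.label!r} references unknown channels "
                    f"{missing}"
                )
        A = matrix[list(comp.ref_channels)].to_numpy(dtype=float)
        B = matrix[list(comp.test_channels)].to_numpy(dtype=float)
        A = np.nan_to_num(A, nan=0.0)
        B = np.nan_to_num(B, nan=0.0)
        imputed = (A == 0).any(axis=1) | (B == 0).any(axis=1)
        A2 = np.where(A == 0, dataset_min, A)
        B2 = np.where(B == 0, dataset_min, B)
        if config.fc_mode == "paired" and A.shape[1] == B.shape[1]:
            fc = np.median(B2 / A2, axis=1)
        else:
            fc = np.median(B2, axis=1) / np.median(A2, axis=1)
        p = _welch_rows(A, B)
        rescue = (((A == 0).all(axis=1) & (B > 0).all(axis=1))
                  | ((B == 0).all(axis=1) & (A > 0).all(axis=1)))
        fc_ok = (fc > thr) | (fc < 1.0 / thr) | rescue
        sig = fc_ok & (p < config.alpha)
        category = np.where(
            sig, np.where(fc >= 1.0, "increased", "decreased"), "no_change"
        )
        q = multipletests(p, method="fdr_bh")[1]
        frames.append(pd.DataFrame({
            "feature": matrix.index,
            "comparison": comp.label,
            "median_fc": fc,
            "p_value": p,
            "q_value": q,
            "category": category,
            "zero_rescue": rescue & sig,
            "imputed": imputed,
        }))
    return pd.concat(frames, ignore_index=True)


def summarize_calls(results: pd.DataFrame) -> pd.DataFrame:
    """Per-feature verdict over a family of comparisons.

    dynamic = significant in at least one comparison; direction is
    ``increased``/``decreased`` when all significant comparisons agree,
    ``variable`` otherwise.
    """
    def _one(group: pd.DataFrame) -> pd.Series:
        sig = group[group["category"] != "no_change"]
        if sig.empty:
            direction = "no_change"
        else:
            dirs = set(sig["category"])
            direction = dirs.pop() if len(dirs) == 1 else "variable"
        return pd.Series({
            "dynamic": not sig.empty,
            "direction": direction,
            "n_significant": len(sig),
            "best_p": group["p_value"].min(),
            "any_zero_rescue": bool(group["zero_rescue"].any()),
        })

    out = results.groupby("feature", sort=False).apply(_one,
                                                       include_groups=False)
    return out


def classify_transition(
    matrix: pd.DataFrame,
    design: SampleDesign,
    strain: str,
    enrichment: str,
    anchor_tp: int,
    config: AnalysisConfig,
    dataset_min: float | None = None,
) -> pd.Series:
    """Per-feature behaviour after a metaphase anchor timepoint.

    ``increased``/``decreased`` when any later timepoint passes the
    fold-change + t-test rule versus the anchor (direction taken from the
    most significant such comparison), else ``no_change``.
    """
    comps = metaphase_comparisons(design, strain, enrichment, anchor_tp)
    res = call_differential(matrix, comps, config, dataset_min)
    sig = res[res["category"] != "no_change"]
    best = (
        sig.sort_values("p_value", kind="stable")
        .drop_duplicates("feature")
        .set_index("feature")["category"]
    )
    out = pd.Series("no_change", index=matrix.index, dtype=object)
    out.loc[best.index] = best
    out.name = f"after_t{anchor_tp}"
    return out


# ---------------------------------------------------------------------------
# Profile transforms
# ---------------------------------------------------------------------------


def average_replicates(rep1: Sequence[float],
                       rep2: Sequence[float]) -> np.ndarray:
    """Arithmetic mean of two aligned replicate profiles, zeros included,
    so a value missing in one replicate is halved rather than dropped."""
    rep1 = np.asarray(rep1, dtype=float)
    rep2 = np.asarray(rep2, dtype=float)
    if rep1.shape != rep2.shape:
        raise ValueError("replicate profiles differ in length")
    return (rep1 + rep2) / 2.0


def average_replicate_channels(
    matrix: pd.DataFrame, design: SampleDesign, strain: str, enrichment: str,
) -> pd.DataFrame:
    """Feature x timepoint matrix averaged over replicates (zeros included)."""
    cols = {}
    for tp in design.timepoints:
        chans = _strain_tp_channels(design, strain, tp, enrichment)
        cols[tp] = matrix[list(chans)].mean(axis=1)
    out = pd.DataFrame(cols)
    out.index.name = matrix.index.name
    return out


def scale_profiles(
    matrix: pd.DataFrame,
    mode: str = "mean",
    reference_col: int | str | None = None,
) -> tuple[pd.DataFrame, pd.Index]:
    """Scale each feature's profile to its own mean or a reference timepoint.

    Mean mode divides by the feature's mean over all supplied columns,
    zeros included (so the scaled mean is exactly 1 over that scope; for a
    combined two-strain matrix, pass all 20 columns to preserve
    inter-strain differences).  Reference mode divides by the value at
    ``reference_col``.  Features with a zero mean or zero reference are
    excluded and returned in the second element.
    """
    vals = matrix.to_numpy(dtype=float)
    if mode == "mean":
        denom = vals.mean(axis=1)
    elif mode == "reference_tp":
        if reference_col is None:
            raise ValueError("reference_tp mode requires reference_col")
        denom = matrix[reference_col].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ok = denom > 0
    excluded = matrix.index[~ok]
    if len(excluded):
        log.info("profile scaling: excluded %d features with zero %s",
                 len(excluded), "mean" if mode == "mean" else "reference")
    scaled = pd.DataFrame(
        vals[ok] / denom[ok, None], index=matrix.index[ok],
        columns=matrix.columns,
    )
    scaled.index.name = matrix.index.name
    return scaled, excluded
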