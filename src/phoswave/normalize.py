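"""Channel normalization, phospho-to-protein ratios, and batch correction.

All matrices are pandas DataFrames of nonnegative reporter intensities
(features x channels) in which 0 means "not detected".  Zeros are masked
out of every median, mean and fit and restored afterwards, so missingness
never leaks into the statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationReport:
    """Per-channel scaling diagnostics from :func:`median_scale_channels`."""

    factors: pd.Series          # grand_median / channel_median
    channel_medians: pd.Series  # medians of nonmissing values
    grand_median: float
    n_missing: pd.Series        # zero counts per channel

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": self.factors.index,
            "channel_median": self.channel_medians.to_numpy(),
            "scaling_factor": self.factors.to_numpy(),
            "grand_median": self.grand_median,
            "n_missing": self.n_missing.to_numpy(),
        })


def _masked(matrix: pd.DataFrame) -> pd.DataFrame:
    if (matrix.to_numpy() < 0).any():
        raise ValueError("intensity matrix contains negative values")
    return matrix.where(matrix > 0)


def median_scale_channels(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Scale each channel so its nonmissing median equals the grand median.

    The grand median is taken over the pooled nonmissing values of all
    channels; each channel is multiplied by grand_median / channel_median.
    Zeros are excluded from all medians and restored as zeros afterwards.
    The operation is idempotent.
    """
    masked = _masked(matrix)
    n_missing = masked.isna().sum()
    if masked.notna().sum().eq(0).any():
        empty = masked.columns[masked.notna().sum() == 0].tolist()
        raise ValueError(f"channels with no nonmissing values: {empty}")
    channel_medians = masked.median()
    grand_median = float(np.nanmedian(masked.to_numpy()))
    factors = grand_median / channel_medians
    scaled = (masked * factors).fillna(0.0)
    report = NormalizationReport(
        factors=factors,
        channel_medians=channel_medians,
        grand_median=grand_median,
        n_missing=n_missing,
    )
    return scaled, report


def phospho_to_protein(
    pe: pd.DataFrame,
    n: pd.DataFrame,
    site_to_protein: Mapping[str, str],
    channel_map: Mapping[str, str],
) -> pd.DataFrame:
    """Normalize phospho-site abundance to the parent protein's abundance.

    ``channel_map`` pairs each PE channel with the N channel of the same
    (strain, replicate, timepoint).  The value is 1000 x PE / N; a zero PE
    stays 0 (missing remains missing) while a zero protein denominator
    yields NaN, flagging the timepoint as not normalizable so the site can
    be excluded downstream.
    """
    missing_proteins = sorted(
        {p for p in (site_to_protein[s] for s in pe.index)
         if p not in n.index}
    )
    if missing_proteins:
        victims = [s for s in pe.index
                   if site_to_protein[s] in set(missing_proteins)]
        raise KeyError(
            f"proteins absent from the N table for sites {victims[:5]} "
            f"(and {max(0, len(victims) - 5)} more)"
        )
    protein_rows = n.loc[[site_to_protein[s] for s in pe.index],
                         [channel_map[c] for c in pe.columns]]
    denom = protein_rows.to_numpy(dtype=float)
    numer = pe.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = 1000.0 * numer / denom
    ratio[numer == 0] = 0.0          # missing site stays missing
    ratio[denom == 0] = np.nan       # not normalizable at this channel
    out = pd.DataFrame(ratio, index=pe.index, columns=pe.columns)
    out.index.name = pe.index.name
    return out


def correct_batch(
    matrix: pd.DataFrame,
    batches: Sequence[int] | pd.Series,
) -> pd.DataFrame:
    """Remove per-feature batch offsets on the log2 scale.

    Each feature's nonmissing values are log2-transformed and the batch
    means are equalized at the feature's grand mean (a least-squares
    removal of batch-indicator coefficients under sum-to-zero coding for
    balanced designs); the result is back-transformed with antilog 2 and
    zeros restored.  Features observed in only one batch are passed
    through unchanged and logged.
    """
    batches = np.asarray(list(batches))
    if batches.shape[0] != matrix.shape[1]:
        raise ValueError("one batch label per channel is required")
    levels = pd.unique(batches)
    if len(levels) < 2:
        raise ValueError("batch correction needs at least two batches")
    masked = _masked(matrix)
    logm = np.log2(masked.to_numpy(dtype=float))
    observed = ~np.isnan(logm)
    out = logm.copy()
    def _row_mean(block: np.ndarray) -> np.ndarray:
        cnt = (~np.isnan(block)).sum(axis=1)
        total = np.nansum(block, axis=1)
        return np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)

    single_batch = 0
    grand = _row_mean(logm)
    for b in levels:
        cols = batches == b
        block = logm[:, cols]
        bmean = _row_mean(block)
        out[:, cols] = block - bmean[:, None] + grand[:, None]
    # features observed in fewer than two batches keep their values
    n_batches_obs = np.zeros(matrix.shape[0], dtype=int)
    for b in levels:
        n_batches_obs += observed[:, batches == b].any(axis=1)
    lonely = n_batches_obs < 2
    if lonely.any():
        single_batch = int(lonely.sum())
        out[lonely] = logm[lonely]
        log.info("batch correction: %d features observed in a single batch "
                 "passed through unchanged", single_batch)
    result = pd.DataFrame(
        np.where(observed, np.exp2(out), 0.0),
        index=matrix.index, columns=matrix.columns,
    )
    result.index.name = matrix.index.name
    return result
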