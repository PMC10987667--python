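"""Inclusion rules defining the final protein and phospho-site datasets.

Rule order (also the audit's "first failing rule" order): search-engine
flags, localization probability, detection pattern, protein
normalizability.  "Sequential" timepoints means adjacent entries in the
ordered timepoint list, so the 0 -> 45 min step counts as sequential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mq_io import SampleDesign

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for dataset inclusion.

    min_localization is a strict lower bound (a site at exactly the
    threshold fails).  The protein rule asks for detection (>0) in at
    least one timepoint of every replicate of every required strain; the
    phospho rule for two consecutive detected timepoints instead, plus
    the localization bound and, when ``require_normalizable_all_timepoints``
    is set, a nonzero parent-protein value at every timepoint.
    """

    min_localization: float = 0.75
    require_normalizable_all_timepoints: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_localization <= 1.0:
            raise ValueError("min_localization must be in [0, 1]")


@dataclass
class FilterAudit:
    """Per-feature pass/fail bookkeeping; every input appears exactly once."""

    table: pd.DataFrame  # columns: passed (bool), first_fail (str)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def passed(self) -> pd.Index:
        return self.table.index[self.table["passed"]]

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index()


def drop_flagged_features(
    meta: pd.DataFrame,
) -> tuple[pd.Index, dict[str, int]]:
    """Indices of features free of contaminant/reverse flags, plus tallies.

    A feature carrying both flags is removed once but counted in both
    per-flag tallies.
    """
    contam = meta.get("is_contaminant",
                      pd.Series(False, index=meta.index)).astype(bool)
    reverse = meta.get("is_reverse",
                       pd.Series(False, index=meta.index)).astype(bool)
    keep = meta.index[~(contam | reverse)]
    counts = {
        "contaminant": int(contam.sum()),
        "reverse": int(reverse.sum()),
        "removed": int((contam | reverse).sum()),
    }
    return keep, counts


def _detected_any(values: np.ndarray) -> np.ndarray:
    return (values > 0).any(axis=1)


def _detected_consecutive(values: np.ndarray) -> np.ndarray:
    det = values > 0
    if det.shape[1] < 2:
        return np.zeros(det.shape[0], dtype=bool)
    return (det[:, :-1] & det[:, 1:]).any(axis=1)


def detection_filter(
    matrix: pd.DataFrame,
    design: SampleDesign,
    config: FilterConfig,
    kind: str,
    strains: Sequence[str] | None = None,
    localization: pd.Series | None = None,
    normalizable: pd.Series | None = None,
    enrichment: str | None = None,
) -> tuple[pd.Index, FilterAudit]:
    """Apply the detection rules to an intensity matrix.

    ``kind`` is ``"protein"`` (detected in >=1 timepoint of every replicate
    of every required strain) or ``"phospho"`` (detected in >=2 consecutive
    timepoints instead, with localization and normalizability rules).
    ``normalizable`` is a per-site boolean (parent protein nonzero at all
    timepoints), supplied by the pipeline when the config requires it.
    """
    if kind not in ("protein", "phospho"):
        raise ValueError(f"unknown kind {kind!r}")
    if enrichment is None:
        enrichment = "N" if kind == "protein" else "PE"
    strains = tuple(strains) if strains is not None else design.strains
    design_channels = design.channels(enrichment=enrichment)
    missing = [c for c in design_channels if c not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks designed channels: {missing}")

    n = len(matrix)
    fail = pd.Series("", index=matrix.index, dtype=object)

    if kind == "phospho" and localization is not None:
        loc = localization.reindex(matrix.index)
        bad = ~(loc > config.min_localization)
        fail[bad & fail.eq("")] = "localization"

    detect_ok = np.ones(n, dtype=bool)
    for strain in strains:
        for rep in design.replicates:
            t = design.table
            sub = t[(t["enrichment"] == enrichment)
                    & (t["strain"] == strain)
                    & (t["replicate"] == rep)]
            chans = sub.sort_values("timepoint_min")["channel_label"].tolist()
            if not chans:
                continue
            vals = matrix[chans].to_numpy(dtype=float)
            vals = np.nan_to_num(vals, nan=0.0)
            if kind == "protein":
                detect_ok &= _detected_any(vals)
            else:
                detect_ok &= _detected_consecutive(vals)
    fail[(~detect_ok) & fail.eq("")] = "detection"

    if (kind == "phospho" and config.require_normalizable_all_timepoints
            and normalizable is not None):
        ok = normalizable.reindex(matrix.index).fillna(False).astype(bool)
        fail[(~ok) & fail.eq("")] = "not_normalizable"

    passed = fail.eq("")
    audit = FilterAudit(
        table=pd.DataFrame({"passed": passed, "first_fail": fail}),
        counts={
            "input": n,
            "passed": int(passed.sum()),
            **{
                rule: int(fail.eq(rule).sum())
                for rule in ("localization", "detection", "not_normalizable")
            },
        },
    )
    return matrix.index[passed], audit


def arrest_detection_filter(
    matrix: pd.DataFrame,
    design: SampleDesign,
    min_reps: int,
    strains: Sequence[str],
    enrichment: str = "N",
) -> pd.Index:
    """Keep features detected in >= min_reps replicates of *every* strain.

    For replicate designs without a timecourse (e.g. a metaphase-I arrest
    with 3-4 replicates per strain, or analogue-sensitive inhibition with
    a 1-of-2 or 2-of-2 rule).
    """
    keep = np.ones(len(matrix), dtype=bool)
    for strain in strains:
        chans = design.channels(enrichment=enrichment, strain=strain)
        if min_reps > len(chans):
            raise ValueError(
                f"min_reps={min_reps} exceeds the {len(chans)} replicates "
                f"of strain {strain!r}"
            )
        vals = np.nan_to_num(matrix[chans].to_numpy(dtype=float), nan=0.0)
        keep &= (vals > 0).sum(axis=1) >= min_reps
    return matrix.index[keep]
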