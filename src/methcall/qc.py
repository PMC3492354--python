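"""Probe and sample quality control.

Reproduces the pre-analysis exclusions applied to Infinium 27K data:
gender-specific (chrX/chrY) probes, low-quality probes (detection
failure in too many samples, or too many missing values), and samples
with globally poor detection p-values.  The exclusion *mechanism* is the
reproducible content; the cut-offs follow common Infinium practice and
are all configuration-exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix

__all__ = ["QCConfig", "filter_probes", "filter_samples"]


@dataclass
class QCConfig:
    """Cut-offs for probe/sample exclusion.

    probe_detection_alpha
        detection p above this counts as a failed measurement (default 0.01).
    probe_fail_fraction
        a probe failing in more than this fraction of samples is dropped
        (default 0.05).
    sample_fail_fraction
        a sample failing more than this fraction of probes is dropped
        (default 0.01).
    drop_gonosomal
        remove chrX/chrY probes (default True).
    max_missing_fraction
        per-probe missing-value cut-off (default 0.20).
    """

    probe_detection_alpha: float = 0.01
    probe_fail_fraction: float = 0.05
    sample_fail_fraction: float = 0.01
    drop_gonosomal: bool = True
    max_missing_fraction: float = 0.20
    drop_unannotated: bool = False

    def __post_init__(self) -> None:
        for name in ("probe_detection_alpha", "probe_fail_fraction",
                     "sample_fail_fraction", "max_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def filter_probes(
    beta: BetaMatrix,
    ann: pd.DataFrame | None,
    cfg: QCConfig | None = None,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Drop gonosomal, low-quality and mostly-missing probes.

    Returns the filtered matrix and an exclusion report with one row per
    removed probe (columns: reason, statistic).  Probes absent from the
    annotation are reported as ``unannotated`` and kept unless
    ``cfg.drop_unannotated``.  Without a detection-p matrix only the
    gonosomal/missing rules apply.
    """
    cfg = cfg or QCConfig()
    reasons: list[tuple[str, str, float]] = []
    drop: set[str] = set()

    probe_index = beta.beta.index
    if ann is not None:
        covered = probe_index.isin(ann.index)
        for pid in probe_index[~covered]:
            reasons.append((pid, "unannotated", np.nan))
            if cfg.drop_unannotated:
                drop.add(pid)
        if cfg.drop_gonosomal:
            gono = ann.reindex(probe_index)["is_gonosomal"]
            gono = gono.where(gono.notna(), False).astype(bool)
            for pid in probe_index[gono.to_numpy()]:
                reasons.append((pid, "gonosomal", np.nan))
                drop.add(pid)

    if beta.detection_p is not None:
        fail_frac = (beta.detection_p.to_numpy() > cfg.probe_detection_alpha).mean(axis=1)
        for pid, frac in zip(probe_index, fail_frac):
            if frac > cfg.probe_fail_fraction:
                reasons.append((pid, "low_quality", float(frac)))
                drop.add(pid)

    miss_frac = beta.beta.isna().to_numpy().mean(axis=1)
    for pid, frac in zip(probe_index, miss_frac):
        if frac > cfg.max_missing_fraction:
            reasons.append((pid, "missing", float(frac)))
            drop.add(pid)

    keep = [p for p in probe_index if p not in drop]
    if not keep:
        warnings.warn("probe QC removed every probe", stacklevel=2)
    report = pd.DataFrame(reasons, columns=["probe_id", "reason", "statistic"])
    out = beta.subset(probes=keep) if keep else BetaMatrix(
        beta.beta.iloc[0:0], None if beta.detection_p is None else beta.detection_p.iloc[0:0]
    )
    return out, report


def filter_samples(
    beta: BetaMatrix,
    cfg: QCConfig | None = None,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Drop samples whose detection p-values fail too many probes.

    No-op (with a warning) when no detection-p matrix is present; a
    hard error if every sample would be removed.
    """
    cfg = cfg or QCConfig()
    if beta.detection_p is None:
        warnings.warn("no detection p-values: sample QC skipped", stacklevel=2)
        return beta, pd.DataFrame(columns=["sample_id", "reason", "statistic"])
    fail_frac = (beta.detection_p.to_numpy() > cfg.probe_detection_alpha).mean(axis=0)
    rows = []
    keep = []
    for sid, frac in zip(beta.beta.columns, fail_frac):
        if frac > cfg.sample_fail_fraction:
            rows.append((sid, "poor_detection", float(frac)))
        else:
            keep.append(sid)
    if not keep:
        raise ValueError("sample QC would remove every sample")
    report = pd.DataFrame(rows, columns=["sample_id", "reason", "statistic"])
    return beta.subset(samples=keep), report
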