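"""Temporal activation features of synergy coefficient curves.

A synergy is "active" where its coefficient curve is at or above a fraction
(default 20 %) of its own maximum.  On the normalized 0-100 cycle timeline
the features are: activation duration T (count of above-threshold samples),
peak moment T_max (argmax position), onset T_start and offset T_stop (first
and last above-threshold positions).  The threshold convention is
configurable and recorded in every output row.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

import numpy as np
import pandas as pd

__all__ = ["TemporalFeatures", "extract_features", "summarize_features",
           "FEATURE_COLUMNS"]

FEATURE_COLUMNS = ("T", "T_max", "T_start", "T_stop")


@dataclass(frozen=True)
class TemporalFeatures:
    duration_T: float          # number of above-threshold samples (<= 100)
    peak_T_max: float          # normalized time of the maximum
    onset_T_start: float       # first above-threshold time (nan if inactive)
    offset_T_stop: float       # last above-threshold time (nan if inactive)
    threshold_used: float
    active: bool = True

    def as_dict(self) -> dict[str, float]:
        return {"T": self.duration_T, "T_max": self.peak_T_max,
                "T_start": self.onset_T_start, "T_stop": self.offset_T_stop,
                "threshold": self.threshold_used}


def extract_features(curve: np.ndarray,
                     threshold: float = 0.20) -> TemporalFeatures:
    """Threshold-based activation features of one coefficient curve.

    Plateau ties resolve to the first sample for onset and peak and the last
    sample for offset.  An all-zero curve is flagged inactive with duration 0
    and undefined onset/offset/peak (NaN).
    """
    c = np.asarray(curve, dtype=float)
    if c.ndim != 1:
        raise ValueError("curve must be 1-D")
    if (c < 0).any():
        raise ValueError("curve must be non-negative")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    t = np.linspace(0.0, 100.0, c.size)
    peak = c.max()
    if peak == 0:
        return TemporalFeatures(duration_T=0.0, peak_T_max=nan,
                                onset_T_start=nan, offset_T_stop=nan,
                                threshold_used=threshold, active=False)
    above = np.nonzero(c >= threshold * peak)[0]
    return TemporalFeatures(
        duration_T=float(above.size),
        peak_T_max=float(t[int(np.argmax(c))]),
        onset_T_start=float(t[above[0]]),
        offset_T_stop=float(t[above[-1]]),
        threshold_used=threshold)


def summarize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Per-protocol mean +/- sample SD of each feature, by synergy.

    ``features`` is long-format with columns ``synergy``, ``protocol``,
    ``subject`` and the feature columns ``T``, ``T_max``, ``T_start``,
    ``T_stop``.  Requires at least two subjects per (synergy, protocol)
    group; the SD uses the n-1 denominator.
    """
    required = {"synergy", "protocol", "subject", *FEATURE_COLUMNS}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if features.empty:
        raise ValueError("empty feature table")
    counts = features.groupby(["synergy", "protocol"])["subject"].nunique()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 subjects per group; too few in {bad}")
    agg = features.groupby(["synergy", "protocol"])[
        list(FEATURE_COLUMNS)].agg(["mean", lambda s: s.std(ddof=1)])
    agg.columns = [f"{feat}_{'sd' if name == '<lambda_0>' else name}"
                   for feat, name in agg.columns]
    return agg.reset_index()
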