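"""Trait transformation and descriptive statistics.

The keel-bone-fracture score is a bounded, strongly right-skewed tVAS
severity score on [0, 10].  Normality of residuals is improved by the
shifted natural log

    log_kbf = ln(score + 0.05)

where 0.05 is the smallest observed nonzero score, so zeros remain
transformable.  The transform is strictly increasing and exactly
inverted by exp(x) - 0.05.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

__all__ = ["LOG_OFFSET", "TraitSummary", "log_transform", "describe"]

#: Shift added before taking logs: the smallest observed nonzero score.
LOG_OFFSET = 0.05


def log_transform(score, offset: float = LOG_OFFSET):
    """Natural log of (score + offset), vectorized.

    Accepts a scalar, array, Series or a sample table (any DataFrame with
    a ``kbf_score`` column); for a table, returns a copy with ``log_kbf``
    filled in.  Negative scores are rejected.
    """
    if isinstance(score, pd.DataFrame):
        out = score.copy()
        out["log_kbf"] = log_transform(out["kbf_score"].to_numpy(), offset=offset)
        return out
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 0):
        raise ValueError("scores must be non-negative")
    result = np.log(arr + offset)
    if np.isscalar(score) or arr.ndim == 0:
        return float(result)
    if isinstance(score, pd.Series):
        return pd.Series(result, index=score.index, name="log_kbf")
    return result


@dataclasses.dataclass
class TraitSummary:
    """Min/max/mean/SD of a trait (sample SD, n-1 denominator)."""

    minimum: float
    maximum: float
    mean: float
    sd: float
    n: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    def to_tsv(self) -> str:
        d = dataclasses.asdict(self)
        return "\t".join(d.keys()) + "\n" + "\t".join(str(v) for v in d.values()) + "\n"


def describe(values) -> TraitSummary:
    """Descriptive statistics over non-missing values; needs >= 2 of them."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("need at least 2 non-missing values")
    return TraitSummary(
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n=int(arr.size),
    )
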