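"""Survey-weighted consumption summaries, principally per-category
90th-percentile intake caps.

The quantile estimator is the left-continuous inverse of the weighted
empirical distribution: the smallest observed value whose cumulative
normalised weight reaches the requested fraction.  No interpolation — a cap
must be an attainable observed amount.
"""

from __future__ import annotations

from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import IntakeSample
from .errors import ValidationError

__all__ = ["weighted_quantile", "intake_p90", "compute_caps", "load_caps", "write_caps"]

#: Marker returned when no consumer exists for a category (no cap applies).
NO_CAP = None


def weighted_quantile(
    values: Sequence[float], weights: Sequence[float], q: float
) -> float:
    """Smallest value whose cumulative normalised weight is >= ``q``."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValidationError("weighted_quantile: empty input")
    if v.shape != w.shape:
        raise ValidationError("values and weights must have equal length")
    if np.any(w <= 0):
        raise ValidationError("weights must be > 0")
    if not 0 < q <= 1:
        raise ValidationError(f"q must satisfy 0 < q <= 1, got {q!r}")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / np.sum(w)
    # absolute slop guards against cumulative rounding at q == 1 or ties
    idx = int(np.searchsorted(cum, q - 1e-12, side="left"))
    return float(v[min(idx, v.size - 1)])


def intake_p90(
    samples: Sequence[IntakeSample],
    code: int,
    *,
    consumers_only: bool = True,
    q: float = 0.9,
) -> float | None:
    """Survey-weighted intake percentile for one category, in grams.

    With ``consumers_only`` (the default) the percentile is taken over persons
    who consumed the category; if nobody did, :data:`NO_CAP` is returned.
    Without it, non-consumers enter as zeros — which caps rarely-consumed
    categories at 0 g.
    """
    if not samples:
        raise ValidationError("intake_p90: no samples")
    if not any(code in s.grams_by_category for s in samples):
        raise ValidationError(f"code {code} does not appear in any intake sample")
    grams = np.array([s.grams_by_category.get(code, 0.0) for s in samples])
    weights = np.array([s.sample_weight for s in samples])
    if consumers_only:
        mask = grams > 0
        if not mask.any():
            return NO_CAP
        grams, weights = grams[mask], weights[mask]
    return weighted_quantile(grams, weights, q)


def compute_caps(
    samples: Sequence[IntakeSample],
    codes: Sequence[int],
    *,
    consumers_only: bool = True,
    q: float = 0.9,
) -> pd.DataFrame:
    """Caps table ``code,p90_g,n_consumers`` for the given categories.

    Codes absent from every sample, or with no consumers under
    ``consumers_only``, get ``p90_g = NaN`` (no cap).
    """
    rows = []
    for code in codes:
        n_consumers = sum(
            1 for s in samples if s.grams_by_category.get(code, 0.0) > 0
        )
        try:
            cap = intake_p90(samples, code, consumers_only=consumers_only, q=q)
        except ValidationError:
            cap = NO_CAP
        rows.append(
            {
                "code": code,
                "p90_g": np.nan if cap is NO_CAP else cap,
                "n_consumers": n_consumers,
            }
        )
    return pd.DataFrame(rows, columns=["code", "p90_g", "n_consumers"])


def write_caps(caps: pd.DataFrame, path: str | Path) -> None:
    caps.to_csv(path, index=False)


def load_caps(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("code", "p90_g") if c not in df.columns]
    if missing:
        raise ValidationError(f"caps table missing column(s): {missing}")
    return df
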