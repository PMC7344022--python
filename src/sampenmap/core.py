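"""Sample entropy for single series and whole 4D volumes.

Sample entropy (SampEn) quantifies the irregularity of a time series
x = [x_1 .. x_N].  Templates of m consecutive points are compared under
the Chebyshev (component-wise maximum) distance; with B the number of
template pairs matching within tolerance r and A the number still
matching when each window is extended by one point,

    SampEn(m, r, N, x) = -ln(A / B).

Lower values mean a more regular, predictable signal.  Both window
lengths are counted over the same start range i = 1 .. N - m, so A <= B
holds structurally and SampEn >= 0 whenever it is defined.  The common
1 / ((N-m)(N-m-1)) normalisations of A and B cancel in the ratio and are
never materialised.

The tolerance follows the r = r_factor * SD convention with the SD of the
series itself (sample SD, n-1 denominator); a fixed absolute tolerance is
available through ``sd_mode="fixed"``.  Degenerate inputs (too short,
zero variance, no matches) produce an UNDEFINED sentinel with a reason
code rather than an arbitrary substitute value, because silent ceiling
values would bias downstream ROI means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.signal

from ._kernels import count_matches_1d, count_matches_batch
from .errors import BadLengthError, GridMismatchError, InvalidSeriesError, ShortSeriesError
from .images import (
    Bold4D,
    EntropyMap3D,
    REASON_OUT_OF_MASK,
    REASON_SHORT_SERIES,
    REASON_ZERO_MATCHES,
    REASON_ZERO_VARIANCE,
)

REASON_SHORT = "short-series"
REASON_ZERO_VAR = "zero-variance"
REASON_NO_MATCH = "zero-matches"


@dataclass(frozen=True)
class SampEnParams:
    """Parameters of the sample-entropy statistic.

    m : embedding dimension (template length), default 3.
    r_factor : tolerance as a multiple of the series SD, default 0.6.
    sd_mode : "per-series" scales r by each series' own sample SD;
        "fixed" uses ``r_abs`` directly in signal units.
    r_abs : absolute tolerance, only read when sd_mode == "fixed".
    detrend : remove a linear trend before matching (off by default; the
        statistic is computed on the series as given).
    distance_norm : only "chebyshev" is supported.
    """

    m: int = 3
    r_factor: float = 0.6
    sd_mode: str = "per-series"
    r_abs: Optional[float] = None
    detrend: bool = False
    distance_norm: str = "chebyshev"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be > 0")
        if self.sd_mode not in ("per-series", "fixed"):
            raise ValueError("sd_mode must be 'per-series' or 'fixed'")
        if self.sd_mode == "fixed" and (self.r_abs is None or self.r_abs < 0):
            raise ValueError("sd_mode='fixed' needs r_abs >= 0")
        if self.distance_norm != "chebyshev":
            raise ValueError("only the Chebyshev distance is supported")


@dataclass(frozen=True)
class MatchCounts:
    """Ordered-pair template match totals.

    b_total counts m-window matches, a_total the (m+1)-window matches over
    the same start range; n_templates = N - m.
    """

    b_total: int
    a_total: int
    n_templates: int


@dataclass(frozen=True)
class EntropyValue:
    """SampEn result: a nonnegative value, or NaN with a reason code."""

    value: float
    reason: Optional[str] = None
    counts: Optional[MatchCounts] = None

    @property
    def defined(self) -> bool:
        return self.reason is None


def count_template_matches(x, m: int, r_abs: float) -> MatchCounts:
    """Exhaustive ordered-pair match counts for series ``x``.

    Raises ShortSeriesError when N < m + 2 (the extended window at the
    last template start needs index N, and at least two templates are
    required for any i != j pair).
    """
    x = _as_series(x)
    if r_abs < 0:
        raise ValueError("r_abs must be >= 0")
    n = x.shape[0]
    if n < m + 2:
        raise ShortSeriesError(f"need N >= m + 2 = {m + 2}, got N = {n}")
    b, a = count_matches_1d(x, m, float(r_abs))
    return MatchCounts(b_total=int(b), a_total=int(a), n_templates=n - m)


def sample_entropy(x, params: SampEnParams = SampEnParams()) -> EntropyValue:
    """Sample entropy of a 1D series under ``params``.

    Returns an :class:`EntropyValue`; undefined outcomes carry one of the
    reason codes "short-series", "zero-variance" or "zero-matches".
    """
    x = _as_series(x)
    if params.detrend and x.shape[0] > 1:
        x = scipy.signal.detrend(x)
    n = x.shape[0]
    if n < params.m + 2:
        return EntropyValue(math.nan, REASON_SHORT)
    if params.sd_mode == "per-series":
        # ptp, not sd: rounding can leave a constant series with sd ~ 1e-16
        if np.ptp(x) == 0.0:
            return EntropyValue(math.nan, REASON_ZERO_VAR)
        r_abs = params.r_factor * float(np.std(x, ddof=1))
    else:
        r_abs = float(params.r_abs)
    counts = count_template_matches(x, params.m, r_abs)
    if counts.b_total == 0 or counts.a_total == 0:
        return EntropyValue(math.nan, REASON_NO_MATCH, counts)
    return EntropyValue(-math.log(counts.a_total / counts.b_total), None, counts)


def sample_entropy_map(vol: Bold4D, mask, params: SampEnParams = SampEnParams()) -> EntropyMap3D:
    """Voxelwise sample entropy over a 4D volume.

    Every in-mask voxel's time series is scored; out-of-mask voxels and
    undefined results are stored as NaN with a reason lattice alongside.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.grid_shape:
        raise GridMismatchError(f"mask grid {mask.shape} != volume grid {vol.grid_shape}")
    values = np.full(vol.grid_shape, np.nan)
    reasons = np.full(vol.grid_shape, REASON_OUT_OF_MASK, dtype=np.uint8)
    series = vol.data[mask]  # (V, T)
    if series.size and not np.all(np.isfinite(series)):
        raise InvalidSeriesError("volume contains non-finite values inside the mask")
    v_values, v_reasons = _entropy_batch(series, params)
    values[mask] = v_values
    reasons[mask] = v_reasons
    return EntropyMap3D(values=values, reasons=reasons, affine=vol.affine)


def _entropy_batch(series: np.ndarray, params: SampEnParams):
    """SampEn for a (V, T) stack; returns value and reason-code vectors."""
    n_series, n = series.shape if series.ndim == 2 else (0, 0)
    out_vals = np.full(n_series, np.nan)
    out_reasons = np.zeros(n_series, dtype=np.uint8)
    if n_series == 0:
        return out_vals, out_reasons
    if params.detrend:
        series = scipy.signal.detrend(series, axis=1)
    if n < params.m + 2:
        out_reasons[:] = REASON_SHORT_SERIES
        return out_vals, out_reasons
    if params.sd_mode == "per-series":
        sd = np.std(series, axis=1, ddof=1)
        r_abs = params.r_factor * sd
        degenerate = np.ptp(series, axis=1) == 0.0
    else:
        r_abs = np.full(n_series, float(params.r_abs))
        degenerate = np.zeros(n_series, dtype=bool)
    live = ~degenerate
    counts = np.zeros((int(live.sum()), 2), dtype=np.int64)
    count_matches_batch(
        np.ascontiguousarray(series[live], dtype=np.float64),
        params.m,
        np.ascontiguousarray(r_abs[live], dtype=np.float64),
        counts,
    )
    b, a = counts[:, 0].astype(float), counts[:, 1].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = -np.log(a / b)
    no_match = (counts[:, 0] == 0) | (counts[:, 1] == 0)
    se[no_match] = np.nan
    out_vals[live] = se
    live_reasons = np.zeros(no_match.shape, dtype=np.uint8)
    live_reasons[no_match] = REASON_ZERO_MATCHES
    out_reasons[live] = live_reasons
    out_reasons[degenerate] = REASON_ZERO_VARIANCE
    return out_vals, out_reasons


def truncate_series(vol: Bold4D, n_target: int) -> Bold4D:
    """Keep the first ``n_target`` time points; grid metadata unchanged."""
    if not 1 <= n_target <= vol.n_timepoints:
        raise BadLengthError(
            f"n_target = {n_target} outside [1, {vol.n_timepoints}]"
        )
    return Bold4D(data=vol.data[..., :n_target].copy(), affine=vol.affine, tr=vol.tr)


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise InvalidSeriesError(f"expected a 1D series, got {x.ndim}D")
    if not np.all(np.isfinite(x)):
        raise InvalidSeriesError("series contains non-finite values")
    return x
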