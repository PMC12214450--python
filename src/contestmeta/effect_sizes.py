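"""Conversion of reported test statistics to signed Fisher-Z effect sizes.

Every effect size in the pipeline is a correlation *r* between contest
duration and an RHP-linked trait, carried on the Fisher-Z scale
``z = atanh(r)`` with known sampling variance ``v = 1/(n - 3)``, where *n*
is the number of contests behind the regression.  Inverse-variance weights
``w = 1/v`` then enter the multilevel model.

Supported source statistics: a correlation coefficient directly, a
*t* statistic with its degrees of freedom, a single-numerator-df *F*
statistic with its error degrees of freedom (sign supplied separately,
since F is unsigned), or raw paired data from which a Pearson r is
computed.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "R_ABS_MAX",
    "r_from_t",
    "r_from_f",
    "r_from_raw",
    "fisher_z",
    "z_variance",
    "derive_effect",
]

#: Correlations at or beyond this magnitude are rejected: their Fisher Z is
#: effectively infinite and would silently dominate any weighted fit.
R_ABS_MAX = 0.9999


class EffectSizeError(ValueError):
    """Raised when a reported statistic cannot be converted to an effect size."""


def r_from_t(t: float, df: int) -> float:
    """Correlation implied by a t statistic: ``r = t / sqrt(t^2 + df)``.

    The sign of *r* follows the sign of *t*.
    """
    if df < 1:
        raise EffectSizeError(f"t-to-r conversion needs df >= 1, got df={df}")
    return float(t / math.sqrt(t * t + df))


def r_from_f(f: float, df_error: int, direction: str) -> float:
    """Correlation magnitude implied by a 1-numerator-df F statistic.

    ``|r| = sqrt(F / (F + df_error))``; because F carries no sign, the
    direction of the underlying relationship must be stated as ``'+'`` or
    ``'-'``.  Equivalent to :func:`r_from_t` at ``t = sign * sqrt(F)``.
    """
    if f < 0:
        raise EffectSizeError(f"F statistic must be nonnegative, got {f}")
    if df_error < 1:
        raise EffectSizeError(f"F-to-r conversion needs df_error >= 1, got {df_error}")
    if direction not in {"+", "-"}:
        raise EffectSizeError(f"direction must be '+' or '-', got {direction!r}")
    r = math.sqrt(f / (f + df_error))
    return -r if direction == "-" else r


def r_from_raw(x, y) -> tuple[float, int]:
    """Pearson r from raw paired observations, pairwise-complete.

    Any pair with a missing value is dropped and the effective n is reduced
    accordingly, so that ``v = 1/(n - 3)`` matches the data actually used.
    Returns ``(r, n_used)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EffectSizeError("raw data must be two equal-length 1-d columns")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 4:
        raise EffectSizeError(f"raw-data correlation needs n >= 4 complete pairs, got {n}")
    sx = x.std(ddof=0)
    sy = y.std(ddof=0)
    if sx == 0 or sy == 0:
        raise EffectSizeError("raw-data correlation undefined: a column is constant")
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r, n


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform ``z = atanh(r)``.

    Unlike *r*, *z* is unbounded and approximately normal, which is what
    makes it the meta-analytic effect size of choice for correlations.
    Correlations with ``|r| >= 0.9999`` are rejected rather than clamped.
    """
    if abs(r) >= R_ABS_MAX:
        raise EffectSizeError(
            f"|r|={abs(r):.6g} is at or beyond {R_ABS_MAX}; Fisher Z would be "
            "unbounded (no clamping is applied)"
        )
    return float(math.atanh(r))


def z_variance(n: int) -> float:
    """Sampling variance of Fisher's Z: ``1/(n - 3)`` for sample size n >= 4."""
    if n <= 3:
        raise EffectSizeError(f"sampling variance 1/(n-3) undefined for n={n}")
    return 1.0 / (n - 3)


def derive_effect(record):
    """Populate ``r``, ``z`` and ``v`` on an :class:`~contestmeta.dataio.EffectRecord`.

    Dispatches on ``stat_kind`` (r, t, F or raw), chains the conversions
    above, and returns a new record; re-deriving an already-derived record
    is idempotent.
    """
    from . import dataio  # deferred: dataio imports this module

    kind = record.stat_kind
    if kind == "r":
        if record.stat_value is None:
            raise EffectSizeError(f"{record.effect_id}: stat_kind='r' but no value given")
        r = float(record.stat_value)
        n = record.n
    elif kind == "t":
        if record.stat_value is None or record.df is None:
            raise EffectSizeError(f"{record.effect_id}: t conversion needs stat_value and df")
        r = r_from_t(float(record.stat_value), int(record.df))
        n = record.n
    elif kind == "F":
        if record.stat_value is None or record.df is None:
            raise EffectSizeError(f"{record.effect_id}: F conversion needs stat_value and df")
        if record.sign is None:
            raise EffectSizeError(f"{record.effect_id}: F conversion needs a stated sign")
        r = r_from_f(float(record.stat_value), int(record.df), record.sign)
        n = record.n
    elif kind == "raw":
        if record.raw_x is None or record.raw_y is None:
            raise EffectSizeError(f"{record.effect_id}: raw conversion needs raw_x and raw_y")
        r, n = r_from_raw(record.raw_x, record.raw_y)
    else:
        raise EffectSizeError(f"{record.effect_id}: unknown stat_kind {kind!r}")

    try:
        z = fisher_z(r)
        v = z_variance(n)
    except EffectSizeError as exc:
        raise EffectSizeError(f"{record.effect_id}: {exc}") from exc
    sign = "+" if r >= 0 else "-"
    return dataio.replace_record(record, r=r, z=z, v=v, n=n, sign=sign)
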