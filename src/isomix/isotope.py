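"""Stable carbon isotope algebra for dual-tracer source apportionment.

All isotopic compositions are expressed in delta notation: the per-mil (‰)
deviation of a sample's 13C/12C ratio from the Vienna Pee Dee Belemnite
(VPDB) international standard,

    δ13C = (R_sample / R_standard − 1) × 1000 .

A δ13C value is therefore bounded below by −1000‰ (the isotope ratio must
stay positive).  The intermolecular fractionation factor between two
co-produced compounds (here formic and acetic acid) is

    α = (δ13C_formic + 1000) / (δ13C_acetic + 1000) ,

a dimensionless number close to 1 for carbon systems.  Linear mass-balance
mixing, the model underlying the whole apportionment chain, states that a
mixture's δ13C is the fraction-weighted mean of the source δ13C values.

This module also carries the atmospheric-lifetime bound arithmetic: an air
mass that took ``H`` hours to reach a receptor while still carrying a
tracer implies a tracer lifetime of at least ``H/24`` days, and that lower
bound can be compared against modelled lifetimes as a relative
underestimation percentage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "VPDB_RATIO",
    "LifetimeBound",
    "delta_from_ratio",
    "ratio_from_delta",
    "fractionation_factor",
    "delta_gap_from_alpha",
    "mixing_forward",
    "lifetime_lower_bound_days",
    "relative_underestimate_percent",
    "round_half_away",
]

#: 13C/12C ratio of the VPDB standard (Craig 1957 re-evaluation).
VPDB_RATIO = 0.0112372

#: fractionation factors outside this band are implausible for carbon systems
_ALPHA_PLAUSIBLE = (0.9, 1.1)


@dataclass(frozen=True)
class LifetimeBound:
    """Lower bound on an atmospheric lifetime implied by transport survival.

    Attributes
    ----------
    transport_hours : float
        Back-trajectory transport duration in hours (≥ 0).
    lower_bound_days : float
        ``transport_hours / 24`` — the tracer survived at least this long.
    """

    transport_hours: float
    lower_bound_days: float


def delta_from_ratio(r_sample: float, r_standard: float = VPDB_RATIO) -> float:
    """Convert an absolute 13C/12C ratio to δ13C in ‰ vs the standard.

    Parameters
    ----------
    r_sample, r_standard : float
        Strictly positive isotope ratios.

    Returns
    -------
    float
        δ13C in ‰: ``(r_sample / r_standard − 1) × 1000``.
    """
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError(
            f"isotope ratios must be strictly positive, got sample={r_sample}, "
            f"standard={r_standard}"
        )
    return (r_sample / r_standard - 1.0) * 1000.0


def ratio_from_delta(delta_permil: float, r_standard: float = VPDB_RATIO) -> float:
    """Inverse of :func:`delta_from_ratio`: recover the absolute ratio."""
    if delta_permil <= -1000.0:
        raise ValueError(f"δ13C must exceed −1000‰, got {delta_permil}")
    if r_standard <= 0:
        raise ValueError(f"standard ratio must be positive, got {r_standard}")
    return r_standard * (1.0 + delta_permil / 1000.0)


def fractionation_factor(delta_formic: float, delta_acetic: float) -> float:
    """Intermolecular fractionation factor α between formic and acetic acid.

    α = (δ13C_formic + 1000) / (δ13C_acetic + 1000).  Values far from 1
    (outside [0.9, 1.1]) are physically implausible for carbon and trigger a
    warning but are still returned.
    """
    num = delta_formic + 1000.0
    den = delta_acetic + 1000.0
    if den <= 0:
        raise ValueError(
            f"δ13C_acetic must exceed −1000‰ (got {delta_acetic}): "
            "denominator of α would be non-positive"
        )
    if num <= 0:
        raise ValueError(f"δ13C_formic must exceed −1000‰ (got {delta_formic})")
    alpha = num / den
    if not (_ALPHA_PLAUSIBLE[0] <= alpha <= _ALPHA_PLAUSIBLE[1]):
        warnings.warn(
            f"fractionation factor α={alpha:.4f} outside plausible carbon "
            f"range {_ALPHA_PLAUSIBLE}",
            stacklevel=2,
        )
    return alpha


def delta_gap_from_alpha(
    alpha: float,
    mode: str = "ln",
    delta_acetic: float | None = None,
) -> float:
    """δ13C_formic − δ13C_acetic implied by a fractionation factor α.

    Two forms are supported:

    ``"ln"`` (default)
        The logarithmic approximation ``10³·ln α``, the form used by the
        secondary-source estimator.  It is independent of the absolute
        isotopic composition.
    ``"exact"``
        The exact algebraic gap ``(α − 1)(δ13C_acetic + 1000)``, which
        requires ``delta_acetic``.  At α = 1.002 the two gaps differ by
        about 0.06‰ for tropospheric δ13C values; in the solved secondary
        source signatures the difference stays below 0.05‰.
    """
    if alpha <= 0:
        raise ValueError(f"fractionation factor must be positive, got {alpha}")
    if mode == "ln":
        return 1000.0 * math.log(alpha)
    if mode == "exact":
        if delta_acetic is None:
            raise ValueError("exact mode requires delta_acetic")
        if delta_acetic <= -1000.0:
            raise ValueError(f"δ13C_acetic must exceed −1000‰, got {delta_acetic}")
        return (alpha - 1.0) * (delta_acetic + 1000.0)
    raise ValueError(f"mode must be 'ln' or 'exact', got {mode!r}")


def mixing_forward(
    fractions: Sequence[float],
    source_deltas: Sequence[float],
    atol: float = 1e-9,
) -> float:
    """Mass-balance mixture δ13C for one tracer: ``Σ_s F_s · δ_s``.

    ``fractions`` must be a simplex vector (non-negative, summing to 1
    within ``atol``) with one entry per source δ13C.  Mixing is linear in
    δ — exactly the mass-balance model — not in isotope-ratio space; the
    difference is below 0.01‰ for tropospheric δ13C values.
    """
    f = np.asarray(fractions, dtype=float)
    d = np.asarray(source_deltas, dtype=float)
    if f.shape != d.shape or f.ndim != 1:
        raise ValueError(
            f"fractions {f.shape} and source deltas {d.shape} must be 1-D and equal length"
        )
    if np.any(f < -atol):
        raise ValueError(f"fractions must be non-negative, got {f}")
    if abs(f.sum() - 1.0) > atol:
        raise ValueError(f"fractions must sum to 1 (got {f.sum():.12f})")
    return float(f @ d)


def lifetime_lower_bound_days(transport_hours: float) -> LifetimeBound:
    """Lifetime lower bound (days) from a back-trajectory transport duration."""
    if transport_hours < 0:
        raise ValueError(f"transport duration must be ≥ 0 h, got {transport_hours}")
    return LifetimeBound(
        transport_hours=float(transport_hours),
        lower_bound_days=transport_hours / 24.0,
    )


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def relative_underestimate_percent(
    observed_lb_days: float, modeled_days: float
) -> int:
    """By how many percent a modelled lifetime undershoots an observed bound.

    Returns ``round((observed/modeled − 1) × 100)`` as an integer percent,
    ties away from zero.  A positive value means the model underestimates
    the lifetime.
    """
    if modeled_days <= 0:
        raise ValueError(f"modelled lifetime must be positive, got {modeled_days}")
    if observed_lb_days < 0:
        raise ValueError(f"observed bound must be ≥ 0, got {observed_lb_days}")
    return round_half_away((observed_lb_days / modeled_days - 1.0) * 100.0)
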