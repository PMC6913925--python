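"""Most-probable-number (MPN) estimation for a single Quanti-Tray.

A Quanti-Tray 2000 partitions roughly 100 mL of assay fluid into 49 large
and 48 small wells.  After incubation with a defined-substrate reagent each
well is scored positive (fluorescing) or negative.  Under the standard MPN
model — organisms Poisson-distributed in the fluid, wells independent — a
well of volume ``v`` is sterile with probability ``exp(-lambda * v)`` where
``lambda`` is the organism concentration per mL.  The MPN is the maximum
likelihood estimate of ``lambda`` rescaled to a reference volume (100 mL),
which is what the manufacturer's lookup table tabulates.

This module solves the likelihood problem directly instead of shipping the
lookup table: the score function is strictly decreasing in ``lambda``, so
the MLE is the unique root of the score equation and is found by bracketed
root-finding.  Trays with zero positive wells (non-detect) or all wells
positive (over-range) have no interior maximum and are returned as censored
statuses; numeric substitution for censored trays is the job of the
dilution pipeline, not of this module.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

from scipy.optimize import brentq
from scipy.stats import chi2

__all__ = [
    "TrayGeometry",
    "TrayObservation",
    "TrayEstimate",
    "CensoringStatus",
    "QUANTI_TRAY_2000",
    "log_likelihood",
    "score",
    "mpn_mle",
    "mpn_confidence_interval",
]

# Bracket (per mL) within which the score root is sought.  The lower edge is
# far below one organism per tray; the upper edge corresponds to ~10^5 MPN
# per 100 mL, beyond any quantifiable well pattern.
_LAMBDA_LO = 1e-9
_LAMBDA_HI = 1e3
_REL_TOL = 1e-10


class CensoringStatus(str, enum.Enum):
    """Detection status of a single tray."""

    NONDETECT = "nondetect"
    QUANTIFIABLE = "quantifiable"
    OVERRANGE = "overrange"


@dataclass(frozen=True)
class TrayGeometry:
    """Well layout of an MPN tray.

    Parameters
    ----------
    n_large, n_small
        Number of large and small wells.
    v_large, v_small
        Volume of assay fluid per large / small well, in mL.
    reference_volume
        Volume (mL) over which the MPN is reported; 100 mL for the
        Quanti-Tray 2000, whose total well volume (49*1.86 + 48*0.186
        = 100.07 mL) is within 2% of it.
    """

    n_large: int = 49
    n_small: int = 48
    v_large: float = 1.86
    v_small: float = 0.186
    reference_volume: float = 100.0

    def __post_init__(self) -> None:
        if self.n_large <= 0 and self.n_small <= 0:
            raise ValueError("tray must contain at least one well")
        if self.n_large < 0 or self.n_small < 0:
            raise ValueError("well counts must be non-negative")
        if self.n_large > 0 and self.v_large <= 0:
            raise ValueError("v_large must be positive")
        if self.n_small > 0 and self.v_small <= 0:
            raise ValueError("v_small must be positive")
        if self.reference_volume <= 0:
            raise ValueError("reference_volume must be positive")

    @property
    def total_volume(self) -> float:
        """Total assay fluid in the tray, mL."""
        return self.n_large * self.v_large + self.n_small * self.v_small

    @property
    def n_wells(self) -> int:
        return self.n_large + self.n_small


#: Default geometry: IDEXX Quanti-Tray 2000 (manufacturer constants,
#: consistent with a quantifiable range of >1 to 2419.6 MPN per tray).
QUANTI_TRAY_2000 = TrayGeometry()


@dataclass(frozen=True)
class TrayObservation:
    """Positive-well counts for one tray at one dilution."""

    p_large: int
    p_small: int
    geometry: TrayGeometry = field(default=QUANTI_TRAY_2000)

    def __post_init__(self) -> None:
        g = self.geometry
        if not 0 <= self.p_large <= g.n_large:
            raise ValueError(
                f"p_large={self.p_large} outside [0, {g.n_large}]"
            )
        if not 0 <= self.p_small <= g.n_small:
            raise ValueError(
                f"p_small={self.p_small} outside [0, {g.n_small}]"
            )

    @property
    def all_negative(self) -> bool:
        return self.p_large == 0 and self.p_small == 0

    @property
    def all_positive(self) -> bool:
        g = self.geometry
        return self.p_large == g.n_large and self.p_small == g.n_small


@dataclass(frozen=True)
class TrayEstimate:
    """MPN estimate (per ``reference_volume``) with censoring status.

    ``mpn`` is defined only for quantifiable trays; non-detect and
    over-range trays carry no number here — the dilution pipeline applies
    the study's substitution constants to them.
    """

    status: CensoringStatus
    mpn: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    @property
    def quantifiable(self) -> bool:
        return self.status is CensoringStatus.QUANTIFIABLE


def log_likelihood(lam: float, obs: TrayObservation) -> float:
    """Binomial log-likelihood of a well pattern at concentration ``lam``.

    ``lam`` is the organism concentration per mL of the fluid loaded into
    the tray.  Each well of volume ``v`` is positive with probability
    ``1 - exp(-lam*v)``.  Combinatorial constants are omitted (they do not
    depend on ``lam``).

    Raises
    ------
    ValueError
        If ``lam`` is not strictly positive.
    """
    if lam <= 0:
        raise ValueError("lambda must be strictly positive")
    g = obs.geometry
    ll = 0.0
    for p, n, v in (
        (obs.p_large, g.n_large, g.v_large),
        (obs.p_small, g.n_small, g.v_small),
    ):
        if n == 0:
            continue
        if p > 0:
            ll += p * math.log(-math.expm1(-lam * v))
        ll -= (n - p) * lam * v
    return ll


def score(lam: float, obs: TrayObservation) -> float:
    """Derivative of :func:`log_likelihood` in ``lam``; strictly decreasing."""
    if lam <= 0:
        raise ValueError("lambda must be strictly positive")
    g = obs.geometry
    s = 0.0
    for p, n, v in (
        (obs.p_large, g.n_large, g.v_large),
        (obs.p_small, g.n_small, g.v_small),
    ):
        if n == 0:
            continue
        if p > 0 and lam * v < 700:  # beyond that e^{lam v} overflows, term ~ 0
            # v * e^{-lam v} / (1 - e^{-lam v})
            s += p * v / math.expm1(lam * v)
        s -= (n - p) * v
    return s


def _solve_mle(obs: TrayObservation) -> float:
    """Root of the score equation, per mL."""
    lo, hi = _LAMBDA_LO, _LAMBDA_HI
    # score -> +inf as lam -> 0 (some positive well) and is negative for
    # large lam (some negative well); widen the bracket defensively for
    # unusual geometries.
    while score(hi, obs) > 0:
        hi *= 10
        if hi > 1e12:  # pragma: no cover - unreachable for valid trays
            raise RuntimeError("failed to bracket the MPN score root")
    while score(lo, obs) < 0:
        lo /= 10
    return brentq(score, lo, hi, args=(obs,), rtol=_REL_TOL)


def mpn_mle(obs: TrayObservation) -> TrayEstimate:
    """Maximum-likelihood MPN for one tray.

    Returns a :class:`TrayEstimate` whose status reflects censoring:
    zero positive wells → ``nondetect``; every well positive →
    ``overrange``; otherwise ``quantifiable`` with
    ``mpn = reference_volume * argmax_lambda log_likelihood``.
    """
    if obs.all_negative:
        return TrayEstimate(status=CensoringStatus.NONDETECT)
    if obs.all_positive:
        return TrayEstimate(status=CensoringStatus.OVERRANGE)
    lam = _solve_mle(obs)
    return TrayEstimate(
        status=CensoringStatus.QUANTIFIABLE,
        mpn=lam * obs.geometry.reference_volume,
    )


def mpn_confidence_interval(
    obs: TrayObservation, level: float = 0.95
) -> Tuple[float, float]:
    """Profile-likelihood interval for the MPN of a quantifiable tray.

    The interval is ``{lam : 2*(l(lam_hat) - l(lam)) <= chi2_1(level)}``
    rescaled to the reference volume.  ``level=0`` degenerates to the MLE.

    Raises
    ------
    ValueError
        For non-detect or over-range trays, which admit only a one-sided
        bound, not a two-sided interval.
    """
    if not 0 <= level < 1:
        raise ValueError("level must lie in [0, 1)")
    if obs.all_negative or obs.all_positive:
        raise ValueError(
            "censored tray: only a one-sided bound exists, not a "
            "two-sided profile interval"
        )
    lam_hat = _solve_mle(obs)
    ref = obs.geometry.reference_volume
    if level == 0:
        return lam_hat * ref, lam_hat * ref

    cutoff = chi2.ppf(level, df=1) / 2.0
    ll_hat = log_likelihood(lam_hat, obs)

    def deficit(lam: float) -> float:
        return (ll_hat - log_likelihood(lam, obs)) - cutoff

    lo_edge = _LAMBDA_LO
    while deficit(lo_edge) < 0:
        lo_edge /= 10
    hi_edge = _LAMBDA_HI
    while deficit(hi_edge) < 0:
        hi_edge *= 10
    low = brentq(deficit, lo_edge, lam_hat, rtol=_REL_TOL)
    high = brentq(deficit, lam_hat, hi_edge, rtol=_REL_TOL)
    return low * ref, high * ref
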