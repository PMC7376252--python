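"""Bootstrap inference and between-condition comparison of cosinor parameters.

Resampling-based confidence intervals for MESOR, amplitude and acrophase,
and a paired-draw comparison of two conditions (mean-level difference,
amplitude ratio, circular phase difference) with a rhythm-change
classification (gained / lost / phase_shifted / ...).

Two resampling schemes are provided, both preserving the fixed-ZT design
so every resample stays estimable:

* ``stratified`` (default) — case resampling of replicates with
  replacement *within* each time point; appropriate for the unbalanced
  few-animals-per-ZT designs this package targets.
* ``residual`` — residuals of the point fit resampled with replacement
  and added back to the fitted curve; useful when strata are as small as
  n = 3 and case resampling is coarse.

Intervals are percentile intervals (default 95%).  Acrophase draws live on
the circle [0, T); their interval is a percentile interval of deviations
about the circular mean of the draws, so wrap-around (e.g. draws at 23.5 h
and 0.5 h) is handled correctly.

The default comparison criterion is the bootstrap CI of the paired
difference (or ratio) excluding its null value; an ``overlap`` mode is
also available that instead flags non-overlapping per-condition CIs — a
common but conservative reading of "comparing confidence intervals".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cosinor import (
    ND,
    RHYTHMIC,
    CosinorParams,
    EstimabilityError,
    linearized_fit,
    predict,
)

__all__ = [
    "BootstrapDistribution",
    "ParamCI",
    "GroupComparison",
    "bootstrap_params",
    "param_ci",
    "compare_conditions",
    "classify_change",
    "circular_mean",
    "wrap_phase_difference",
]

MIN_BOOTSTRAP_DRAWS = 200

CHANGE_CLASSES = (
    "both_arrhythmic",
    "gained",
    "lost",
    "phase_shifted",
    "amplitude_modulated",
    "mesor_shifted",
    "unchanged",
    "compound",
    "indeterminate",
)


def wrap_phase_difference(delta: np.ndarray | float, period: float = 24.0) -> np.ndarray | float:
    """Wrap an hour difference onto (−T/2, T/2]."""
    wrapped = -(np.mod(-np.asarray(delta, dtype=float) + period / 2.0, period) - period / 2.0)
    return float(wrapped) if np.isscalar(delta) else wrapped


def circular_mean(phases: np.ndarray, period: float = 24.0) -> float:
    """Circular mean of clock times in hours, returned on [0, period)."""
    ang = 2.0 * math.pi * np.asarray(phases, dtype=float) / period
    mean_ang = math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float(np.mod(mean_ang * period / (2.0 * math.pi), period))


@dataclass(frozen=True)
class ParamCI:
    """Point estimate with a percentile confidence interval.

    For circular parameters (acrophase, phase difference) the interval is
    centered on the circular mean of the draws: ``lower``/``upper`` are
    ``center + deviation`` and may fall outside [0, T); wrap them for
    display.  Half-width never exceeds T/2.
    """

    point: float
    lower: float
    upper: float
    circular: bool = False
    period: float = 24.0

    def contains(self, value: float) -> bool:
        if not self.circular:
            return self.lower <= value <= self.upper
        center = (self.lower + self.upper) / 2.0
        dev = wrap_phase_difference(value - center, self.period)
        return (self.lower - center) <= dev <= (self.upper - center)

    def overlaps(self, other: "ParamCI") -> bool:
        if not self.circular:
            return self.lower <= other.upper and other.lower <= self.upper
        # circular intervals: overlap iff either contains an endpoint of the other
        return (
            self.contains(other.lower)
            or self.contains(other.upper)
            or other.contains(self.lower)
            or other.contains(self.upper)
        )


@dataclass(frozen=True)
class BootstrapDistribution:
    """Bootstrap draws of (MESOR, amplitude, acrophase) for one series."""

    draws: np.ndarray  # shape (B, 3): columns M, A, phi
    point: CosinorParams
    scheme: str
    B: int
    seed: int
    ci_level: float = 0.95
    n_redraws: int = 0

    @property
    def period(self) -> float:
        return self.point.period


def _stratum_indices(t: np.ndarray, period: float) -> list[np.ndarray]:
    keys = np.round(np.mod(t, period), 9)
    return [np.flatnonzero(keys == k) for k in np.unique(keys)]


def bootstrap_params(
    t: np.ndarray,
    y: np.ndarray,
    period: float = 24.0,
    B: int = 1000,
    scheme: str = "stratified",
    seed: int = 0,
    ci_level: float = 0.95,
) -> BootstrapDistribution:
    """Bootstrap the cosinor parameters of one series.

    Each resample keeps the design matrix intact (resampling happens
    within time points, or on residuals), so the closed-form harmonic OLS
    refit can be fully vectorized across draws.  Draws are canonicalized
    (A ≥ 0, φ in [0, T)).  Deterministic for fixed (data, B, scheme, seed).
    """
    if B < MIN_BOOTSTRAP_DRAWS:
        raise ValueError(f"B must be >= {MIN_BOOTSTRAP_DRAWS} for reported CIs, got {B}")
    if scheme not in ("stratified", "residual"):
        raise ValueError(f"unknown scheme {scheme!r}")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    t, y = t[keep], y[keep]
    point = linearized_fit(t, y, period)  # raises EstimabilityError if unfittable

    rng = np.random.default_rng(seed)
    n = y.size
    Y = np.empty((n, B))
    if scheme == "stratified":
        # case resampling within a stratum of n_j values draws from an
        # empirical distribution whose variance is the biased (n_j-1)/n_j
        # sample variance; with n_j as small as 3 this narrows the CIs
        # noticeably, so the centered stratum values are inflated by
        # sqrt(n_j/(n_j-1)) before resampling (noise-free strata unaffected)
        for idx in _stratum_indices(t, period):
            vals = y[idx]
            if idx.size > 1:
                center = vals.mean()
                vals = center + math.sqrt(idx.size / (idx.size - 1)) * (vals - center)
            picks = rng.integers(0, idx.size, size=(idx.size, B))
            Y[idx, :] = vals[picks]
    else:  # residual
        fitted = np.asarray(predict(point, t))
        # residuals of a p=3-parameter fit carry (n-p)/n of the error
        # variance; rescale so resampled errors have the right size
        resid = (y - fitted) * math.sqrt(n / max(n - 3, 1))
        picks = rng.integers(0, n, size=(n, B))
        Y = fitted[:, None] + resid[picks]

    omega = 2.0 * math.pi / period
    X = np.column_stack([np.ones(n), np.cos(omega * t), np.sin(omega * t)])
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < 3:  # cannot happen for designs that passed estimability
        raise EstimabilityError("rank-deficient design in bootstrap refit")
    mesor = coef[0]
    amp = np.hypot(coef[1], coef[2])
    phi = np.mod(np.arctan2(coef[2], coef[1]) * period / (2.0 * math.pi), period)
    draws = np.column_stack([mesor, amp, phi])
    return BootstrapDistribution(
        draws=draws,
        point=point,
        scheme=scheme,
        B=B,
        seed=seed,
        ci_level=ci_level,
    )


_PARAM_COLUMN = {"mesor": 0, "amplitude": 1, "acrophase": 2}


def _circular_percentile_ci(
    draws: np.ndarray, level: float, period: float, point: float | None = None
) -> ParamCI:
    center = circular_mean(draws, period)
    dev = wrap_phase_difference(draws - center, period)
    lo, hi = np.percentile(dev, [50 * (1 - level), 50 * (1 + level)])
    return ParamCI(
        point=center if point is None else point,
        lower=float(center + lo),
        upper=float(center + hi),
        circular=True,
        period=period,
    )


def param_ci(
    dist: BootstrapDistribution, which: str, level: float | None = None
) -> ParamCI:
    """Percentile CI for one parameter of a bootstrap distribution.

    ``which`` is ``"mesor"``, ``"amplitude"`` or ``"acrophase"``.  MESOR
    and amplitude get plain percentile intervals; the acrophase gets a
    circular percentile interval about the circular mean of the draws.
    Requesting the acrophase of an undefined-phase fit (amplitude
    numerically zero) is an error — treat such a feature as arrhythmic.
    """
    if which not in _PARAM_COLUMN:
        raise ValueError(f"unknown parameter {which!r}")
    level = dist.ci_level if level is None else level
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    col = dist.draws[:, _PARAM_COLUMN[which]]
    if which == "acrophase":
        if not dist.point.phase_defined:
            raise ValueError(
                "acrophase CI requested for an undefined-phase fit; "
                "treat this feature as arrhythmic"
            )
        return _circular_percentile_ci(col, level, dist.period, point=dist.point.acrophase)
    lo, hi = np.percentile(col, [50 * (1 - level), 50 * (1 + level)])
    point = dist.point.mesor if which == "mesor" else dist.point.amplitude
    return ParamCI(point=point, lower=float(lo), upper=float(hi), circular=False)


@dataclass(frozen=True)
class GroupComparison:
    """Between-condition contrasts of the oscillation parameters.

    ``delta_mesor`` is condition A minus condition B; ``amplitude_ratio``
    is A over B; ``delta_phi`` is the circular difference φ_A − φ_B in
    hours on (−T/2, T/2], positive when A peaks later than B.  Phase and
    amplitude contrasts are None when either side is not rhythmic.
    ``significant`` maps parameter name to the CI-exclusion verdict (None
    when the contrast was suppressed); ``change_class`` is the rhythm-
    change label of :func:`classify_change`.
    """

    delta_mesor: ParamCI
    amplitude_ratio: ParamCI | None
    delta_phi: ParamCI | None
    significant: dict[str, bool | None]
    change_class: str
    mode: str = "difference"


def _ci_excludes(ci: ParamCI, null_value: float) -> bool:
    return not ci.contains(null_value)


def compare_conditions(
    dist_a: BootstrapDistribution,
    dist_b: BootstrapDistribution,
    call_a: str = RHYTHMIC,
    call_b: str = RHYTHMIC,
    level: float | None = None,
    mode: str = "difference",
) -> GroupComparison:
    """Compare two conditions' oscillation parameters by paired bootstrap.

    Draw i of condition A is paired with draw i of condition B (the
    streams are independent; pairing just indexes them), giving bootstrap
    distributions of the MESOR difference, amplitude ratio and circular
    phase difference.  In ``difference`` mode a contrast is significant
    when its CI excludes the null value (0 for differences, 1 for the
    ratio); in ``overlap`` mode when the two per-condition CIs do not
    overlap.  Phase and amplitude contrasts are computed only when both
    conditions are rhythmic; the MESOR contrast is always available.
    """
    if mode not in ("difference", "overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    if dist_a.B != dist_b.B:
        raise ValueError("paired comparison needs equal draw counts")
    level = dist_a.ci_level if level is None else level
    period = dist_a.period
    both_rhythmic = call_a == RHYTHMIC and call_b == RHYTHMIC

    dm_draws = dist_a.draws[:, 0] - dist_b.draws[:, 0]
    lo, hi = np.percentile(dm_draws, [50 * (1 - level), 50 * (1 + level)])
    delta_mesor = ParamCI(
        point=dist_a.point.mesor - dist_b.point.mesor,
        lower=float(lo),
        upper=float(hi),
    )
    if mode == "difference":
        sig_mesor = _ci_excludes(delta_mesor, 0.0)
    else:
        sig_mesor = not param_ci(dist_a, "mesor", level).overlaps(
            param_ci(dist_b, "mesor", level)
        )

    amplitude_ratio = delta_phi = None
    sig_amp: bool | None = None
    sig_phase: bool | None = None
    if both_rhythmic:
        ratio_draws = dist_a.draws[:, 1] / np.maximum(dist_b.draws[:, 1], 1e-300)
        lo, hi = np.percentile(ratio_draws, [50 * (1 - level), 50 * (1 + level)])
        amplitude_ratio = ParamCI(
            point=dist_a.point.amplitude / dist_b.point.amplitude,
            lower=float(lo),
            upper=float(hi),
        )
        dphi_draws = wrap_phase_difference(
            dist_a.draws[:, 2] - dist_b.draws[:, 2], period
        )
        delta_phi = _circular_percentile_ci(
            dphi_draws,
            level,
            period,
            point=wrap_phase_difference(
                dist_a.point.acrophase - dist_b.point.acrophase, period
            ),
        )
        if mode == "difference":
            sig_amp = _ci_excludes(amplitude_ratio, 1.0)
            sig_phase = _ci_excludes(delta_phi, 0.0)
        else:
            sig_amp = not param_ci(dist_a, "amplitude", level).overlaps(
                param_ci(dist_b, "amplitude", level)
            )
            sig_phase = not param_ci(dist_a, "acrophase", level).overlaps(
                param_ci(dist_b, "acrophase", level)
            )

    significant = {"mesor": sig_mesor, "amplitude": sig_amp, "phase": sig_phase}
    change_class = classify_change(call_a, call_b, significant)
    return GroupComparison(
        delta_mesor=delta_mesor,
        amplitude_ratio=amplitude_ratio,
        delta_phi=delta_phi,
        significant=significant,
        change_class=change_class,
        mode=mode,
    )


def classify_change(
    call_a: str, call_b: str, significant: dict[str, bool | None]
) -> str:
    """Label the rhythm change from condition A to condition B.

    A is the reference (e.g. control diet), B the contrast (e.g.
    challenge): B newly rhythmic = ``gained`` (de novo rhythmicity), B
    newly arrhythmic = ``lost``.  When both are rhythmic the label follows
    which contrasts are significant: exactly one of phase / amplitude /
    mesor gives ``phase_shifted`` / ``amplitude_modulated`` /
    ``mesor_shifted``; several give ``compound``; none gives
    ``unchanged``.  An unfittable side (``nd``) yields ``indeterminate``,
    never a silent drop.
    """
    if call_a == ND or call_b == ND:
        return "indeterminate"
    a_rhythmic = call_a == RHYTHMIC
    b_rhythmic = call_b == RHYTHMIC
    if not a_rhythmic and b_rhythmic:
        return "gained"
    if a_rhythmic and not b_rhythmic:
        return "lost"
    if not a_rhythmic and not b_rhythmic:
        return "both_arrhythmic"
    hits = [name for name in ("phase", "amplitude", "mesor") if significant.get(name)]
    if len(hits) > 1:
        return "compound"
    if hits == ["phase"]:
        return "phase_shifted"
    if hits == ["amplitude"]:
        return "amplitude_modulated"
    if hits == ["mesor"]:
        return "mesor_shifted"
    return "unchanged"
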