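"""Fixed-period single-component cosinor regression.

Fits y(t) = M + A·cos(2π(t − φ)/T) to sparse diurnal series by least
squares, tests the zero-amplitude null with a nested-model F test, and
emits a rhythm call (``rhythmic`` / ``nsr`` / ``nd``).

The period T is fixed (default 24 h): with only four distinct zeitgeber
times the period is not identifiable and estimating it would be
meaningless.  With T fixed the model is linear in the reparameterization
y = M + β·cos(ωt) + γ·sin(ωt), so the global least-squares optimum has a
closed form (:func:`linearized_fit`); :func:`fit_cosinor` additionally
polishes the (M, A, φ) parameterization with a nonlinear solver and must
agree with the closed form to high precision.

Acrophase convention: φ is the clock time of the fitted peak, in hours on
[0, T) — i.e. zeitgeber time for entrained data — rather than the
traditional negative-radians cosinor angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CosinorParams",
    "CosinorFitResult",
    "EstimabilityError",
    "canonicalize",
    "linearized_fit",
    "fit_cosinor",
    "zero_amplitude_test",
    "call_rhythm",
    "predict",
]

#: Relative amplitude below which the acrophase is reported as undefined.
DEGENERATE_AMPLITUDE_RTOL = 1e-12

#: Rhythm call labels.
RHYTHMIC = "rhythmic"
NSR = "nsr"  # non-significantly rhythmic
ND = "nd"  # not detected / not estimable


class EstimabilityError(ValueError):
    """The design cannot identify the cosinor parameters.

    Raised when fewer than three distinct time points (modulo the period)
    are available, or the harmonic design matrix is rank deficient.
    """


@dataclass(frozen=True)
class CosinorParams:
    """Cosinor parameter triple at a fixed period.

    Attributes
    ----------
    mesor : float
        Rhythm-adjusted mean level M (MESOR), in data units.
    amplitude : float
        Half the peak-to-trough range, A ≥ 0.
    acrophase : float
        Clock time of the fitted peak, hours in [0, period).
    period : float
        Fixed oscillation period T in hours.
    phase_defined : bool
        False when the amplitude is numerically zero, in which case the
        acrophase is reported as 0.0 by convention and must not be
        interpreted.
    """

    mesor: float
    amplitude: float
    acrophase: float
    period: float = 24.0
    phase_defined: bool = True

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError(f"period must be > 0, got {self.period}")


@dataclass(frozen=True)
class CosinorFitResult:
    """A cosinor fit plus rhythmicity diagnostics for one series.

    ``sse_full`` / ``sse_mesor_only`` are the residual sums of squares of
    the cosinor and of the constant-mean (MESOR-only) model; their nested
    comparison drives the zero-amplitude F test.  ``call`` is ``nd`` when
    the series was not estimable, in which case the numeric fields are NaN.
    """

    params: CosinorParams | None
    sse_full: float
    sse_mesor_only: float
    n: int
    df_residual: int
    f_statistic: float
    p_zero_amplitude: float
    call: str

    @property
    def rhythmic(self) -> bool:
        return self.call == RHYTHMIC


def canonicalize(
    mesor: float, amplitude: float, acrophase: float, period: float = 24.0
) -> CosinorParams:
    """Map an arbitrary (M, A, φ) triple to the canonical representation.

    A negative amplitude is folded to A > 0 by shifting the acrophase half
    a period (cos is antiperiodic over T/2); the acrophase is then wrapped
    to [0, T).  A numerically zero amplitude yields an undefined phase,
    reported as φ = 0 with ``phase_defined=False`` rather than whatever
    angle the solver happened to land on.
    """
    if amplitude < 0:
        amplitude = -amplitude
        acrophase = acrophase + period / 2.0
    acrophase = float(np.mod(acrophase, period))
    scale = max(abs(mesor), amplitude, 1.0)
    if amplitude <= DEGENERATE_AMPLITUDE_RTOL * scale:
        return CosinorParams(float(mesor), float(amplitude), 0.0, period, False)
    return CosinorParams(float(mesor), float(amplitude), acrophase, period, True)


def _design_matrix(t: np.ndarray, period: float) -> np.ndarray:
    omega = 2.0 * math.pi / period
    return np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])


def _check_estimable(t: np.ndarray, period: float) -> None:
    if period <= 0:
        raise ValueError(f"period must be > 0, got {period}")
    # distinct time points modulo the period, with a tolerance for float fuzz
    phases = np.sort(np.mod(np.asarray(t, dtype=float), period))
    if phases.size == 0:
        raise EstimabilityError("empty series")
    distinct = 1 + int(np.count_nonzero(np.diff(phases) > 1e-9 * period))
    # first and last may alias across the wrap point
    if distinct > 1 and (phases[-1] - phases[0]) > period - 1e-9 * period:
        distinct -= 1
    if distinct < 3:
        raise EstimabilityError(
            f"need >= 3 distinct time points modulo the period, got {distinct}"
        )


def linearized_fit(
    t: np.ndarray, y: np.ndarray, period: float = 24.0
) -> CosinorParams:
    """Exact least-squares cosinor via the harmonic reparameterization.

    Regresses y on [1, cos ωt, sin ωt] by ordinary least squares and maps
    the coefficients back: A = √(β² + γ²), φ = (T/2π)·atan2(γ, β), so that
    the fitted curve peaks at t = φ.

    Raises
    ------
    EstimabilityError
        If fewer than 3 distinct time points (mod period) are present or
        the design is otherwise rank deficient.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise ValueError("t and y must have the same shape")
    _check_estimable(t, period)
    X = _design_matrix(t, period)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise EstimabilityError("rank-deficient harmonic design (aliased time points)")
    mesor, beta, gamma = coef
    amplitude = math.hypot(beta, gamma)
    # peak of beta·cos(ωt) + gamma·sin(ωt) = A·cos(ω(t − φ)) is at ωφ = atan2(γ, β)
    acrophase = (period / (2.0 * math.pi)) * math.atan2(gamma, beta)
    return canonicalize(mesor, amplitude, acrophase, period)


def predict(params: CosinorParams, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate M + A·cos(2π(t − φ)/T) at time(s) ``t`` (hours)."""
    omega = 2.0 * math.pi / params.period
    return params.mesor + params.amplitude * np.cos(omega * (np.asarray(t, dtype=float) - params.acrophase))


def zero_amplitude_test(
    sse_full: float, sse_mesor_only: float, n: int
) -> tuple[float, float]:
    """Nested-model F test of the cosinor against the constant mean.

    F = ((SSE₀ − SSE)/2) / (SSE/(n − 3)) on (2, n − 3) degrees of freedom;
    a small p rejects the zero-amplitude null, i.e. calls the series
    rhythmic.  A perfect fit (SSE = 0) returns p = 0 by convention.

    Returns (F, p). Requires n ≥ 4 so that df_residual ≥ 1.
    """
    df_resid = n - 3
    if df_resid < 1:
        raise ValueError(f"zero-amplitude test needs n >= 4, got n={n}")
    if sse_mesor_only <= 0.0:
        # constant series: the mesor-only model already fits perfectly,
        # there is no variance a rhythm could explain
        return 0.0, 1.0
    if sse_full <= 0.0:
        return math.inf, 0.0
    f_stat = ((sse_mesor_only - sse_full) / 2.0) / (sse_full / df_resid)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, 2, df_resid))
    return float(f_stat), p


def call_rhythm(p_zero_amplitude: float, alpha: float = 0.05) -> str:
    """Rhythm verdict: ``rhythmic`` iff p < alpha (strict), else ``nsr``.

    NaN p-values (unfittable series) propagate to ``nd``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if p_zero_amplitude is None or math.isnan(p_zero_amplitude):
        return ND
    return RHYTHMIC if p_zero_amplitude < alpha else NSR


def _nd_result(n: int) -> CosinorFitResult:
    return CosinorFitResult(
        params=None,
        sse_full=math.nan,
        sse_mesor_only=math.nan,
        n=n,
        df_residual=n - 3,
        f_statistic=math.nan,
        p_zero_amplitude=math.nan,
        call=ND,
    )


def fit_cosinor(
    t: np.ndarray,
    y: np.ndarray,
    period: float = 24.0,
    alpha: float = 0.05,
    polish: bool = True,
    max_missing_fraction: float = 0.5,
) -> CosinorFitResult:
    """Fit the fixed-period cosinor to one series and call its rhythmicity.

    Missing values (NaN in ``y``, e.g. below-detection-floor samples) are
    dropped before fitting; if more than ``max_missing_fraction`` of the
    series is missing, or the remaining design is not estimable (fewer
    than 3 distinct time points mod period, or n < 4), the result carries
    ``call='nd'`` with NaN parameters instead of an exception, so that
    unfittable features are reported rather than dropped.

    The closed-form harmonic OLS solution (:func:`linearized_fit`) is the
    global optimum; with ``polish=True`` it is additionally refined by a
    trust-region nonlinear least-squares pass on (M, A, φ), which must and
    does land on the same optimum (the fixed period makes the problem
    linear).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise ValueError("t and y must have the same shape")
    n_total = y.size
    keep = np.isfinite(y)
    if n_total == 0 or keep.sum() < (1.0 - max_missing_fraction) * n_total:
        return _nd_result(int(keep.sum()))
    t, y = t[keep], y[keep]
    n = y.size
    if n < 4:
        return _nd_result(n)
    try:
        params = linearized_fit(t, y, period)
    except EstimabilityError:
        return _nd_result(n)

    omega = 2.0 * math.pi / period
    if polish and params.phase_defined:
        def residuals(theta: np.ndarray) -> np.ndarray:
            m, a, phi = theta
            return y - (m + a * np.cos(omega * (t - phi)))

        sol = optimize.least_squares(
            residuals,
            x0=[params.mesor, params.amplitude, params.acrophase],
            method="lm",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        refined = canonicalize(sol.x[0], sol.x[1], sol.x[2], period)
        # the closed form is the exact global optimum of this linear problem;
        # adopt the polished solution only if it strictly beats it beyond roundoff
        sse_refined = float(np.sum(residuals(sol.x) ** 2))
        sse_closed = float(np.sum((y - predict(params, t)) ** 2))
        if sse_refined < sse_closed * (1.0 - 1e-12):
            params = refined

    fitted = predict(params, t)
    sse_full = float(np.sum((y - fitted) ** 2))
    sse_mesor = float(np.sum((y - y.mean()) ** 2))
    sse_full = min(sse_full, sse_mesor)  # guard float fuzz on A≈0 series
    f_stat, p = zero_amplitude_test(sse_full, sse_mesor, n)
    return CosinorFitResult(
        params=params,
        sse_full=sse_full,
        sse_mesor_only=sse_mesor,
        n=n,
        df_residual=n - 3,
        f_statistic=f_stat,
        p_zero_amplitude=p,
        call=call_rhythm(p, alpha),
    )
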