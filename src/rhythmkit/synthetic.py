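"""Synthetic diurnal study generator.

Emulates the sampling design of an around-the-clock rodent feeding study:
measurements taken every 6 h over one cycle (zeitgeber times ZT3, ZT9,
ZT15, ZT21), a small unbalanced number of animals per time point (e.g.
3–4 controls, 5–6 challenged), and two conditions per feature whose true
cosinor parameters (MESOR, amplitude, acrophase) are set per condition.
Alongside the measurements a truth table records the generating
parameters so every downstream estimate can be benchmarked.

A raw qPCR Ct table can also be generated for the same design, such that
comparative-threshold-cycle (2^–ΔΔCt) normalization recovers the
configured relative-expression profiles up to noise.

Randomness is one stream per feature, sub-seeded from the dataset seed and
a stable hash of the feature id, so adding a feature never perturbs the
values generated for the others.  Replicate counts are drawn from a
separate design-level stream shared by all features, because in the
emulated study every feature is measured on the same animals.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConditionParams",
    "FeatureSpec",
    "SimulationConfig",
    "ConfigError",
    "generate_dataset",
    "generate_ct_table",
    "truth_table",
]

DATASET_COLUMNS = ["feature", "condition", "zt", "replicate", "value"]
CT_COLUMNS = ["feature", "sample_id", "condition", "zt", "ct_target", "ct_reference"]
TRUTH_COLUMNS = ["feature", "condition", "mesor", "amplitude", "acrophase", "rhythmic"]


class ConfigError(ValueError):
    """A simulation configuration violates an invariant; names the field."""


@dataclass(frozen=True)
class ConditionParams:
    """True cosinor parameters of one feature under one condition."""

    mesor: float
    amplitude: float = 0.0
    acrophase: float = 0.0
    rhythmic: bool = False

    def validate(self, where: str) -> None:
        if self.amplitude < 0:
            raise ConfigError(f"{where}.amplitude must be >= 0, got {self.amplitude}")
        if not self.rhythmic and self.amplitude != 0:
            raise ConfigError(
                f"{where}: amplitude must be 0 when rhythmic is False "
                f"(got {self.amplitude})"
            )
        if self.rhythmic and not 0 <= self.acrophase < 24:
            raise ConfigError(
                f"{where}.acrophase must lie in [0, 24), got {self.acrophase}"
            )


@dataclass(frozen=True)
class FeatureSpec:
    """Generating model for one feature across conditions.

    ``params`` maps condition label -> :class:`ConditionParams`.
    ``noise_sd`` is the additive Gaussian measurement noise on the
    reported scale (or the log-scale SD under the log-normal noise model).
    Values falling below ``detection_floor`` are emitted as missing, to
    exercise the not-detected pathway.
    """

    feature_id: str
    params: dict[str, ConditionParams]
    noise_sd: float = 0.0
    detection_floor: float | None = None

    def validate(self) -> None:
        if not self.feature_id:
            raise ConfigError("feature_id must be non-empty")
        if self.noise_sd < 0:
            raise ConfigError(
                f"feature {self.feature_id!r}: noise_sd must be >= 0, "
                f"got {self.noise_sd}"
            )
        for cond, p in self.params.items():
            p.validate(f"feature {self.feature_id!r}, condition {cond!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a synthetic around-the-clock study.

    ``replicates_per_timepoint`` is either a fixed integer or an inclusive
    (low, high) range; a range reproduces unbalanced designs ("n = 3–4 per
    ZT") by drawing each condition × time-point count uniformly.
    """

    features: tuple[FeatureSpec, ...]
    conditions: tuple[str, ...] = ("CD", "MCDD")
    timepoints: tuple[float, ...] = (3.0, 9.0, 15.0, 21.0)
    replicates_per_timepoint: int | tuple[int, int] = (3, 6)
    period: float = 24.0
    seed: int = 0
    noise_model: str = "gaussian"  # or "lognormal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        """Build a config from a plain mapping (the YAML/JSON mirror)."""
        features = tuple(
            FeatureSpec(
                feature_id=f["feature_id"],
                params={
                    cond: ConditionParams(**p) for cond, p in f["params"].items()
                },
                noise_sd=float(f.get("noise_sd", 0.0)),
                detection_floor=f.get("detection_floor"),
            )
            for f in data.get("features", ())
        )
        reps = data.get("replicates_per_timepoint", (3, 6))
        if isinstance(reps, (list, tuple)):
            reps = (int(reps[0]), int(reps[1]))
        return cls(
            features=features,
            conditions=tuple(data.get("conditions", ("CD", "MCDD"))),
            timepoints=tuple(data.get("timepoints", (3.0, 9.0, 15.0, 21.0))),
            replicates_per_timepoint=reps,
            period=float(data.get("period", 24.0)),
            seed=int(data.get("seed", 0)),
            noise_model=data.get("noise_model", "gaussian"),
        )

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "timepoints": list(self.timepoints),
            "replicates_per_timepoint": (
                self.replicates_per_timepoint
                if isinstance(self.replicates_per_timepoint, int)
                else list(self.replicates_per_timepoint)
            ),
            "period": self.period,
            "seed": self.seed,
            "noise_model": self.noise_model,
            "features": [
                {
                    "feature_id": f.feature_id,
                    "noise_sd": f.noise_sd,
                    "detection_floor": f.detection_floor,
                    "params": {
                        cond: {
                            "mesor": p.mesor,
                            "amplitude": p.amplitude,
                            "acrophase": p.acrophase,
                            "rhythmic": p.rhythmic,
                        }
                        for cond, p in f.params.items()
                    },
                }
                for f in self.features
            ],
        }

    def replicate_range(self) -> tuple[int, int]:
        r = self.replicates_per_timepoint
        return (r, r) if isinstance(r, int) else (int(r[0]), int(r[1]))

    def validate(self) -> None:
        if not self.conditions:
            raise ConfigError("conditions must be non-empty")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("conditions contains duplicate labels")
        if self.period <= 0:
            raise ConfigError(f"period must be > 0, got {self.period}")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise ConfigError(f"noise_model must be gaussian|lognormal, got {self.noise_model!r}")
        lo, hi = self.replicate_range()
        if lo < 1 or hi < lo:
            raise ConfigError(
                f"replicates_per_timepoint must be >= 1 with low <= high, got {self.replicates_per_timepoint}"
            )
        n_distinct = len({round(t % self.period, 9) for t in self.timepoints})
        any_rhythmic = any(
            p.rhythmic for f in self.features for p in f.params.values()
        )
        if any_rhythmic and n_distinct < 3:
            raise ConfigError(
                f"timepoints: need >= 3 distinct time points (mod period) to "
                f"identify a rhythm, got {n_distinct}"
            )
        seen: set[str] = set()
        for f in self.features:
            f.validate()
            if f.feature_id in seen:
                raise ConfigError(f"duplicate feature_id {f.feature_id!r}")
            seen.add(f.feature_id)
            missing = set(self.conditions) - set(f.params)
            if missing:
                raise ConfigError(
                    f"feature {f.feature_id!r}: no params for condition(s) {sorted(missing)}"
                )


def _feature_rng(seed: int, feature_id: str) -> np.random.Generator:
    digest = hashlib.sha256(feature_id.encode("utf-8")).digest()
    sub = int.from_bytes(digest[:8], "little")
    return np.random.default_rng([seed, sub])


def _replicate_counts(config: SimulationConfig) -> dict[tuple[str, float], int]:
    """Animals per condition x time point — one draw shared by all features."""
    lo, hi = config.replicate_range()
    rng = np.random.default_rng([config.seed, 0xD51])
    return {
        (cond, zt): int(rng.integers(lo, hi + 1))
        for cond in config.conditions
        for zt in config.timepoints
    }


def _model_value(p: ConditionParams, t: float, period: float) -> float:
    if not p.rhythmic:
        return p.mesor
    return p.mesor + p.amplitude * math.cos(2.0 * math.pi * (t - p.acrophase) / period)


def generate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Generate a long-format measurement table for the configured study.

    Each record is M + A·cos(2π(t − φ)/T) plus i.i.d. Gaussian noise (or
    multiplicative log-normal noise under ``noise_model='lognormal'``).
    Columns: ``feature, condition, zt, replicate, value``.  Values below a
    feature's detection floor are emitted as NaN.  Deterministic for a
    fixed config (including seed).
    """
    config.validate()
    counts = _replicate_counts(config)
    rows: list[tuple] = []
    for spec in config.features:
        rng = _feature_rng(config.seed, spec.feature_id)
        for cond in config.conditions:
            p = spec.params[cond]
            for zt in config.timepoints:
                n = counts[(cond, zt)]
                mu = _model_value(p, zt, config.period)
                if config.noise_model == "lognormal":
                    vals = mu * np.exp(rng.normal(0.0, spec.noise_sd, size=n))
                else:
                    vals = mu + rng.normal(0.0, spec.noise_sd, size=n)
                if spec.detection_floor is not None:
                    vals = np.where(vals < spec.detection_floor, np.nan, vals)
                for r, v in enumerate(vals, start=1):
                    rows.append((spec.feature_id, cond, zt, r, float(v)))
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def generate_ct_table(
    config: SimulationConfig,
    reference_spec: FeatureSpec,
    assay_offset: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, object]]:
    """Generate raw qPCR Ct values whose 2^–ΔΔCt readout matches the config.

    The reference gene's Ct per sample is its configured constant mean plus
    Gaussian noise (cycles).  The target Ct is built so that
    ΔCt = Ct_target − Ct_reference = offset − log2(model value) + noise,
    i.e. one extra cycle of ΔCt halves the implied expression.  Noise SDs
    are interpreted on the cycle scale here.  All configured model values
    must be strictly positive (expression scale).

    Returns the Ct table (columns ``feature, sample_id, condition, zt,
    ct_target, ct_reference``) and the baseline group flag — first
    configured condition at the earliest time point — that downstream
    normalization should use.

    A rhythmic reference gene is scientifically invalid but deliberately
    allowed (with a warning): normalizing to an oscillating reference is a
    failure mode worth simulating.
    """
    config.validate()
    reference_spec.validate()
    if any(p.rhythmic for p in reference_spec.params.values()):
        warnings.warn(
            f"reference gene {reference_spec.feature_id!r} is rhythmic; "
            "proceeding, but normalization to it will distort target profiles",
            UserWarning,
            stacklevel=2,
        )
    counts = _replicate_counts(config)
    ref_rng = _feature_rng(config.seed, "__reference__" + reference_spec.feature_id)
    rows: list[tuple] = []
    for spec in config.features:
        rng = _feature_rng(config.seed, "__ct__" + spec.feature_id)
        for cond in config.conditions:
            p = spec.params[cond]
            ref_p = reference_spec.params.get(cond) or next(iter(reference_spec.params.values()))
            for zt in config.timepoints:
                mu = _model_value(p, zt, config.period)
                if mu <= 0:
                    raise ConfigError(
                        f"feature {spec.feature_id!r}: model value {mu} at ZT{zt} "
                        "is not positive; Ct generation needs a positive expression scale"
                    )
                ref_mu = _model_value(ref_p, zt, config.period)
                for r in range(1, counts[(cond, zt)] + 1):
                    ct_ref = ref_mu + ref_rng.normal(0.0, reference_spec.noise_sd)
                    dct = assay_offset - math.log2(mu) + rng.normal(0.0, spec.noise_sd)
                    rows.append(
                        (
                            spec.feature_id,
                            f"{cond}_ZT{zt:g}_r{r}",
                            cond,
                            zt,
                            float(ct_ref + dct),
                            float(ct_ref),
                        )
                    )
    baseline = {"condition": config.conditions[0], "zt": min(config.timepoints)}
    return pd.DataFrame(rows, columns=CT_COLUMNS), baseline


def truth_table(config: SimulationConfig) -> pd.DataFrame:
    """One row of generating parameters per feature x condition.

    Values are copied verbatim from the config, never re-estimated; the
    ``rhythmic`` column holds the true label ("rhythmic"/"arrhythmic").
    """
    config.validate()
    rows = [
        (
            f.feature_id,
            cond,
            f.params[cond].mesor,
            f.params[cond].amplitude,
            f.params[cond].acrophase if f.params[cond].rhythmic else np.nan,
            "rhythmic" if f.params[cond].rhythmic else "arrhythmic",
        )
        for f in config.features
        for cond in config.conditions
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)
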