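"""End-to-end diurnal rhythmometry pipeline.

Orchestrates (optional) qPCR normalization → per-feature×condition cosinor
fits with rhythm calls → stratified-bootstrap parameter CIs → between-
condition comparison and rhythm-change classification, and produces the
flat per-feature report tables a study supplement would carry, plus
double-plot-ready summary series (first time point repeated one period
later so a cyclic profile closes).

Everything is deterministic for a fixed :class:`PipelineConfig`: per-
series bootstrap seeds are derived from the config seed and a stable hash
of the (feature, condition) pair, so adding a feature never perturbs the
draws of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import ND, bootstrap_params, classify_change, compare_conditions
from .cosinor import fit_cosinor
from .normalize import BaselineSpec, delta_delta_ct
from .synthetic import DATASET_COLUMNS

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "load_dataset",
    "fit_table",
    "comparison_table",
    "run_pipeline",
    "double_plot_series",
]

logger = logging.getLogger(__name__)

FIT_COLUMNS = [
    "feature",
    "condition",
    "n",
    "mesor",
    "amplitude",
    "acrophase",
    "period",
    "sse",
    "p_zero_amplitude",
    "call",
]
COMPARISON_COLUMNS = [
    "feature",
    "pair",
    "class",
    "delta_mesor",
    "dm_lo",
    "dm_hi",
    "amp_ratio",
    "ar_lo",
    "ar_hi",
    "delta_phi",
    "dp_lo",
    "dp_hi",
    "flags",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one analysis run.

    ``condition_pairs`` lists (reference, contrast) label pairs to compare
    — explicit, never inferred from column order, to rule out silent
    miscomparison.  ``baseline`` is only needed when the input is a raw Ct
    table to be normalized first.
    """

    period: float = 24.0
    alpha: float = 0.05
    B: int = 1000
    scheme: str = "stratified"
    seed: int = 0
    ci_level: float = 0.95
    condition_pairs: tuple[tuple[str, str], ...] = ()
    comparison_mode: str = "difference"
    baseline: BaselineSpec | None = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.ci_level < 1:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.period <= 0:
            raise ValueError(f"period must be > 0, got {self.period}")


@dataclass(frozen=True)
class PipelineResult:
    """Result bundle: cosinor table, comparison table, run manifest."""

    cosinor: pd.DataFrame
    comparisons: pd.DataFrame
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cosinor.to_csv(out / "cosinor.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def load_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format dataset CSV, naming bad lines."""
    raw = pd.read_csv(path, dtype=str)
    missing = set(DATASET_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = raw.copy()
    for col in ("zt", "value"):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(
                f"{path}, line {line}: non-numeric {col} value {raw.loc[bad.idxmax(), col]!r}"
            )
        out[col] = converted
    return out[DATASET_COLUMNS]


def _series_seed(seed: int, feature: str, condition: str) -> list[int]:
    digest = hashlib.sha256(f"{feature}|{condition}".encode("utf-8")).digest()
    return [int(seed), int.from_bytes(digest[:8], "little")]


def fit_table(
    dataset: pd.DataFrame, period: float = 24.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Cosinor fit + rhythm call for every feature × condition.

    Unfittable series are reported with ``call='nd'`` and NaN parameters —
    a feature is never dropped from the table.
    """
    rows = []
    for (feat, cond), grp in dataset.groupby(["feature", "condition"], sort=True):
        fit = fit_cosinor(
            grp["zt"].to_numpy(float), grp["value"].to_numpy(float), period, alpha
        )
        if fit.params is None:
            rows.append((feat, cond, fit.n, np.nan, np.nan, np.nan, period, np.nan, np.nan, fit.call))
        else:
            rows.append(
                (
                    feat,
                    cond,
                    fit.n,
                    fit.params.mesor,
                    fit.params.amplitude,
                    fit.params.acrophase if fit.params.phase_defined else 0.0,
                    period,
                    fit.sse_full,
                    fit.p_zero_amplitude,
                    fit.call,
                )
            )
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def comparison_table(
    dataset: pd.DataFrame,
    fits: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Between-condition comparison rows for every configured pair.

    Returns the table and per-series bootstrap redraw counters (kept in
    the manifest; structurally zero for the design-preserving schemes).
    """
    rows = []
    redraws: dict[str, int] = {}
    calls = fits.set_index(["feature", "condition"])["call"]
    for feat in fits["feature"].unique():
        sub = dataset[dataset["feature"] == feat]
        for ref, contrast in config.condition_pairs:
            pair_label = f"{contrast}_vs_{ref}"
            call_ref = calls.get((feat, ref), ND)
            call_con = calls.get((feat, contrast), ND)
            if call_ref == ND or call_con == ND:
                rows.append(
                    (feat, pair_label, "indeterminate", *[np.nan] * 9, "")
                )
                continue
            dists = {}
            for cond in (contrast, ref):
                g = sub[sub["condition"] == cond]
                dists[cond] = bootstrap_params(
                    g["zt"].to_numpy(float),
                    g["value"].to_numpy(float),
                    period=config.period,
                    B=config.B,
                    scheme=config.scheme,
                    seed=_series_seed(config.seed, feat, cond),
                    ci_level=config.ci_level,
                )
                redraws[f"{feat}|{cond}"] = dists[cond].n_redraws
            cmp = compare_conditions(
                dists[contrast],
                dists[ref],
                call_a=call_con,
                call_b=call_ref,
                level=config.ci_level,
                mode=config.comparison_mode,
            )
            # classify from the reference's perspective: ref -> contrast
            change = classify_change(call_ref, call_con, cmp.significant)
            flags = ";".join(k for k, v in cmp.significant.items() if v)
            ar = cmp.amplitude_ratio
            dp = cmp.delta_phi
            rows.append(
                (
                    feat,
                    pair_label,
                    change,
                    cmp.delta_mesor.point,
                    cmp.delta_mesor.lower,
                    cmp.delta_mesor.upper,
                    ar.point if ar else np.nan,
                    ar.lower if ar else np.nan,
                    ar.upper if ar else np.nan,
                    dp.point if dp else np.nan,
                    dp.lower if dp else np.nan,
                    dp.upper if dp else np.nan,
                    flags,
                )
            )
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS), redraws


def run_pipeline(
    config: PipelineConfig,
    dataset: pd.DataFrame | str | Path | None = None,
    ct_table: pd.DataFrame | str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a dataset or a raw Ct table.

    Exactly one of ``dataset`` / ``ct_table`` must be given; a Ct table is
    first normalized by 2^–ΔΔCt against ``config.baseline``.  The manifest
    snapshot of the configuration, seeds and redraw counters is sufficient
    to reproduce the tables byte for byte.
    """
    config.validate()
    if (dataset is None) == (ct_table is None):
        raise ValueError("provide exactly one of dataset / ct_table")
    if ct_table is not None:
        if config.baseline is None:
            raise ValueError("normalizing a Ct table requires config.baseline")
        if not isinstance(ct_table, pd.DataFrame):
            ct_table = pd.read_csv(ct_table)
        dataset = delta_delta_ct(ct_table, config.baseline)
    elif not isinstance(dataset, pd.DataFrame):
        dataset = load_dataset(dataset)

    known = set(dataset["condition"].unique())
    for pair in config.condition_pairs:
        for label in pair:
            if label not in known and not dataset.empty:
                raise ValueError(f"unknown condition label {label!r} in condition_pairs")
    if config.baseline is not None and not dataset.empty:
        if config.baseline.condition not in known:
            raise ValueError(
                f"unknown condition label {config.baseline.condition!r} in baseline"
            )

    fits = fit_table(dataset, config.period, config.alpha)
    comparisons, redraws = comparison_table(dataset, fits, config)
    for row in fits.itertuples(index=False):
        logger.info("fit %s/%s: call=%s", row.feature, row.condition, row.call)
    manifest = {
        "package": "rhythmkit",
        "version": __version__,
        "config": {
            **{
                k: (list(map(list, v)) if k == "condition_pairs" else v)
                for k, v in dataclasses.asdict(config).items()
                if k != "baseline"
            },
            "baseline": dataclasses.asdict(config.baseline) if config.baseline else None,
        },
        "n_records": int(len(dataset)),
        "bootstrap_redraws": redraws,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return PipelineResult(cosinor=fits, comparisons=comparisons, manifest=manifest)


def double_plot_series(dataset: pd.DataFrame, period: float = 24.0) -> pd.DataFrame:
    """Per-ZT mean ± SEM summaries, with the first time point double-plotted.

    For each feature × condition the earliest time point's summary is
    repeated at t + period so the cyclic profile plots as a closed curve.
    SEM is the sample SD (ddof=1) over √n; NaN for singleton groups.
    Rows are ordered by feature, condition, then time ascending.
    """
    if dataset.empty:
        return pd.DataFrame(columns=["feature", "condition", "zt", "mean", "sem", "n"])
    grouped = (
        dataset.dropna(subset=["value"])
        .groupby(["feature", "condition", "zt"], sort=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    grouped["sem"] = grouped["sd"] / np.sqrt(grouped["n"])
    grouped = grouped.drop(columns="sd")
    pieces = [grouped]
    firsts = grouped.loc[
        grouped.groupby(["feature", "condition"])["zt"].transform("min") == grouped["zt"]
    ].copy()
    firsts["zt"] = firsts["zt"] + period
    pieces.append(firsts)
    out = (
        pd.concat(pieces, ignore_index=True)
        .sort_values(["feature", "condition", "zt"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out[["feature", "condition", "zt", "mean", "sem", "n"]]
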