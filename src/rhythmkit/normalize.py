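"""Comparative-threshold-cycle (2^–ΔΔCt) qPCR normalization.

Converts raw Ct tables to relative expression with a designated reference
gene and baseline group, following the Livak formulation: per sample,
ΔCt = Ct(target) − Ct(reference); ΔΔCt subtracts the arithmetic mean ΔCt
of the baseline group of the same feature; expression = 2^(−ΔΔCt).  With
arithmetic averaging on the ΔCt (log) scale, the *geometric* mean of the
baseline group's relative expression is exactly 1.

Amplification efficiency is fixed at 2 (one Ct cycle = one doubling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CT_COLUMNS, DATASET_COLUMNS

__all__ = ["BaselineSpec", "delta_delta_ct", "rescale_relative"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaselineSpec:
    """The calibrator group: one condition at one zeitgeber time.

    E.g. control diet at ZT3 — the group every relative expression value
    is expressed against.
    """

    condition: str
    zt: float

    def mask(self, frame: pd.DataFrame) -> pd.Series:
        return (frame["condition"] == self.condition) & (
            np.isclose(frame["zt"].astype(float), self.zt)
        )


def delta_delta_ct(records: pd.DataFrame, baseline: BaselineSpec) -> pd.DataFrame:
    """Relative expression from a raw Ct table via 2^–ΔΔCt.

    Parameters
    ----------
    records
        Ct table with columns ``feature, sample_id, condition, zt,
        ct_target, ct_reference``.  Rows with a missing target or
        reference Ct are rejected (logged by sample id), not imputed.
    baseline
        Calibrator group; must be non-empty for every feature.

    Returns
    -------
    Long-format dataset (``feature, condition, zt, replicate, value``)
    where value = 2^(−ΔΔCt).  Within each feature the baseline group's
    geometric mean is 1 by construction.
    """
    missing = set(CT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"Ct table lacks column(s): {sorted(missing)}")
    records = records.copy()
    bad = records["ct_target"].isna() | records["ct_reference"].isna()
    if bad.any():
        for sid in records.loc[bad, "sample_id"]:
            logger.warning("rejecting Ct record %s: missing target or reference Ct", sid)
        records = records.loc[~bad]

    records["_dct"] = records["ct_target"].astype(float) - records["ct_reference"].astype(float)
    out_rows = []
    for feat, grp in records.groupby("feature", sort=False):
        base = grp.loc[baseline.mask(grp), "_dct"]
        if base.empty:
            raise ValueError(
                f"empty baseline group ({baseline.condition} at ZT{baseline.zt:g}) "
                f"for feature {feat!r}"
            )
        ddct = grp["_dct"] - base.mean()
        expr = np.power(2.0, -ddct)
        sub = pd.DataFrame(
            {
                "feature": feat,
                "condition": grp["condition"].to_numpy(),
                "zt": grp["zt"].astype(float).to_numpy(),
                "replicate": grp.groupby(["condition", "zt"]).cumcount().to_numpy() + 1,
                "value": expr.to_numpy(),
            }
        )
        out_rows.append(sub)
    if not out_rows:
        return pd.DataFrame(columns=DATASET_COLUMNS)
    return pd.concat(out_rows, ignore_index=True)[DATASET_COLUMNS]


def rescale_relative(dataset: pd.DataFrame, baseline: BaselineSpec) -> pd.DataFrame:
    """Express every value relative to its feature's baseline-group mean.

    Divides each feature's values by the arithmetic mean of that feature's
    baseline group, so the baseline group averages 1.  Idempotent:
    rescaling an already-rescaled dataset changes nothing.
    """
    out = dataset.copy()
    for feat, grp in dataset.groupby("feature", sort=False):
        base = grp.loc[baseline.mask(grp), "value"]
        if base.empty:
            raise ValueError(
                f"empty baseline group ({baseline.condition} at ZT{baseline.zt:g}) "
                f"for feature {feat!r}"
            )
        mean = base.mean()
        if mean == 0 or not np.isfinite(mean):
            raise ValueError(
                f"baseline mean for feature {feat!r} is {mean}; rescaling undefined"
            )
        out.loc[grp.index, "value"] = grp["value"] / mean
    return out
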