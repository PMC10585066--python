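"""Composite physiological thermotolerance index.

For each cultivar the after/before stress ratios of Fv/Fm, root weight and
shoot weight, and the mean leaf wilting index (LWI), are z-scored across
cultivars; the unweighted mean of the four z-scores is the composite index.
The cultivar with the highest total is labeled most tolerant, the lowest
most sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError, validate_physio_table

__all__ = ["PhysioIndex", "parameter_ratios", "zscore_across", "composite_index"]

RATIO_PARAMS = ("ratio_fvfm", "ratio_root", "ratio_shoot", "lwi_mean")

_RATIO_PAIRS = {
    "ratio_fvfm": ("fvfm_after", "fvfm_before"),
    "ratio_root": ("root_wt_after_g", "root_wt_before_g"),
    "ratio_shoot": ("shoot_wt_after_g", "shoot_wt_before_g"),
}


@dataclass
class PhysioIndex:
    ratios: pd.DataFrame    # cultivar x (ratio_fvfm, ratio_root, ratio_shoot, lwi_mean)
    zscores: pd.DataFrame   # same shape, z across cultivars per parameter
    total: pd.Series        # mean of the four z-scores per cultivar
    ranking: list           # cultivars by total descending, lexicographic ties

    @property
    def most_tolerant(self) -> str:
        return self.ranking[0]

    @property
    def most_sensitive(self) -> str:
        return self.ranking[-1]


def parameter_ratios(physio: pd.DataFrame) -> pd.DataFrame:
    """After/before ratios of replicate means per cultivar; LWI as replicate mean."""
    physio = validate_physio_table(physio)
    means = physio.groupby(["cultivar", "parameter"])["value"].mean().unstack()
    out = pd.DataFrame(index=means.index)
    for ratio_name, (after, before) in _RATIO_PAIRS.items():
        if (means[before] <= 0).any():
            bad = means.index[means[before] <= 0][0]
            raise ValidationError(
                f"cultivar {bad!r}: non-positive before-stress mean for {before!r}"
            )
        out[ratio_name] = means[after] / means[before]
    out["lwi_mean"] = means["lwi"]
    out.index.name = "cultivar"
    return out


def zscore_across(values: pd.Series, ddof: int = 1) -> pd.Series:
    """z-scores of per-cultivar values: (x - mean) / SD with the given ddof."""
    if len(values) < 2:
        raise ValidationError("need >= 2 cultivars for a z-score")
    sd = values.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError(f"degenerate parameter: zero variance across cultivars")
    return (values - values.mean()) / sd


def composite_index(ratios: pd.DataFrame, ddof: int = 1) -> PhysioIndex:
    """z-score each of the four parameters across cultivars, average, rank."""
    missing = set(RATIO_PARAMS) - set(ratios.columns)
    if missing:
        raise ValidationError(f"missing parameter column(s): {sorted(missing)}")
    z = pd.DataFrame({p: zscore_across(ratios[p], ddof=ddof) for p in RATIO_PARAMS})
    total = z.mean(axis=1)
    ranking = sorted(total.index, key=lambda c: (-total[c], c))
    return PhysioIndex(ratios=ratios, zscores=z, total=total, ranking=ranking)
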