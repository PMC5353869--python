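"""Sample-associated exon selection via Z-normalized splicing profiles.

Each exon's log I/S ratios e_1..e_n across the n samples of an analysis
context are normalized to Z-scores z_i = (e_i - mean)/s with the sample
(n-1 denominator) standard deviation s.  An exon is associated with sample i
as HIGH when z_i >= z_high (default 1.5) and as LOW when z_i <= z_low
(default -1.5); exons with zero variance are uninformative and never selected
(they remain members of the cassette population for the overlap tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correspondence import AssociatedExonSet
from .errors import ConfigurationError, DomainError
from .splicing_quant import IsRatioMatrix

__all__ = [
    "ZScoreProfile",
    "AssociationConfig",
    "zscore_profile",
    "zscore_matrix",
    "select_associated",
]


@dataclass(frozen=True)
class ZScoreProfile:
    exon_id: str
    z: np.ndarray
    mean: float
    sd: float

    @property
    def uninformative(self) -> bool:
        return self.sd == 0.0


@dataclass(frozen=True)
class AssociationConfig:
    """Selection thresholds; comparisons are inclusive (>= / <=)."""

    z_high: float = 1.5
    z_low: float = -1.5

    def __post_init__(self):
        if not (self.z_high > 0 > self.z_low):
            raise ConfigurationError("need z_high > 0 > z_low")


def zscore_profile(series, exon_id: str = "") -> ZScoreProfile:
    """Normalize one ratio series to Z-scores (n-1 denominator sd)."""
    e = np.asarray(series, dtype=float)
    if len(e) < 2:
        raise DomainError("need at least 2 samples to normalize")
    mean = float(e.mean())
    sd = float(e.std(ddof=1))
    if sd == 0.0:
        return ZScoreProfile(exon_id=exon_id, z=np.full(len(e), np.nan), mean=mean, sd=0.0)
    return ZScoreProfile(exon_id=exon_id, z=(e - mean) / sd, mean=mean, sd=sd)


def zscore_matrix(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise Z-scores of an exon x sample matrix.

    Returns (z, uninformative) where z has NaN rows for zero-variance exons and
    ``uninformative`` is the boolean row mask.
    """
    if values.shape[1] < 2:
        raise DomainError("need at least 2 samples to normalize")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[flat] = np.nan
    return (
        pd.DataFrame(z, index=values.index, columns=values.columns),
        pd.Series(flat, index=values.index, name="uninformative"),
    )


def select_associated(
    matrix: IsRatioMatrix | pd.DataFrame,
    config: AssociationConfig = AssociationConfig(),
) -> list[AssociatedExonSet]:
    """Associated-exon sets, one per sample (column) of the ratio matrix.

    Z-scores are computed across exactly the samples present in the matrix, so
    the caller controls the analysis context (stage-only, tissue/cell-only or
    pooled) by what it passes in.
    """
    values = matrix.values if isinstance(matrix, IsRatioMatrix) else matrix
    z, flat = zscore_matrix(values)
    zv = z.to_numpy()
    out = []
    for j, sample in enumerate(values.columns):
        col = zv[:, j]
        with np.errstate(invalid="ignore"):
            high = (col >= config.z_high) & ~flat.to_numpy()
            low = (col <= config.z_low) & ~flat.to_numpy()
        members = {(e, "HIGH") for e in values.index[high]} | {
            (e, "LOW") for e in values.index[low]
        }
        out.append(AssociatedExonSet(sample_id=str(sample), members=frozenset(members)))
    return out
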