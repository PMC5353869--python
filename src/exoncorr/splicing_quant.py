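"""Inclusion/skipping quantification: I/S ratios, cassette filter, LOESS smoothing.

The splicing level of a cassette exon in one sample is the log ratio of the
expression (FPKM) of its inclusion pseudo-transcript to its skipping
pseudo-transcript, each offset by one:

    e = ln((FPKM_I + 1) / (FPKM_S + 1))

Exons whose inclusion or skipping transcript is never expressed in any sample
are not alternatively spliced and are removed (cassette filter).  Because
splicing dynamics change smoothly along development, the stage-ordered series
of each exon is smoothed with a local polynomial (LOESS) before associated
exons are selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CompletenessError, ConfigurationError, DomainError

__all__ = [
    "SmootherConfig",
    "IsRatioMatrix",
    "compute_is_ratio",
    "cassette_filter",
    "loess_smooth",
    "loess_hat_matrix",
    "build_ratio_matrix",
    "load_fpkm_table",
    "load_sample_table",
]

logger = logging.getLogger(__name__)


def compute_is_ratio(fpkm_i, fpkm_s):
    """Natural-log inclusion/skipping ratio ln((FPKM_I + 1)/(FPKM_S + 1)).

    Accepts scalars or arrays; inputs must be finite and non-negative.
    Positive iff the inclusion transcript is the more expressed one.
    """
    i = np.asarray(fpkm_i, dtype=float)
    s = np.asarray(fpkm_s, dtype=float)
    if not (np.all(np.isfinite(i)) and np.all(np.isfinite(s))):
        raise DomainError("FPKM values must be finite")
    if np.any(i < 0) or np.any(s < 0):
        raise DomainError("FPKM values must be non-negative")
    out = np.log1p(i) - np.log1p(s)
    return float(out) if np.isscalar(fpkm_i) and np.isscalar(fpkm_s) else out


def cassette_filter(quants: pd.DataFrame) -> list[str]:
    """Exon IDs whose inclusion AND skipping transcripts are each expressed somewhere.

    ``quants`` is the long table (exon_id, sample_id, fpkm_I, fpkm_S); every
    exon must have a row for every sample.  An exon is retained iff
    max_s fpkm_I > 0 and max_s fpkm_S > 0 (not necessarily in the same sample).
    """
    counts = quants.groupby("exon_id")["sample_id"].nunique()
    n_samples = quants["sample_id"].nunique()
    incomplete = counts[counts != n_samples]
    if len(incomplete):
        raise CompletenessError(
            f"exon '{incomplete.index[0]}' has {incomplete.iloc[0]} of {n_samples} samples"
        )
    g = quants.groupby("exon_id")[["fpkm_I", "fpkm_S"]].max()
    keep = g[(g["fpkm_I"] > 0) & (g["fpkm_S"] > 0)]
    return sorted(keep.index)


@dataclass(frozen=True)
class SmootherConfig:
    """Local-polynomial smoother settings (tricube kernel).

    ``span`` is the fraction of points in each local neighborhood (default 0.3,
    the value used throughout the stage analyses); ``degree`` the local
    polynomial degree (2 by default, i.e. local quadratics).
    """

    span: float = 0.3
    degree: int = 2

    def __post_init__(self):
        if not (0.0 < self.span <= 1.0):
            raise ConfigurationError("span must lie in (0, 1]")
        if self.degree not in (1, 2):
            raise ConfigurationError("degree must be 1 or 2")


def loess_hat_matrix(n: int, config: SmootherConfig) -> np.ndarray:
    """The n x n linear smoother matrix L with y_hat = L @ y on x = 1..n.

    For each target point, the q = max(degree+1, floor(span*n)) nearest
    neighbors receive tricube weights w = (1 - (d/d_max)^3)^3 and a weighted
    polynomial is fit; the fitted value at the target is a linear functional of
    y, collected as one row of L.  Because all exon series share the stage
    grid, smoothing a whole matrix is a single matrix product.  If a
    neighborhood has fewer than degree+1 points with positive weight it is
    widened until the local fit is well-posed.
    """
    q0 = max(config.degree + 1, int(np.floor(config.span * n)))
    x = np.arange(1, n + 1, dtype=float)
    hat = np.zeros((n, n))
    for t in range(n):
        q = min(q0, n)
        while True:
            d = np.abs(x - x[t])
            d_max = np.sort(d)[q - 1]
            if d_max == 0:
                w = np.where(d == 0, 1.0, 0.0)
            else:
                w = np.clip(1 - (d / d_max) ** 3, 0, None) ** 3
            if np.count_nonzero(w) >= config.degree + 1 or q >= n:
                break
            q += 1
        if np.count_nonzero(w) < config.degree + 1:
            w = np.ones(n)  # degenerate tiny series: global fit
        basis = np.vander(x - x[t], N=config.degree + 1, increasing=True)
        wb = basis * w[:, None]
        # fitted value at the target = e0^T (B^T W B)^{-1} B^T W y
        gram = basis.T @ wb
        coef_map = np.linalg.solve(gram, wb.T)
        hat[t] = coef_map[0]
    return hat


def loess_smooth(series, config: SmootherConfig = SmootherConfig()) -> np.ndarray:
    """LOESS-smooth one stage-ordered series (x = stage ranks 1..n).

    Series shorter than degree+2 are returned unchanged with a warning.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < config.degree + 2:
        logger.warning("series of length %d too short to smooth; returned unchanged", n)
        return y.copy()
    return loess_hat_matrix(n, config) @ y


@dataclass
class IsRatioMatrix:
    """Exon x sample matrix of log I/S ratios with sample-class metadata."""

    values: pd.DataFrame  # index exon_id, columns sample_id
    sample_class: dict[str, str]  # sample_id -> "stage" | "tissue" | "cell"
    stage_order: list[str] = field(default_factory=list)  # stage samples, chronological

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise DomainError("ratio matrix contains non-finite entries")
        has_stage = any(c == "stage" for c in self.sample_class.values())
        if has_stage and not self.stage_order:
            raise ConfigurationError("stage samples present but no stage_order given")

    @property
    def exon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def build_ratio_matrix(
    quants: pd.DataFrame,
    sample_metadata: pd.DataFrame,
    smoother: SmootherConfig | None = SmootherConfig(),
) -> IsRatioMatrix:
    """Build the (smoothed) ratio matrix from per-exon FPKM quantifications.

    ``quants``: long table (exon_id, sample_id, fpkm_I, fpkm_S), already
    cassette-filtered.  ``sample_metadata``: (sample_id, class, stage_rank).
    Smoothing is applied to the stage-ordered block only — tissue/cell samples
    carry no time axis and are left as computed.  Pass ``smoother=None`` to
    skip smoothing entirely.
    """
    dup = quants.duplicated(subset=["exon_id", "sample_id"])
    if dup.any():
        row = quants[dup].iloc[0]
        raise CompletenessError(
            f"duplicate quantification for exon '{row['exon_id']}' sample '{row['sample_id']}'"
        )
    ratios = quants.assign(
        ratio=compute_is_ratio(quants["fpkm_I"].to_numpy(), quants["fpkm_S"].to_numpy())
    )
    mat = ratios.pivot(index="exon_id", columns="sample_id", values="ratio")
    if mat.isna().any().any():
        exon = mat.index[mat.isna().any(axis=1)][0]
        raise CompletenessError(f"exon '{exon}' missing samples")

    meta = sample_metadata.set_index("sample_id")
    missing = [s for s in mat.columns if s not in meta.index]
    if missing:
        raise CompletenessError(f"sample '{missing[0]}' missing from sample metadata")
    sample_class = {s: str(meta.loc[s, "class"]) for s in mat.columns}
    stage_samples = [s for s in mat.columns if sample_class[s] == "stage"]
    stage_order = sorted(stage_samples, key=lambda s: float(meta.loc[s, "stage_rank"]))

    if smoother is not None and stage_order:
        n = len(stage_order)
        if n >= smoother.degree + 2:
            hat = loess_hat_matrix(n, smoother)
            block = mat[stage_order].to_numpy()
            mat.loc[:, stage_order] = block @ hat.T
        else:
            logger.warning("only %d stage samples; smoothing skipped", n)

    ordered_cols = stage_order + [s for s in mat.columns if sample_class[s] != "stage"]
    mat = mat[ordered_cols].sort_index()
    return IsRatioMatrix(values=mat, sample_class=sample_class, stage_order=stage_order)


def load_fpkm_table(path: str | Path) -> pd.DataFrame:
    """Read the long FPKM TSV (exon_id, sample_id, fpkm_I, fpkm_S)."""
    df = pd.read_csv(path, sep="\t")
    required = {"exon_id", "sample_id", "fpkm_I", "fpkm_S"}
    if not required <= set(df.columns):
        raise CompletenessError(f"FPKM table missing columns {required - set(df.columns)}")
    return df


def load_sample_table(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, class, stage_rank)."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "class"} <= set(df.columns):
        raise CompletenessError("sample table needs sample_id and class columns")
    if "stage_rank" not in df.columns:
        df["stage_rank"] = np.nan
    return df
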