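"""Methylation matrices, the β↔M transform, and probe-level filtering.

β-values are methylation proportions in (0, 1); M-values are their log2
odds, M = log2(β / (1 − β)).  M-values are approximately homoscedastic and
are the scale on which the Gaussian models operate.  Filtering removes
probes on sex chromosomes, probes within a configurable distance of a known
SNP (whose apparent "inheritance" is a hybridisation artefact), and probes
that fail detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "FilterReport",
    "beta_to_m",
    "m_to_beta",
    "load_matrix",
    "load_annotation",
    "filter_probes",
]

BETA_EPS = 1e-6
_SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


def beta_to_m(beta, eps: float = BETA_EPS):
    """Logit-2 transform of methylation proportions.

    Values at or beyond the open interval (0, 1) are clipped to
    [eps, 1 − eps] first; non-finite input raises.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta values must be finite")
    clipped = np.clip(beta, eps, 1.0 - eps)
    m = np.log2(clipped / (1.0 - clipped))
    return m if m.ndim else float(m)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: β = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("M-values must be finite")
    beta = 1.0 / (1.0 + np.exp2(-m))
    return beta if beta.ndim else float(beta)


@dataclass
class MethylationMatrix:
    """Probes × samples matrix with an explicit scale ('beta' or 'm')."""

    values: pd.DataFrame  # index = probe ids, columns = sample ids
    scale: Literal["beta", "m"] = "m"

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise ValueError(
                f"missing methylation values are not supported; first probes: {bad[:5]}"
            )
        if self.scale not in ("beta", "m"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_m(self) -> "MethylationMatrix":
        if self.scale == "m":
            return self
        return MethylationMatrix(
            values=pd.DataFrame(
                beta_to_m(self.values.to_numpy()),
                index=self.values.index,
                columns=self.values.columns,
            ),
            scale="m",
        )

    def site(self, probe_id: str, sample_ids=None) -> np.ndarray:
        row = self.values.loc[probe_id]
        if sample_ids is not None:
            row = row[list(sample_ids)]
        return row.to_numpy(dtype=float)


def load_matrix(path: str | Path, scale: Literal["beta", "m"]) -> MethylationMatrix:
    """Read a TSV matrix: first column probe ids, header row sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return MethylationMatrix(values=df, scale=scale)


def load_annotation(path: str | Path) -> pd.DataFrame:
    """Read the probe annotation TSV (probe_id, chr, pos, snp_distance[, detection_fail])."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chr": str})
    required = {"probe_id", "chr", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"annotation missing columns: {sorted(required - set(df.columns))}"
        )
    if (df["pos"] <= 0).any():
        raise ValueError("annotation positions must be 1-based positive")
    return df.set_index("probe_id")


@dataclass
class FilterReport:
    """Counts of probes removed per reason (a probe counts once, at the
    first rule that removes it: SNP proximity, then sex chromosome, then
    detection failure)."""

    n_input: int = 0
    n_retained: int = 0
    removed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.removed = dict(self.removed)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def filter_probes(
    matrix: MethylationMatrix,
    annotations: pd.DataFrame,
    snp_bp: int = 10,
    drop_sex: bool = True,
    detection_threshold: float = 0.05,
    detection_policy: Literal["any-sample", "mean", "fraction"] = "any-sample",
    detection_pvalues: pd.DataFrame | None = None,
    detection_fraction: float = 0.05,
) -> tuple[MethylationMatrix, FilterReport]:
    """Apply the probe exclusions used before screening.

    Removes probes with ``snp_distance <= snp_bp`` (inclusive: a SNP *within*
    N bp includes distance exactly N), probes on X/Y when ``drop_sex``, and
    probes whose detection p-values exceed ``detection_threshold`` under the
    chosen aggregation policy.  Probe order is preserved.
    """
    probe_ids = matrix.probe_ids
    missing = [p for p in probe_ids if p not in annotations.index]
    if missing:
        raise ValueError(f"probes without annotation: {missing[:10]}" +
                         (f" (+{len(missing)-10} more)" if len(missing) > 10 else ""))
    ann = annotations.loc[probe_ids]

    removed: dict[str, int] = {}
    drop = pd.Series(False, index=probe_ids)

    if "snp_distance" in ann.columns:
        near = ann["snp_distance"].notna() & (ann["snp_distance"] <= snp_bp)
        removed["snp"] = int((near & ~drop).sum())
        drop |= near

    if drop_sex:
        on_sex = ann["chr"].isin(_SEX_CHROMS)
        removed["sex"] = int((on_sex & ~drop).sum())
        drop |= on_sex

    if detection_pvalues is not None:
        det = detection_pvalues.loc[probe_ids]
        exceeds = det.to_numpy() > detection_threshold
        if detection_policy == "any-sample":
            fails = exceeds.any(axis=1)
        elif detection_policy == "mean":
            fails = det.to_numpy().mean(axis=1) > detection_threshold
        elif detection_policy == "fraction":
            fails = exceeds.mean(axis=1) > detection_fraction
        else:
            raise ValueError(f"unknown detection policy {detection_policy!r}")
        fails = pd.Series(fails, index=probe_ids)
        removed["detection"] = int((fails & ~drop).sum())
        drop |= fails
    elif "detection_fail" in ann.columns:
        fails = ann["detection_fail"].fillna(False).astype(bool)
        removed["detection"] = int((fails & ~drop).sum())
        drop |= fails

    keep = [p for p in probe_ids if not drop[p]]
    out = MethylationMatrix(values=matrix.values.loc[keep], scale=matrix.scale)
    report = FilterReport(
        n_input=len(probe_ids),
        n_retained=len(keep),
        removed={k: v for k, v in removed.items() if v},
    )
    return out, report
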