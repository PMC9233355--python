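"""Pooled-sequencing noise model for allele-frequency tracks.

Sequencing a pool re-estimates each locus's allele frequency from a finite
number of reads. This module models that at the read-count level: per-locus
depth is fixed or Poisson around a mean, and the alt-read count is binomial
in the error-perturbed allele frequency p' = AF*(1-e) + (1-AF)*e, where e is
the per-read allele error rate. Read simulation, alignment and variant
calling are deliberately abstracted away; the model isolates the sampling
and error components of pool sequencing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

READ_COUNT_COLUMNS = ["chrom", "pos_bp", "depth", "alt_count"]


@dataclass
class PoolSeqConfig:
    """Pool-sequencing sampling parameters.

    mean_depth: expected reads per locus.
    depth_model: 'fixed' (every locus at mean_depth) or 'poisson'.
    error_rate: per-read probability of reporting the other allele; < 0.5.
    min_depth: loci sequenced below this depth are dropped at AF estimation.
    """

    mean_depth: float = 50.0
    depth_model: Literal["fixed", "poisson"] = "poisson"
    error_rate: float = 0.001
    min_depth: int = 1

    def __post_init__(self) -> None:
        if self.mean_depth < 1:
            raise ValueError("mean depth must be >= 1")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")
        if self.depth_model not in ("fixed", "poisson"):
            raise ValueError(f"unknown depth model {self.depth_model!r}")
        if self.min_depth < 1:
            raise ValueError("min depth must be >= 1")


def simulate_read_counts(
    af: pd.DataFrame, cfg: PoolSeqConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-locus read depths and alt-allele read counts.

    Depth is fixed or Poisson(mean_depth); the alt count at a locus with true
    allele frequency AF is Binomial(depth, AF*(1-e) + (1-AF)*e).
    """
    p = af["af"].to_numpy(float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    n = len(p)
    if cfg.depth_model == "fixed":
        depth = np.full(n, int(round(cfg.mean_depth)), dtype=np.int64)
    else:
        depth = rng.poisson(cfg.mean_depth, size=n)
    e = cfg.error_rate
    p_seq = p * (1.0 - e) + (1.0 - p) * e
    alt = rng.binomial(depth, p_seq)
    out = af[["chrom", "pos_bp"]].copy()
    out["depth"] = depth
    out["alt_count"] = alt
    return out


def estimate_af_from_counts(
    rc: pd.DataFrame, min_depth: int = 1
) -> tuple[pd.DataFrame, dict]:
    """Allele frequencies from read counts; returns (AF track, filter report).

    AF = alt_count / depth. Loci below min_depth (zero-depth loci always)
    are dropped and counted in the report.
    """
    depth = rc["depth"].to_numpy()
    floor = max(int(min_depth), 1)
    keep = depth >= floor
    n_zero = int((depth == 0).sum())
    if n_zero and min_depth <= 1:
        warnings.warn(f"{n_zero} zero-depth locus(loci) dropped", stacklevel=2)
    kept = rc.loc[keep]
    out = kept[["chrom", "pos_bp"]].copy()
    out["af"] = kept["alt_count"].to_numpy(float) / kept["depth"].to_numpy(float)
    report = {
        "input": len(rc),
        "dropped_low_depth": int((~keep).sum()),
        "retained": len(out),
    }
    return out.reset_index(drop=True), report
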