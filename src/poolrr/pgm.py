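"""Pool genetic map (PGM) construction from a pooled allele-frequency track.

The core statistic of the method: for each pair of physically adjacent
polymorphic loci M1, M2 the factor

    K = |AF(M1) - AF(M2)| / log10(dist_bp(M1, M2))

relates the local allele-frequency deviation, created by recombination and
drift in the segregating pool, to the physical distance separating the loci.
Accumulating K along each chromosome yields the raw pool genetic map; its
absolute scale is meaningless until calibrated (see poolrr.adjust).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

K_COLUMNS = ["chrom", "left_bp", "right_bp", "delta_af", "dist_bp", "k"]
POOLMAP_COLUMNS = ["chrom", "pos_bp", "map_pos"]


class FilterError(ValueError):
    """Raised when marker filtering leaves nothing to map."""


@dataclass
class FilterReport:
    """Counts of markers removed per filter reason."""

    input: int
    monomorphic: int = 0
    duplicated_bp: int = 0
    missing_bp: int = 0
    high_missing: int = 0
    low_maf: int = 0

    @property
    def retained(self) -> int:
        return (
            self.input
            - self.monomorphic
            - self.duplicated_bp
            - self.missing_bp
            - self.high_missing
            - self.low_maf
        )

    def dominating(self) -> str:
        reasons = {
            "monomorphic": self.monomorphic,
            "duplicated_bp": self.duplicated_bp,
            "missing_bp": self.missing_bp,
            "high_missing": self.high_missing,
            "low_maf": self.low_maf,
        }
        return max(reasons, key=reasons.get)  # type: ignore[arg-type]


def filter_markers(
    af: pd.DataFrame,
    max_missing: float = 0.10,
    min_maf: float = 0.0,
    drop_monomorphic: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the standard marker filters to an allele-frequency track.

    Removes monomorphic loci (AF exactly 0 or 1), loci with missing or
    duplicated physical positions (all copies of a duplicated position are
    dropped), loci whose missing fraction strictly exceeds max_missing, and
    loci below a minor-allele-frequency floor. Returns the surviving track
    (sorted by chrom, pos_bp) and a per-reason count report.
    """
    report = FilterReport(input=len(af))
    df = af.copy()

    no_pos = df["pos_bp"].isna()
    report.missing_bp = int(no_pos.sum())
    df = df.loc[~no_pos]

    dup = df.duplicated(subset=["chrom", "pos_bp"], keep=False)
    report.duplicated_bp = int(dup.sum())
    df = df.loc[~dup]

    if drop_monomorphic:
        mono = (df["af"] <= 0.0) | (df["af"] >= 1.0)
        report.monomorphic = int(mono.sum())
        df = df.loc[~mono]

    if "missing_frac" in df.columns:
        high = df["missing_frac"].fillna(0.0) > max_missing  # strict >
        report.high_missing = int(high.sum())
        df = df.loc[~high]

    if min_maf > 0.0:
        maf = np.minimum(df["af"], 1.0 - df["af"])
        low = maf < min_maf
        report.low_maf = int(low.sum())
        df = df.loc[~low]

    if len(df) == 0:
        raise FilterError(
            f"no markers survive filtering (dominating filter: {report.dominating()})"
        )
    df = df.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
    return df, report


def compute_k(af: pd.DataFrame, min_dist_bp: int = 2) -> pd.DataFrame:
    """K factors for physically adjacent marker pairs, per chromosome.

    K = |dAF| / log10(d_bp). Pairs closer than min_dist_bp are dropped (a
    1 bp pair would make log10 non-positive); the count of dropped pairs is
    attached as DataFrame attribute 'n_dropped_close'. Pairs never span
    chromosome boundaries.
    """
    if min_dist_bp < 2:
        raise ValueError("min_dist_bp must be >= 2 to keep log10(dist) positive")
    frames = []
    n_dropped = 0
    for chrom, grp in af.groupby("chrom", sort=False):
        bp = grp["pos_bp"].to_numpy(np.int64)
        a = grp["af"].to_numpy(float)
        if len(bp) < 2:
            continue
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"track not sorted/unique on {chrom}; filter first")
        dist = np.diff(bp)
        daf = np.abs(np.diff(a))
        ok = dist >= min_dist_bp
        n_dropped += int((~ok).sum())
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "left_bp": bp[:-1][ok],
                    "right_bp": bp[1:][ok],
                    "delta_af": daf[ok],
                    "dist_bp": dist[ok],
                    "k": daf[ok] / np.log10(dist[ok]),
                }
            )
        )
    if not frames:
        raise ValueError("no chromosome has two or more markers")
    pairs = pd.concat(frames, ignore_index=True)
    pairs.attrs["n_dropped_close"] = n_dropped
    return pairs


def build_pgm(
    pairs: pd.DataFrame,
    use_adjusted: bool = False,
    af_track: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cumulate K along each chromosome into a pool genetic map.

    Marker j's map position is the sum of K over pairs to its left on the
    chromosome; each chromosome starts at 0. With use_adjusted=True the
    calibrated column 'k_adj' is cumulated instead (after apply_adjustment),
    giving positions in cM. If the source allele-frequency track is passed,
    chromosomes that contributed no pairs (single-marker chromosomes) are
    kept as zero-length maps.
    """
    col = "k_adj" if use_adjusted else "k"
    if use_adjusted and "k_adj" not in pairs.columns:
        raise ValueError("pairs carry no adjusted K; run apply_adjustment first")
    frames = []
    for chrom, grp in pairs.groupby("chrom", sort=False):
        bp = np.concatenate([[grp["left_bp"].iloc[0]], grp["right_bp"].to_numpy()])
        pos = np.concatenate([[0.0], np.cumsum(grp[col].to_numpy(float))])
        frames.append(pd.DataFrame({"chrom": chrom, "pos_bp": bp, "map_pos": pos}))
    if af_track is not None:
        paired = set(pairs["chrom"].unique())
        for chrom, grp in af_track.groupby("chrom", sort=False):
            if chrom not in paired:
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos_bp": grp["pos_bp"].to_numpy(np.int64),
                            "map_pos": 0.0,
                        }
                    )
                )
    pgm = pd.concat(frames, ignore_index=True)
    return pgm


def map_length(pool_map: pd.DataFrame, per_chromosome: bool = False):
    """Genome (or per-chromosome) length of a map as the sum of chromosome ends."""
    ends = pool_map.groupby("chrom", sort=False)["map_pos"].max()
    if per_chromosome:
        return ends
    return float(ends.sum())
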