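"""Readers and writers for the package's tab-separated formats and VCF input.

All TSV outputs begin with '#'-prefixed comment lines recording the tool
version, the command line and the seed, followed by a mandatory column
header. Physical coordinates are 1-based throughout (as in VCF); the
optional BED export of windows is 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised for malformed input files."""


def _version() -> str:
    from . import __version__

    return __version__


def _header_lines(meta: dict | None) -> list[str]:
    lines = [f"# poolrr {_version()}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    return lines


def _write_tsv(df: pd.DataFrame, path, meta: dict | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # malformed / empty file
        raise FormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing column header(s) {missing}; "
            "a tab-separated header line is mandatory"
        )
    return df


def _check_unique_positions(df: pd.DataFrame, path) -> None:
    dup = df.duplicated(subset=["chrom", "pos_bp"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicated position {row['chrom']}:{int(row['pos_bp'])}"
        )


def write_map_tsv(gmap: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a genetic map (true map 'cM' or pool/Haldane map 'map_pos')."""
    pos_col = "cM" if "cM" in gmap.columns else "map_pos"
    _write_tsv(gmap[["chrom", "pos_bp", pos_col]], path, meta)


def read_map_tsv(path) -> pd.DataFrame:
    """Read a genetic map TSV; accepts a 'cM' or 'map_pos' genetic column.

    Errors on duplicated positions and on a genetic column that decreases
    within a chromosome.
    """
    df = _read_tsv(path, ["chrom", "pos_bp"])
    pos_col = "cM" if "cM" in df.columns else "map_pos" if "map_pos" in df.columns else None
    if pos_col is None:
        raise FormatError(f"{path}: needs a 'cM' or 'map_pos' column")
    _check_unique_positions(df, path)
    for chrom, grp in df.groupby("chrom", sort=False):
        g = grp.sort_values("pos_bp")[pos_col].to_numpy(float)
        if np.any(np.diff(g) < 0):
            raise FormatError(
                f"{path}: genetic positions decrease along chromosome {chrom}"
            )
    return df.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)


def write_af_tsv(af: pd.DataFrame, path, meta: dict | None = None) -> None:
    cols = ["chrom", "pos_bp", "af"]
    if "missing_frac" in af.columns:
        cols.append("missing_frac")
    _write_tsv(af[cols], path, meta)


def read_af_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, ["chrom", "pos_bp", "af"])
    _check_unique_positions(df, path)
    return df.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)


def write_windows_tsv(
    win: pd.DataFrame, path, meta: dict | None = None, bed: bool = False
) -> None:
    """Window track as TSV; bed=True writes 0-based half-open BED3+ columns."""
    df = win.copy()
    if bed:
        df = df[["chrom", "start_bp", "end_bp", "rr", "n_pairs"]].rename(
            columns={"start_bp": "start", "end_bp": "end"}
        )
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t", index=False, header=False, float_format="%.6g")
        return
    _write_tsv(
        df[["chrom", "start_bp", "end_bp", "rr", "n_pairs", "partial"]], path, meta
    )


def read_windows_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, ["chrom", "start_bp", "end_bp", "rr", "n_pairs"])


def write_counts_tsv(rc: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_tsv(rc[["chrom", "pos_bp", "depth", "alt_count"]], path, meta)


def read_counts_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, ["chrom", "pos_bp", "depth", "alt_count"])
    _check_unique_positions(df, path)
    if (df["alt_count"] > df["depth"]).any() or (df["alt_count"] < 0).any():
        raise FormatError(f"{path}: alt_count outside [0, depth]")
    return df.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)


def read_af_from_vcf(
    path, min_depth: int = 0, allele_policy: str = "alt"
) -> tuple[pd.DataFrame, dict]:
    """Pooled allele frequencies from a VCF with AD (or INFO AF) fields.

    Biallelic SNPs only; multiallelic records and indels are skipped and
    counted. AF is the ALT-read fraction pooled over all samples'
    allele-depth (AD) fields; records lacking AD fall back to the INFO AF
    field, and a record with neither is an error. allele_policy 'ref'
    reports the reference-allele frequency instead (1 - ALT AF). Positions
    are 1-based as in the VCF; an unsorted VCF is an error.
    """
    from cyvcf2 import VCF

    if allele_policy not in ("alt", "ref"):
        raise ValueError("allele_policy must be 'alt' or 'ref'")
    report = {
        "records": 0,
        "multiallelic": 0,
        "indel": 0,
        "low_depth": 0,
        "retained": 0,
    }
    rows = []
    last: dict[str, int] = {}
    for rec in VCF(str(path)):
        report["records"] += 1
        if rec.CHROM in last and rec.POS < last[rec.CHROM]:
            raise FormatError(
                f"{path}: unsorted VCF at {rec.CHROM}:{rec.POS}"
            )
        last[rec.CHROM] = rec.POS
        if len(rec.ALT) != 1:
            report["multiallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            report["indel"] += 1
            continue
        ad = rec.format("AD")
        if ad is not None:
            ad = np.asarray(ad, float)
            ad[ad < 0] = np.nan  # cyvcf2 encodes missing as negative
            ref_d = np.nansum(ad[:, 0])
            alt_d = np.nansum(ad[:, 1])
            total = ref_d + alt_d
            if total < max(min_depth, 1):
                report["low_depth"] += 1
                continue
            af = alt_d / total
        else:
            info_af = rec.INFO.get("AF")
            if info_af is None:
                raise FormatError(
                    f"{path}: record {rec.CHROM}:{rec.POS} has neither an AD "
                    "format field nor an INFO AF field"
                )
            af = float(info_af[0] if isinstance(info_af, tuple) else info_af)
        if allele_policy == "ref":
            af = 1.0 - af
        rows.append((rec.CHROM, rec.POS, af))
        report["retained"] += 1
    track = pd.DataFrame(rows, columns=["chrom", "pos_bp", "af"])
    return track, report
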