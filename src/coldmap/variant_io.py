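"""Pooled-variant I/O and hard filtering.

Reads biallelic SNPs with per-bulk allele depths from VCF, applies
GATK-style hard filters (QD/FS/MQ site filters, a GQ genotype mask, and a
SNP-cluster filter), and writes scan tracks (TSV) and regions (BED).

Internally coordinates are 1-based closed, as in VCF; BED output converts
to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "t_ref", "t_alt", "s_ref", "s_alt"]


@dataclass(frozen=True)
class HardFilterThresholds:
    """Site and genotype hard-filter thresholds (GATK-style defaults)."""

    qd_min: float = 4.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    gq_min: int = 20
    cluster_window: int = 10   # bp window for the SNP-cluster filter
    cluster_count: int = 3     # >= this many SNPs in the window -> cluster


def read_pooled_vcf(
    path: str, tolerant_sample: str, sensitive_sample: str
) -> pd.DataFrame:
    """Parse biallelic SNPs with AD depths for the two named bulk samples.

    Multi-allelic and indel records are skipped (count logged). Site
    annotations QD/FS/MQ and per-sample GQ are carried through when present.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    for name in (tolerant_sample, sensitive_sample):
        if name not in samples:
            raise ValueError(f"sample {name!r} not found in {path}")
    it_idx = samples.index(tolerant_sample)
    is_idx = samples.index(sensitive_sample)

    def has_header(key: str) -> bool:
        try:
            vcf.get_header_type(key)
            return True
        except KeyError:
            return False

    if not has_header("AD"):
        raise ValueError(f"{path} defines no AD FORMAT field")
    header_has_gq = has_header("GQ")

    rows = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise ValueError(
                f"record {var.CHROM}:{var.POS} has no AD field for samples"
            )
        t_ad = ad[it_idx]
        s_ad = ad[is_idx]
        row = {
            "chrom": var.CHROM,
            "pos": var.POS,
            "ref": var.REF,
            "alt": var.ALT[0],
            "t_ref": max(int(t_ad[0]), 0),
            "t_alt": max(int(t_ad[1]), 0),
            "s_ref": max(int(s_ad[0]), 0),
            "s_alt": max(int(s_ad[1]), 0),
        }
        for key, col in (("QD", "QD"), ("FS", "FS"), ("MQ", "MQ")):
            val = var.INFO.get(key)
            row[col] = float(val) if val is not None else np.nan
        gq = var.format("GQ") if header_has_gq else None
        if gq is not None:
            gq = np.asarray(gq, dtype=float).reshape(len(samples), -1)[:, 0]
            row["t_gq"] = float(gq[it_idx])
            row["s_gq"] = float(gq[is_idx])
        rows.append(row)
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records", n_skipped)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=COUNT_COLUMNS)
    return df


def write_pooled_vcf(
    counts: pd.DataFrame,
    path: str,
    tolerant_sample: str = "T_pool",
    sensitive_sample: str = "S_pool",
    contig_lengths: Optional[dict] = None,
) -> None:
    """Write a pooled-counts table as a minimal VCF 4.2 with AD (and GQ)."""
    has_gq = {"t_gq", "s_gq"}.issubset(counts.columns)
    has_info = {"QD", "FS", "MQ"}.issubset(counts.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=coldmap\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        if has_info:
            fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Qual by depth">\n')
            fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand">\n')
            fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{tolerant_sample}\t{sensitive_sample}\n"
        )
        fmt = "GT:AD:GQ" if has_gq else "GT:AD"
        for row in counts.itertuples(index=False):
            info = (
                f"QD={row.QD:.2f};FS={row.FS:.2f};MQ={row.MQ:.2f}"
                if has_info
                else "."
            )
            t_field = f"./.:{row.t_ref},{row.t_alt}"
            s_field = f"./.:{row.s_ref},{row.s_alt}"
            if has_gq:
                t_field += f":{int(row.t_gq)}"
                s_field += f":{int(row.s_gq)}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                f"{info}\t{fmt}\t{t_field}\t{s_field}\n"
            )


def _cluster_mask(positions: np.ndarray, window: int, count: int) -> np.ndarray:
    """True for sites sitting in a run of >= count SNPs within `window` bp."""
    n = len(positions)
    bad = np.zeros(n, dtype=bool)
    if n < count or count < 2:
        return bad
    span = positions[count - 1 :] - positions[: n - count + 1]
    starts = np.nonzero(span < window)[0]
    for s in starts:
        bad[s : s + count] = True
    return bad


def hard_filter(
    counts: pd.DataFrame, thresholds: HardFilterThresholds = HardFilterThresholds()
) -> pd.DataFrame:
    """Apply site filters, the GQ mask, and the SNP-cluster filter.

    Sites missing an annotation pass that test by default (logged).
    A pool whose GQ falls below ``gq_min`` has its counts masked (set to
    zero = missing); sites left with zero depth in either pool are dropped.
    The filter is idempotent and never alters retained counts.
    """
    df = counts.copy()
    n0 = len(df)
    keep = np.ones(n0, dtype=bool)
    for col, test in (
        ("QD", lambda v: v >= thresholds.qd_min),
        ("FS", lambda v: v <= thresholds.fs_max),
        ("MQ", lambda v: v >= thresholds.mq_min),
    ):
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            ok = np.where(np.isnan(vals), True, test(vals))
            keep &= ok
        else:
            logger.debug("annotation %s absent; sites pass by default", col)
    df = df.loc[keep].copy()

    for gq_col, ref_col, alt_col in (
        ("t_gq", "t_ref", "t_alt"),
        ("s_gq", "s_ref", "s_alt"),
    ):
        if gq_col in df.columns:
            gq = df[gq_col].to_numpy(dtype=float)
            mask = ~np.isnan(gq) & (gq < thresholds.gq_min)
            df.loc[mask, [ref_col, alt_col]] = 0

    cluster_bad = np.zeros(len(df), dtype=bool)
    offset = 0
    for _, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        cluster_bad[offset : offset + len(sub)] = _cluster_mask(
            pos, thresholds.cluster_window, thresholds.cluster_count
        )
        offset += len(sub)
    df = df.loc[~cluster_bad]

    nonzero = ((df["t_ref"] + df["t_alt"]) > 0) & ((df["s_ref"] + df["s_alt"]) > 0)
    df = df.loc[nonzero].reset_index(drop=True)
    logger.info("hard_filter: %d of %d sites retained", len(df), n0)
    return df


def read_counts_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index=False)


def write_track(track: pd.DataFrame, path: str, float_fmt: str = "%.6g") -> None:
    """Write a windowed track as TSV; input must be position-sorted."""
    _check_sorted(track, start_col="start")
    track.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def read_track(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(regions: Sequence, path: str) -> None:
    """Write regions as BED (0-based half-open).

    An internal 1-based closed interval [start, end] becomes the BED line
    ``chrom  start-1  end``.
    """
    rows = [(r.chrom, r.start, r.end, getattr(r, "method", ".")) for r in regions]
    for i in range(1, len(rows)):
        if rows[i][0] == rows[i - 1][0] and rows[i][1] < rows[i - 1][1]:
            raise ValueError("regions must be sorted by start within chromosome")
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def _check_sorted(df: pd.DataFrame, start_col: str) -> None:
    for _, sub in df.groupby("chrom", sort=False):
        if np.any(np.diff(sub[start_col].to_numpy()) < 0):
            raise ValueError("input must be sorted by start position")
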