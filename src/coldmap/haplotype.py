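"""Haplotype grouping over candidate-gene SNPs and qRT-PCR utilities.

Lines are grouped by their concatenated allele string over a small set of
candidate SNPs (heterozygous calls form their own class; no phasing).
Group phenotype contrasts use Welch's t-test. Relative expression follows
the 2^-ddCt convention against a housekeeping reference and a calibrator
sample, and expression-phenotype association reuses the Pearson
correlation from the phenotype module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype import pearson

logger = logging.getLogger(__name__)

MISSING = {"-", "", "N", "NA", None}


@dataclass
class HaplotypeTable:
    """Haplotype string -> member lines, with per-class phenotype summaries."""

    table: pd.DataFrame  # columns: haplotype, n, line_ids, mean_sr, sd_sr
    members: Dict[str, List[str]]

    def class_of(self, line_id: str) -> str:
        for hap, lines in self.members.items():
            if line_id in lines:
                return hap
        raise KeyError(line_id)


def call_haplotypes(
    genotypes: pd.DataFrame,
    site_columns: Sequence[str],
    phenotypes: pd.DataFrame | None = None,
) -> HaplotypeTable:
    """Group lines by their allele string over ``site_columns``.

    ``genotypes`` has one row per line (column ``line_id``) and one column
    per SNP site holding allele strings (e.g. "T", "C", or "T/C" for an
    unphased heterozygote). Lines missing any call are excluded (logged).
    Optional phenotypes (line_id, SR) add per-class means and SDs.
    """
    if len(site_columns) == 0:
        raise ValueError("need at least one site")
    members: Dict[str, List[str]] = {}
    n_dropped = 0
    for row in genotypes.itertuples(index=False):
        alleles = [getattr(row, c) for c in site_columns]
        if any(a in MISSING or (isinstance(a, float) and np.isnan(a)) for a in alleles):
            n_dropped += 1
            continue
        hap = "".join(str(a) for a in alleles)
        members.setdefault(hap, []).append(row.line_id)
    if n_dropped:
        logger.info("excluded %d lines with missing calls", n_dropped)
    sr_by_line = (
        dict(zip(phenotypes["line_id"], phenotypes["SR"]))
        if phenotypes is not None
        else {}
    )
    rows = []
    for hap, lines in sorted(members.items(), key=lambda kv: -len(kv[1])):
        srs = [sr_by_line[l] for l in lines if l in sr_by_line]
        rows.append(
            {
                "haplotype": hap,
                "n": len(lines),
                "line_ids": ",".join(lines),
                "mean_sr": float(np.mean(srs)) if srs else np.nan,
                "sd_sr": float(np.std(srs, ddof=1)) if len(srs) > 1 else np.nan,
            }
        )
    return HaplotypeTable(table=pd.DataFrame(rows), members=members)


def haplotype_phenotype_test(
    table: HaplotypeTable,
    phenotypes: pd.DataFrame,
    hap_a: str,
    hap_b: str,
) -> Tuple[float, float, float]:
    """Welch two-sample t-test on SR between two haplotype classes.

    Returns (mean difference a-b, t, two-sided p).
    """
    sr_by_line = dict(zip(phenotypes["line_id"], phenotypes["SR"]))
    groups = []
    for hap in (hap_a, hap_b):
        if hap not in table.members:
            raise KeyError(f"haplotype {hap!r} not present")
        vals = np.array(
            [sr_by_line[l] for l in table.members[hap] if l in sr_by_line], dtype=float
        )
        if len(vals) < 2:
            raise ValueError(f"haplotype {hap!r} has fewer than 2 phenotyped members")
        groups.append(vals)
    a, b = groups
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(np.mean(a) - np.mean(b)), float(t), float(p)


def relative_expression(
    ct_target: float,
    ct_reference: float,
    calibrator_ct_target: float,
    calibrator_ct_reference: float,
) -> float:
    """Fold change 2^-ddCt relative to the calibrator sample.

    ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator.
    Assumes 100% amplification efficiency.
    """
    for v in (ct_target, ct_reference, calibrator_ct_target, calibrator_ct_reference):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError("missing Ct value")
    ddct = (ct_target - ct_reference) - (
        calibrator_ct_target - calibrator_ct_reference
    )
    return float(2.0 ** (-ddct))


def expression_phenotype_correlation(
    expr_by_line: Dict[str, float], sr_by_line: Dict[str, float]
) -> Tuple[float, float]:
    """Pearson correlation between per-line expression and SR."""
    unpaired = set(expr_by_line) ^ set(sr_by_line)
    if unpaired:
        raise ValueError(f"unpaired line ids: {sorted(unpaired)}")
    lines = sorted(expr_by_line)
    x = [expr_by_line[l] for l in lines]
    y = [sr_by_line[l] for l in lines]
    return pearson(x, y)
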