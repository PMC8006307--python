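"""F2 linkage analysis: genetic map construction and interval mapping.

Markers are codominant and coded A (tolerant-parent homozygote),
H (heterozygote), B (sensitive-parent homozygote), '-' (missing).
Recombination fractions are estimated by EM over the ambiguous
double-heterozygote class, converted to map distance with the Kosambi
(default) or Haldane function, and the QTL scan uses Haley-Knott
regression on the expected additive/dominance predictors given the
flanking markers. Significance comes from a permutation test on the
genome-wide maximum LOD, combined with a fixed LOD floor.

Sign convention: a positive additive effect means the tolerant-parent
allele increases the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CODE_TO_COUNT = {"A": 2, "H": 1, "B": 0, "-": -1, "": -1}
_PRIOR = np.array([0.25, 0.5, 0.25])  # F2 genotype prior (SS, TS, TT order-free)


def encode_genotypes(geno: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    """{A,H,B,-} frame (line_id + marker columns) -> int matrix (-1 missing).

    Returns counts of the tolerant-parent (A) allele: A=2, H=1, B=0.
    """
    markers = [c for c in geno.columns if c != "line_id"]
    mat = np.full((len(geno), len(markers)), -1, dtype=np.int8)
    for j, m in enumerate(markers):
        col = geno[m].astype(str).str.strip().str.upper()
        mat[:, j] = col.map(CODE_TO_COUNT).fillna(-1).to_numpy(dtype=np.int8)
    return mat, markers


def estimate_rf(
    g1: np.ndarray, g2: np.ndarray, max_iter: int = 200, tol: float = 1e-10
) -> float:
    """ML recombination fraction between two codominant F2 markers (EM).

    Each individual contributes two meioses. All genotype classes except the
    double heterozygote determine their recombinant-gamete count; the double
    heterozygote mixes coupling (0 recombinants) and repulsion (2) and is
    resolved iteratively via its posterior under the current r.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 >= 0) & (g2 >= 0)
    if not np.any(ok):
        raise ValueError("no co-genotyped lines")
    g1, g2 = g1[ok], g2[ok]
    n = len(g1)
    # recombinant gametes for unambiguous classes: |i - j| mapped via table
    counts = np.zeros((3, 3), dtype=np.int64)
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.count_nonzero((g1 == i) & (g2 == j))
    # fixed recombinant-gamete contributions (double het handled separately)
    rec_fixed = (
        0 * (counts[0, 0] + counts[2, 2])
        + 1 * (counts[0, 1] + counts[1, 0] + counts[1, 2] + counts[2, 1])
        + 2 * (counts[0, 2] + counts[2, 0])
    )
    n_hh = counts[1, 1]
    r = 0.25
    for _ in range(max_iter):
        # P(double recombinant | double het) under current r
        denom = r * r + (1 - r) * (1 - r)
        p_rr = (r * r) / denom if denom > 0 else 0.0
        rec = rec_fixed + n_hh * 2.0 * p_rr
        r_new = min(max(rec / (2.0 * n), 1e-9), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return float(r)


def kosambi(r: float) -> float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) cM."""
    if not (0 <= r < 0.5):
        raise ValueError("r must lie in [0, 0.5)")
    return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))


def kosambi_inverse(d_cm: float) -> float:
    return 0.5 * np.tanh(d_cm / 50.0)


def haldane(r: float) -> float:
    if not (0 <= r < 0.5):
        raise ValueError("r must lie in [0, 0.5)")
    return -50.0 * np.log(1 - 2 * r)


def haldane_inverse(d_cm: float) -> float:
    return 0.5 * (1 - np.exp(-d_cm / 50.0))


@dataclass
class GeneticMap:
    """Ordered markers with physical (bp) and map (cM) positions."""

    table: pd.DataFrame  # columns: marker, chrom, pos_bp, cm

    def __post_init__(self) -> None:
        cm = self.table["cm"].to_numpy()
        if np.any(np.diff(cm) < 0):
            raise ValueError("cM positions must be non-decreasing")

    @property
    def cm(self) -> np.ndarray:
        return self.table["cm"].to_numpy(dtype=float)

    @property
    def markers(self) -> List[str]:
        return self.table["marker"].tolist()

    def cm_of_bp(self, bp: float) -> float:
        """Map position of a physical coordinate by linear interpolation."""
        t = self.table
        return float(np.interp(bp, t["pos_bp"].to_numpy(), t["cm"].to_numpy()))


def build_genetic_map(
    genotypes: np.ndarray,
    marker_ids: Sequence[str],
    chrom: str,
    phys_pos: Sequence[int],
    mapping: str = "kosambi",
) -> GeneticMap:
    """Chain adjacent-marker recombination fractions into a cM map.

    Markers must already be in physical order; the first marker anchors 0 cM.
    """
    func = {"kosambi": kosambi, "haldane": haldane}[mapping]
    cm = [0.0]
    for j in range(1, genotypes.shape[1]):
        r = estimate_rf(genotypes[:, j - 1], genotypes[:, j])
        r = min(r, 0.499999)
        cm.append(cm[-1] + func(r))
    table = pd.DataFrame(
        {
            "marker": list(marker_ids),
            "chrom": chrom,
            "pos_bp": list(phys_pos),
            "cm": cm,
        }
    )
    return GeneticMap(table)


def _transition(r: float) -> np.ndarray:
    """F2 genotype transition matrix between two loci at rec. fraction r.

    Entry [i, k]: P(count k at locus B | count i at locus A), counts of the
    tolerant allele; the two gametes recombine independently.
    """
    s = 1 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


def _qtl_posterior(
    left: np.ndarray,
    right: Optional[np.ndarray],
    r_left: float,
    r_right: float,
) -> np.ndarray:
    """P(QTL genotype | flanking marker genotypes) per individual.

    ``left``/``right`` are allele counts with -1 for missing; a missing
    flank is marginalized against the 1:2:1 prior.
    """
    n = len(left)
    t_l = _transition(r_left)
    t_r = _transition(r_right) if right is not None else None
    post = np.empty((n, 3))
    for i in range(n):
        f = np.ones(3)
        if left[i] >= 0:
            f = f * t_l[left[i], :]
        else:
            f = f * _PRIOR
        if t_r is not None and right is not None and right[i] >= 0:
            f = f * t_r[:, right[i]]
        total = f.sum()
        post[i] = f / total if total > 0 else _PRIOR
    return post


@dataclass
class ScanResult:
    """Grid LOD/effect profile plus the marker map used."""

    profile: pd.DataFrame  # columns: cm, lod, add, dom, pve
    genetic_map: GeneticMap
    n_lines: int


def _fit_position(y: np.ndarray, x: np.ndarray, z: np.ndarray) -> Tuple[float, float, float, float]:
    """OLS of y on [1, x, z]; returns (lod, add, dom, pve)."""
    n = len(y)
    X = np.column_stack([np.ones(n), x, z])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss1 = float(resid @ resid)
    rss0 = float(((y - y.mean()) ** 2).sum())
    if rss1 <= 0:
        rss1 = np.finfo(float).tiny
    lod = (n / 2.0) * np.log10(rss0 / rss1) if rss0 > 0 else 0.0
    pve = 100.0 * (1.0 - rss1 / rss0) if rss0 > 0 else 0.0
    return max(lod, 0.0), float(coef[1]), float(coef[2]), pve


def _grid_positions(gmap: GeneticMap, step_cm: float) -> np.ndarray:
    cm = gmap.cm
    grid = np.arange(cm[0], cm[-1] + step_cm / 2, step_cm)
    grid = np.union1d(np.round(grid, 9), np.round(cm, 9))
    return grid


def _predictors_at(
    pos_cm: float,
    genotypes: np.ndarray,
    gmap: GeneticMap,
    mapping_inverse,
) -> Tuple[np.ndarray, np.ndarray]:
    """Expected additive (x) and dominance (z) predictors at a grid point."""
    cm = gmap.cm
    j_right = int(np.searchsorted(cm, pos_cm, side="left"))
    j_right = min(j_right, len(cm) - 1)
    j_left = j_right if cm[j_right] <= pos_cm else max(j_right - 1, 0)
    if cm[j_left] > pos_cm:
        j_left = 0
    if j_left == j_right or abs(cm[j_right] - pos_cm) < 1e-9:
        # at a marker
        j = j_right if abs(cm[j_right] - pos_cm) < 1e-9 else j_left
        left = genotypes[:, j]
        r_l = 0.0
        # use neighbors to rescue missing calls
        j_nb = j + 1 if j + 1 < len(cm) else (j - 1 if j > 0 else None)
        if j_nb is None:
            post = _qtl_posterior(left, None, 0.0, 0.0)
        else:
            r_nb = mapping_inverse(abs(cm[j_nb] - cm[j]))
            post = _qtl_posterior(left, genotypes[:, j_nb], 0.0, r_nb)
    else:
        r_l = mapping_inverse(pos_cm - cm[j_left])
        r_r = mapping_inverse(cm[j_right] - pos_cm)
        post = _qtl_posterior(genotypes[:, j_left], genotypes[:, j_right], r_l, r_r)
    x = post[:, 2] - post[:, 0]
    z = post[:, 1]
    return x, z


def _stepwise_background(
    y: np.ndarray,
    genotypes: np.ndarray,
    p_enter: float = 0.001,
    p_exit: float = 0.002,
) -> List[int]:
    """Forward/backward stepwise marker selection (ICIM-style background)."""
    from scipy import stats as sps

    n, m = genotypes.shape
    selected: List[int] = []

    def design(idx: List[int]) -> np.ndarray:
        cols = [np.ones(n)]
        for j in idx:
            g = genotypes[:, j].astype(float)
            g = np.where(g < 0, np.nanmean(np.where(g < 0, np.nan, g)), g)
            cols.append(g - 1.0)
            cols.append((g == 1).astype(float))
        return np.column_stack(cols)

    def rss(X: np.ndarray) -> float:
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    improved = True
    while improved:
        improved = False
        base_X = design(selected)
        base_rss = rss(base_X)
        best_p, best_j = 1.0, -1
        for j in range(m):
            if j in selected:
                continue
            X = design(selected + [j])
            new_rss = rss(X)
            df2 = n - X.shape[1]
            if df2 <= 0 or new_rss <= 0:
                continue
            f = ((base_rss - new_rss) / 2.0) / (new_rss / df2)
            p = sps.f.sf(max(f, 0.0), 2, df2)
            if p < best_p:
                best_p, best_j = p, j
        if best_j >= 0 and best_p < p_enter:
            selected.append(best_j)
            improved = True
            # backward pass
            removed = True
            while removed and len(selected) > 1:
                removed = False
                full_rss = rss(design(selected))
                for j in list(selected):
                    rest = [k for k in selected if k != j]
                    red_rss = rss(design(rest))
                    df2 = n - (1 + 2 * len(selected))
                    if df2 <= 0 or full_rss <= 0:
                        continue
                    f = ((red_rss - full_rss) / 2.0) / (full_rss / df2)
                    p = sps.f.sf(max(f, 0.0), 2, df2)
                    if p > p_exit:
                        selected.remove(j)
                        removed = True
                        break
    return selected


def scan_interval_mapping(
    genotypes: np.ndarray,
    gmap: GeneticMap,
    phenotype: np.ndarray,
    step_cm: float = 0.5,
    mapping: str = "kosambi",
    cofactors: bool = False,
    cofactor_exclusion_cm: float = 10.0,
) -> ScanResult:
    """Haley-Knott regression scan over a cM grid.

    At each grid position the phenotype is regressed on the expected
    additive and dominance predictors given the flanking markers;
    LOD = (n/2) log10(RSS0/RSS1). With ``cofactors`` the phenotype is
    pre-adjusted by stepwise-selected background markers, excluding any
    within ``cofactor_exclusion_cm`` of the tested position.
    """
    y_all = np.asarray(phenotype, dtype=float)
    ok = ~np.isnan(y_all)
    if ok.sum() < 50:
        raise ValueError("need phenotypes for at least 50 genotyped lines")
    y = y_all[ok]
    genos = genotypes[ok]
    inverse = {"kosambi": kosambi_inverse, "haldane": haldane_inverse}[mapping]
    grid = _grid_positions(gmap, step_cm)
    cm = gmap.cm

    background: List[int] = []
    if cofactors:
        background = _stepwise_background(y, genos)

    rows = []
    for pos in grid:
        x, z = _predictors_at(pos, genos, gmap, inverse)
        if cofactors and background:
            near = [j for j in background if abs(cm[j] - pos) > cofactor_exclusion_cm]
            if near:
                cols = [np.ones(len(y))]
                for j in near:
                    g = genos[:, j].astype(float)
                    g = np.where(g < 0, 1.0, g)
                    cols.append(g - 1.0)
                    cols.append((g == 1).astype(float))
                Xb = np.column_stack(cols)
                coef, _, _, _ = np.linalg.lstsq(Xb, y, rcond=None)
                y_use = y - Xb @ coef + y.mean()
            else:
                y_use = y
        else:
            y_use = y
        lod, add, dom, pve = _fit_position(y_use, x, z)
        rows.append((pos, lod, add, dom, pve))
    profile = pd.DataFrame(rows, columns=["cm", "lod", "add", "dom", "pve"])
    return ScanResult(profile=profile, genetic_map=gmap, n_lines=int(ok.sum()))


def permutation_threshold(
    genotypes: np.ndarray,
    gmap: GeneticMap,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    step_cm: float = 0.5,
    mapping: str = "kosambi",
) -> float:
    """(1-alpha) nearest-rank quantile of the permutation max-LOD null.

    The phenotype vector is permuted against the (fixed) genotypes; the scan
    is vectorized across permutations via per-position orthonormal bases.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y_all = np.asarray(phenotype, dtype=float)
    ok = ~np.isnan(y_all)
    y = y_all[ok]
    genos = genotypes[ok]
    n = len(y)
    inverse = {"kosambi": kosambi_inverse, "haldane": haldane_inverse}[mapping]
    grid = _grid_positions(gmap, step_cm)

    bases = []
    for pos in grid:
        x, z = _predictors_at(pos, genos, gmap, inverse)
        X = np.column_stack([np.ones(n), x, z])
        q, _ = np.linalg.qr(X)
        bases.append(q[:, : np.linalg.matrix_rank(X)])
    max_rank = max(b.shape[1] for b in bases)
    Q = np.zeros((len(grid), n, max_rank))
    for i, b in enumerate(bases):
        Q[i, :, : b.shape[1]] = b

    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Y = y[perm_idx].T  # (n, n_perm)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    yy = float(y @ y)
    # (grid, rank, n_perm)
    proj = np.einsum("pnr,nb->prb", Q, Y, optimize=True)
    rss1 = yy - (proj**2).sum(axis=1)  # (grid, n_perm)
    rss1 = np.maximum(rss1, np.finfo(float).tiny)
    lod = (n / 2.0) * np.log10(ss_tot / rss1)
    max_lod = lod.max(axis=0)
    from .genome_scan import nearest_rank_quantile

    return nearest_rank_quantile(max_lod, 1.0 - alpha)


def summarize_qtl(
    scan: ScanResult,
    threshold: float,
    fixed_lod_floor: float = 3.0,
    trait: str = "SR",
) -> pd.DataFrame:
    """Report peaks exceeding max(threshold, floor) with a 1-LOD interval.

    One row per detected QTL: peak position, flanking markers, LOD, PVE,
    additive/dominance effects, and the 1-LOD-drop support interval.
    """
    cut = max(threshold, fixed_lod_floor)
    prof = scan.profile
    lod = prof["lod"].to_numpy()
    if not np.any(lod >= cut):
        return pd.DataFrame(
            columns=[
                "trait", "position_cm", "left_marker", "right_marker",
                "lod", "pve", "add", "dom", "ci_left", "ci_right",
            ]
        )
    k = int(np.argmax(lod))
    peak_cm = float(prof["cm"].iloc[k])
    peak_lod = float(lod[k])
    # 1-LOD drop interval, walking out from the peak
    left = k
    while left > 0 and lod[left - 1] >= peak_lod - 1.0:
        left -= 1
    right = k
    while right < len(lod) - 1 and lod[right + 1] >= peak_lod - 1.0:
        right += 1
    gmap = scan.genetic_map
    cm = gmap.cm
    names = gmap.markers
    j = int(np.searchsorted(cm, peak_cm, side="right"))
    left_marker = names[max(j - 1, 0)]
    right_marker = names[min(j, len(names) - 1)]
    row = {
        "trait": trait,
        "position_cm": peak_cm,
        "left_marker": left_marker,
        "right_marker": right_marker,
        "lod": peak_lod,
        "pve": float(prof["pve"].iloc[k]),
        "add": float(prof["add"].iloc[k]),
        "dom": float(prof["dom"].iloc[k]),
        "ci_left": float(prof["cm"].iloc[left]),
        "ci_right": float(prof["cm"].iloc[right]),
    }
    return pd.DataFrame([row])
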