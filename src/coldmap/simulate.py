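"""Synthetic F2:3 bulked-segregant experiments with a known, planted QTL.

The generator emulates the design of an extreme-bulk QTL-seq study in a
selfing crop: a biparental cross between a tolerant (T) and a sensitive (S)
parent, an F2 population produced by standard meiosis (Poisson crossovers,
no interference), a quantitative survival-rate phenotype driven by one or
more planted QTL, selection of the two phenotypic extreme bulks, and pooled
short-read allele depths at every parental SNP with sequencing error.

Every stage is seed-deterministic so downstream modules can be tested
against known ground truth without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .phenotype import BulkAssignment

BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class QtlSpec:
    """One planted QTL: additive/dominance effects in survival-rate %-points.

    ``additive`` is the half-difference between the two homozygote means, with
    the tolerant-parent homozygote on the positive side; ``dominance`` is the
    heterozygote deviation from the homozygote midpoint.
    """

    chrom: str
    pos: int
    additive: float
    dominance: float = 0.0


@dataclass
class SimConfig:
    """Parameters of one simulated bulked-segregant experiment.

    Defaults mirror the study design the package targets: a 460-line F2:3
    population, 30+30 extreme bulks, ~100x pooled depth, and a rice-typical
    recombination scale of 4 cM/Mb.
    """

    chrom_lengths: Dict[str, int]
    snp_density: float = 100.0           # expected SNPs per Mb
    n_individuals: int = 460
    bulk_size: int = 30
    qtl: List[QtlSpec] = field(default_factory=list)
    baseline_sr: float = 50.0            # population-mean survival rate (%)
    noise_sd: float = 10.0               # residual SR noise (%-points)
    sd_noise_sd: float = 0.2             # damage-score noise (0-7 scale)
    mean_depth: float = 100.0            # reads per site per pool
    error_rate: float = 0.001            # per-base sequencing error
    recomb_cm_per_mb: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be non-empty")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"zero-length chromosome {chrom!r}")
        if 2 * self.bulk_size > self.n_individuals:
            raise ValueError("2*bulk_size must not exceed n_individuals")
        for q in self.qtl:
            if q.chrom not in self.chrom_lengths:
                raise ValueError(f"QTL on unknown chromosome {q.chrom!r}")
            if not (1 <= q.pos <= self.chrom_lengths[q.chrom]):
                raise ValueError(f"QTL position {q.pos} outside {q.chrom}")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must lie in [0, 0.05]")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not (0.0 <= self.baseline_sr <= 100.0):
            raise ValueError("baseline_sr must lie in [0, 100]")


@dataclass
class SnpPanel:
    """Ordered parental SNP sites: chrom, pos (1-based), t_base, s_base."""

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "t_base", "s_base"}
        if not required.issubset(self.sites.columns):
            raise ValueError(f"panel frame needs columns {sorted(required)}")
        for _, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing")
        if (self.sites["t_base"] == self.sites["s_base"]).any():
            raise ValueError("parental bases must differ at every site")

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self, chrom: str) -> np.ndarray:
        return self.sites.loc[self.sites["chrom"] == chrom, "pos"].to_numpy()


# Parental-origin labels used in gamete mosaics: 0 = tolerant, 1 = sensitive.
T_ORIGIN = 0
S_ORIGIN = 1


@dataclass
class Gamete:
    """One chromosome copy as a mosaic of parental segments.

    ``ends`` holds the (sorted, 1-based, inclusive) end position of each
    segment, the last equalling the chromosome length; ``origins`` holds the
    parental origin of each segment.
    """

    ends: np.ndarray
    origins: np.ndarray

    def origin_at(self, positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.ends, positions, side="left")
        return self.origins[idx]


@dataclass
class F2Individual:
    """Two gametes per chromosome; genotype = tolerant-allele count (0/1/2)."""

    gametes: Dict[str, Tuple[Gamete, Gamete]]

    def t_count_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        g1, g2 = self.gametes[chrom]
        return (g1.origin_at(positions) == T_ORIGIN).astype(np.int8) + (
            g2.origin_at(positions) == T_ORIGIN
        ).astype(np.int8)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent streams per stage so each operation is reproducible even
    # when earlier stages are skipped
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_founders(config: SimConfig) -> SnpPanel:
    """Draw the parental SNP panel: Poisson site counts at ``snp_density``."""
    rng = _rng(config, 0)
    rows = []
    for chrom, length in config.chrom_lengths.items():
        n = rng.poisson(config.snp_density * length / 1e6)
        n = min(n, length)
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        t_idx = rng.integers(0, 4, size=n)
        shift = rng.integers(1, 4, size=n)
        s_idx = (t_idx + shift) % 4
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "t_base": BASES[t_idx],
                    "s_base": BASES[s_idx],
                }
            )
        )
    sites = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "pos", "t_base", "s_base"]
    )
    return SnpPanel(sites)


def _draw_gamete(
    rng: np.random.Generator, length: int, morgans: float
) -> Gamete:
    n_co = rng.poisson(morgans)
    if n_co > 0:
        breaks = np.sort(rng.integers(1, length, size=n_co).astype(np.int64))
        breaks = np.unique(breaks)
    else:
        breaks = np.empty(0, dtype=np.int64)
    ends = np.append(breaks, length)
    start = rng.integers(0, 2)
    origins = (start + np.arange(len(ends))) % 2
    return Gamete(ends=ends, origins=origins.astype(np.int8))


def simulate_f2(panel: SnpPanel, config: SimConfig) -> List[F2Individual]:
    """Simulate F2 meiosis: Poisson crossovers, uniform placement."""
    if len(panel) == 0:
        raise ValueError("cannot simulate F2 individuals on an empty panel")
    rng = _rng(config, 1)
    individuals = []
    for _ in range(config.n_individuals):
        gametes: Dict[str, Tuple[Gamete, Gamete]] = {}
        for chrom, length in config.chrom_lengths.items():
            morgans = length / 1e6 * config.recomb_cm_per_mb / 100.0
            gametes[chrom] = (
                _draw_gamete(rng, length, morgans),
                _draw_gamete(rng, length, morgans),
            )
        individuals.append(F2Individual(gametes))
    return individuals


def genotype_matrix(
    individuals: Sequence[F2Individual], chrom: str, positions: np.ndarray
) -> np.ndarray:
    """(n_individuals, n_sites) matrix of tolerant-allele counts 0/1/2."""
    positions = np.asarray(positions)
    out = np.empty((len(individuals), len(positions)), dtype=np.int8)
    for i, ind in enumerate(individuals):
        out[i] = ind.t_count_at(chrom, positions)
    return out


def simulate_phenotypes(
    individuals: Sequence[F2Individual], config: SimConfig
) -> pd.DataFrame:
    """Survival rate and damage score per line.

    SR_i = clip(baseline + sum_q (a_q x_i + d_q z_i) + eps, 0, 100) with
    x in {+1, 0, -1} for {TT, TS, SS} and z the heterozygosity indicator;
    SD is derived from SR (7 * (1 - SR/100)) plus small noise, making the two
    indices strongly anticorrelated as in real damage-score assays.
    """
    rng = _rng(config, 2)
    n = len(individuals)
    sr = np.full(n, config.baseline_sr, dtype=float)
    for q in config.qtl:
        counts = genotype_matrix(individuals, q.chrom, np.array([q.pos]))[:, 0]
        x = counts.astype(float) - 1.0
        z = (counts == 1).astype(float)
        sr += q.additive * x + q.dominance * z
    if config.noise_sd > 0:
        sr += rng.normal(0.0, config.noise_sd, size=n)
    sr = np.clip(sr, 0.0, 100.0)
    sd = 7.0 * (1.0 - sr / 100.0)
    if config.sd_noise_sd > 0:
        sd += rng.normal(0.0, config.sd_noise_sd, size=n)
    sd = np.clip(sd, 0.0, 7.0)
    return pd.DataFrame(
        {
            "line_id": [f"L{i:04d}" for i in range(n)],
            "SR": sr,
            "SD": sd,
        }
    )


def simulate_pooled_reads(
    individuals: Sequence[F2Individual],
    bulks: BulkAssignment,
    panel: SnpPanel,
    config: SimConfig,
) -> pd.DataFrame:
    """Pooled allele depths for the two bulks at every panel site.

    Per site and pool: the true tolerant-allele frequency is the bulk allele
    count over 2*bulk_size chromosomes; read depth ~ Poisson(mean_depth) and
    tolerant-allele reads ~ Binomial(depth, f(1-e) + (1-f)e).

    The table is VCF-oriented with REF = sensitive-parent base and
    ALT = tolerant-parent base, so the alt-allele index in a bulk is its
    tolerant-parent SNP-index.
    """
    if not bulks.tolerant_ids or not bulks.sensitive_ids:
        raise ValueError("both bulks must be non-empty")
    rng = _rng(config, 3)
    by_id = {f"L{i:04d}": ind for i, ind in enumerate(individuals)}
    pools = {
        "t": [by_id[i] for i in sorted(bulks.tolerant_ids)],
        "s": [by_id[i] for i in sorted(bulks.sensitive_ids)],
    }
    out = []
    for chrom, sub in panel.sites.groupby("chrom", sort=False):
        positions = sub["pos"].to_numpy()
        block = {
            "chrom": chrom,
            "pos": positions,
            "ref": sub["s_base"].to_numpy(),
            "alt": sub["t_base"].to_numpy(),
        }
        for key, members in pools.items():
            counts = genotype_matrix(members, chrom, positions)
            f = counts.sum(axis=0) / (2.0 * len(members))
            p = f * (1.0 - config.error_rate) + (1.0 - f) * config.error_rate
            depth = rng.poisson(config.mean_depth, size=len(positions))
            alt_reads = rng.binomial(depth, p)
            block[f"{key}_ref"] = depth - alt_reads
            block[f"{key}_alt"] = alt_reads
        out.append(pd.DataFrame(block))
    df = pd.concat(out, ignore_index=True)
    df["usable"] = (df["t_ref"] + df["t_alt"] > 0) & (df["s_ref"] + df["s_alt"] > 0)
    return df


def true_allele_freq(
    individuals: Sequence[F2Individual],
    ids: Sequence[str],
    chrom: str,
    positions: np.ndarray,
) -> np.ndarray:
    """Noise-free tolerant-allele frequency of a bulk (testing aid)."""
    by_id = {f"L{i:04d}": ind for i, ind in enumerate(individuals)}
    members = [by_id[i] for i in ids]
    counts = genotype_matrix(members, chrom, positions)
    return counts.sum(axis=0) / (2.0 * len(members))


def marker_genotype_frame(
    individuals: Sequence[F2Individual],
    chrom: str,
    positions: np.ndarray,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Codominant marker matrix coded {A, H, B, -}.

    A = tolerant-parent homozygote, B = sensitive-parent homozygote.
    Rows are lines, columns are markers named ``C{chrom}_{pos}``.
    """
    counts = genotype_matrix(individuals, chrom, np.asarray(positions))
    codes = np.array(["B", "H", "A"])[counts]
    if missing_rate > 0:
        rng = np.random.default_rng(seed)
        mask = rng.random(codes.shape) < missing_rate
        codes = np.where(mask, "-", codes)
    cols = [f"C{chrom}_{p}" for p in positions]
    df = pd.DataFrame(codes, columns=cols)
    df.insert(0, "line_id", [f"L{i:04d}" for i in range(len(individuals))])
    return df


def write_truth(config: SimConfig, path: str) -> None:
    """Record the planted QTL and key generator settings as JSON."""
    payload = {
        "seed": config.seed,
        "n_individuals": config.n_individuals,
        "bulk_size": config.bulk_size,
        "qtl": [
            {
                "chrom": q.chrom,
                "pos": q.pos,
                "additive": q.additive,
                "dominance": q.dominance,
            }
            for q in config.qtl
        ],
        "alt_allele": "tolerant_parent",
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
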