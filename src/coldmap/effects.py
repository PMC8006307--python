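"""SNP effect classification against gene models.

Each SNP is placed into one of five categories — intergenic, intronic, UTR,
synonymous, nonsynonymous — by containment tests against GFF3 gene models
in priority order CDS > UTR > intron > intergenic, with the first
overlapping transcript winning. For coding SNPs the codon is rebuilt in
transcript orientation (reverse-complemented on the minus strand) and
translated with the standard genetic code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

CATEGORIES = ("intergenic", "intronic", "UTR", "synonymous", "nonsynonymous")


@dataclass
class GeneModel:
    """One transcript: ordered exons/CDS (1-based closed genomic intervals)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def utr_intervals(self) -> List[Tuple[int, int]]:
        """Exonic, non-CDS intervals (5' and 3' UTR merged into one class)."""
        out = []
        for es, ee in self.exons:
            cursor = es
            for cs, ce in self.cds:
                if ce < es or cs > ee:
                    continue
                if cs > cursor:
                    out.append((cursor, cs - 1))
                cursor = max(cursor, ce + 1)
            if cursor <= ee:
                out.append((cursor, ee))
        return out


@dataclass(frozen=True)
class EffectCall:
    """Classification of one SNP against the gene models."""

    chrom: str
    pos: int
    ref: str
    alt: str
    category: str
    gene_id: Optional[str] = None
    codon_change: Optional[str] = None
    aa_change: Optional[str] = None


def load_gene_models(gff3_path: str) -> List[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into transcript models.

    Transcripts whose CDS length is not a multiple of 3 are skipped with a
    warning rather than aborting the run.
    """
    db = gffutils.create_db(
        gff3_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: List[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        if not exons:
            exons = sorted(cds)
        try:
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=mrna.id,
                    chrom=mrna.seqid,
                    strand=mrna.strand,
                    exons=exons,
                    cds=cds,
                )
            )
        except ValueError as exc:
            logger.warning("skipping transcript: %s", exc)
    return models


def _contains(intervals: Sequence[Tuple[int, int]], pos: int) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _classify_coding(
    snp_pos: int, ref: str, alt: str, model: GeneModel, fasta: Fasta
) -> Tuple[str, str, str]:
    """Rebuild and translate the affected codon; returns category + changes."""
    cds_seq = "".join(
        str(fasta[model.chrom][s - 1 : e]) for s, e in model.cds
    ).upper()
    offset = 0
    cds_pos = None
    for s, e in model.cds:
        if s <= snp_pos <= e:
            cds_pos = offset + (snp_pos - s)
            break
        offset += e - s + 1
    assert cds_pos is not None
    ref_in_cds = cds_seq[cds_pos]
    if ref_in_cds != ref.upper():
        raise ValueError(
            f"reference mismatch at {model.chrom}:{snp_pos}: "
            f"FASTA has {ref_in_cds}, variant says {ref}"
        )
    mutated = cds_seq[:cds_pos] + alt.upper() + cds_seq[cds_pos + 1 :]
    if model.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
        cds_pos = len(cds_seq) - 1 - cds_pos
    codon_idx = cds_pos // 3
    ref_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    alt_codon = mutated[codon_idx * 3 : codon_idx * 3 + 3]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    category = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    return (
        category,
        f"{ref_codon}>{alt_codon}",
        f"{ref_aa}{codon_idx + 1}{alt_aa}",
    )


def classify_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    models: Sequence[GeneModel],
    fasta: Fasta,
) -> EffectCall:
    """Classify one SNP; the first transcript containing it wins.

    The reference base is checked against the FASTA and a mismatch raises,
    naming the position.
    """
    genomic = str(fasta[chrom][pos - 1]).upper()
    if genomic != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: FASTA has {genomic}, variant says {ref}"
        )
    for model in models:
        if model.chrom != chrom:
            continue
        lo, hi = model.span
        if not (lo <= pos <= hi):
            continue
        if _contains(model.cds, pos):
            category, codon_change, aa_change = _classify_coding(
                pos, ref, alt, model, fasta
            )
            return EffectCall(
                chrom, pos, ref, alt, category, model.gene_id, codon_change, aa_change
            )
        if _contains(model.utr_intervals(), pos):
            return EffectCall(chrom, pos, ref, alt, "UTR", model.gene_id)
        return EffectCall(chrom, pos, ref, alt, "intronic", model.gene_id)
    return EffectCall(chrom, pos, ref, alt, "intergenic")


def summarize_effects(
    calls: Sequence[EffectCall],
) -> Tuple[Dict[str, int], pd.DataFrame]:
    """Category counts plus the per-gene nonsynonymous-SNP table.

    Returns the count dict (all five categories plus ``genic`` and
    ``total``) and a frame listing genes carrying at least one
    nonsynonymous SNP with the SNP positions and amino-acid changes.
    """
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    counts["total"] = len(calls)
    counts["genic"] = counts["total"] - counts["intergenic"]
    rows = [
        {
            "gene_id": c.gene_id,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "codon_change": c.codon_change,
            "aa_change": c.aa_change,
        }
        for c in calls
        if c.category == "nonsynonymous"
    ]
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "pos", "ref", "alt", "codon_change", "aa_change"],
    )
    return counts, table
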