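"""Candidate risk-SNP calling, gene mapping and tag-SNP comparison.

SNPs with prediction score > 0.5 become candidate calls; candidates are
mapped to genes through promoters (3 kb strictly upstream of the TSS,
strand-aware) and enhancer intervals linked to genes in an input file —
deliberately not through nearest-gene assignment, since the closest gene
is typically not the regulatory target.  Blocks that also contain a
genome-wide-significant tag-SNP (p < 5e-8) are flagged, and the gene sets
reached from candidates in flagged blocks versus from the tag-SNPs
themselves are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .blocks import (
    GENOME_WIDE_SIG,
    AssociationBlock,
    SummaryStatRecord,
    normalize_chrom,
)

PROMOTER_BP = 3000


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: str
    strand: str
    tss: int  # 1-based
    enhancers: list[tuple[str, int, int]] = field(default_factory=list)  # 0-based half-open

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        self.chrom = normalize_chrom(self.chrom)
        for c, s, e in self.enhancers:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty enhancer [{s}, {e})")


@dataclass
class CandidateCall:
    snp_id: str
    block_id: str
    score: float
    is_lead: bool
    genes: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, via)
    block_has_tag_snp: bool = False


def read_gene_annotations(
    genes_path: str | Path, enhancers_path: str | Path | None = None
) -> list[GeneAnnotation]:
    """Load genes from a TSV (gene_id, chrom, strand, tss) and optional
    enhancer links from a BED file whose 4th column names the target gene."""
    df = pd.read_csv(genes_path, sep="\t", dtype={"chrom": str})
    genes = {
        str(r.gene_id): GeneAnnotation(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss))
        for r in df.itertuples(index=False)
    }
    if enhancers_path is not None:
        enh = pd.read_csv(
            enhancers_path, sep="\t", header=None, usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "gene_id"], dtype={"chrom": str},
        )
        for r in enh.itertuples(index=False):
            gid = str(r.gene_id)
            if gid in genes:
                genes[gid].enhancers.append(
                    (normalize_chrom(r.chrom), int(r.start), int(r.end))
                )
    return list(genes.values())


def call_candidates(
    scores: pd.DataFrame, threshold: float = 0.5
) -> list[CandidateCall]:
    """SNPs with prediction score strictly greater than ``threshold``."""
    calls = []
    for r in scores.itertuples(index=False):
        if r.score > threshold:
            calls.append(
                CandidateCall(
                    snp_id=str(r.snp_id),
                    block_id=str(r.block_id),
                    score=float(r.score),
                    is_lead=bool(getattr(r, "is_lead", False)),
                )
            )
    return calls


def map_snp_to_genes(
    snp: SummaryStatRecord,
    genes: Sequence[GeneAnnotation],
    promoter_bp: int = PROMOTER_BP,
) -> list[tuple[str, str]]:
    """Genes whose promoter or enhancer the SNP falls in.

    The promoter is the ``promoter_bp`` window strictly upstream of the
    TSS: on the + strand positions [tss - promoter_bp, tss), on the -
    strand positions (tss, tss + promoter_bp].  Enhancer overlap tests the
    SNP's 0-based coordinate (pos - 1) against half-open intervals.  A SNP
    may map to several genes; all mappings are kept.
    """
    chrom = normalize_chrom(snp.chrom)
    hits: list[tuple[str, str]] = []
    for g in genes:
        if g.chrom == chrom:
            if g.strand == "+":
                in_promoter = g.tss - promoter_bp <= snp.pos < g.tss
            else:
                in_promoter = g.tss < snp.pos <= g.tss + promoter_bp
            if in_promoter:
                hits.append((g.gene_id, "promoter"))
        for c, s, e in g.enhancers:
            if c == chrom and s <= snp.pos - 1 < e:
                hits.append((g.gene_id, "enhancer"))
                break
    return hits


def flag_tag_blocks(
    blocks: Sequence[AssociationBlock],
    candidates: Sequence[CandidateCall],
    genes: Sequence[GeneAnnotation],
    gwas_threshold: float = GENOME_WIDE_SIG,
) -> pd.DataFrame:
    """Flag blocks containing a tag-SNP and compare the two gene sets.

    A block is flagged iff any member's p-value is strictly below
    ``gwas_threshold``.  Candidate calls in flagged blocks have their
    ``block_has_tag_snp`` flag set (in place).  Returns a table comparing
    the genes mapped from candidates in flagged blocks with the genes
    mapped from the tag-SNPs themselves.
    """
    block_map = {b.block_id: b for b in blocks}
    member_map = {
        (b.block_id, m.snp_id): m for b in blocks for m in b.members
    }
    flagged = {
        b.block_id for b in blocks if any(m.p_value < gwas_threshold for m in b.members)
    }
    candidate_genes: set[str] = set()
    for call in candidates:
        call.block_has_tag_snp = call.block_id in flagged
        snp = member_map.get((call.block_id, call.snp_id))
        if snp is not None:
            call.genes = map_snp_to_genes(snp, genes)
            if call.block_has_tag_snp:
                candidate_genes.update(g for g, _ in call.genes)
    tag_genes: set[str] = set()
    for b in blocks:
        for m in b.members:
            if m.p_value < gwas_threshold:
                tag_genes.update(g for g, _ in map_snp_to_genes(m, genes))
    shared = candidate_genes & tag_genes
    rows = (
        [("candidate_only", g) for g in sorted(candidate_genes - tag_genes)]
        + [("shared", g) for g in sorted(shared)]
        + [("tag_only", g) for g in sorted(tag_genes - candidate_genes)]
    )
    return pd.DataFrame(rows, columns=["set", "gene_id"])


def candidates_frame(candidates: Sequence[CandidateCall]) -> pd.DataFrame:
    """Flatten candidate calls to one row per (SNP, gene) pair."""
    rows = []
    for c in candidates:
        targets = c.genes or [("", "")]
        for gene_id, via in targets:
            rows.append(
                (c.snp_id, c.block_id, c.score, gene_id, via,
                 c.block_has_tag_snp, c.is_lead)
            )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "block_id", "score", "gene_id", "via",
                 "block_has_tag_snp", "is_lead"],
    )
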