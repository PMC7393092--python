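"""Association-block construction from GWAS summary statistics.

An *association block* is a lead SNP (the locally strongest association,
leads forced > 1 Mb apart) together with the most significant neighboring
SNPs within a flanking window, capped at 30 members in total.  Each block
carries an uncertainty weight derived from its minimum p-value: blocks with
genome-wide-significant minima are the most trusted positive training bags,
blocks barely below the 5e-4 inclusion threshold the least.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: SNPs with association p-value above this are discarded outright.
GWAS_P_MAX = 5e-4
#: Conventional genome-wide significance threshold (tag-SNP definition).
GENOME_WIDE_SIG = 5e-8

DEFAULT_COLUMNS = {"snp_id": "SNP", "chrom": "CHR", "pos": "BP", "p_value": "P"}

TRUE_CASE = "true_case"
CONTROL = "control"


class SummaryStatsFormatError(ValueError):
    """The summary-statistics file is structurally malformed (e.g. missing column)."""


class SummaryStatsValidationError(ValueError):
    """A data row fails validation (non-numeric or out-of-range value)."""


class BlockConsistencyError(ValueError):
    """Blocks or leads are inconsistent with the records they were built from."""


def normalize_chrom(chrom: str) -> str:
    """Strip an optional 'chr' prefix so 'chr3' and '3' compare equal."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


def chrom_sort_key(chrom: str) -> tuple:
    c = normalize_chrom(chrom)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP from a GWAS summary-statistics file (1-based coordinate)."""

    snp_id: str
    chrom: str
    pos: int
    p_value: float


def _rank_key(r: SummaryStatRecord) -> tuple:
    # p ascending, ties broken by (chrom, pos) ascending for reproducibility
    return (r.p_value, chrom_sort_key(r.chrom), r.pos)


@dataclass
class AssociationBlock:
    block_id: str
    lead_snp: SummaryStatRecord
    members: list[SummaryStatRecord]  # ordered by position, includes the lead
    min_p: float
    label: str
    weight: int
    chrom: str

    def __post_init__(self) -> None:
        if not (1 <= len(self.members) <= 30):
            raise BlockConsistencyError(
                f"{self.block_id}: block size {len(self.members)} outside [1, 30]"
            )
        if self.lead_snp not in self.members:
            raise BlockConsistencyError(f"{self.block_id}: lead SNP not a member")

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive (start, end) positions covered by the block."""
        positions = [m.pos for m in self.members]
        return min(positions), max(positions)


def read_summary_stats(
    path: str | Path,
    columns: dict[str, str] | None = None,
) -> list[SummaryStatRecord]:
    """Read a tab-separated summary-statistics file into validated records.

    Parameters
    ----------
    path
        TSV file with a header row naming at least the SNP id, chromosome,
        position and p-value columns.
    columns
        Mapping from field name (``snp_id``, ``chrom``, ``pos``, ``p_value``)
        to the column header used in the file.  Defaults to
        ``SNP / CHR / BP / P``.

    Raises
    ------
    SummaryStatsFormatError
        If a required column is missing from the header.
    SummaryStatsValidationError
        If a row carries a non-numeric position or p-value, a p-value
        outside (0, 1], a position < 1, or a duplicated (chrom, pos).
        The error message names the offending 1-based file line.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for key, name in cols.items():
        if name not in df.columns:
            raise SummaryStatsFormatError(
                f"{path}: required column {name!r} (for {key}) not found in header"
            )
    records: list[SummaryStatRecord] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        raw = dict(zip(df.columns, row))
        try:
            pos = int(float(raw[cols["pos"]]))
            p = float(raw[cols["p_value"]])
        except (TypeError, ValueError):
            raise SummaryStatsValidationError(
                f"{path}: line {line}: non-numeric position or p-value"
            ) from None
        if not (0.0 < p <= 1.0):
            raise SummaryStatsValidationError(
                f"{path}: line {line}: p-value {p!r} outside (0, 1]"
            )
        if pos < 1:
            raise SummaryStatsValidationError(
                f"{path}: line {line}: position {pos} < 1"
            )
        chrom = normalize_chrom(raw[cols["chrom"]])
        key = (chrom, pos)
        if key in seen:
            raise SummaryStatsValidationError(
                f"{path}: line {line}: duplicate (chrom, pos) = {key}"
            )
        seen.add(key)
        records.append(SummaryStatRecord(str(raw[cols["snp_id"]]), chrom, pos, p))
    return records


def select_lead_snps(
    records: Iterable[SummaryStatRecord],
    p_max: float = GWAS_P_MAX,
    min_spacing: int = 1_000_000,
) -> list[SummaryStatRecord]:
    """Greedy lead-SNP selection.

    SNPs with p > ``p_max`` are discarded; the remaining SNP with the
    smallest p-value becomes a lead and every SNP on the same chromosome
    within ``min_spacing`` bp of it is removed; repeat until exhausted.
    Selected leads on one chromosome are therefore > ``min_spacing`` apart.
    Ties in p-value are broken by (chrom, pos) ascending.
    """
    remaining = sorted((r for r in records if r.p_value <= p_max), key=_rank_key)
    leads: list[SummaryStatRecord] = []
    while remaining:
        lead = remaining[0]
        leads.append(lead)
        remaining = [
            r
            for r in remaining[1:]
            if r.chrom != lead.chrom or abs(r.pos - lead.pos) > min_spacing
        ]
    return leads


def assign_block_weight(min_p: float | None = None, *, control: bool = False) -> int:
    """Tiered uncertainty weight for a block label.

    True-case blocks are weighted by how strongly their best SNP associates:

    ======================  ======
    block minimum p-value   weight
    ======================  ======
    < 5e-8                  10
    [5e-8, 5e-7)             8
    [5e-7, 5e-6)             6
    [5e-6, 5e-5)             4
    [5e-5, 5e-4)             2
    control (false case)     2
    ======================  ======

    Boundaries are strict on the stronger side: a minimum of exactly 5e-8
    falls in the weight-8 tier.
    """
    if control:
        return 2
    if min_p is None:
        raise ValueError("min_p is required for true-case blocks")
    if not 0.0 < min_p:
        raise ValueError(f"min_p must be positive, got {min_p}")
    if min_p >= GWAS_P_MAX:
        raise ValueError(
            f"true-case block with min_p {min_p} >= {GWAS_P_MAX}: block should not exist"
        )
    if min_p < 5e-8:
        return 10
    if min_p < 5e-7:
        return 8
    if min_p < 5e-6:
        return 6
    if min_p < 5e-5:
        return 4
    return 2


def build_blocks(
    records: Sequence[SummaryStatRecord],
    leads: Sequence[SummaryStatRecord],
    max_block_size: int = 30,
    window: int = 1_000_000,
    p_max: float = GWAS_P_MAX,
) -> list[AssociationBlock]:
    """Build non-overlapping association blocks around selected leads.

    Each block contains its lead plus the most significant SNPs with
    p <= ``p_max`` on the same chromosome within +/- ``window`` bp of the
    lead, capped at ``max_block_size`` members total.  A SNP qualifying for
    several leads is assigned to exactly one: the lead with the smaller
    p-value wins, then the nearer lead, then the lead at the lower position.
    """
    record_set = set(records)
    for lead in leads:
        if lead not in record_set:
            raise BlockConsistencyError(f"lead {lead.snp_id} not among input records")
    lead_set = set(leads)
    assigned: dict[SummaryStatRecord, list[SummaryStatRecord]] = {l: [] for l in leads}
    for r in records:
        if r in lead_set or r.p_value > p_max:
            continue
        eligible = [
            l for l in leads if l.chrom == r.chrom and abs(l.pos - r.pos) <= window
        ]
        if not eligible:
            continue
        owner = min(eligible, key=lambda l: (l.p_value, abs(l.pos - r.pos), l.pos))
        assigned[owner].append(r)
    blocks: list[AssociationBlock] = []
    for i, lead in enumerate(leads):
        neighbors = sorted(assigned[lead], key=_rank_key)[: max_block_size - 1]
        members = sorted([lead, *neighbors], key=lambda m: m.pos)
        min_p = min(m.p_value for m in members)
        blocks.append(
            AssociationBlock(
                block_id=f"block_{i + 1:04d}",
                lead_snp=lead,
                members=members,
                min_p=min_p,
                label=TRUE_CASE,
                weight=assign_block_weight(min_p),
                chrom=lead.chrom,
            )
        )
    return blocks


def _default_roles() -> dict[str, frozenset[str]]:
    return {
        "train": frozenset(str(c) for c in range(1, 11)),
        "test": frozenset(str(c) for c in range(11, 15)),
        "validation": frozenset(str(c) for c in range(15, 23)),
    }


@dataclass(frozen=True)
class SplitAssignment:
    """Chromosome-level train/validation/test partition.

    Defaults: chromosomes 1-10 train, 11-14 test, 15-22 validation.
    """

    train: frozenset[str] = field(default_factory=lambda: _default_roles()["train"])
    validation: frozenset[str] = field(
        default_factory=lambda: _default_roles()["validation"]
    )
    test: frozenset[str] = field(default_factory=lambda: _default_roles()["test"])

    def __post_init__(self) -> None:
        norm = {
            role: frozenset(normalize_chrom(c) for c in chroms)
            for role, chroms in (
                ("train", self.train),
                ("validation", self.validation),
                ("test", self.test),
            )
        }
        if (
            norm["train"] & norm["validation"]
            or norm["train"] & norm["test"]
            or norm["validation"] & norm["test"]
        ):
            raise ValueError("split roles must have disjoint chromosome sets")
        for role, chroms in norm.items():
            object.__setattr__(self, role, chroms)

    def role_of(self, chrom: str) -> str | None:
        c = normalize_chrom(chrom)
        if c in self.train:
            return "train"
        if c in self.validation:
            return "validation"
        if c in self.test:
            return "test"
        return None


def split_by_chromosome(
    blocks: Sequence[AssociationBlock],
    assignment: SplitAssignment | None = None,
    unassigned: str = "drop",
) -> tuple[list[AssociationBlock], list[AssociationBlock], list[AssociationBlock]]:
    """Partition blocks into (train, validation, test) lists by chromosome.

    A block whose chromosome appears in no role is dropped with a warning by
    default, or rejected when ``unassigned='error'``.
    """
    assignment = assignment or SplitAssignment()
    out: dict[str, list[AssociationBlock]] = {"train": [], "validation": [], "test": []}
    for b in blocks:
        role = assignment.role_of(b.chrom)
        if role is None:
            if unassigned == "error":
                raise ValueError(f"{b.block_id}: chromosome {b.chrom} in no split role")
            warnings.warn(
                f"{b.block_id}: chromosome {b.chrom} in no split role; dropped",
                stacklevel=2,
            )
            continue
        out[role].append(b)
    return out["train"], out["validation"], out["test"]


def write_blocks(blocks: Sequence[AssociationBlock], out_dir: str | Path) -> Path:
    """Write blocks.tsv (one row per member SNP) and blocks.bed (block spans)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "block_id": b.block_id,
            "snp_id": m.snp_id,
            "chrom": m.chrom,
            "pos": m.pos,
            "p": m.p_value,
            "is_lead": int(m == b.lead_snp),
            "weight": b.weight,
        }
        for b in blocks
        for m in b.members
    ]
    pd.DataFrame(rows).to_csv(
        out / "blocks.tsv", sep="\t", index=False, float_format="%.17g"
    )
    with open(out / "blocks.bed", "w") as fh:
        for b in blocks:
            start, end = b.span
            fh.write(f"{b.chrom}\t{start - 1}\t{end}\t{b.block_id}\n")
    return out / "blocks.tsv"


def read_blocks(path: str | Path) -> list[AssociationBlock]:
    """Reconstruct blocks from a blocks.tsv written by :func:`write_blocks`."""
    p = Path(path)
    if p.is_dir():
        p = p / "blocks.tsv"
    df = pd.read_csv(p, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    blocks: list[AssociationBlock] = []
    for block_id, grp in df.groupby("block_id", sort=True):
        members = [
            SummaryStatRecord(str(r.snp_id), normalize_chrom(r.chrom), int(r.pos), float(r.p))
            for r in grp.itertuples(index=False)
        ]
        members.sort(key=lambda m: m.pos)
        lead_rows = grp[grp.is_lead == 1]
        if len(lead_rows) != 1:
            raise BlockConsistencyError(f"{block_id}: expected exactly one lead row")
        lr = lead_rows.iloc[0]
        lead = SummaryStatRecord(
            str(lr.snp_id), normalize_chrom(lr.chrom), int(lr.pos), float(lr.p)
        )
        min_p = min(m.p_value for m in members)
        blocks.append(
            AssociationBlock(
                block_id=str(block_id),
                lead_snp=lead,
                members=members,
                min_p=min_p,
                label=TRUE_CASE,
                weight=int(grp.weight.iloc[0]),
                chrom=lead.chrom,
            )
        )
    return blocks
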