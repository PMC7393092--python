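"""Binary SNP x feature maps from annotation tracks.

Positional tracks (DHS, histone marks, TFBS) arrive as BED intervals;
pathway tracks arrive as gene sets and are matched through a SNP-to-gene
map.  The per-block tensor pads every block to a fixed number of SNP slots
with an explicit presence mask, so downstream layers can ignore padding.

Control (false-case) blocks are built by shuffling feature annotations
within true blocks: per-block, per-feature-column permutation destroys
SNP-level feature co-occurrence while conserving each feature's marginal
count inside the block — the null the classifier is trained against.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

from .blocks import (
    AssociationBlock,
    SplitAssignment,
    SummaryStatRecord,
    normalize_chrom,
)

#: Histone marks associated with repression; excluded from importance analysis.
REPRESSIVE_MARKS = ("H3K9me3", "H3K27me3")


@dataclass
class AnnotationTrack:
    """One functional feature: either genomic intervals or a gene set."""

    name: str
    category: str
    intervals: dict[str, IntervalTree] | None = None
    genes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if (self.intervals is None) == (self.genes is None):
            raise ValueError(f"track {self.name}: exactly one of intervals/genes required")

    @classmethod
    def from_intervals(
        cls, name: str, category: str, intervals: Iterable[tuple[str, int, int]]
    ) -> "AnnotationTrack":
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"track {name}: empty interval [{start}, {end})")
            trees.setdefault(normalize_chrom(chrom), IntervalTree()).addi(start, end)
        return cls(name=name, category=category, intervals=trees)

    @classmethod
    def from_bed(cls, name: str, category: str, path: str | Path) -> "AnnotationTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], dtype={"chrom": str}, comment="#",
        )
        return cls.from_intervals(
            name, category, df.itertuples(index=False, name=None)
        )

    @property
    def is_repressive(self) -> bool:
        return "repressive" in self.category.lower() or any(
            m.lower() in self.name.lower() for m in REPRESSIVE_MARKS
        )

    def hits(self, snp: SummaryStatRecord, genes: Iterable[str] = ()) -> bool:
        if self.intervals is not None:
            tree = self.intervals.get(normalize_chrom(snp.chrom))
            # SNP is a 1-bp point: test 0-based coordinate pos-1 against
            # half-open intervals
            return bool(tree is not None and tree.overlaps_point(snp.pos - 1))
        assert self.genes is not None
        return any(g in self.genes for g in genes)


def load_tracks(manifest_path: str | Path) -> list[AnnotationTrack]:
    """Load tracks from a YAML manifest.

    Each manifest entry is ``{name, category, path, type}`` with type
    ``bed`` (one positional track) or ``gmt`` (one track per GMT line,
    named by the line's first field).  Paths are resolved relative to the
    manifest file.
    """
    manifest_path = Path(manifest_path)
    entries = yaml.safe_load(manifest_path.read_text())
    tracks: list[AnnotationTrack] = []
    for entry in entries:
        path = manifest_path.parent / entry["path"]
        kind = entry.get("type", "bed")
        if kind == "bed":
            tracks.append(AnnotationTrack.from_bed(entry["name"], entry["category"], path))
        elif kind == "gmt":
            for line in path.read_text().splitlines():
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                tracks.append(
                    AnnotationTrack(
                        name=fields[0],
                        category=entry["category"],
                        genes=frozenset(fields[2:]),
                    )
                )
        else:
            raise ValueError(f"unknown track type {kind!r} for {entry['name']}")
    return tracks


def annotate_snp(
    snp: SummaryStatRecord,
    tracks: Sequence[AnnotationTrack],
    gene_map: Mapping[str, Iterable[str]] | None = None,
) -> np.ndarray:
    """Binary feature vector for one SNP: 1 iff the SNP hits each track."""
    genes = tuple((gene_map or {}).get(snp.snp_id, ()))
    return np.array([t.hits(snp, genes) for t in tracks], dtype=np.uint8)


@dataclass
class FeatureTensor:
    """Blocks x padded SNP slots x binary features, with a presence mask."""

    block_ids: list[str]
    snp_ids: list[list[str]]
    chroms: list[str]
    values: np.ndarray  # (B, N, M) uint8
    mask: np.ndarray  # (B, N) bool
    lead_mask: np.ndarray  # (B, N) bool
    feature_names: list[str]
    feature_categories: list[str]
    labels: np.ndarray  # (B,) int, 1 = true case
    weights: np.ndarray  # (B,) float

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be (blocks, slots, features)")
        if ((self.values != 0) & ~self.mask[:, :, None]).any():
            raise ValueError("nonzero entries in masked slots")

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    @property
    def n_slots(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def select_blocks(self, idx: Sequence[int]) -> "FeatureTensor":
        idx = list(idx)
        return replace(
            self,
            block_ids=[self.block_ids[i] for i in idx],
            snp_ids=[self.snp_ids[i] for i in idx],
            chroms=[self.chroms[i] for i in idx],
            values=self.values[idx].copy(),
            mask=self.mask[idx].copy(),
            lead_mask=self.lead_mask[idx].copy(),
            labels=self.labels[idx].copy(),
            weights=self.weights[idx].copy(),
        )

    def split(
        self, assignment: SplitAssignment | None = None
    ) -> tuple["FeatureTensor", "FeatureTensor", "FeatureTensor"]:
        """Partition blocks into (train, validation, test) tensors by chromosome."""
        assignment = assignment or SplitAssignment()
        roles = {"train": [], "validation": [], "test": []}
        for i, chrom in enumerate(self.chroms):
            role = assignment.role_of(chrom)
            if role is not None:
                roles[role].append(i)
        return tuple(self.select_blocks(roles[r]) for r in ("train", "validation", "test"))

    def snp_vectors(self) -> tuple[np.ndarray, list[tuple[str, str]]]:
        """All unmasked SNP feature vectors with their (block_id, snp_id) keys."""
        vecs, keys = [], []
        for b in range(self.n_blocks):
            for j in range(self.n_slots):
                if self.mask[b, j]:
                    vecs.append(self.values[b, j])
                    keys.append((self.block_ids[b], self.snp_ids[b][j]))
        return np.array(vecs, dtype=np.uint8).reshape(len(keys), self.n_features), keys

    def to_frame(self) -> pd.DataFrame:
        """Flat (block_id, snp_id, feature, value) table of unmasked entries."""
        rows = []
        for b in range(self.n_blocks):
            for j in range(self.n_slots):
                if not self.mask[b, j]:
                    continue
                for f, name in enumerate(self.feature_names):
                    rows.append(
                        (self.block_ids[b], self.snp_ids[b][j], name, int(self.values[b, j, f]))
                    )
        return pd.DataFrame(rows, columns=["block_id", "snp_id", "feature", "value"])


def concat_tensors(a: FeatureTensor, b: FeatureTensor) -> FeatureTensor:
    """Stack two tensors sharing the same feature axis and slot count."""
    if a.feature_names != b.feature_names:
        raise ValueError("feature axes differ")
    if a.n_slots != b.n_slots:
        raise ValueError("slot counts differ")
    return FeatureTensor(
        block_ids=a.block_ids + b.block_ids,
        snp_ids=a.snp_ids + b.snp_ids,
        chroms=a.chroms + b.chroms,
        values=np.concatenate([a.values, b.values]),
        mask=np.concatenate([a.mask, b.mask]),
        lead_mask=np.concatenate([a.lead_mask, b.lead_mask]),
        feature_names=list(a.feature_names),
        feature_categories=list(a.feature_categories),
        labels=np.concatenate([a.labels, b.labels]),
        weights=np.concatenate([a.weights, b.weights]),
    )


def build_feature_tensor(
    blocks: Sequence[AssociationBlock],
    tracks: Sequence[AnnotationTrack],
    gene_map: Mapping[str, Iterable[str]] | None = None,
    n_slots: int = 30,
) -> FeatureTensor:
    """Annotate every block member and assemble the padded binary tensor.

    SNPs are ordered within each block by position ascending; empty slots
    are masked and zero-filled.
    """
    n_blocks, n_feat = len(blocks), len(tracks)
    values = np.zeros((n_blocks, n_slots, n_feat), dtype=np.uint8)
    mask = np.zeros((n_blocks, n_slots), dtype=bool)
    lead_mask = np.zeros((n_blocks, n_slots), dtype=bool)
    snp_ids: list[list[str]] = []
    weights = np.empty(n_blocks)
    for b, block in enumerate(blocks):
        if len(block.members) > n_slots:
            raise ValueError(
                f"{block.block_id}: {len(block.members)} members exceed {n_slots} slots"
            )
        ids = []
        for j, snp in enumerate(sorted(block.members, key=lambda m: m.pos)):
            values[b, j] = annotate_snp(snp, tracks, gene_map)
            mask[b, j] = True
            lead_mask[b, j] = snp == block.lead_snp
            ids.append(snp.snp_id)
        ids.extend("" for _ in range(n_slots - len(ids)))
        snp_ids.append(ids)
        weights[b] = block.weight
    return FeatureTensor(
        block_ids=[b.block_id for b in blocks],
        snp_ids=snp_ids,
        chroms=[b.chrom for b in blocks],
        values=values,
        mask=mask,
        lead_mask=lead_mask,
        feature_names=[t.name for t in tracks],
        feature_categories=[t.category for t in tracks],
        labels=np.ones(n_blocks, dtype=int),
        weights=weights,
    )


@dataclass
class FilterReport:
    kept: list[str]
    dropped: list[str]
    absent_fraction: dict[str, float]


def filter_features(
    tensor: FeatureTensor, absent_fraction_threshold: float = 0.95
) -> tuple[FeatureTensor, FilterReport]:
    """Drop sparse features to curb overfitting.

    A feature is dropped iff the fraction of blocks in which *no* member
    SNP carries it is strictly greater than ``absent_fraction_threshold``
    (default: absent in > 95% of blocks).  Survivor order is preserved.
    """
    if not 0.0 < absent_fraction_threshold <= 1.0:
        raise ValueError("absent_fraction_threshold must lie in (0, 1]")
    present = (tensor.values.astype(bool) & tensor.mask[:, :, None]).any(axis=1)  # (B, M)
    absent_frac = 1.0 - present.mean(axis=0)
    keep = absent_frac <= absent_fraction_threshold
    report = FilterReport(
        kept=[n for n, k in zip(tensor.feature_names, keep) if k],
        dropped=[n for n, k in zip(tensor.feature_names, keep) if not k],
        absent_fraction=dict(zip(tensor.feature_names, absent_frac.tolist())),
    )
    filtered = replace(
        tensor,
        values=tensor.values[:, :, keep].copy(),
        feature_names=report.kept,
        feature_categories=[
            c for c, k in zip(tensor.feature_categories, keep) if k
        ],
    )
    return filtered, report


def generate_control_blocks(
    tensor: FeatureTensor,
    ratio: int = 10,
    seed: int | None = None,
    mode: str = "column",
) -> FeatureTensor:
    """Generate shuffled-feature control (false-case) blocks.

    Each control block is derived from a uniformly sampled true block
    (with replacement) by permuting annotations across that block's
    unmasked SNP slots — independently per feature column in ``column``
    mode (default), or as whole per-SNP rows in ``row`` mode.  Column mode
    conserves every feature's within-block count while destroying feature
    co-occurrence on individual SNPs.  All control weights are 2.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if mode not in ("column", "row"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    rng = np.random.default_rng(seed)
    n_controls = ratio * tensor.n_blocks
    values = np.zeros((n_controls, tensor.n_slots, tensor.n_features), dtype=np.uint8)
    mask = np.zeros((n_controls, tensor.n_slots), dtype=bool)
    block_ids, snp_ids, chroms = [], [], []
    sources = rng.integers(0, tensor.n_blocks, size=n_controls)
    for c, src in enumerate(sources):
        slots = np.flatnonzero(tensor.mask[src])
        sub = tensor.values[src, slots, :]
        if mode == "column":
            # independent permutation per feature column via random sort keys
            order = np.argsort(rng.random((len(slots), tensor.n_features)), axis=0)
            shuffled = np.take_along_axis(sub, order, axis=0)
        else:
            shuffled = sub[rng.permutation(len(slots))]
        values[c, slots, :] = shuffled
        mask[c, slots] = True
        bid = f"ctrl_{c + 1:05d}"
        block_ids.append(bid)
        chroms.append(tensor.chroms[src])
        ids = [f"{bid}:s{j + 1:02d}" if tensor.mask[src, j] else "" for j in range(tensor.n_slots)]
        snp_ids.append(ids)
    return FeatureTensor(
        block_ids=block_ids,
        snp_ids=snp_ids,
        chroms=chroms,
        values=values,
        mask=mask,
        lead_mask=np.zeros_like(mask),
        feature_names=list(tensor.feature_names),
        feature_categories=list(tensor.feature_categories),
        labels=np.zeros(n_controls, dtype=int),
        weights=np.full(n_controls, 2.0),
    )


def save_tensor(tensor: FeatureTensor, path: str | Path) -> None:
    """Serialize a tensor to a compressed .npz archive."""
    np.savez_compressed(
        path,
        values=tensor.values,
        mask=tensor.mask,
        lead_mask=tensor.lead_mask,
        labels=tensor.labels,
        weights=tensor.weights,
        block_ids=np.array(tensor.block_ids, dtype=str),
        chroms=np.array(tensor.chroms, dtype=str),
        snp_ids=np.array(tensor.snp_ids, dtype=str),
        feature_names=np.array(tensor.feature_names, dtype=str),
        feature_categories=np.array(tensor.feature_categories, dtype=str),
    )


def load_tensor(path: str | Path) -> FeatureTensor:
    with np.load(path, allow_pickle=False) as z:
        return FeatureTensor(
            block_ids=z["block_ids"].tolist(),
            snp_ids=[list(row) for row in z["snp_ids"]],
            chroms=z["chroms"].tolist(),
            values=z["values"],
            mask=z["mask"],
            lead_mask=z["lead_mask"],
            feature_names=z["feature_names"].tolist(),
            feature_categories=z["feature_categories"].tolist(),
            labels=z["labels"],
            weights=z["weights"],
        )
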