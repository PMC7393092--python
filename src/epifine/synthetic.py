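"""Self-contained synthetic datasets with planted causal SNPs.

The generator emulates the statistical structure the classifier assumes:
association blocks of linked SNPs whose minimum p-values fall in the five
uncertainty-weight tiers, sparse binary feature vectors, and — in causal
blocks — exactly one causal SNP whose vector is enriched in a designated
causal-feature subset.  Everything is written as ordinary text files
(summary-stats TSV, per-feature BED tracks with a YAML manifest, gene TSV,
enhancer BED) so the whole pipeline can be exercised end to end without
any external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .blocks import GWAS_P_MAX

#: (low, high) p-value range of each uncertainty-weight tier, strongest first.
WEIGHT_TIERS = (
    (1e-10, 5e-8),
    (5e-8, 5e-7),
    (5e-7, 5e-6),
    (5e-6, 5e-5),
    (5e-5, GWAS_P_MAX),
)

_CATEGORY_CYCLE = (
    "neural_DHS",
    "neural_histone",
    "neural_TFBS",
    "immune_DHS",
    "circulatory_histone",
    "digestive_DHS",
    "other_TFBS",
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults define the bundled benchmark: 25 blocks of 30 SNPs, 200
    features of which 20 are causal, 20 causal blocks, causal SNPs carrying
    each causal feature with probability 0.7 against a 0.05 background.
    """

    n_blocks: int = 25
    snps_per_block: int = 30
    n_features: int = 200
    n_causal_features: int = 20
    n_causal_blocks: int = 20
    causal_feature_prob: float = 0.7
    background_prob: float = 0.05
    p_tier_mix: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    seed: int = 17

    def __post_init__(self) -> None:
        if not 1 <= self.snps_per_block <= 30:
            raise ValueError("snps_per_block must lie in [1, 30]")
        if self.n_causal_features > self.n_features:
            raise ValueError("n_causal_features exceeds n_features")
        if self.n_causal_blocks > self.n_blocks:
            raise ValueError("n_causal_blocks exceeds n_blocks")
        if not self.causal_feature_prob > self.background_prob:
            raise ValueError("causal_feature_prob must exceed background_prob")
        if len(self.p_tier_mix) != len(WEIGHT_TIERS):
            raise ValueError(f"p_tier_mix needs {len(WEIGHT_TIERS)} entries")
        if not math.isclose(sum(self.p_tier_mix), 1.0, abs_tol=1e-9):
            raise ValueError("p_tier_mix must sum to 1")


@dataclass
class GroundTruth:
    causal_snp_ids: set[str]
    causal_feature_names: set[str]
    causal_block_leads: dict[str, bool]  # lead snp_id -> block is causal
    tier_assignment: dict[str, int] = field(default_factory=dict)  # lead -> tier index

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "causal_snp_ids": sorted(self.causal_snp_ids),
                    "causal_feature_names": sorted(self.causal_feature_names),
                    "causal_block_leads": self.causal_block_leads,
                    "tier_assignment": self.tier_assignment,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            causal_snp_ids=set(d["causal_snp_ids"]),
            causal_feature_names=set(d["causal_feature_names"]),
            causal_block_leads=d["causal_block_leads"],
            tier_assignment=d.get("tier_assignment", {}),
        )


def _noncausal_block_indices(n_blocks: int, n_causal: int) -> set[int]:
    # interleave non-causal blocks deterministically (last block of each
    # stride group) so every chromosome split contains causal signal
    n_nonc = n_blocks - n_causal
    if n_nonc == 0:
        return set()
    stride = n_blocks // n_nonc
    return {min(j * stride + stride - 1, n_blocks - 1) for j in range(n_nonc)}


def _loguniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Path, Path, Path, GroundTruth]:
    """Write a complete synthetic dataset and return its key paths.

    Blocks are laid out on chromosomes 1-22 (round robin), >= 2 Mb apart
    within a chromosome, with members 1 kb apart.  The block's lead SNP
    carries the minimum p-value, drawn log-uniformly inside the tier
    sampled from ``p_tier_mix``; other members draw log-uniformly between
    that minimum and the 5e-4 retention bound.  Feature vectors are
    Bernoulli(background_prob) everywhere except the one causal SNP per
    causal block, whose causal features are Bernoulli(causal_feature_prob).
    Tracks are emitted as 1-bp BED intervals realizing the vectors exactly.

    Returns (sumstats_path, manifest_path, genes_path, ground_truth).
    """
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    nb, ns, nf = config.n_blocks, config.snps_per_block, config.n_features
    feature_names = [f"F{f:04d}" for f in range(nf)]
    categories = [_CATEGORY_CYCLE[f % len(_CATEGORY_CYCLE)] for f in range(nf)]
    causal_features = feature_names[: config.n_causal_features]
    noncausal_blocks = _noncausal_block_indices(nb, config.n_causal_blocks)

    snp_rows = []  # (snp_id, chrom, pos)
    values = (rng.random((nb, ns, nf)) < config.background_prob).astype(np.uint8)
    truth = GroundTruth(set(), set(causal_features), {})
    gene_rows = []
    enhancer_rows = []
    per_chrom_count: dict[int, int] = {}
    for b in range(nb):
        chrom = b % 22 + 1
        slot_on_chrom = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = slot_on_chrom + 1
        start = 10_000_000 + slot_on_chrom * 3_000_000
        positions = [start + j * 1_000 for j in range(ns)]
        lead_slot = ns // 2
        tier = int(rng.choice(len(WEIGHT_TIERS), p=config.p_tier_mix))
        low, high = WEIGHT_TIERS[tier]
        min_p = _loguniform(rng, low * 1.01, high * 0.99)
        pvals = [_loguniform(rng, min_p, GWAS_P_MAX * 0.998) for _ in range(ns)]
        pvals[lead_slot] = min_p
        ids = [f"snp_b{b:03d}_{j:02d}" for j in range(ns)]
        for j in range(ns):
            snp_rows.append((ids[j], chrom, positions[j], pvals[j]))
        lead_id = ids[lead_slot]
        causal = b not in noncausal_blocks
        truth.causal_block_leads[lead_id] = causal
        truth.tier_assignment[lead_id] = tier
        if causal:
            causal_slot = int(rng.integers(ns))
            causal_mask = rng.random(config.n_causal_features) < config.causal_feature_prob
            values[b, causal_slot, : config.n_causal_features] = causal_mask
            truth.causal_snp_ids.add(ids[causal_slot])
        gene_id = f"GENE{b:03d}"
        tss = positions[lead_slot] + 1500
        gene_rows.append((gene_id, chrom, "+", tss))
        if causal:
            cpos = positions[causal_slot]
            enhancer_rows.append((chrom, cpos - 51, cpos + 50, gene_id))

    sumstats_path = out / "sumstats.tsv"
    with open(sumstats_path, "w") as fh:
        fh.write("SNP\tCHR\tBP\tP\n")
        for sid, chrom, pos, p in snp_rows:
            fh.write(f"{sid}\t{chrom}\t{pos}\t{p:.8e}\n")

    # 1-bp interval per (feature, carrying SNP): [pos-1, pos) 0-based half-open
    manifest = []
    pos_lookup = [(r[1], r[2]) for r in snp_rows]
    flat = values.reshape(nb * ns, nf)
    for f, name in enumerate(feature_names):
        bed_path = out / "tracks" / f"{name}.bed"
        with open(bed_path, "w") as fh:
            for i in np.flatnonzero(flat[:, f]):
                chrom, pos = pos_lookup[i]
                fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{name}\n")
        manifest.append(
            {"name": name, "category": categories[f],
             "path": f"tracks/{name}.bed", "type": "bed"}
        )
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))

    genes_path = out / "genes.tsv"
    with open(genes_path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for gid, chrom, strand, tss in gene_rows:
            fh.write(f"{gid}\t{chrom}\t{strand}\t{tss}\n")
    with open(out / "enhancers.bed", "w") as fh:
        for chrom, s, e, gid in enhancer_rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{gid}\n")
    truth.to_json(out / "truth.json")
    return sumstats_path, manifest_path, genes_path, truth


def score_recovery(
    truth: GroundTruth,
    called_snp_ids: set[str],
    eligible_snp_ids: set[str] | None = None,
    importance_ranking: list[str] | None = None,
) -> dict:
    """Recovery metrics of the planted signal.

    ``called_snp_ids`` are the SNPs called at score > 0.5 (restricted to
    true blocks); ``eligible_snp_ids`` (default: all called) lets callers
    compute the non-causal positive rate; ``importance_ranking`` is the
    feature list sorted by decreasing Gini importance.
    """
    causal = truth.causal_snp_ids
    unknown = called_snp_ids - (eligible_snp_ids or called_snp_ids)
    if unknown:
        raise ValueError(f"called SNPs not among eligible ids: {sorted(unknown)[:5]}")
    hits = called_snp_ids & causal
    out = {
        "snp_recall": len(hits) / len(causal) if causal else float("nan"),
        "snp_precision": len(hits) / len(called_snp_ids) if called_snp_ids else 0.0,
    }
    if eligible_snp_ids is not None:
        noncausal = eligible_snp_ids - causal
        out["noncausal_positive_rate"] = (
            len(called_snp_ids - causal) / len(noncausal) if noncausal else 0.0
        )
    if importance_ranking is not None:
        top = set(importance_ranking[: len(truth.causal_feature_names)])
        out["feature_recall"] = (
            len(top & truth.causal_feature_names) / len(truth.causal_feature_names)
        )
    return out
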