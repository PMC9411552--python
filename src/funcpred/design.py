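"""Stratified 80/20 splitting and balanced negative-block partitioning.

The positive class is split once; training negatives are partitioned into
disjoint blocks equal in size to the positive training set, one block per
ensemble member, so each negative gene is used at most once. Leftover
negatives (pool size mod block size) are excluded and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import LabelSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    pos_train: tuple[str, ...]
    pos_test: tuple[str, ...]
    neg_train: tuple[str, ...]
    neg_test: tuple[str, ...]
    test_fraction: float
    seed: int

    def __post_init__(self) -> None:
        pt, ps = set(self.pos_train), set(self.pos_test)
        nt, ns = set(self.neg_train), set(self.neg_test)
        if pt & ps or nt & ns or (pt | ps) & (nt | ns):
            raise ValueError("split partitions are not disjoint")


@dataclass(frozen=True)
class BalancedEnsembleDesign:
    """Training sets = fixed positive training genes + one disjoint negative block each."""

    pos_train: tuple[str, ...]
    neg_blocks: tuple[tuple[str, ...], ...]
    leftover_negatives: tuple[str, ...]
    seed: int

    @property
    def n_sets(self) -> int:
        return len(self.neg_blocks)

    @property
    def training_sets(self) -> list[list[str]]:
        return [list(self.pos_train) + list(b) for b in self.neg_blocks]


def stratified_split(labels: LabelSet, test_fraction: float, seed: int) -> SplitSpec:
    """Class-stratified random split; per class, floor(test_fraction * n)
    genes go to the test side (92 positives at 0.2 -> 74 train / 18 test)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if len(labels.positives) < 2:
        raise ValueError("need at least 2 positive genes to split")
    rng = np.random.default_rng(seed)

    def _split(ids: Sequence[str]) -> tuple[list[str], list[str]]:
        ids = sorted(ids)
        n_test = math.floor(test_fraction * len(ids))
        if n_test == 0 or n_test == len(ids):
            raise ValueError(
                f"test_fraction {test_fraction} leaves an empty partition for {len(ids)} genes"
            )
        perm = rng.permutation(len(ids))
        test = sorted(ids[i] for i in perm[:n_test])
        train = sorted(ids[i] for i in perm[n_test:])
        return train, test

    pos_train, pos_test = _split(sorted(labels.positives))
    neg_train, neg_test = _split(sorted(labels.negatives))
    return SplitSpec(
        tuple(pos_train), tuple(pos_test), tuple(neg_train), tuple(neg_test),
        test_fraction, seed,
    )


def partition_negatives(
    neg_ids: Sequence[str], block_size: int, seed: int
) -> tuple[list[list[str]], list[str]]:
    """Randomly partition ids into floor(n / block_size) disjoint blocks.

    Returns ``(blocks, leftover)``; ``len(leftover) == n % block_size``.
    A pool smaller than one block yields zero blocks and a warning.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    ids = sorted(neg_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in the negative pool")
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(len(ids))]
    n_blocks = len(ids) // block_size
    if n_blocks == 0:
        logger.warning(
            "negative pool of %d smaller than block size %d: zero blocks", len(ids), block_size
        )
        return [], shuffled
    blocks = [
        sorted(shuffled[k * block_size : (k + 1) * block_size]) for k in range(n_blocks)
    ]
    leftover = sorted(shuffled[n_blocks * block_size :])
    if leftover:
        logger.info("%d leftover negative gene(s) excluded: %s", len(leftover), leftover[:10])
    return blocks, leftover


def build_design(split: SplitSpec, seed: int) -> BalancedEnsembleDesign:
    blocks, leftover = partition_negatives(split.neg_train, len(split.pos_train), seed)
    if not blocks:
        raise ValueError("no balanced training set could be formed")
    return BalancedEnsembleDesign(
        pos_train=split.pos_train,
        neg_blocks=tuple(tuple(b) for b in blocks),
        leftover_negatives=tuple(leftover),
        seed=seed,
    )


def build_test_sets(
    pos_test: Sequence[str], neg_test_blocks: Sequence[Sequence[str]]
) -> list[list[str]]:
    """Each balanced test set = all held-out positives + one negative block."""
    if not pos_test:
        raise ValueError("pos_test is empty")
    return [list(pos_test) + list(b) for b in neg_test_blocks]


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_split_manifest(split: SplitSpec, path: str | Path) -> None:
    rows = (
        [(g, "pos_train") for g in split.pos_train]
        + [(g, "pos_test") for g in split.pos_test]
        + [(g, "neg_train") for g in split.neg_train]
        + [(g, "neg_test") for g in split.neg_test]
    )
    pd.DataFrame(rows, columns=["gene_id", "role"]).to_csv(path, sep="\t", index=False)


def read_split_manifest(path: str | Path, test_fraction: float, seed: int) -> SplitSpec:
    df = pd.read_csv(path, sep="\t", dtype=str)
    by_role = {r: tuple(sub["gene_id"]) for r, sub in df.groupby("role")}
    return SplitSpec(
        by_role.get("pos_train", ()), by_role.get("pos_test", ()),
        by_role.get("neg_train", ()), by_role.get("neg_test", ()),
        test_fraction, seed,
    )


def write_block_manifest(
    blocks: Sequence[Sequence[str]], leftover: Sequence[str], path: str | Path
) -> None:
    rows = [(g, k) for k, block in enumerate(blocks) for g in block]
    rows += [(g, -1) for g in leftover]
    pd.DataFrame(rows, columns=["gene_id", "block_index"]).to_csv(path, sep="\t", index=False)


def read_block_manifest(path: str | Path) -> tuple[list[list[str]], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "block_index": int})
    blocks: list[list[str]] = []
    leftover: list[str] = []
    for k, sub in df.groupby("block_index"):
        if k == -1:
            leftover = list(sub["gene_id"])
        else:
            while len(blocks) <= k:
                blocks.append([])
            blocks[k] = list(sub["gene_id"])
    return blocks, leftover
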