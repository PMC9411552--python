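"""Synthetic benchmark generators with planted class and block structure.

Feature model: every feature is Bernoulli, conditionally independent given
class. Background features fire at rate ``p0`` for every gene; each family's
signal features fire at rate ``p1`` for positives and ``p0`` for negatives,
so ``p1 > p0`` plants a recoverable class signal.

Network model: a stochastic block model whose positive genes are
concentrated in designated blocks; within-block edges draw scores from a
high range, between-block edges from a low range.

All randomness derives from one global seed via fixed per-stage offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import GeneFeatureMatrix, GeneSetCollection, LabelSet, PPIGraph

# fixed offsets fanning the global seed out to independent stage streams
_SEED_MATRIX = 11
_SEED_NETWORK = 23
_SEED_ANNOTATION = 37


@dataclass(frozen=True)
class FamilyConfig:
    """One dataset family of one-hot features."""

    name: str
    n_features: int
    background_rate: float
    n_signal: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.background_rate < 1:
            raise ValueError(f"background_rate must be in (0,1), got {self.background_rate}")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_signal < 0 or self.n_signal > self.n_features:
            raise ValueError(
                f"family {self.name!r}: n_signal {self.n_signal} exceeds "
                f"n_features {self.n_features}"
            )


@dataclass(frozen=True)
class NetworkConfig:
    """Stochastic-block-model parameters for the synthetic PPI network."""

    block_sizes: tuple[int, ...]
    p_within: float = 0.05
    p_between: float = 0.005
    within_score_range: tuple[int, int] = (601, 1000)
    between_score_range: tuple[int, int] = (400, 600)
    positive_block_ids: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if not 0 <= self.p_within <= 1 or not 0 <= self.p_between <= 1:
            raise ValueError("edge probabilities must be in [0, 1]")
        for b in self.positive_block_ids:
            if not 0 <= b < len(self.block_sizes):
                raise ValueError(f"positive block id {b} out of range")
        for lo, hi in (self.within_score_range, self.between_score_range):
            if not (0 <= lo <= hi <= 1000):
                raise ValueError("score ranges must satisfy 0 <= lo <= hi <= 1000")


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    n_genes: int
    n_positives: int
    families: tuple[FamilyConfig, ...]
    signal_rate: float = 0.4
    network: NetworkConfig | None = None
    annotation_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n_positives >= self.n_genes:
            raise ValueError("n_positives must be < n_genes")
        if not 0 < self.signal_rate < 1:
            raise ValueError("signal_rate must be in (0,1)")
        if not 0 <= self.annotation_noise < 1:
            raise ValueError("annotation_noise must be in [0,1)")
        if self.network is not None and sum(self.network.block_sizes) != self.n_genes:
            raise ValueError(
                f"block sizes sum to {sum(self.network.block_sizes)}, expected {self.n_genes}"
            )


def default_config(seed: int = 0) -> SyntheticConfig:
    """Desk-scale default: 3,000 genes, 90 positives, 6 families / 2,000
    features with 50 signal features, echoing the real data's class imbalance
    at roughly 1/10 genome scale."""
    families = (
        FamilyConfig("GTEx", 900, 0.05, 20),
        FamilyConfig("GO", 300, 0.05, 10),
        FamilyConfig("InterPro", 150, 0.05, 5),
        FamilyConfig("HPA", 250, 0.05, 5),
        FamilyConfig("BioGPS", 250, 0.05, 5),
        FamilyConfig("PathCommons", 150, 0.05, 5),
    )
    network = NetworkConfig(
        block_sizes=(500, 500, 500, 500, 500, 500),
        p_within=0.05,
        p_between=0.002,
        positive_block_ids=(0,),
    )
    return SyntheticConfig(
        seed=seed,
        n_genes=3000,
        n_positives=90,
        families=families,
        signal_rate=0.4,
        network=network,
        annotation_noise=0.05,
    )


def null_config(seed: int = 0, rate: float = 0.3) -> SyntheticConfig:
    """No-signal control: the "signal" features fire at the same rate for both
    classes (p1 = p0 = ``rate``), chosen inside [0.2, 0.8] so they survive the
    variance filter and the downstream models train on pure noise."""
    base = default_config(seed)
    families = (FamilyConfig("sig", 50, rate, 50),) + tuple(
        FamilyConfig(f.name, f.n_features - f.n_signal, f.background_rate, 0)
        for f in base.families
        if f.n_features > f.n_signal
    )
    return SyntheticConfig(
        seed=seed,
        n_genes=base.n_genes,
        n_positives=base.n_positives,
        families=families,
        signal_rate=rate,
        network=base.network,
        annotation_noise=base.annotation_noise,
    )


def gene_ids(config: SyntheticConfig) -> list[str]:
    width = len(str(config.n_genes - 1))
    return [f"g{i:0{width}d}" for i in range(config.n_genes)]


def signal_feature_ids(config: SyntheticConfig) -> list[str]:
    return [
        f"{fam.name}:sig{j:04d}" for fam in config.families for j in range(fam.n_signal)
    ]


def generate_feature_matrix(config: SyntheticConfig) -> tuple[GeneFeatureMatrix, LabelSet]:
    """Draw the planted-signal feature matrix and its label set.

    Positives are a seeded random sample of the gene universe. Bit-identical
    for identical configs.
    """
    rng = np.random.default_rng(config.seed + _SEED_MATRIX)
    genes = gene_ids(config)
    positives = sorted(rng.choice(genes, size=config.n_positives, replace=False))
    pos_mask = np.isin(np.array(genes), np.array(positives))

    blocks: list[np.ndarray] = []
    feature_ids: list[str] = []
    family: dict[str, str] = {}
    for fam in config.families:
        sig_ids = [f"{fam.name}:sig{j:04d}" for j in range(fam.n_signal)]
        bg_ids = [f"{fam.name}:bg{j:04d}" for j in range(fam.n_features - fam.n_signal)]
        if sig_ids:
            rates = np.where(pos_mask[:, None], config.signal_rate, fam.background_rate)
            blocks.append(
                (rng.random((config.n_genes, len(sig_ids))) < rates).astype(np.int8)
            )
        if bg_ids:
            blocks.append(
                (rng.random((config.n_genes, len(bg_ids))) < fam.background_rate).astype(
                    np.int8
                )
            )
        feature_ids.extend(sig_ids + bg_ids)
        for f in sig_ids + bg_ids:
            family[f] = fam.name
    values = np.concatenate(blocks, axis=1) if blocks else np.zeros((config.n_genes, 0), np.int8)
    matrix = GeneFeatureMatrix(genes, feature_ids, values, family)
    labels = LabelSet.from_iterables(positives, genes)
    return matrix, labels


def block_assignment(config: SyntheticConfig, labels: LabelSet) -> dict[str, int]:
    """Deterministic gene -> block map placing positives in the positive blocks."""
    net = config.network
    if net is None:
        raise ValueError("config has no network section")
    rng = np.random.default_rng(config.seed + _SEED_NETWORK)
    positives = sorted(labels.positives)
    negatives = sorted(labels.universe - labels.positives)
    pos_capacity = sum(net.block_sizes[b] for b in net.positive_block_ids)
    if len(positives) > pos_capacity:
        raise ValueError(
            f"positive blocks hold {pos_capacity} genes but there are {len(positives)} positives"
        )
    slots: list[int] = []
    for b in net.positive_block_ids:
        slots.extend([b] * net.block_sizes[b])
    pos_slots = rng.choice(len(slots), size=len(positives), replace=False)
    assignment: dict[str, int] = {}
    taken = np.zeros(len(slots), dtype=bool)
    for g, s in zip(positives, pos_slots):
        assignment[g] = slots[s]
        taken[s] = True
    remaining = [slots[i] for i in range(len(slots)) if not taken[i]]
    for b in range(len(net.block_sizes)):
        if b not in net.positive_block_ids:
            remaining.extend([b] * net.block_sizes[b])
    shuffled_negatives = [negatives[i] for i in rng.permutation(len(negatives))]
    for g, b in zip(shuffled_negatives, remaining):
        assignment[g] = b
    return assignment


def generate_ppi_network(config: SyntheticConfig, labels: LabelSet) -> PPIGraph:
    """Stochastic-block-model graph over the label universe.

    Within-block pairs connect with ``p_within`` and score uniformly in the
    high range; between-block pairs use ``p_between`` and the low range.
    """
    net = config.network
    if net is None:
        raise ValueError("config has no network section")
    assignment = block_assignment(config, labels)
    genes = sorted(labels.universe)
    block = np.array([assignment[g] for g in genes])
    n = len(genes)
    rng = np.random.default_rng(config.seed + _SEED_NETWORK + 1)

    iu, ju = np.triu_indices(n, k=1)
    same = block[iu] == block[ju]
    p = np.where(same, net.p_within, net.p_between)
    present = rng.random(len(iu)) < p
    iu, ju, same = iu[present], ju[present], same[present]
    lo_w, hi_w = net.within_score_range
    lo_b, hi_b = net.between_score_range
    scores = np.where(
        same,
        rng.integers(lo_w, hi_w + 1, size=len(iu)),
        rng.integers(lo_b, hi_b + 1, size=len(iu)),
    )
    edges = [(genes[i], genes[j], int(s)) for i, j, s in zip(iu, ju, scores)]
    return PPIGraph(genes, edges)


def generate_annotation_sets(
    config: SyntheticConfig, labels: LabelSet, graph: PPIGraph
) -> GeneSetCollection:
    """One gene set per planted block, with symmetric membership noise.

    With noise ``e``, each true member is dropped with probability ``e`` and
    replaced by a uniformly drawn outsider, so E[Jaccard(set, block)] ~
    (1-e)/(1+e).
    """
    assignment = block_assignment(config, labels)
    rng = np.random.default_rng(config.seed + _SEED_ANNOTATION)
    coll = GeneSetCollection()
    n_blocks = len(config.network.block_sizes)  # type: ignore[union-attr]
    genes = sorted(labels.universe)
    for b in range(n_blocks):
        members = [g for g in genes if assignment[g] == b]
        outsiders = [g for g in genes if assignment[g] != b]
        kept = [g for g in members if rng.random() >= config.annotation_noise]
        n_add = len(members) - len(kept)
        added = (
            list(rng.choice(outsiders, size=n_add, replace=False)) if n_add else []
        )
        coll.add(f"block_{b}", kept + added, f"planted block {b}")
    return coll
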