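"""Readers and writers for every external format the pipeline touches.

Formats are deliberately plain text: TSV for matrices, edge lists and
prediction tables, GMT for gene sets. Every reader/writer pair is a
lossless round trip on valid files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import FormatError, GeneFeatureMatrix, GeneSetCollection, PPIGraph

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def read_feature_matrix(path: str | Path, family_path: str | Path) -> GeneFeatureMatrix:
    """Read a binary gene x feature TSV plus its feature -> family companion.

    The matrix TSV has a header row of feature ids and gene ids in the first
    column. Cells must be exactly 0 or 1; anything else is a hard error
    naming the offending position.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    feature_ids = [str(f) for f in df.columns]
    raw = df.to_numpy()
    values = np.zeros(raw.shape, dtype=np.int8)
    ok = (raw == "0") | (raw == "1")
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise FormatError(
            f"non-binary cell at gene {gene_ids[i]!r}, feature {feature_ids[j]!r}: "
            f"{raw[i, j]!r} in {path}"
        )
    values[raw == "1"] = 1
    fam = pd.read_csv(family_path, sep="\t", header=None, names=["feature_id", "family"], dtype=str)
    family = dict(zip(fam["feature_id"], fam["family"]))
    return GeneFeatureMatrix(gene_ids, feature_ids, values, family)


def write_feature_matrix(
    matrix: GeneFeatureMatrix, path: str | Path, family_path: str | Path
) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.feature_ids)
    df.to_csv(path, sep="\t")
    with open(family_path, "w") as fh:
        for f in matrix.feature_ids:
            fh.write(f"{f}\t{matrix.feature_family[f]}\n")


# ---------------------------------------------------------------------------
# gene lists / labels
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


# ---------------------------------------------------------------------------
# PPI edges
# ---------------------------------------------------------------------------

def read_ppi_edges(path: str | Path, min_score: int = 400) -> PPIGraph:
    """Read a three-column (node, node, combined score) TSV into a graph.

    Edges scoring below ``min_score`` are dropped (threshold inclusive:
    score >= min_score is retained). Duplicate pairs collapse to the
    maximum score; self-loops are dropped and logged. Scores outside
    [0, 1000] are a hard error.
    """
    best: dict[tuple[str, str], int] = {}
    nodes: dict[str, None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            u, v, raw = parts
            if lineno == 1:
                try:
                    int(raw)
                except ValueError:
                    continue  # header row
            try:
                score = int(raw)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer score {raw!r}") from None
            if not 0 <= score <= 1000:
                raise FormatError(f"{path}:{lineno}: score {score} outside [0, 1000]")
            if u == v:
                logger.info("dropping self-loop on %s (line %d)", u, lineno)
                continue
            nodes.setdefault(u)
            nodes.setdefault(v)
            key = (u, v) if u <= v else (v, u)
            if key not in best or score > best[key]:
                best[key] = score
    edges = [(u, v, s) for (u, v), s in best.items() if s >= min_score]
    return PPIGraph(nodes.keys(), edges)


def write_ppi_edges(graph: PPIGraph, path: str | Path) -> None:
    # isolated nodes are not representable in an edge list and are dropped
    with open(path, "w") as fh:
        for (u, v), s in sorted(graph.edges.items()):
            fh.write(f"{u}\t{v}\t{s}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    coll = GeneSetCollection()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: gene set {parts[0]!r} is empty")
        name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
        coll.add(name, members, desc)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in coll:
            members = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{coll.descriptions.get(name, '')}\t{members}\n")


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def write_predictions(
    scores: dict[str, float],
    path: str | Path,
    per_model: pd.DataFrame | None = None,
) -> None:
    """Write a ranked prediction table: descending probability, ties by gene id."""
    order = sorted(scores, key=lambda g: (-scores[g], g))
    df = pd.DataFrame({"gene_id": order, "mean_probability": [scores[g] for g in order]})
    if per_model is not None:
        df = df.join(per_model.reindex(order).reset_index(drop=True))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "mean_probability" not in df.columns:
        raise FormatError(f"{path}: not a prediction table")
    return df
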