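"""Readers and writers for the package's tab-separated text formats.

Formats
-------
expression      TSV, first column gene symbol, header row of sample ids
stage table     TSV with columns ``sample`` and ``stage`` (header optional);
                stage temporal order = order of first appearance
edge list       TSV ``gene1<TAB>gene2<TAB>score``; scores rescaled by a
                configurable divisor (1000 for STRING combined scores)
gene list       plain text, one symbol per line
coordinates     TSV ``gene<TAB>chrom<TAB>start<TAB>end``
ranking         TSV ``rank<TAB>gene<TAB>score`` with full float precision,
                ``#``-prefixed provenance header lines
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    BackgroundNetwork,
    ExpressionMatrix,
    GeneAnnotation,
    GeneSet,
    StagePartition,
    ValidationError,
)

logger = logging.getLogger(__name__)


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x sample expression table.

    Duplicate gene ids and non-numeric cells are hard errors that name the
    offending gene / coordinates; silent coercion would corrupt the k-sigma
    statistics downstream.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise ValidationError(f"empty expression table: {path}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id in {path}: {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            i = bad[0]
            raise ValidationError(
                f"non-numeric expression value {df.iloc[i, j]!r} at "
                f"gene {df.index[i]!r}, sample {col!r} in {path}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def read_stage_annotation(path, expr: ExpressionMatrix) -> StagePartition:
    """Read the sample -> stage table and check it covers ``expr`` exactly.

    An optional third integer column gives an explicit temporal order;
    otherwise stages are ordered by first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.empty:
        raise ValidationError(f"empty stage annotation: {path}")
    # tolerate a header row
    first = str(df.iloc[0, 0]).lower()
    if first in {"sample", "sample_id", "id"}:
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 2:
        raise ValidationError(f"stage annotation needs >= 2 columns: {path}")
    assignment = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    if df.shape[1] >= 3:
        order_col = pd.to_numeric(df.iloc[:, 2], errors="coerce")
        if order_col.isna().any():
            raise ValidationError(f"non-numeric stage-order column in {path}")
        order = (
            pd.DataFrame({"stage": df.iloc[:, 1].astype(str), "ord": order_col})
            .drop_duplicates("stage")
            .sort_values("ord")["stage"]
            .tolist()
        )
    else:
        order = list(dict.fromkeys(df.iloc[:, 1].astype(str)))
    missing = [s for s in expr.sample_ids if s not in assignment]
    if missing:
        raise ValidationError(f"samples missing from stage annotation: {missing[:5]}")
    unknown = [s for s in assignment if s not in set(expr.sample_ids)]
    if unknown:
        raise ValidationError(f"stage annotation lists unknown samples: {unknown[:5]}")
    return StagePartition(order, assignment)


def read_edge_list(path, score_divisor: float = 1.0) -> BackgroundNetwork:
    """Read a weighted undirected edge list into a background network.

    ``score_divisor`` rescales raw scores into [0, 1] (use 1000 for
    STRING-style combined scores). Duplicate undirected edges collapse by
    maximum weight; self-edges are dropped with a warning.
    """
    if score_divisor <= 0:
        raise ValidationError("score_divisor must be positive")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    first = str(df.iloc[0, 0]).lower()
    if first in {"gene1", "protein1", "node1", "source"}:
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise ValidationError(f"empty edge list: {path}")
    if df.shape[1] < 3:
        raise ValidationError(f"edge list needs 3 columns (gene1, gene2, score): {path}")
    g1 = df.iloc[:, 0].astype(str).to_numpy()
    g2 = df.iloc[:, 1].astype(str).to_numpy()
    score = pd.to_numeric(df.iloc[:, 2], errors="coerce").to_numpy()
    if np.isnan(score).any():
        i = int(np.flatnonzero(np.isnan(score))[0])
        raise ValidationError(f"non-numeric score {df.iloc[i, 2]!r} on line {i + 1} of {path}")
    if (score < 0).any():
        raise ValidationError(f"negative edge score in {path}")
    w = score / float(score_divisor)
    if (w > 1 + 1e-12).any():
        raise ValidationError(
            f"edge weight above 1 after dividing by {score_divisor}; wrong score_divisor?"
        )
    self_loops = g1 == g2
    if self_loops.any():
        logger.warning("dropping %d self-edge(s) from %s", int(self_loops.sum()), path)
        g1, g2, w = g1[~self_loops], g2[~self_loops], w[~self_loops]
    if g1.size == 0:
        raise ValidationError(f"edge list {path} has no usable edges")
    genes = sorted(set(g1) | set(g2))
    index = {g: i for i, g in enumerate(genes)}
    i = np.array([index[g] for g in g1])
    j = np.array([index[g] for g in g2])
    n = len(genes)
    # duplicate undirected edges collapse by maximum (order-independent)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    best = (
        pd.DataFrame({"lo": lo, "hi": hi, "w": w}).groupby(["lo", "hi"], sort=False)["w"].max()
    )
    lo = best.index.get_level_values("lo").to_numpy()
    hi = best.index.get_level_values("hi").to_numpy()
    wmax = best.to_numpy()
    A = sp.coo_matrix(
        (np.concatenate([wmax, wmax]), (np.concatenate([lo, hi]), np.concatenate([hi, lo]))),
        shape=(n, n),
    ).tocsr()
    return BackgroundNetwork(genes, A)


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene list (one symbol per line)."""
    path = Path(path)
    members = [ln.strip() for ln in path.read_text().splitlines()]
    members = [m for m in members if m and not m.startswith("#")]
    if not members:
        raise ValidationError(f"empty gene list: {path}")
    return GeneSet(name or path.stem, frozenset(members))


def read_gene_coordinates(path) -> GeneAnnotation:
    """Read a 4-column gene coordinate table (gene, chrom, start, end)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    first = str(df.iloc[0, 0]).lower()
    if first in {"gene", "symbol", "gene_id"}:
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise ValidationError(f"empty coordinate table: {path}")
    if df.shape[1] < 4:
        raise ValidationError(f"coordinate table needs 4 columns: {path}")
    start = pd.to_numeric(df.iloc[:, 2], errors="coerce")
    end = pd.to_numeric(df.iloc[:, 3], errors="coerce")
    if start.isna().any() or end.isna().any():
        i = int((start.isna() | end.isna()).to_numpy().argmax())
        raise ValidationError(f"malformed coordinate row {i + 1} in {path}")
    table = pd.DataFrame(
        {
            "chrom": df.iloc[:, 1].astype(str).to_numpy(),
            "start": start.astype(int).to_numpy(),
            "end": end.astype(int).to_numpy(),
        },
        index=pd.Index(df.iloc[:, 0].astype(str), name="gene"),
    )
    return GeneAnnotation(table)


def write_ranking(ranking, path, header: dict | None = None) -> None:
    """Write a ranked gene list as ``rank<TAB>gene<TAB>score``.

    Scores are written with ``repr`` so that a write/read round trip is
    bit-identical. ``header`` entries become ``# key: value`` comment lines.
    """
    if len(ranking.genes) == 0:
        raise ValidationError("refusing to write an empty ranking")
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        for r, (gene, score) in enumerate(zip(ranking.genes, ranking.scores), start=1):
            fh.write(f"{r}\t{gene}\t{float(score)!r}\n")


def read_ranking(path):
    """Parse a ranking file back into a :class:`~stagewalk.RankedGeneList`."""
    from .propagation import RankedGeneList

    genes: list[str] = []
    scores: list[float] = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            _, gene, score = ln.split("\t")
            genes.append(gene)
            scores.append(float(score))
    if not genes:
        raise ValidationError(f"empty ranking file: {path}")
    return RankedGeneList(genes=genes, scores=np.asarray(scores), meta={"source": str(path)})
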