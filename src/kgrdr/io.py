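"""Readers and writers for the plain-text artifact formats.

All matrices travel as dense TSV with identifier headers; knowledge-graph
triples as 3-column TSV; metrics as JSON. Every writer round-trips through
the matching reader bit-exactly at the value precision used (repr floats).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError
from .types import InteractionMatrix, SimilarityMatrix


# ---------------------------------------------------------------------------
# similarity matrices
# ---------------------------------------------------------------------------

def read_similarity(path: str | Path, source_name: str | None = None) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ParseError(f"{path}: row and column identifiers differ")
    name = source_name if source_name is not None else Path(path).stem
    return SimilarityMatrix(ids=ids, values=df.to_numpy(dtype=np.float64), source_name=name)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# interaction matrices (dense 0/1 grid or 2-column edge list, autodetected)
# ---------------------------------------------------------------------------

def read_interactions(
    path: str | Path,
    drug_ids: list[str] | None = None,
    disease_ids: list[str] | None = None,
) -> InteractionMatrix:
    """Read a drug-disease interaction table.

    A file whose rows all have exactly two columns is treated as an
    edge list (``drug_id<TAB>disease_id``); anything wider as a dense 0/1
    matrix with drug rows and disease columns. For edge lists the id
    universe defaults to the ids present, unless explicit lists are given.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise ParseError(f"{path}: empty interaction file")
    n_cols = len(first.rstrip("\n").split("\t"))
    if n_cols == 2:
        edges = pd.read_csv(path, sep="\t", header=None, names=["drug", "disease"], dtype=str)
        drugs = drug_ids if drug_ids is not None else sorted(edges["drug"].unique())
        diseases = disease_ids if disease_ids is not None else sorted(edges["disease"].unique())
        d_idx = {d: i for i, d in enumerate(drugs)}
        s_idx = {s: j for j, s in enumerate(diseases)}
        values = np.zeros((len(drugs), len(diseases)), dtype=np.int8)
        for drug, disease in edges.itertuples(index=False):
            try:
                values[d_idx[drug], s_idx[disease]] = 1
            except KeyError as exc:
                raise InvalidInputError(f"{path}: unknown identifier {exc}") from exc
        return InteractionMatrix(drug_ids=list(drugs), disease_ids=list(diseases), values=values)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return InteractionMatrix(
        drug_ids=[str(i) for i in df.index],
        disease_ids=[str(c) for c in df.columns],
        values=df.to_numpy(),
    )


def write_interactions(inter: InteractionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(inter.values, index=inter.drug_ids, columns=inter.disease_ids)
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# feature / score matrices
# ---------------------------------------------------------------------------

def read_features(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=np.float64)


def write_features(ids: list[str], values: np.ndarray, path: str | Path) -> None:
    values = np.asarray(values)
    cols = [f"f{j}" for j in range(values.shape[1])]
    pd.DataFrame(values, index=ids, columns=cols).to_csv(path, sep="\t", float_format="%.17g")


def write_scores(
    drug_ids: list[str], disease_ids: list[str], scores: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame(scores, index=drug_ids, columns=disease_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_scores(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return (
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# metrics / json
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
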