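"""Knowledge-graph embedding.

Loads (head, relation, tail) triples, aligns the drug-disease relation with a
benchmark interaction matrix, and trains complex-valued entity/relation
embeddings with the ComplEx trilinear score and a logistic loss over positive
and corrupted (negative-sampled) triples. Gradients are computed analytically
(the score is trilinear), so no autodiff framework is involved.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConvergenceError, InvalidInputError, ParseError
from .types import InteractionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# triple store
# ---------------------------------------------------------------------------

@dataclass
class TripleStore:
    """Deduplicated set of (head, relation, tail) triples with stable indices."""

    triples: list[tuple[str, str, str]]
    entity_index: dict[str, int] = field(default_factory=dict)
    relation_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.triples = sorted(set(tuple(t) for t in self.triples))
        self._reindex()

    def _reindex(self) -> None:
        entities = sorted({h for h, _, _ in self.triples} | {t for _, _, t in self.triples})
        relations = sorted({r for _, r, _ in self.triples})
        self.entity_index = {e: i for i, e in enumerate(entities)}
        self.relation_index = {r: i for i, r in enumerate(relations)}

    @property
    def n_entities(self) -> int:
        return len(self.entity_index)

    @property
    def n_relations(self) -> int:
        return len(self.relation_index)

    def __len__(self) -> int:
        return len(self.triples)

    def indexed(self) -> np.ndarray:
        """Integer array (T, 3) of (head, relation, tail) indices, canonical order."""
        return np.array(
            [
                (self.entity_index[h], self.relation_index[r], self.entity_index[t])
                for h, r, t in self.triples
            ],
            dtype=np.int64,
        ).reshape(-1, 3)


def read_triples(path: str | Path) -> TripleStore:
    """Read a 3-column TSV of triples; duplicates collapse to one."""
    triples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}")
            triples.append(tuple(parts))
    return TripleStore(triples=triples)


def write_triples(store: TripleStore, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h, r, t in store.triples:
            fh.write(f"{h}\t{r}\t{t}\n")


def align_benchmark(
    kg: TripleStore, interactions: InteractionMatrix, dd_relation: str
) -> TripleStore:
    """Force the drug-disease relation of the KG to match the benchmark.

    Every ``dd_relation`` triple absent from ``interactions`` is removed and
    a triple is added for every 1-entry of ``interactions``; all other
    relations are untouched. Interaction identifiers missing from the KG are
    added to the entity index (count logged).
    """
    benchmark_pairs = set(interactions.pairs())
    kept = [
        (h, r, t) for h, r, t in kg.triples
        if r != dd_relation or (h, t) in benchmark_pairs
    ]
    existing_dd = {(h, t) for h, r, t in kg.triples if r == dd_relation}
    added = [(d, dd_relation, s) for d, s in sorted(benchmark_pairs - existing_dd)]
    known_entities = set(kg.entity_index)
    new_entities = {e for pair in benchmark_pairs for e in pair} - known_entities
    if new_entities:
        logger.info("align_benchmark added %d new entities from the benchmark", len(new_entities))
    return TripleStore(triples=kept + added)


# ---------------------------------------------------------------------------
# ComplEx embeddings
# ---------------------------------------------------------------------------

@dataclass
class ComplexEmbeddingTable:
    entity_real: np.ndarray
    entity_imag: np.ndarray
    relation_real: np.ndarray
    relation_imag: np.ndarray
    k: int
    reg_lambda: float
    entity_index: dict[str, int] = field(default_factory=dict)
    relation_index: dict[str, int] = field(default_factory=dict)
    loss_trace: list[float] = field(default_factory=list)

    def l2_penalty(self) -> float:
        """``reg_lambda * sum of squares`` over all four embedding matrices."""
        return self.reg_lambda * float(
            (self.entity_real ** 2).sum()
            + (self.entity_imag ** 2).sum()
            + (self.relation_real ** 2).sum()
            + (self.relation_imag ** 2).sum()
        )


def score_triple(indices: tuple[int, int, int], emb: ComplexEmbeddingTable) -> float:
    """Trilinear ComplEx score of one (head, relation, tail) index triple."""
    s, r, o = indices
    return float(
        _score_batch(
            np.array([s]), np.array([r]), np.array([o]),
            emb.entity_real, emb.entity_imag, emb.relation_real, emb.relation_imag,
        )[0]
    )


def _score_batch(s, r, o, er, ei, wr, wi) -> np.ndarray:
    ers, eis = er[s], ei[s]
    ero, eio = er[o], ei[o]
    wrr, wri = wr[r], wi[r]
    return (
        (wrr * ers * ero).sum(axis=1)
        + (wrr * eis * eio).sum(axis=1)
        + (wri * ers * eio).sum(axis=1)
        - (wri * eis * ero).sum(axis=1)
    )


def triple_probability(score: float) -> float:
    """Logistic inverse link: sigma(score)."""
    return float(1.0 / (1.0 + np.exp(-np.asarray(score, dtype=np.float64))))


def sample_negatives(
    triple: tuple[str, str, str],
    store: TripleStore,
    n_neg: int,
    seed: int,
) -> list[tuple[str, str, str]]:
    """Corrupt head or tail (fair coin) with a uniform entity, rejecting positives.

    The RNG stream is derived from ``seed`` and the triple's content, so the
    result does not depend on where the triple sits in the store.
    """
    if n_neg < 1:
        raise InvalidInputError("n_neg must be >= 1")
    if store.n_entities < 2:
        raise InvalidInputError("cannot corrupt triples in a store with < 2 entities")
    positives = set(store.triples)
    entities = sorted(store.entity_index)
    rng = np.random.default_rng(_content_seed(seed, triple))
    h, r, t = triple
    out: list[tuple[str, str, str]] = []
    while len(out) < n_neg:
        corrupt_head = rng.random() < 0.5
        replacement = entities[int(rng.integers(len(entities)))]
        candidate = (replacement, r, t) if corrupt_head else (h, r, replacement)
        if candidate in positives or candidate == triple:
            continue
        out.append(candidate)
    return out


def _content_seed(seed: int, triple: tuple[str, str, str]) -> np.random.SeedSequence:
    # process-independent content hash (python's hash() is salted per run)
    material = "\t".join(triple).encode()
    digest = int.from_bytes(hashlib.blake2s(material, digest_size=4).digest(), "big")
    return np.random.SeedSequence([int(seed) % (2 ** 32), digest])


def fit_complex(
    store: TripleStore,
    k: int = 32,
    lr: float = 0.1,
    reg_lambda: float = 1e-7,
    epochs: int = 200,
    n_neg: int = 2,
    seed: int = 0,
    batch_size: int = 512,
    early_stop_tol: float = 1e-5,
    early_stop_patience: int = 10,
) -> ComplexEmbeddingTable:
    """Mini-batch gradient descent on the logistic ComplEx loss.

    Positives carry label +1, sampled corruptions -1; the loss is
    ``sum softplus(-y * score) + reg_lambda * ||Theta||^2``. Triples are
    visited in an epoch-seeded shuffle of the store's canonical order, so the
    on-disk ordering of the triple file cannot influence the result.
    """
    if len(store) == 0:
        raise InvalidInputError("cannot train on an empty triple store")
    if k < 1:
        raise InvalidInputError("embedding dimension k must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 32), 11]))
    ne, nr = store.n_entities, store.n_relations
    er = 0.1 * rng.standard_normal((ne, k))
    ei = 0.1 * rng.standard_normal((ne, k))
    wr = 0.1 * rng.standard_normal((nr, k))
    wi = 0.1 * rng.standard_normal((nr, k))
    positives = store.indexed()
    positive_set = {tuple(row) for row in positives}
    n_pos = positives.shape[0]
    trace: list[float] = []
    # AdaGrad accumulators (dense; entity/relation counts are modest here)
    acc = [np.full_like(m, 1e-8) for m in (er, ei, wr, wi)]
    for epoch in range(epochs):
        epoch_rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 32), 13, epoch]))
        order = epoch_rng.permutation(n_pos)
        epoch_loss = 0.0
        for start in range(0, n_pos, batch_size):
            batch = positives[order[start:start + batch_size]]
            b = batch.shape[0]
            # vectorized corruption: fair coin head/tail, uniform entity,
            # resampled while the corruption hits a known positive
            neg = np.repeat(batch, n_neg, axis=0)
            coin = epoch_rng.random(b * n_neg) < 0.5
            repl = epoch_rng.integers(ne, size=b * n_neg)
            neg[coin, 0] = repl[coin]
            neg[~coin, 2] = repl[~coin]
            for i in range(neg.shape[0]):
                guard = 0
                while tuple(neg[i]) in positive_set and guard < 100:
                    j = int(epoch_rng.integers(ne))
                    neg[i, 0 if coin[i] else 2] = j
                    guard += 1
            triples = np.vstack([batch, neg])
            labels = np.concatenate([np.ones(b), -np.ones(neg.shape[0])])
            s, r, o = triples[:, 0], triples[:, 1], triples[:, 2]
            phi = _score_batch(s, r, o, er, ei, wr, wi)
            z = -labels * phi
            epoch_loss += float(np.logaddexp(0.0, z).sum())
            # d softplus(-y phi) / d phi = -y sigmoid(-y phi)
            coeff = -labels * expit(z)
            ers, eis, ero, eio = er[s], ei[s], er[o], ei[o]
            wrr, wri = wr[r], wi[r]
            c = coeff[:, None]
            grads = [np.zeros_like(er), np.zeros_like(ei),
                     np.zeros_like(wr), np.zeros_like(wi)]
            np.add.at(grads[0], s, c * (wrr * ero + wri * eio))
            np.add.at(grads[1], s, c * (wrr * eio - wri * ero))
            np.add.at(grads[0], o, c * (wrr * ers - wri * eis))
            np.add.at(grads[1], o, c * (wrr * eis + wri * ers))
            np.add.at(grads[2], r, c * (ers * ero + eis * eio))
            np.add.at(grads[3], r, c * (ers * eio - eis * ero))
            # AdaGrad step including the weight-decay gradient 2*lambda*theta
            for mat, g, a in zip((er, ei, wr, wi), grads, acc):
                g += 2.0 * reg_lambda * mat
                a += g * g
                mat -= lr * g / np.sqrt(a)
        total = epoch_loss + reg_lambda * float(
            (er ** 2).sum() + (ei ** 2).sum() + (wr ** 2).sum() + (wi ** 2).sum()
        )
        if not np.isfinite(total):
            raise ConvergenceError(
                f"ComplEx training diverged (loss={total}) -- reduce lr (currently {lr})"
            )
        trace.append(total)
        if len(trace) > early_stop_patience:
            prev = trace[-early_stop_patience - 1]
            if abs(prev - total) / max(abs(prev), 1e-30) < early_stop_tol:
                logger.info("ComplEx early stop at epoch %d", epoch + 1)
                break
    return ComplexEmbeddingTable(
        entity_real=er, entity_imag=ei, relation_real=wr, relation_imag=wi,
        k=k, reg_lambda=reg_lambda,
        entity_index=dict(store.entity_index), relation_index=dict(store.relation_index),
        loss_trace=trace,
    )


def extract_features(emb: ComplexEmbeddingTable, entity_ids: list[str]) -> np.ndarray:
    """Per-entity feature rows ``[real || imag]`` (width 2k), in the given order."""
    missing = [e for e in entity_ids if e not in emb.entity_index]
    if missing:
        raise InvalidInputError(f"entities not in embedding table: {missing}")
    idx = [emb.entity_index[e] for e in entity_ids]
    return np.hstack([emb.entity_real[idx], emb.entity_imag[idx]])


def write_embeddings(emb: ComplexEmbeddingTable, path: str | Path) -> None:
    """TSV of [Re || Im] rows plus a JSON sidecar with training metadata."""
    path = Path(path)
    ids = sorted(emb.entity_index, key=emb.entity_index.get)
    feats = extract_features(emb, ids)
    cols = [f"re{j}" for j in range(emb.k)] + [f"im{j}" for j in range(emb.k)]
    pd.DataFrame(feats, index=ids, columns=cols).to_csv(path, sep="\t", float_format="%.17g")
    sidecar = {
        "k": emb.k,
        "reg_lambda": emb.reg_lambda,
        "relations": sorted(emb.relation_index, key=emb.relation_index.get),
        "final_loss": emb.loss_trace[-1] if emb.loss_trace else None,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")
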