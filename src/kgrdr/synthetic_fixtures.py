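"""Seeded synthetic inputs with the statistical structure the method assumes.

A planted low-rank factor model drives everything: the binary interaction
matrix thresholds the factor product, the similarity views are noisy copies
of a Gaussian kernel on the per-side factors (with exact duplicates and an
optional pure-noise view to exercise the selection step), and the knowledge
graph's drug-disease edges coincide with the interaction matrix while extra
relations connect entities through auxiliary "gene" nodes that share high
factor affinity. Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidInputError
from .io import write_interactions, write_similarity
from .kg_embedding import TripleStore, write_triples
from .types import InteractionMatrix, SimilarityMatrix

DD_RELATION = "drug:disease"


@dataclass
class FixtureSpec:
    n_drugs: int = 58
    n_diseases: int = 54
    latent_rank: int = 4
    density: float = 0.0125
    n_views: int = 4
    noise_sigma: float = 0.05
    redundancy_copies: int = 1
    add_noise_view: bool = True
    kg_extra_relations: int = 2
    n_aux_entities: int = 30
    seed: int = 0
    n_views_drug: int | None = None
    n_views_disease: int | None = None

    def __post_init__(self):
        if not (0 < self.density < 1):
            raise InvalidInputError("density must lie in (0, 1)")
        if self.latent_rank > min(self.n_drugs, self.n_diseases):
            raise InvalidInputError("latent_rank must not exceed the entity counts")

    def views_for(self, side: str) -> int:
        if side == "drugs":
            return self.n_views_drug if self.n_views_drug is not None else self.n_views
        return self.n_views_disease if self.n_views_disease is not None else self.n_views


def default_fixture_spec(seed: int = 0) -> FixtureSpec:
    """Desk-scale profile mirroring the sparse benchmark regime."""
    return FixtureSpec(seed=seed, n_views_drug=10, n_views_disease=14)


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed % (2 ** 32), stream]))


def _factors(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    rng = _rng(spec, 0)
    U = rng.standard_normal((spec.n_drugs, spec.latent_rank))
    V = rng.standard_normal((spec.n_diseases, spec.latent_rank))
    return U, V


def _ids(spec: FixtureSpec) -> tuple[list[str], list[str]]:
    return (
        [f"drug::r{i:03d}" for i in range(spec.n_drugs)],
        [f"disease::d{j:03d}" for j in range(spec.n_diseases)],
    )


def make_interactions(spec: FixtureSpec) -> InteractionMatrix:
    """Threshold the top ``density`` fraction of the factor product to 1."""
    U, V = _factors(spec)
    scores = U @ V.T
    total = spec.n_drugs * spec.n_diseases
    n_ones = int(round(spec.density * total))
    if n_ones < 1:
        raise InvalidInputError("density too low: would yield zero positive pairs")
    cutoff_order = np.argsort(scores.ravel(), kind="stable")[::-1][:n_ones]
    values = np.zeros(total, dtype=np.int8)
    values[cutoff_order] = 1
    drug_ids, disease_ids = _ids(spec)
    return InteractionMatrix(
        drug_ids=drug_ids,
        disease_ids=disease_ids,
        values=values.reshape(spec.n_drugs, spec.n_diseases),
    )


def _base_similarity(factors: np.ndarray) -> np.ndarray:
    dist = pdist(factors)
    h = float(np.median(dist))
    values = squareform(np.exp(-(dist ** 2) / (2.0 * h * h)))
    np.fill_diagonal(values, 1.0)
    return values


def make_similarity_stack(spec: FixtureSpec, side: str = "drugs") -> list[SimilarityMatrix]:
    """Noisy, partially redundant similarity views sharing the planted structure."""
    if side not in ("drugs", "diseases"):
        raise InvalidInputError("side must be 'drugs' or 'diseases'")
    U, V = _factors(spec)
    factors = U if side == "drugs" else V
    ids = _ids(spec)[0 if side == "drugs" else 1]
    n = factors.shape[0]
    n_views = spec.views_for(side)
    if n_views < 1:
        raise InvalidInputError("n_views must be >= 1")
    base = _base_similarity(factors)
    rng = _rng(spec, 1 if side == "drugs" else 2)
    views: list[SimilarityMatrix] = []
    for v in range(n_views):
        noise = rng.standard_normal((n, n)) * spec.noise_sigma
        noise = (noise + noise.T) / 2.0
        values = np.clip(base + noise, 0.0, 1.0)
        np.fill_diagonal(values, 1.0)
        views.append(SimilarityMatrix(ids=ids, values=values, source_name=f"{side}_view{v}"))
    for c in range(spec.redundancy_copies):
        views.append(SimilarityMatrix(
            ids=ids, values=views[0].values.copy(), source_name=f"{side}_dup{c}",
        ))
    if spec.add_noise_view:
        noise = np.abs(rng.standard_normal((n, n))) * 0.1 + 0.45
        noise = np.clip((noise + noise.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(noise, 1.0)
        views.append(SimilarityMatrix(ids=ids, values=noise, source_name=f"{side}_noise"))
    return views


def make_kg(spec: FixtureSpec, interactions: InteractionMatrix) -> TripleStore:
    """Multi-relation KG whose drug-disease edges equal the interaction matrix.

    Every drug and disease is attached to its best-affinity auxiliary "gene"
    entity, and each extra relation additionally links the top-decile
    affinity pairs, so the KG carries the planted factor signal.
    """
    U, V = _factors(spec)
    rng = _rng(spec, 3)
    triples: list[tuple[str, str, str]] = [
        (d, DD_RELATION, s) for d, s in interactions.pairs()
    ]
    drug_ids, disease_ids = _ids(spec)
    aux_ids = [f"gene::g{t:03d}" for t in range(spec.n_aux_entities)]
    gene_dirs = rng.standard_normal((spec.n_aux_entities, spec.latent_rank))
    drug_aff = U @ gene_dirs.T        # (n_drugs, n_aux)
    disease_aff = V @ gene_dirs.T     # (n_diseases, n_aux)
    # guarantee coverage: every entity linked to its best-affinity gene
    for i, drug in enumerate(drug_ids):
        triples.append((drug, "drug:gene:0", aux_ids[int(drug_aff[i].argmax())]))
    for j, disease in enumerate(disease_ids):
        triples.append((disease, "disease:gene:0", aux_ids[int(disease_aff[j].argmax())]))
    for t, aux in enumerate(aux_ids):  # and every gene to its best drug
        triples.append((drug_ids[int(drug_aff[:, t].argmax())], "drug:gene:0", aux))
    for rel in range(spec.kg_extra_relations):
        d_cut = np.quantile(drug_aff, 0.9)
        s_cut = np.quantile(disease_aff, 0.9)
        jitter_d = drug_aff + 0.1 * rel * rng.standard_normal(drug_aff.shape)
        jitter_s = disease_aff + 0.1 * rel * rng.standard_normal(disease_aff.shape)
        for i, t in zip(*np.nonzero(jitter_d > d_cut)):
            triples.append((drug_ids[i], f"drug:gene:{rel}", aux_ids[t]))
        for j, t in zip(*np.nonzero(jitter_s > s_cut)):
            triples.append((disease_ids[j], f"disease:gene:{rel}", aux_ids[t]))
    return TripleStore(triples=triples)


def sparsity(interactions: InteractionMatrix) -> float:
    """Fraction of unobserved (zero) entries of the interaction matrix."""
    total = interactions.values.size
    if total == 0:
        raise InvalidInputError("empty interaction matrix")
    return 1.0 - float(interactions.values.sum()) / total


def write_fixture_set(spec: FixtureSpec, out_dir: str | Path) -> dict[str, list[str] | str]:
    """Write the complete synthetic input set in the formats the CLI reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    interactions = make_interactions(spec)
    manifest: dict[str, list[str] | str] = {}
    write_interactions(interactions, out / "interactions.tsv")
    manifest["interactions"] = "interactions.tsv"
    for side in ("drugs", "diseases"):
        names = []
        for sim in make_similarity_stack(spec, side):
            fname = f"sim_{sim.source_name}.tsv"
            write_similarity(sim, out / fname)
            names.append(fname)
        manifest[f"{side}_similarities"] = names
    write_triples(make_kg(spec, interactions), out / "triples.tsv")
    manifest["triples"] = "triples.tsv"
    return manifest
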