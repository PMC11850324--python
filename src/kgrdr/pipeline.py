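"""End-to-end orchestration of the four stages.

integrate (multi-similarity -> X) -> embed (KG -> Y) -> fuse (iAFF -> Z)
-> predict (hetero-GCN). Ablation variants reroute the feature inputs:
``no_kg`` feeds X directly, ``no_gri`` feeds Y, ``no_kg_gri`` hands the
first raw similarity per side straight to the predictor.

Every stage records the files it reads in an audit log; the expensive
feature stages run once per pipeline invocation and are reused across CV
folds, which retrain only the predictor (and fresh fusion parameters).
Artifacts are written in the formats of :mod:`kgrdr.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import hetero_gcn, io, kg_embedding, similarity_integration as si
from .attention_fusion import AttentionFusion, FusionConfig, gate_statistics, iaff
from .config import RunConfig, save_config
from .errors import InvalidInputError
from .hetero_gcn import FusionContext, ScoreMatrix, build_network, network_from_similarities
from .types import InteractionMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# audit + cache plumbing
# ---------------------------------------------------------------------------

class Audit:
    """Per-stage record of every input file read during a run."""

    def __init__(self):
        self.reads: dict[str, list[str]] = {}

    def record(self, stage: str, path: str | Path) -> None:
        self.reads.setdefault(stage, []).append(str(path))

    def to_dict(self) -> dict:
        return {stage: sorted(set(paths)) for stage, paths in self.reads.items()}


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

@dataclass
class PipelineInputs:
    """Resolved in-memory inputs for one run."""

    interactions: InteractionMatrix
    drug_similarities: list[SimilarityMatrix] = field(default_factory=list)
    disease_similarities: list[SimilarityMatrix] = field(default_factory=list)
    triples: kg_embedding.TripleStore | None = None


def load_inputs(
    interactions_path: str | Path,
    drug_similarity_paths: list[str | Path],
    disease_similarity_paths: list[str | Path],
    triples_path: str | Path | None,
    audit: Audit | None = None,
    need_triples: bool = True,
    need_similarities: bool = True,
) -> PipelineInputs:
    audit = audit or Audit()
    audit.record("load", interactions_path)
    interactions = io.read_interactions(interactions_path)
    drug_sims: list[SimilarityMatrix] = []
    disease_sims: list[SimilarityMatrix] = []
    if need_similarities:
        for p in drug_similarity_paths:
            audit.record("integrate", p)
            drug_sims.append(_reindex(io.read_similarity(p), interactions.drug_ids))
        for p in disease_similarity_paths:
            audit.record("integrate", p)
            disease_sims.append(_reindex(io.read_similarity(p), interactions.disease_ids))
    triples = None
    if need_triples:
        if triples_path is None:
            raise InvalidInputError("this variant requires a triples file")
        audit.record("embed", triples_path)
        triples = kg_embedding.read_triples(triples_path)
    return PipelineInputs(
        interactions=interactions,
        drug_similarities=drug_sims,
        disease_similarities=disease_sims,
        triples=triples,
    )


def _reindex(sim: SimilarityMatrix, ids: list[str]) -> SimilarityMatrix:
    if sim.ids == ids:
        return sim
    missing = set(ids) - set(sim.ids)
    if missing:
        raise InvalidInputError(
            f"similarity {sim.source_name!r} lacks entities: {sorted(missing)[:5]}..."
        )
    idx = [sim.ids.index(i) for i in ids]
    return SimilarityMatrix(
        ids=ids, values=sim.values[np.ix_(idx, idx)], source_name=sim.source_name
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def integrate_stage(
    similarities: list[SimilarityMatrix],
    interactions: InteractionMatrix,
    axis: str,
    config: RunConfig,
    seed: int,
) -> np.ndarray:
    """Similarity stack + profile kernel -> selected/denoised -> joint X."""
    gip = si.gip_similarity(interactions, axis=axis, gamma_prime=config.gip_gamma)
    stack = list(similarities) + [gip]
    selected = si.select_similarities(
        stack,
        entropy_quantile=config.entropy_quantile,
        redundancy_threshold=config.redundancy_threshold,
    )
    denoised = [si.denoise(s, alpha=config.alpha) for s in selected]
    n = denoised[0].values.shape[0]
    result = si.fit_joint_decomposition(
        denoised,
        dim_D=min(config.GR_dim, n),
        lambda_reg=config.lambda_reg,
        seed=seed,
    )
    return result.X


def embed_stage(
    triples: kg_embedding.TripleStore,
    interactions: InteractionMatrix,
    config: RunConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Benchmark-aligned KG -> ComplEx -> [Re || Im] features per side."""
    aligned = kg_embedding.align_benchmark(triples, interactions, config.dd_relation)
    emb = kg_embedding.fit_complex(
        aligned,
        k=config.kg_k,
        lr=config.KG_lr,
        reg_lambda=config.KG_regularization,
        epochs=config.KG_epochs,
        n_neg=config.KG_n_neg,
        seed=seed,
        batch_size=config.KG_batch_size,
    )
    # benchmark entities missing from the KG (possible for isolated rows)
    # get zero feature rows rather than failing the whole run
    def features_for(ids: list[str]) -> np.ndarray:
        out = np.zeros((len(ids), 2 * emb.k))
        known = [i for i, e in enumerate(ids) if e in emb.entity_index]
        if known:
            out[known] = kg_embedding.extract_features(emb, [ids[i] for i in known])
        return out

    return features_for(interactions.drug_ids), features_for(interactions.disease_ids)


def fuse_stage(
    X_drug: np.ndarray, Y_drug: np.ndarray,
    X_disease: np.ndarray, Y_disease: np.ndarray,
    config: RunConfig, seed: int,
) -> tuple[AttentionFusion, np.ndarray, np.ndarray]:
    if X_drug.shape != Y_drug.shape or X_disease.shape != Y_disease.shape:
        raise InvalidInputError(
            "fusion requires dimension-matched X and Y "
            f"(got {X_drug.shape} vs {Y_drug.shape})"
        )
    module = AttentionFusion(FusionConfig(channels=config.channels, ratio=config.ratio, seed=seed))
    Z_drug, gates = iaff(X_drug, Y_drug, module, return_gates=True)
    logger.info("fusion gate stats (drugs, stage 2): %s", gate_statistics(gates[1]))
    Z_disease = iaff(X_disease, Y_disease, module)
    return module, Z_drug, Z_disease


@dataclass
class PreparedProblem:
    """Everything the predictor needs, after the feature stages."""

    network: hetero_gcn.HeteroNetwork
    fusion: FusionContext | None
    features: dict[str, np.ndarray] = field(default_factory=dict)


def prepare_problem(
    inputs: PipelineInputs, config: RunConfig, seed: int,
    A_override: np.ndarray | None = None,
) -> PreparedProblem:
    """Run the feature stages for the configured variant and build the network.

    ``A_override`` substitutes the training association matrix (used by
    masked-holdout evaluation) for *every* stage that consumes interactions,
    so held-out test pairs never inform the features.
    """
    inter = inputs.interactions
    if A_override is not None:
        inter = InteractionMatrix(
            drug_ids=inter.drug_ids, disease_ids=inter.disease_ids, values=A_override
        )
    variant = config.variant
    features: dict[str, np.ndarray] = {}
    if variant == "no_kg_gri":
        if not inputs.drug_similarities or not inputs.disease_similarities:
            raise InvalidInputError("no_kg_gri variant needs one raw similarity per side")
        network = network_from_similarities(
            inputs.drug_similarities[0], inputs.disease_similarities[0],
            inter.values.astype(np.float64), topk=config.topk,
        )
        return PreparedProblem(network=network, fusion=None, features=features)

    if variant in ("full", "no_kg"):
        X_r = integrate_stage(inputs.drug_similarities, inter, "drugs", config, seed)
        X_d = integrate_stage(inputs.disease_similarities, inter, "diseases", config, seed + 1)
        features["X_drug"], features["X_disease"] = X_r, X_d
    if variant in ("full", "no_gri"):
        if inputs.triples is None:
            raise InvalidInputError("this variant requires knowledge-graph triples")
        Y_r, Y_d = embed_stage(inputs.triples, inter, config, seed)
        features["Y_drug"], features["Y_disease"] = Y_r, Y_d

    fusion = None
    if variant == "full":
        module, Z_r, Z_d = fuse_stage(
            features["X_drug"], features["Y_drug"],
            features["X_disease"], features["Y_disease"],
            config, seed,
        )
        fusion = FusionContext(
            module=module,
            X_drug=features["X_drug"], Y_drug=features["Y_drug"],
            X_disease=features["X_disease"], Y_disease=features["Y_disease"],
        )
        features["Z_drug"], features["Z_disease"] = Z_r, Z_d
    elif variant == "no_kg":
        Z_r, Z_d = features["X_drug"], features["X_disease"]
    else:  # no_gri
        Z_r, Z_d = features["Y_drug"], features["Y_disease"]

    network = build_network(
        Z_r, Z_d, inter.values.astype(np.float64),
        inter.drug_ids, inter.disease_ids, topk=config.topk,
    )
    return PreparedProblem(network=network, fusion=fusion, features=features)


# ---------------------------------------------------------------------------
# top-level runs
# ---------------------------------------------------------------------------

def run_pipeline(
    config: RunConfig,
    inputs: PipelineInputs,
    out_dir: str | Path,
    seed: int = 0,
    audit: Audit | None = None,
    run_cv: bool = True,
) -> Path:
    """Execute integrate -> embed -> fuse -> train (and CV) for one variant.

    Writes features, scores, metrics, the resolved config and the I/O audit
    into ``out_dir`` and returns that path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit = audit or Audit()
    problem = prepare_problem(inputs, config, seed)
    for name, matrix in problem.features.items():
        ids = inputs.interactions.drug_ids if "drug" in name else inputs.interactions.disease_ids
        io.write_features(ids, matrix, out / f"{name}.tsv")
    result = hetero_gcn.train(problem.network, config, seed=seed, fusion=problem.fusion)
    io.write_scores(
        result.scores.drug_ids, result.scores.disease_ids, result.scores.values,
        out / "scores.tsv",
    )
    metrics: dict = {"variant": config.variant, "seed": seed,
                     "final_train_loss": result.loss_trace[-1]}
    if run_cv and config.folds > 1:
        cv = hetero_gcn.evaluate_cv(
            inputs.interactions.values,
            _fold_trainer(problem, config, seed),
            folds=config.folds,
            seed=seed,
        )
        metrics.update(cv)
    io.write_json(metrics, out / "metrics.json")
    save_config(config, out / "resolved_config.yaml")
    io.write_json(audit.to_dict(), out / "audit.json")
    with open(out / "loss_trace.csv", "w") as fh:
        fh.write("epoch,loss\n")
        for i, value in enumerate(result.loss_trace):
            fh.write(f"{i},{value}\n")
    return out


def _fold_trainer(problem: PreparedProblem, config: RunConfig, seed: int):
    """Per-fold retraining closure reusing the (cached) feature stages."""

    def trainer(A_train: np.ndarray) -> np.ndarray:
        network = hetero_gcn.HeteroNetwork(
            drug_ids=problem.network.drug_ids,
            disease_ids=problem.network.disease_ids,
            A_r=problem.network.A_r,
            A_d=problem.network.A_d,
            A=A_train,
            topk=problem.network.topk,
            R=problem.network.R,
            D_sim=problem.network.D_sim,
            h_r=problem.network.h_r,
            h_d=problem.network.h_d,
        )
        fusion = None
        if problem.fusion is not None:
            # fresh fusion parameters per fold
            fusion = FusionContext(
                module=AttentionFusion(problem.fusion.module.config),
                X_drug=problem.fusion.X_drug, Y_drug=problem.fusion.Y_drug,
                X_disease=problem.fusion.X_disease, Y_disease=problem.fusion.Y_disease,
            )
        return hetero_gcn.train(network, config, seed=seed, fusion=fusion).scores.values

    return trainer


def masked_holdout_experiment(
    inputs: PipelineInputs,
    config: RunConfig,
    seed: int,
    mask_fraction: float = 0.1,
    shuffle_labels: bool = False,
) -> dict:
    """Leakage-free holdout: the whole pipeline runs on the masked matrix.

    A ``mask_fraction`` of positives is removed from the association matrix
    *before any stage runs* (features included), and the same fraction of
    zero pairs is reserved; AUROC/AUPR are computed on those held-out pairs.
    With ``shuffle_labels`` the association entries are randomly permuted
    first, which must drive AUROC to chance.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2 ** 32), 47]))
    A = inputs.interactions.values.astype(np.float64)
    if shuffle_labels:
        flat = A.ravel().copy()
        rng.shuffle(flat)
        A = flat.reshape(A.shape)
    flat = A.ravel()
    pos_idx = np.nonzero(flat == 1)[0]
    neg_idx = np.nonzero(flat == 0)[0]
    n_pos_test = max(1, int(round(mask_fraction * len(pos_idx))))
    n_neg_test = max(1, int(round(mask_fraction * len(neg_idx))))
    pos_test = rng.permutation(pos_idx)[:n_pos_test]
    neg_test = rng.permutation(neg_idx)[:n_neg_test]
    A_train = A.copy()
    A_train.ravel()[pos_test] = 0.0
    shuffled_inputs = PipelineInputs(
        interactions=InteractionMatrix(
            drug_ids=inputs.interactions.drug_ids,
            disease_ids=inputs.interactions.disease_ids,
            values=A,
        ),
        drug_similarities=inputs.drug_similarities,
        disease_similarities=inputs.disease_similarities,
        triples=inputs.triples,
    )
    problem = prepare_problem(shuffled_inputs, config, seed, A_override=A_train)
    result = hetero_gcn.train(problem.network, config, seed=seed, fusion=problem.fusion)
    scores = result.scores.values.ravel()
    test_idx = np.concatenate([pos_test, neg_test])
    labels = np.concatenate([np.ones(len(pos_test)), np.zeros(len(neg_test))])
    return {
        "auroc": hetero_gcn.auroc(labels, scores[test_idx]),
        "aupr": hetero_gcn.aupr(labels, scores[test_idx]),
        "n_test_pos": int(n_pos_test),
        "n_test_neg": int(n_neg_test),
    }


def rank_candidates(
    scores: ScoreMatrix,
    interactions: InteractionMatrix,
    disease_id: str,
    top_n: int = 10,
) -> list[tuple[str, float]]:
    """Top-scoring drugs among pairs not already known for one disease.

    Sorted by score descending, ties broken by drug id; at most ``top_n``
    rows.
    """
    if disease_id not in scores.disease_ids:
        raise InvalidInputError(f"unknown disease id {disease_id!r}")
    j = scores.disease_ids.index(disease_id)
    known_j = interactions.disease_ids.index(disease_id)
    candidates = [
        (drug, float(scores.values[i, j]))
        for i, drug in enumerate(scores.drug_ids)
        if interactions.values[interactions.drug_ids.index(drug), known_j] == 0
    ]
    candidates.sort(key=lambda item: (-item[1], item[0]))
    return candidates[:top_n]
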