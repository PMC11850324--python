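"""Heterogeneous GCN link predictor.

Builds a drug-disease heterogeneous network (kNN graphs over fused-feature
similarities plus the binary association matrix), learns intra-domain and
inter-domain embeddings with layer attention, decodes association
probabilities with a bilinear sigmoid decoder, and trains end-to-end with a
class-weighted binary cross entropy.

The plain-numpy functions in this module are the reference forward passes
used by unit tests; :class:`HeteroGCNModel` mirrors them on autodiff tensors
for training (optionally with the attention-fusion parameters in the loop).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import average_precision_score, roc_auc_score

from . import autodiff as ad
from .attention_fusion import AttentionFusion, iaff
from .autodiff import Adam, Tensor
from .errors import ConvergenceError, InvalidInputError
from .types import SimilarityMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def fused_similarity(
    Z: np.ndarray, ids: list[str] | None = None, bandwidth: float | str = "median"
) -> SimilarityMatrix:
    """Gaussian similarity ``exp(-d^2 / 2h^2)`` over feature rows.

    ``h`` is either given or the median off-diagonal Euclidean distance.
    Identical rows get similarity 1; if *all* rows coincide (h = 0) the
    matrix degrades to all-ones with a warning.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise InvalidInputError("fused_similarity needs a 2-D matrix with >= 2 rows")
    n = Z.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    dist = pdist(Z)
    if bandwidth == "median":
        h = float(np.median(dist))
    else:
        h = float(bandwidth)
    if h <= 0:
        logger.warning("degenerate bandwidth h=0 (identical rows); similarity set to 1")
        return SimilarityMatrix(ids=ids, values=np.ones((n, n)), source_name="fused")
    values = squareform(np.exp(-(dist ** 2) / (2.0 * h * h)))
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=ids, values=values, source_name="fused")


def knn_graph(S: SimilarityMatrix, topk: int) -> np.ndarray:
    """Sparsify a similarity matrix to its top-k neighbors per row.

    Self-similarity is excluded; ties at the boundary go to the smaller
    index; the result is symmetrized by elementwise max and has zero
    diagonal, so each row keeps at least ``topk`` nonzeros.
    """
    n = S.n
    if not (1 <= topk < n):
        raise InvalidInputError(f"topk must be in [1, {n - 1}], got {topk}")
    values = S.values
    adj = np.zeros_like(values)
    for i in range(n):
        row = values[i].copy()
        row[i] = -np.inf
        # stable sort on -sim keeps smaller indices first among ties
        neighbors = np.argsort(-row, kind="stable")[:topk]
        adj[i, neighbors] = values[i, neighbors]
    adj = np.maximum(adj, adj.T)
    np.fill_diagonal(adj, 0.0)
    return adj


@dataclass
class HeteroNetwork:
    drug_ids: list[str]
    disease_ids: list[str]
    A_r: np.ndarray
    A_d: np.ndarray
    A: np.ndarray
    topk: int
    R: np.ndarray
    D_sim: np.ndarray
    h_r: float = 0.0
    h_d: float = 0.0

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)


def build_network(
    Z_drug: np.ndarray,
    Z_disease: np.ndarray,
    A: np.ndarray,
    drug_ids: list[str],
    disease_ids: list[str],
    topk: int = 15,
) -> HeteroNetwork:
    """Heterogeneous network from fused features and known associations."""
    dist_r = pdist(np.asarray(Z_drug, dtype=np.float64))
    dist_d = pdist(np.asarray(Z_disease, dtype=np.float64))
    h_r = float(np.median(dist_r))
    h_d = float(np.median(dist_d))
    R = fused_similarity(Z_drug, drug_ids, bandwidth=h_r if h_r > 0 else "median")
    D_sim = fused_similarity(Z_disease, disease_ids, bandwidth=h_d if h_d > 0 else "median")
    topk_r = min(topk, len(drug_ids) - 1)
    topk_d = min(topk, len(disease_ids) - 1)
    return HeteroNetwork(
        drug_ids=list(drug_ids),
        disease_ids=list(disease_ids),
        A_r=knn_graph(R, topk_r),
        A_d=knn_graph(D_sim, topk_d),
        A=np.asarray(A, dtype=np.float64),
        topk=topk,
        R=R.values,
        D_sim=D_sim.values,
        h_r=h_r,
        h_d=h_d,
    )


def network_from_similarities(
    S_r: SimilarityMatrix, S_d: SimilarityMatrix, A: np.ndarray, topk: int = 15
) -> HeteroNetwork:
    """Network built directly from given similarity matrices (no features)."""
    topk_r = min(topk, S_r.n - 1)
    topk_d = min(topk, S_d.n - 1)
    return HeteroNetwork(
        drug_ids=list(S_r.ids),
        disease_ids=list(S_d.ids),
        A_r=knn_graph(S_r, topk_r),
        A_d=knn_graph(S_d, topk_d),
        A=np.asarray(A, dtype=np.float64),
        topk=topk,
        R=S_r.values,
        D_sim=S_d.values,
    )


# ---------------------------------------------------------------------------
# reference (numpy) forward operations
# ---------------------------------------------------------------------------

def init_state(S_r: np.ndarray, S_d: np.ndarray) -> np.ndarray:
    """Block-diagonal initial embedding [[S_r, 0], [0, S_d]]."""
    n, m = S_r.shape[0], S_d.shape[0]
    H0 = np.zeros((n + m, n + m))
    H0[:n, :n] = S_r
    H0[n:, n:] = S_d
    return H0


def _sym_normalize(A: np.ndarray) -> np.ndarray:
    deg = A.sum(axis=1)
    deg = np.where(deg > 0, deg, 1.0)  # zero-degree fallback
    inv_sqrt = 1.0 / np.sqrt(deg)
    return inv_sqrt[:, None] * A * inv_sqrt[None, :]


def normalized_gcn(A: np.ndarray, H: np.ndarray, W: np.ndarray) -> np.ndarray:
    """``ReLU(D^-1/2 A D^-1/2 H W)`` with zero-degree rows clamped to degree 1."""
    return np.maximum(_sym_normalize(A) @ H @ W, 0.0)


def intra_domain_step(
    H_r: np.ndarray, H_d: np.ndarray,
    A_r: np.ndarray, A_d: np.ndarray,
    W_r: np.ndarray, W_d: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent GCN propagation on the drug and disease graphs."""
    return normalized_gcn(A_r, H_r, W_r), normalized_gcn(A_d, H_d, W_d)


def inter_domain_step(
    H_r: np.ndarray, H_d: np.ndarray,
    A: np.ndarray, W: np.ndarray, alpha: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-domain aggregation mixing a bilinear and a mean aggregator.

    Drug i receives ``relu(alpha * (H_r W (.) sum_j A_ij H_dj W) / (deg_i + 1)
    + (1 - alpha) * (sum_j A_ij H_dj W) / deg_i)``; diseases use A^T
    symmetrically. The bilinear branch is normalized by degree + 1 exactly
    as specified; zero degrees in the mean branch fall back to 1.
    """
    HrW = H_r @ W
    HdW = H_d @ W
    deg_r = A.sum(axis=1)
    deg_d = A.sum(axis=0)
    agg_r = A @ HdW
    agg_d = A.T @ HrW
    ba_r = (HrW * agg_r) / (deg_r + 1.0)[:, None]
    ba_d = (HdW * agg_d) / (deg_d + 1.0)[:, None]
    mean_r = agg_r / np.where(deg_r > 0, deg_r, 1.0)[:, None]
    mean_d = agg_d / np.where(deg_d > 0, deg_d, 1.0)[:, None]
    out_r = np.maximum(alpha * ba_r + (1.0 - alpha) * mean_r, 0.0)
    out_d = np.maximum(alpha * ba_d + (1.0 - alpha) * mean_d, 0.0)
    return out_r, out_d


def merge_step(intra: np.ndarray, inter: np.ndarray, H_prev: np.ndarray) -> np.ndarray:
    """Residual merge: intra + inter + previous-layer embedding."""
    return intra + inter + H_prev


def layer_attention_combine(
    states: list[np.ndarray], beta: np.ndarray, n_drugs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Attention-weighted sum of per-layer embeddings, split drug/disease."""
    beta = np.asarray(beta, dtype=np.float64)
    if len(states) != beta.shape[0]:
        raise InvalidInputError("beta length must match the number of layer states")
    combined = sum(b * H for b, H in zip(beta, states))
    return combined[:n_drugs], combined[n_drugs:]


@dataclass
class ScoreMatrix:
    drug_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray


def decode_scores(H_R: np.ndarray, H_D: np.ndarray) -> np.ndarray:
    """Elementwise logistic of the drug-disease inner products."""
    logits = H_R @ H_D.T
    probs = 1.0 / (1.0 + np.exp(-np.clip(logits, -500, 500)))
    return np.clip(probs, 1e-12, 1.0 - 1e-12)


def weighted_bce_loss(scores: np.ndarray, A: np.ndarray) -> float:
    """Class-weighted binary cross entropy.

    ``-(1/NM) [gamma * sum_{S+} log s_ij + sum_{S-} log(1 - s_ij)]`` with
    ``gamma = |S-| / |S+|`` countering the positive/negative imbalance.
    """
    A = np.asarray(A)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != A.shape:
        raise InvalidInputError("scores and A must have the same shape")
    pos = A == 1
    n_pos = int(pos.sum())
    n_neg = A.size - n_pos
    if n_pos == 0:
        raise InvalidInputError("weighted BCE undefined without positive pairs")
    gamma = n_neg / n_pos
    return float(
        -(gamma * np.log(scores[pos]).sum() + np.log(1.0 - scores[~pos]).sum()) / A.size
    )


# ---------------------------------------------------------------------------
# trainable model
# ---------------------------------------------------------------------------

@dataclass
class FusionContext:
    """Inputs for the end-to-end fusion path.

    When present, the initial node embeddings are re-derived every forward
    pass from ``iaff(X, Y)`` through a differentiable Gaussian kernel, so
    gradients reach the fusion parameters. The discrete kNN topology stays
    the one built from the initial fused features.
    """

    module: AttentionFusion
    X_drug: np.ndarray
    Y_drug: np.ndarray
    X_disease: np.ndarray
    Y_disease: np.ndarray


class HeteroGCNModel:
    """Layered intra/inter-domain GCN with layer attention and sigmoid decoder."""

    def __init__(self, network: HeteroNetwork, k: int, n_layers: int, seed: int = 0):
        n, m = network.n_drugs, network.n_diseases
        self.network = network
        self.k = k
        self.n_layers = n_layers
        rng = np.random.default_rng(np.random.SeedSequence([seed % (2 ** 32), 37]))
        scale = 1.0 / np.sqrt(n + m)
        # rows of the (N+M) x k input projection, split by block so the
        # block-diagonal initial state never has to be materialized
        self.P_r = Tensor(scale * rng.standard_normal((n, k)), requires_grad=True)
        self.P_d = Tensor(scale * rng.standard_normal((m, k)), requires_grad=True)
        wscale = 1.0 / np.sqrt(k)
        self.W_r = [Tensor(wscale * rng.standard_normal((k, k)), requires_grad=True)
                    for _ in range(n_layers)]
        self.W_d = [Tensor(wscale * rng.standard_normal((k, k)), requires_grad=True)
                    for _ in range(n_layers)]
        self.W = [Tensor(wscale * rng.standard_normal((k, k)), requires_grad=True)
                  for _ in range(n_layers)]
        self.alpha = [Tensor(np.array([[0.5]]), requires_grad=True) for _ in range(n_layers)]
        self.beta = [Tensor(np.array([[1.0 / n_layers]]), requires_grad=True)
                     for _ in range(n_layers)]
        self.An_r = _sym_normalize(network.A_r)
        self.An_d = _sym_normalize(network.A_d)

    @property
    def params(self) -> list[Tensor]:
        return ([self.P_r, self.P_d] + self.W_r + self.W_d + self.W
                + self.alpha + self.beta)

    # ---- differentiable forward -----------------------------------------

    def _initial_blocks(self, fusion: FusionContext | None):
        net = self.network
        if fusion is None:
            return Tensor(net.R), Tensor(net.D_sim)
        Z_r = iaff(Tensor(fusion.X_drug), Tensor(fusion.Y_drug), fusion.module)
        Z_d = iaff(Tensor(fusion.X_disease), Tensor(fusion.Y_disease), fusion.module)
        return (
            _gaussian_kernel_tensor(Z_r, net.h_r),
            _gaussian_kernel_tensor(Z_d, net.h_d),
        )

    def forward(
        self,
        A_train: np.ndarray,
        fusion: FusionContext | None = None,
        dropout: float = 0.0,
        edge_dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Return the logits tensor (N x M) for the given training adjacency."""
        net = self.network
        A_eff = A_train
        if edge_dropout > 0 and rng is not None:
            mask = rng.random(A_train.shape) >= edge_dropout
            A_eff = A_train * mask
        A_t = Tensor(A_eff)
        At_t = Tensor(A_eff.T)
        deg_r = A_eff.sum(axis=1)
        deg_d = A_eff.sum(axis=0)
        inv_ba_r = Tensor(1.0 / (deg_r + 1.0)[:, None])
        inv_ba_d = Tensor(1.0 / (deg_d + 1.0)[:, None])
        inv_mean_r = Tensor(1.0 / np.where(deg_r > 0, deg_r, 1.0)[:, None])
        inv_mean_d = Tensor(1.0 / np.where(deg_d > 0, deg_d, 1.0)[:, None])
        An_r = Tensor(self.An_r)
        An_d = Tensor(self.An_d)
        R0, D0 = self._initial_blocks(fusion)
        H_r = R0 @ self.P_r
        H_d = D0 @ self.P_d
        layers_r, layers_d = [], []
        for layer in range(self.n_layers):
            intra_r = ad.relu(An_r @ H_r @ self.W_r[layer])
            intra_d = ad.relu(An_d @ H_d @ self.W_d[layer])
            HrW = H_r @ self.W[layer]
            HdW = H_d @ self.W[layer]
            agg_r = A_t @ HdW
            agg_d = At_t @ HrW
            a = self.alpha[layer]
            inter_r = ad.relu(a * (HrW * agg_r) * inv_ba_r + (1.0 - a) * agg_r * inv_mean_r)
            inter_d = ad.relu(a * (HdW * agg_d) * inv_ba_d + (1.0 - a) * agg_d * inv_mean_d)
            H_r = intra_r + inter_r + H_r
            H_d = intra_d + inter_d + H_d
            if dropout > 0 and rng is not None:
                keep_r = (rng.random(H_r.shape) >= dropout) / (1.0 - dropout)
                keep_d = (rng.random(H_d.shape) >= dropout) / (1.0 - dropout)
                H_r = H_r * Tensor(keep_r)
                H_d = H_d * Tensor(keep_d)
            layers_r.append(H_r)
            layers_d.append(H_d)
        H_R = layers_r[0] * self.beta[0]
        H_D = layers_d[0] * self.beta[0]
        for layer in range(1, self.n_layers):
            H_R = H_R + layers_r[layer] * self.beta[layer]
            H_D = H_D + layers_d[layer] * self.beta[layer]
        return H_R @ H_D.T

    def predict(self, fusion: FusionContext | None = None) -> np.ndarray:
        logits = self.forward(self.network.A, fusion=fusion)
        return np.clip(
            1.0 / (1.0 + np.exp(-np.clip(logits.data, -500, 500))), 1e-12, 1.0 - 1e-12
        )


def _gaussian_kernel_tensor(Z: Tensor, h: float) -> Tensor:
    if h <= 0:
        return Tensor(np.ones((Z.shape[0], Z.shape[0])))
    sq_norms = (Z ** 2.0).sum(axis=1, keepdims=True)
    sq_dist = sq_norms + sq_norms.T - 2.0 * (Z @ Z.T)
    return ad.exp(sq_dist * (-1.0 / (2.0 * h * h)))


@dataclass
class TrainResult:
    model: HeteroGCNModel
    scores: ScoreMatrix
    loss_trace: list[float] = field(default_factory=list)


def _bce_from_logits(logits: Tensor, A_train: np.ndarray) -> Tensor:
    pos = (A_train == 1).astype(np.float64)
    neg = 1.0 - pos
    n_pos = pos.sum()
    if n_pos == 0:
        raise InvalidInputError("weighted BCE undefined without positive pairs")
    gamma = neg.sum() / n_pos
    pos_term = (Tensor(pos) * ad.softplus(-logits)).sum()
    neg_term = (Tensor(neg) * ad.softplus(logits)).sum()
    return (gamma * pos_term + neg_term) / float(A_train.size)


def train(
    network: HeteroNetwork,
    config,
    seed: int = 0,
    fusion: FusionContext | None = None,
) -> TrainResult:
    """End-to-end Adam training of the predictor (and fusion, if given).

    ``config`` needs attributes ``epoch``, ``learning_rate``, ``layer_num``,
    ``embedding_dim``, ``dropout`` and ``edge_dropout``. Deterministic for a
    fixed seed.
    """
    model = HeteroGCNModel(
        network, k=config.embedding_dim, n_layers=config.layer_num, seed=seed
    )
    params = model.params + (fusion.module.params if fusion is not None else [])
    optimizer = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2 ** 32), 41]))
    trace: list[float] = []
    for epoch in range(config.epoch):
        logits = model.forward(
            network.A, fusion=fusion,
            dropout=config.dropout, edge_dropout=config.edge_dropout, rng=rng,
        )
        loss = _bce_from_logits(logits, network.A)
        if not np.isfinite(loss.data):
            raise ConvergenceError(
                f"training diverged at epoch {epoch} -- reduce learning rate "
                f"(currently {config.learning_rate})"
            )
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        trace.append(float(loss.data))
    scores = ScoreMatrix(
        drug_ids=network.drug_ids,
        disease_ids=network.disease_ids,
        values=model.predict(fusion=fusion),
    )
    return TrainResult(model=model, scores=scores, loss_trace=trace)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    return float(roc_auc_score(labels, scores))


def aupr(labels: np.ndarray, scores: np.ndarray) -> float:
    return float(average_precision_score(labels, scores))


def cv_folds(
    A: np.ndarray, folds: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition positive and negative pairs independently into test folds.

    Returns per fold a pair of flat-index arrays (positives, negatives);
    every pair of the matrix appears in exactly one fold.
    """
    A = np.asarray(A)
    flat = A.ravel()
    pos_idx = np.nonzero(flat == 1)[0]
    neg_idx = np.nonzero(flat == 0)[0]
    if len(pos_idx) < folds:
        raise InvalidInputError(f"need at least {folds} positives for {folds}-fold CV")
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2 ** 32), 43]))
    pos_perm = rng.permutation(pos_idx)
    neg_perm = rng.permutation(neg_idx)
    return [
        (np.sort(pos_perm[f::folds]), np.sort(neg_perm[f::folds]))
        for f in range(folds)
    ]


def evaluate_cv(A: np.ndarray, trainer, folds: int = 10, seed: int = 0) -> dict:
    """K-fold CV masking test positives to 0 in the training adjacency.

    ``trainer(A_train) -> score matrix`` retrains the model per fold; AUROC
    and AUPR are computed on the held-out labeled pairs only.
    """
    A = np.asarray(A)
    results = []
    for fold_id, (pos_f, neg_f) in enumerate(cv_folds(A, folds=folds, seed=seed)):
        A_train = A.copy().astype(np.float64)
        A_train.ravel()[pos_f] = 0.0
        scores = np.asarray(trainer(A_train), dtype=np.float64)
        test_idx = np.concatenate([pos_f, neg_f])
        labels = np.concatenate([np.ones(len(pos_f)), np.zeros(len(neg_f))])
        preds = scores.ravel()[test_idx]
        results.append({
            "fold": fold_id,
            "auroc": auroc(labels, preds),
            "aupr": aupr(labels, preds),
        })
    aurocs = np.array([r["auroc"] for r in results])
    auprs = np.array([r["aupr"] for r in results])
    return {
        "folds": results,
        "mean_auroc": float(aurocs.mean()),
        "sd_auroc": float(aurocs.std(ddof=1)) if folds > 1 else 0.0,
        "mean_aupr": float(auprs.mean()),
        "sd_aupr": float(auprs.std(ddof=1)) if folds > 1 else 0.0,
    }
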