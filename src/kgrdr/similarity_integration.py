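"""Multi-similarity integration.

Pipeline stage 1: compute interaction-profile kernel similarities, select an
informative low-redundancy subset of similarity views, denoise each view by a
spectral diffusion filter, and fuse the denoised views into a single common
feature matrix by KL-divergence joint decomposition with graph-Laplacian
regularization.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import squareform
from scipy.special import logsumexp

from .errors import InvalidInputError
from .types import DenoisedSimilarity, InteractionMatrix, JointDecompositionResult, SimilarityMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# profile-kernel similarity
# ---------------------------------------------------------------------------

def gip_similarity(
    interactions: InteractionMatrix,
    axis: str = "drugs",
    gamma_prime: float = 1.0,
) -> SimilarityMatrix:
    """Gaussian kernel over binary interaction profiles.

    ``axis='drugs'`` uses row profiles (one per drug), ``axis='diseases'``
    column profiles. The bandwidth is ``gamma_prime * n / sum_i ||p_i||^2``,
    i.e. normalized by the mean squared profile norm.
    """
    if axis not in ("drugs", "diseases"):
        raise InvalidInputError(f"axis must be 'drugs' or 'diseases', got {axis!r}")
    if gamma_prime <= 0:
        raise InvalidInputError("gamma_prime must be positive")
    if axis == "drugs":
        profiles = interactions.values.astype(np.float64)
        ids = interactions.drug_ids
    else:
        profiles = interactions.values.T.astype(np.float64)
        ids = interactions.disease_ids
    n = profiles.shape[0]
    if n == 0:
        raise InvalidInputError("empty interaction matrix")
    norm_sq = (profiles ** 2).sum(axis=1)
    total = norm_sq.sum()
    if total == 0:
        raise InvalidInputError("all-zero interaction matrix: kernel bandwidth undefined")
    gamma_n = gamma_prime * n / total
    # ||p_a - p_b||^2 expanded via the Gram matrix; exact for binary profiles
    gram = profiles @ profiles.T
    sq_dist = norm_sq[:, None] + norm_sq[None, :] - 2.0 * gram
    np.maximum(sq_dist, 0.0, out=sq_dist)
    values = np.exp(-gamma_n * sq_dist)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=ids, values=values, source_name=f"gip_{axis}")


# ---------------------------------------------------------------------------
# similarity selection
# ---------------------------------------------------------------------------

def average_entropy(sim: SimilarityMatrix) -> float:
    """Mean per-row Shannon entropy (nats) of the row-normalized matrix.

    Each row is treated as a probability distribution over entities; a row
    summing to zero contributes entropy 0 (with a warning). Result lies in
    ``[0, log N]``.
    """
    if sim.n < 2:
        raise InvalidInputError("average_entropy needs at least 2 entities")
    values = sim.values
    row_sums = values.sum(axis=1)
    zero_rows = row_sums <= 0
    if zero_rows.any():
        logger.warning(
            "%d zero row(s) in %r treated as entropy 0", int(zero_rows.sum()), sim.source_name
        )
    entropies = np.zeros(sim.n)
    for i in np.nonzero(~zero_rows)[0]:
        p = values[i] / row_sums[i]
        nz = p > 0
        entropies[i] = -(p[nz] * np.log(p[nz])).sum()
    return float(entropies.mean())


def _pairwise_redundancy(a: SimilarityMatrix, b: SimilarityMatrix) -> float:
    """Pearson correlation of the strict upper triangles of two matrices."""
    ua = squareform(a.values, checks=False)
    ub = squareform(b.values, checks=False)
    if ua.std() == 0 or ub.std() == 0:
        # degenerate constant off-diagonals: identical constants are fully
        # redundant, different constants are not comparable by correlation
        return 1.0 if np.allclose(ua, ub) else 0.0
    return float(np.corrcoef(ua, ub)[0, 1])


def select_similarities(
    stack: list[SimilarityMatrix],
    entropy_quantile: float = 0.75,
    redundancy_threshold: float = 0.8,
) -> list[SimilarityMatrix]:
    """Keep the informative, non-redundant subset of a similarity stack.

    Matrices with average entropy above the ``entropy_quantile`` of the
    stack's entropy distribution are dropped (high entropy = flat,
    uninformative rows); of each remaining pair more correlated than
    ``redundancy_threshold``, the higher-entropy member is dropped.
    The result preserves input order and is never empty.
    """
    if not stack:
        raise InvalidInputError("empty similarity stack")
    if not (0 < entropy_quantile <= 1) or not (0 < redundancy_threshold <= 1):
        raise InvalidInputError("selection thresholds must lie in (0, 1]")
    ids0 = stack[0].ids
    for sim in stack[1:]:
        if sim.ids != ids0:
            raise InvalidInputError(
                f"similarity matrix {sim.source_name!r} has a different id ordering"
            )
    entropies = np.array([average_entropy(s) for s in stack])
    cutoff = float(np.quantile(entropies, entropy_quantile))
    surviving = [i for i in range(len(stack)) if entropies[i] <= cutoff]
    if not surviving:  # defensive; quantile of the data always covers the min
        surviving = [int(np.argmin(entropies))]
    # greedy redundancy elimination, most informative (lowest entropy) first;
    # ties broken by input position so the outcome is deterministic
    order = sorted(surviving, key=lambda i: (entropies[i], i))
    kept: list[int] = []
    for i in order:
        if all(_pairwise_redundancy(stack[i], stack[j]) <= redundancy_threshold for j in kept):
            kept.append(i)
    kept.sort()
    selected = [stack[i] for i in kept]
    logger.info(
        "similarity selection kept %d/%d views: %s",
        len(selected), len(stack), [s.source_name for s in selected],
    )
    return selected


# ---------------------------------------------------------------------------
# spectral denoising
# ---------------------------------------------------------------------------

def denoise(sim: SimilarityMatrix, alpha: float = 0.8) -> DenoisedSimilarity:
    """Spectral diffusion filter ``(1-a) U S (I - a S^2)^-1 U^T``.

    The input is first symmetrically normalized (``D^-1/2 S D^-1/2``) so its
    eigenvalues lie in [-1, 1] and the eigenbasis is orthogonal; each
    eigenvalue ``l`` is then mapped to ``(1-a) l / (1 - a l^2)``, damping
    small noisy components relative to dominant structure.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha}")
    values = np.array(sim.values, dtype=np.float64)
    row_sums = values.sum(axis=1)
    isolated = row_sums <= 0
    if isolated.any():
        logger.warning(
            "%d isolated entit(ies) in %r given unit self-loops before normalization",
            int(isolated.sum()), sim.source_name,
        )
        for i in np.nonzero(isolated)[0]:
            values[i, i] = 1.0
        row_sums = values.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(row_sums)
    normalized = inv_sqrt[:, None] * values * inv_sqrt[None, :]
    normalized = (normalized + normalized.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(normalized)
    filtered = (1.0 - alpha) * eigvals / (1.0 - alpha * eigvals ** 2)
    out = (eigvecs * filtered) @ eigvecs.T
    out = (out + out.T) / 2.0
    return DenoisedSimilarity(
        values=out, alpha=alpha, eigvecs=eigvecs, eigvals=eigvals,
        ids=list(sim.ids), source_name=sim.source_name,
    )


# ---------------------------------------------------------------------------
# joint decomposition with graph regularization
# ---------------------------------------------------------------------------

def reconstruct(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-stochastic reconstruction ``softmax(X W)`` (row-wise softmax).

    ``X`` is entities x D (rows are entity features), ``W`` is D x N
    (columns are view-specific features), so entry (i, j) is
    ``exp(x_i . w_j) / sum_j' exp(x_i . w_j')``.
    """
    X = np.asarray(X, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    logits = X @ W
    logits = logits - logits.max(axis=1, keepdims=True)
    np.exp(logits, out=logits)
    logits /= logits.sum(axis=1, keepdims=True)
    return logits


def _normalize_target_rows(values: np.ndarray, name: str = "") -> np.ndarray:
    """Row-normalize a denoised matrix into per-row distributions.

    Negative entries (possible after spectral filtering) are clipped to 0;
    zero rows become uniform (with a warning).
    """
    clipped = np.maximum(np.asarray(values, dtype=np.float64), 0.0)
    sums = clipped.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        logger.warning("%d zero target row(s) in %r treated as uniform", int(zero.sum()), name)
        clipped[zero] = 1.0
        sums = clipped.sum(axis=1)
    return clipped / sums[:, None]


def laplacian_quadratic(X: np.ndarray, S: np.ndarray) -> float:
    """``Tr(X^T L X)`` with ``L = diag(rowsum(S)) - S`` and entity-row X.

    Equals ``(1/2) sum_ij ||x_i - x_j||^2 s_ij`` for symmetric ``S``.
    """
    degrees = S.sum(axis=1)
    return float(np.einsum("id,id->", X * degrees[:, None] - S @ X, X))


def joint_loss(
    denoised: list[DenoisedSimilarity],
    X: np.ndarray,
    W_list: list[np.ndarray],
    lambda_reg: float,
) -> tuple[float, float, float]:
    """Total, approximation (KL) and regularization loss of the decomposition.

    ``L_appr = (1/N) sum_v sum_i KL(t_i^(v) || softmax(X W^(v))_i)`` with
    ``t^(v)`` the row-normalized denoised matrices;
    ``L_reg = sum_v Tr(X^T L^(v) X)``; ``L = L_appr + lambda * L_reg``.
    """
    if len(denoised) != len(W_list):
        raise InvalidInputError("one W matrix required per denoised view")
    n = X.shape[0]
    l_appr = 0.0
    l_reg = 0.0
    for dn, W in zip(denoised, W_list):
        target = _normalize_target_rows(dn.values, dn.source_name)
        logits = X @ W
        log_probs = logits - logsumexp(logits, axis=1, keepdims=True)
        nz = target > 0
        l_appr += float(
            (target[nz] * (np.log(target[nz]) - log_probs[nz])).sum()
        ) / n
        l_reg += laplacian_quadratic(X, dn.values)
    total = l_appr + lambda_reg * l_reg
    return total, l_appr, l_reg


def _joint_grad(
    targets: list[np.ndarray],
    laplacians: list[np.ndarray],
    X: np.ndarray,
    W_list: list[np.ndarray],
    lambda_reg: float,
) -> tuple[np.ndarray, list[np.ndarray]]:
    n = X.shape[0]
    gX = np.zeros_like(X)
    gW_list = []
    for target, lap, W in zip(targets, laplacians, W_list):
        logits = X @ W
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        g_logits = (probs - target) / n
        gX += g_logits @ W.T
        gW_list.append(X.T @ g_logits)
        gX += 2.0 * lambda_reg * (lap @ X)
    return gX, gW_list


def fit_joint_decomposition(
    denoised: list[DenoisedSimilarity],
    dim_D: int,
    lambda_reg: float = 10.0,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> JointDecompositionResult:
    """Minimize the joint loss over X and the per-view W matrices.

    Full-batch gradient descent with step halving: a step is only accepted
    if it does not increase the loss, so the recorded trace is
    non-increasing. Deterministic for a fixed seed.
    """
    if not denoised:
        raise InvalidInputError("no denoised views to decompose")
    n = denoised[0].values.shape[0]
    if not (1 <= dim_D <= n):
        raise InvalidInputError(f"dim_D must be in [1, {n}], got {dim_D}")
    if lambda_reg < 0:
        raise InvalidInputError("lambda_reg must be >= 0")
    rng = np.random.default_rng(seed)
    X = 0.01 * rng.standard_normal((n, dim_D))
    W_list = [0.01 * rng.standard_normal((dim_D, n)) for _ in denoised]
    targets = [_normalize_target_rows(d.values, d.source_name) for d in denoised]
    laplacians = [np.diag(d.values.sum(axis=1)) - d.values for d in denoised]

    def loss_of(Xc, Wc):
        l_appr = 0.0
        l_reg = 0.0
        for target, dn, W in zip(targets, denoised, Wc):
            logits = Xc @ W
            log_probs = logits - logsumexp(logits, axis=1, keepdims=True)
            nz = target > 0
            l_appr += float((target[nz] * (np.log(target[nz]) - log_probs[nz])).sum()) / n
            l_reg += laplacian_quadratic(Xc, dn.values)
        return l_appr + lambda_reg * l_reg, l_appr, l_reg

    current = loss_of(X, W_list)
    trace = [current]
    step = 1.0
    converged = False
    for _ in range(max_iter):
        gX, gW = _joint_grad(targets, laplacians, X, W_list, lambda_reg)
        accepted = False
        for _half in range(50):
            X_new = X - step * gX
            W_new = [W - step * g for W, g in zip(W_list, gW)]
            candidate = loss_of(X_new, W_new)
            if np.isfinite(candidate[0]) and candidate[0] <= current[0]:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            converged = True  # no descent step exists at float precision
            break
        X, W_list = X_new, W_new
        previous = current
        current = candidate
        trace.append(current)
        step = min(step * 1.2, 1e3)
        denom = max(abs(previous[0]), 1e-30)
        if abs(previous[0] - current[0]) / denom < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "joint decomposition hit max_iter=%d before reaching tol=%g", max_iter, tol
        )
    return JointDecompositionResult(
        X=X, W_list=W_list, lambda_reg=lambda_reg, loss_trace=trace, converged=converged
    )
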