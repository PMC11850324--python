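"""Core domain containers used across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

SYMMETRY_TOL = 1e-8


@dataclass
class SimilarityMatrix:
    """Square symmetric pairwise-similarity matrix over one entity set."""

    ids: list[str]
    values: np.ndarray
    source_name: str = ""

    def __post_init__(self):
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InvalidInputError(
                f"similarity matrix shape {self.values.shape} does not match {n} ids"
            )
        if n and np.abs(self.values - self.values.T).max() > SYMMETRY_TOL:
            raise InvalidInputError(f"similarity matrix {self.source_name!r} is not symmetric")
        if n and (self.values.min() < -SYMMETRY_TOL or self.values.max() > 1 + SYMMETRY_TOL):
            raise InvalidInputError(
                f"similarity values of {self.source_name!r} fall outside [0, 1]"
            )

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class InteractionMatrix:
    """Binary drug x disease association matrix with named axes."""

    drug_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.drug_ids = list(self.drug_ids)
        self.disease_ids = list(self.disease_ids)
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise InvalidInputError("interaction matrix shape does not match id lists")
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise InvalidInputError("interaction matrix must be binary")
        self.values = self.values.astype(np.int8)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def pairs(self) -> list[tuple[str, str]]:
        """(drug_id, disease_id) for every 1-entry, in row-major order."""
        rows, cols = np.nonzero(self.values)
        return [(self.drug_ids[i], self.disease_ids[j]) for i, j in zip(rows, cols)]


@dataclass
class DenoisedSimilarity:
    """Spectrally filtered similarity matrix together with its eigenfactors."""

    values: np.ndarray
    alpha: float
    eigvecs: np.ndarray
    eigvals: np.ndarray
    ids: list[str] = field(default_factory=list)
    source_name: str = ""


@dataclass
class JointDecompositionResult:
    """Output of the multi-view joint decomposition.

    ``X`` has one row per entity (entities x D); ``W_list`` holds one
    D x N view-specific matrix per input view.
    """

    X: np.ndarray
    W_list: list[np.ndarray]
    lambda_reg: float
    loss_trace: list[tuple[float, float, float]]
    converged: bool = True
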