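"""Adjacency-matrix constructions and profile-kernel similarities.

Three derived representations of a heterogeneous network feed the
prediction methods:

* the Hadamard-weighted adjacency ``M_MF = M_rd .* (M_rr @ M_rd @ M_dd)``
  used by factorization methods — known associations are re-weighted by how
  well they agree with the similarity structure, unknown pairs stay zero;
* the block adjacency ``M_MC = [[M_rr, M_rd], [M_rd.T, M_dd]]`` used by
  whole-matrix completion;
* the one-sided stacks used by overlap matrix completion (OMC), after a
  k-nearest-neighbour imputation that guarantees every drug and every
  disease enters completion with at least one (possibly pseudo-)
  association.

The module also implements the Gaussian interaction profile (GIP) kernel,
used to derive disease-disease similarity from binary symptom-disease
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netdata import HeterogeneousNetwork

__all__ = [
    "MFAdjacency",
    "BlockAdjacency",
    "SideAdjacency",
    "GipConfig",
    "build_mf_adjacency",
    "build_mc_adjacency",
    "knn_impute_associations",
    "build_omc_adjacency",
    "gip_similarity",
]


@dataclass(frozen=True)
class MFAdjacency:
    """Hadamard-weighted adjacency, normalized to [0, 1].

    ``max_value_used`` is the normalizing constant (0 when the matrix was
    all-zero and no division was performed).
    """

    M_MF: np.ndarray
    max_value_used: float


@dataclass(frozen=True)
class BlockAdjacency:
    """Block adjacency of shape (n+m) x (n+m) with its block index ranges.

    ``block_layout`` maps block names to ``(row_slice, col_slice)``.
    """

    M_MC: np.ndarray
    block_layout: dict


@dataclass(frozen=True)
class SideAdjacency:
    """Drug-side and disease-side stacked matrices for OMC.

    ``drug_side`` is the (n+m) x n stack of ``M_rr`` over ``M_rd1.T``;
    ``disease_side`` is the m x (m+n) concatenation of ``M_dd`` with
    ``M_rd2.T``.  Both expose the unknown drug-disease block to a bounded
    completion, which is read back from rows ``n:`` of the drug side and
    columns ``m:`` of the disease side.
    """

    drug_side: np.ndarray
    disease_side: np.ndarray
    M_rd1: np.ndarray
    M_rd2: np.ndarray


@dataclass(frozen=True)
class GipConfig:
    """Binary profile matrix (profiles x entities) and bandwidth multiplier."""

    profile: np.ndarray
    gamma_prime: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_prime <= 0:
            raise ValueError("gamma_prime must be positive")
        p = np.asarray(self.profile, dtype=float)
        if p.ndim != 2:
            raise ValueError("profile must be a 2-D matrix")
        if not np.all(np.isin(p, (0.0, 1.0))):
            raise ValueError("profile must be binary")
        object.__setattr__(self, "profile", p)


def build_mf_adjacency(network: HeterogeneousNetwork) -> MFAdjacency:
    """Hadamard-weighted adjacency, rescaled by its maximum entry.

    Zero entries of ``M_rd`` stay exactly zero; an all-zero association
    matrix yields an all-zero adjacency with ``max_value_used = 0``.
    """
    raw = network.M_rd * (network.M_rr @ network.M_rd @ network.M_dd)
    max_val = float(raw.max()) if raw.size else 0.0
    if max_val > 0:
        raw = raw / max_val
    return MFAdjacency(M_MF=raw, max_value_used=max_val)


def build_mc_adjacency(network: HeterogeneousNetwork) -> BlockAdjacency:
    """Assemble the (n+m) x (n+m) block adjacency."""
    n, m = network.n_drugs, network.n_diseases
    top = np.hstack([network.M_rr, network.M_rd])
    bottom = np.hstack([network.M_rd.T, network.M_dd])
    layout = {
        "drug_sim": (slice(0, n), slice(0, n)),
        "assoc": (slice(0, n), slice(n, n + m)),
        "assoc_t": (slice(n, n + m), slice(0, n)),
        "disease_sim": (slice(n, n + m), slice(n, n + m)),
    }
    return BlockAdjacency(M_MC=np.vstack([top, bottom]), block_layout=layout)


def knn_impute_associations(
    M_rd: np.ndarray,
    similarity: np.ndarray,
    side: str,
    k: int = 10,
) -> np.ndarray:
    """Fill empty association profiles from the k most similar neighbours.

    For ``side='drug'`` every all-zero *row* of ``M_rd`` is replaced by the
    similarity-weighted average of its k most similar drugs' rows; for
    ``side='disease'`` the same is done for all-zero *columns* using disease
    similarity.  Neighbours whose own profile is all-zero are excluded, and
    the imputed profile is rescaled so its maximum is 1 — pseudo-associations
    never outrank true ones.  Rows/columns that already contain a 1 are
    returned untouched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if side not in ("drug", "disease"):
        raise ValueError("side must be 'drug' or 'disease'")
    M = np.asarray(M_rd, dtype=float)
    profiles = M if side == "drug" else M.T  # entities x profile length
    n_ent = profiles.shape[0]
    if similarity.shape != (n_ent, n_ent):
        raise ValueError(
            f"similarity shape {similarity.shape} does not match "
            f"{n_ent} {side} entities"
        )
    out = profiles.copy()
    nonzero = profiles.sum(axis=1) > 0
    for i in np.flatnonzero(~nonzero):
        candidates = np.flatnonzero(nonzero)
        if candidates.size == 0:
            raise ValueError(
                f"no {side} neighbour with a nonzero profile exists; "
                "input is unusable for imputation"
            )
        sims = similarity[i, candidates]
        order = np.argsort(-sims, kind="stable")[:k]
        nbrs = candidates[order]
        w = similarity[i, nbrs]
        if w.sum() <= 0:
            w = np.ones_like(w)  # degenerate all-zero similarity: plain mean
        imputed = w @ profiles[nbrs] / w.sum()
        peak = imputed.max()
        if peak > 0:
            imputed = imputed / peak
        out[i] = imputed
    return out if side == "drug" else out.T


def build_omc_adjacency(
    network: HeterogeneousNetwork, k: int = 10
) -> SideAdjacency:
    """Build the OMC drug-side and disease-side stacked matrices.

    ``M_rd1`` imputes empty disease columns (disease-similarity KNN) so the
    drug-side network covers every disease; ``M_rd2`` imputes empty drug
    rows so the disease-side network covers every drug.
    """
    m_rd1 = knn_impute_associations(
        network.M_rd, network.M_dd, side="disease", k=k
    )
    m_rd2 = knn_impute_associations(
        network.M_rd, network.M_rr, side="drug", k=k
    )
    drug_side = np.vstack([network.M_rr, m_rd1.T])
    disease_side = np.hstack([network.M_dd, m_rd2.T])
    return SideAdjacency(
        drug_side=drug_side,
        disease_side=disease_side,
        M_rd1=m_rd1,
        M_rd2=m_rd2,
    )


def gip_similarity(config: GipConfig) -> np.ndarray:
    """Gaussian interaction profile kernel between profile columns.

    ``K(i, j) = exp(-gamma * ||p_i - p_j||^2)`` with the bandwidth
    ``gamma = gamma_prime * m / sum_i ||p_i||^2`` normalized by the mean
    squared profile norm over the ``m`` entities (columns).
    """
    p = config.profile
    m = p.shape[1]
    if m < 2:
        raise ValueError("profile must have at least 2 columns")
    norms2 = np.sum(p**2, axis=0)
    total = norms2.sum()
    if total <= 0:
        raise ValueError("all-zero profile matrix: GIP bandwidth undefined")
    gamma = config.gamma_prime * m / total
    d2 = norms2[:, None] + norms2[None, :] - 2.0 * p.T @ p
    np.maximum(d2, 0.0, out=d2)
    k = np.exp(-gamma * d2)
    k = (k + k.T) / 2.0
    np.fill_diagonal(k, 1.0)
    return k
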