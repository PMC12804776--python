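"""Bounded nuclear-norm matrix completion (ADMM) and overlap completion.

The completion model minimizes ``||X||_* + alpha/2 ||P_Omega(X) -
P_Omega(M)||^2`` subject to ``0 <= X <= 1``: a low nuclear norm pulls the
completed matrix toward low rank, the data term keeps it close to the
observed entries, and the box constraint keeps predictions interpretable as
association scores.  The solver is an ADMM splitting ``X = W`` in which the
``W`` step is singular-value soft-thresholding (the proximal operator of
the nuclear norm), the ``X`` step is a closed-form blend of data and
``W`` followed by clipping to [0, 1], and the scaled dual ascends on the
gap; ``beta`` is the ADMM penalty parameter.

Whole-network completion (BNNR) runs the solver on the block adjacency and
reads association scores off the completed drug-disease block.  Overlap
completion (OMC) instead completes the drug-side and disease-side stacked
matrices separately — after KNN imputation has given every drug and disease
at least one association — and averages the two completed blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adjacency import build_mc_adjacency, build_omc_adjacency
from .netdata import HeterogeneousNetwork

__all__ = [
    "BnnrConfig",
    "CompletionResult",
    "singular_value_threshold",
    "bnnr_complete",
    "bnnr_predict",
    "omc_predict",
]


@dataclass(frozen=True)
class BnnrConfig:
    """Completion hyperparameters.

    ``alpha`` weights the data-fit term, ``beta`` is the ADMM penalty.
    ``mask_zeros_unknown`` treats the zeros of the association blocks as
    unobserved rather than as observed negatives.
    """

    alpha: float = 1.0
    beta: float = 10.0
    tol: float = 1e-6
    max_iter: int = 500
    mask_zeros_unknown: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.tol < 0 or self.max_iter < 1:
            raise ValueError("invalid solver settings")


@dataclass(frozen=True)
class CompletionResult:
    """Completed matrix with entries in [0, 1] and the iteration history."""

    X: np.ndarray
    iterations: int
    residual_trace: np.ndarray
    converged: bool


def singular_value_threshold(matrix: np.ndarray, tau: float) -> np.ndarray:
    """Proximal operator of ``tau * ||.||_*``: shrink singular values by tau."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    a = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("input matrix contains non-finite entries")
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (u * s) @ vt


# consecutive iterations of growing residual before declaring divergence
_DIVERGENCE_PATIENCE = 50


def bnnr_complete(
    m: np.ndarray,
    observed_mask: np.ndarray,
    config: BnnrConfig | None = None,
) -> CompletionResult:
    """ADMM solver for bounded nuclear-norm completion.

    ``observed_mask`` marks the entries of ``m`` that the data term fits;
    everything else is reconstructed freely (within [0, 1]).  The solver is
    fully deterministic.
    """
    config = config or BnnrConfig()
    m = np.asarray(m, dtype=float)
    mask = np.asarray(observed_mask, dtype=bool)
    if mask.shape != m.shape:
        raise ValueError("mask shape does not match matrix shape")
    if not mask.any():
        raise ValueError("empty observation mask")
    alpha, beta = config.alpha, config.beta

    x = np.clip(m, 0.0, 1.0)
    w = x.copy()
    y = np.zeros_like(x)  # scaled dual: y = dual / beta

    trace = []
    converged = False
    rising = 0
    it = 0
    for it in range(1, config.max_iter + 1):
        w = singular_value_threshold(x + y, 1.0 / beta)
        z = w - y
        x_new = z.copy()
        x_new[mask] = (alpha * m[mask] + beta * z[mask]) / (alpha + beta)
        np.clip(x_new, 0.0, 1.0, out=x_new)
        rel = float(
            np.linalg.norm(x_new - x)
            / max(np.linalg.norm(x), np.finfo(float).tiny)
        )
        trace.append(rel)
        y = y + (x_new - w)
        x = x_new
        if rel < config.tol:
            converged = True
            break
        if len(trace) >= 2 and trace[-1] > trace[-2]:
            rising += 1
            if rising >= _DIVERGENCE_PATIENCE:
                raise RuntimeError(
                    f"completion diverging: residual grew for {rising} "
                    "consecutive iterations"
                )
        else:
            rising = 0
    return CompletionResult(
        X=x,
        iterations=it,
        residual_trace=np.asarray(trace),
        converged=converged,
    )


def _mc_mask(network: HeterogeneousNetwork, config: BnnrConfig) -> np.ndarray:
    n, m = network.n_drugs, network.n_diseases
    mask = np.ones((n + m, n + m), dtype=bool)
    if config.mask_zeros_unknown:
        assoc_known = network.M_rd > 0
        mask[:n, n:] = assoc_known
        mask[n:, :n] = assoc_known.T
    return mask


def bnnr_predict(
    network: HeterogeneousNetwork, config: BnnrConfig | None = None
):
    """Complete the block adjacency and score pairs by its top-right block.

    By default every entry of the block matrix — similarity blocks and both
    1s and 0s of the association blocks — is treated as observed; the
    bound-constrained low-rank fit denoises the zeros.  Set
    ``mask_zeros_unknown=True`` in the config to treat zeros as missing.
    """
    from .evaluation import PredictionMatrix

    config = config or BnnrConfig()
    block = build_mc_adjacency(network)
    result = bnnr_complete(block.M_MC, _mc_mask(network, config), config)
    p = result.X[block.block_layout["assoc"]]
    return PredictionMatrix(
        P_rd=p,
        provenance={
            "method": "bnnr",
            "alpha": config.alpha,
            "beta": config.beta,
            "iterations": result.iterations,
            "converged": result.converged,
            "mask_zeros_unknown": config.mask_zeros_unknown,
        },
    )


def omc_predict(
    network: HeterogeneousNetwork,
    config: BnnrConfig | None = None,
    knn_k: int = 10,
):
    """Overlap matrix completion: per-side bounded completion, averaged.

    The drug-side stack ``[M_rr; M_rd1.T]`` and disease-side stack
    ``[M_dd, M_rd2.T]`` (built after KNN imputation of empty profiles) are
    completed independently; each side's completed drug-disease block is
    extracted and the two are averaged elementwise.
    """
    from .evaluation import PredictionMatrix

    config = config or BnnrConfig()
    n, m = network.n_drugs, network.n_diseases
    side = build_omc_adjacency(network, k=knn_k)

    mask_drug = np.ones_like(side.drug_side, dtype=bool)
    mask_dis = np.ones_like(side.disease_side, dtype=bool)
    if config.mask_zeros_unknown:
        mask_drug[n:, :] = side.M_rd1.T > 0
        mask_dis[:, m:] = side.M_rd2.T > 0

    res_drug = bnnr_complete(side.drug_side, mask_drug, config)
    res_dis = bnnr_complete(side.disease_side, mask_dis, config)
    p_drug = res_drug.X[n:, :].T  # n x m
    p_dis = res_dis.X[:, m:].T  # n x m
    return PredictionMatrix(
        P_rd=(p_drug + p_dis) / 2.0,
        provenance={
            "method": "omc",
            "alpha": config.alpha,
            "beta": config.beta,
            "knn_k": knn_k,
            "iterations": (res_drug.iterations, res_dis.iterations),
            "mask_zeros_unknown": config.mask_zeros_unknown,
        },
    )
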