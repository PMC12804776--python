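"""Non-negative matrix factorization and its permutation-based extension.

Plain NMF factorizes the Hadamard-weighted adjacency ``V = M_MF`` into
nonnegative ``W @ H`` (Lee-Seung multiplicative updates, squared Frobenius
objective) and uses the reconstruction as association scores.  The rank is
either given or selected as the smallest ``k`` whose cumulative explained
variance of squared singular values reaches a threshold (0.90 by default).

The permutation extension (NMF-PDR) asks, per drug-disease pair, whether the
NMF score obtained from the observed association structure is significantly
larger than scores obtained from randomized structure.  It builds

* an observed ensemble ``O1`` — NMF reconstructions of K copies of ``M_MF``
  whose positive-position values are shuffled among themselves (association
  *pattern* preserved, similarity weighting randomized), and
* three null ensembles ``R0`` / ``C0`` / ``B0`` — NMF reconstructions after
  permuting whole rows, whole columns, or both (association pattern
  destroyed),

then compares ``O1`` against each null with a one-sided Wilcoxon rank-sum
test per pair and combines the three z-scores with a Stouffer-type sum.  The
three statistics share the observed ensemble, so they are positively
correlated under the null; the combination is divided by the exact null
standard deviation of the sum (``sqrt(3 + 6K/(2K+1))``, about ``sqrt(6)``)
rather than ``sqrt(3)``, which keeps the combined score standard normal when
no signal is present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .adjacency import build_mf_adjacency
from .netdata import HeterogeneousNetwork

__all__ = [
    "NMFConfig",
    "RankSelectionReport",
    "PermutationEnsemble",
    "PdrResult",
    "select_rank_cev",
    "nmf_factorize",
    "nmf_predict",
    "permute_observed",
    "permute_null",
    "ranksum_z",
    "stouffer_divisor",
    "nmfpdr_predict",
]


@dataclass(frozen=True)
class NMFConfig:
    """Settings for the multiplicative-update NMF solver.

    ``rank`` may be a positive integer or ``"auto"`` (CEV-based selection
    on the input matrix).  ``epsilon`` stabilizes the update denominators.
    """

    rank: int | str = "auto"
    max_iter: int = 2000
    tol: float = 1e-6
    epsilon: float = 1e-12
    cev_threshold: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.rank, str):
            if self.rank != "auto":
                raise ValueError("rank must be a positive integer or 'auto'")
        elif self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.max_iter < 1 or self.tol < 0 or self.epsilon <= 0:
            raise ValueError("invalid solver settings")


@dataclass(frozen=True)
class RankSelectionReport:
    """Singular spectrum, CEV curve and the selected rank."""

    singular_values: np.ndarray
    cev_curve: np.ndarray
    threshold: float
    selected_rank: int


@dataclass(frozen=True)
class PermutationEnsemble:
    """Per-pair score collections from the permutation runs.

    Each array has shape (n, m, K): K predicted values per drug-disease
    pair.
    """

    K: int
    observed: np.ndarray
    null_rows: np.ndarray
    null_columns: np.ndarray
    null_both: np.ndarray
    seed: int


@dataclass(frozen=True)
class PdrResult:
    """Rank-test z-scores against each null and the combined score."""

    z_rows: np.ndarray
    z_columns: np.ndarray
    z_both: np.ndarray
    combined_Z: np.ndarray
    rank_used: int
    ensemble: PermutationEnsemble | None = None


def select_rank_cev(
    matrix: np.ndarray, threshold: float = 0.90
) -> RankSelectionReport:
    """Pick the smallest rank whose cumulative explained variance of
    squared singular values reaches ``threshold``.
    """
    a = np.asarray(matrix, dtype=float)
    if not np.any(a):
        raise ValueError("cannot select a rank for an all-zero matrix")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    s = np.linalg.svd(a, compute_uv=False)
    power = s**2
    cev = np.cumsum(power) / power.sum()
    selected = int(np.searchsorted(cev, threshold - 1e-12) + 1)
    selected = max(1, min(selected, len(s)))
    return RankSelectionReport(
        singular_values=s,
        cev_curve=cev,
        threshold=threshold,
        selected_rank=selected,
    )


def _resolve_rank(v: np.ndarray, config: NMFConfig) -> int:
    if config.rank == "auto":
        return select_rank_cev(v, config.cev_threshold).selected_rank
    r = int(config.rank)
    if r > min(v.shape):
        raise ValueError(
            f"rank {r} exceeds min(matrix shape) = {min(v.shape)}"
        )
    return r


def nmf_factorize(
    v: np.ndarray, config: NMFConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lee-Seung multiplicative-update NMF of a nonnegative matrix.

    Returns ``(W, H, objective_trace)`` where the trace records the squared
    Frobenius reconstruction error after each full (H then W) update.
    Factors are initialized uniform (0, 1] scaled by ``sqrt(mean(V)/r)`` so
    the initial reconstruction matches the input's mean; a fixed seed makes
    the run reproducible.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("input matrix contains non-finite entries")
    if np.any(v < 0):
        raise ValueError("input matrix must be nonnegative")
    if not np.any(v):
        raise ValueError("cannot factorize an all-zero matrix")
    r = _resolve_rank(v, config)
    n, m = v.shape
    rng = np.random.default_rng(config.seed)
    scale = np.sqrt(v.mean() / r)
    w = scale * (1.0 - rng.random((n, r)))
    h = scale * (1.0 - rng.random((r, m)))
    eps = config.epsilon

    trace = []
    prev = None
    for _ in range(config.max_iter):
        h *= (w.T @ v) / (w.T @ w @ h + eps)
        w *= (v @ h.T) / (w @ h @ h.T + eps)
        obj = float(np.linalg.norm(v - w @ h) ** 2)
        trace.append(obj)
        if prev is not None:
            if abs(prev - obj) <= config.tol * max(prev, np.finfo(float).tiny):
                break
        prev = obj
    return w, h, np.asarray(trace)


def nmf_predict(network: HeterogeneousNetwork, config: NMFConfig | None = None):
    """Score all drug-disease pairs by NMF reconstruction of ``M_MF``."""
    from .evaluation import PredictionMatrix

    config = config or NMFConfig()
    adj = build_mf_adjacency(network)
    w, h, _ = nmf_factorize(adj.M_MF, config)
    return PredictionMatrix(
        P_rd=w @ h,
        provenance={
            "method": "nmf",
            "rank": int(w.shape[1]),
            "max_iter": config.max_iter,
            "tol": config.tol,
            "seed": config.seed,
        },
    )


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------


def permute_observed(
    m_mf: np.ndarray, positive_mask: np.ndarray, seed
) -> np.ndarray:
    """Shuffle the adjacency values sitting at positive positions.

    The multiset of values at positions where ``positive_mask`` is true is
    randomly permuted among those same positions; zeros elsewhere are
    untouched, so the association *pattern* is preserved while the
    similarity weighting is randomized.
    """
    rng = np.random.default_rng(seed)
    mask = np.asarray(positive_mask, dtype=bool)
    out = np.array(m_mf, dtype=float, copy=True)
    idx = np.flatnonzero(mask.ravel())
    if idx.size < 2:
        warnings.warn(
            "fewer than 2 positive positions: observed permutation is "
            "vacuous, matrix returned unchanged",
            stacklevel=2,
        )
        return out
    flat = out.ravel()
    flat[idx] = flat[idx][rng.permutation(idx.size)]
    return out


def permute_null(m_mf: np.ndarray, mode: str, seed) -> np.ndarray:
    """Permute whole rows, whole columns, or both, of the adjacency."""
    rng = np.random.default_rng(seed)
    out = np.array(m_mf, dtype=float, copy=True)
    if mode not in ("rows", "columns", "both"):
        raise ValueError("mode must be 'rows', 'columns' or 'both'")
    if mode in ("rows", "both"):
        out = out[rng.permutation(out.shape[0]), :]
    if mode in ("columns", "both"):
        out = out[:, rng.permutation(out.shape[1])]
    return out


def ranksum_z(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Vectorized one-sided Wilcoxon rank-sum z-scores along the last axis.

    Tests ``observed > null`` per leading index with the normal
    approximation, average ranks for ties, the standard tie-corrected
    variance and a 0.5 continuity correction.  Degenerate comparisons with
    zero variance (all values tied) yield z = 0.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    k1 = observed.shape[-1]
    k2 = null.shape[-1]
    n = k1 + k2
    combined = np.concatenate([observed, null], axis=-1)
    ranks = scipy.stats.rankdata(combined, axis=-1)
    u1 = ranks[..., :k1].sum(axis=-1) - k1 * (k1 + 1) / 2.0
    mu = k1 * k2 / 2.0
    # tie correction: sum over tie groups of (t^3 - t) equals
    # sum over elements of t_e^2 minus n, with t_e the element's group size
    rmax = scipy.stats.rankdata(combined, axis=-1, method="max")
    rmin = scipy.stats.rankdata(combined, axis=-1, method="min")
    t_e = rmax - rmin + 1
    tie_term = (t_e**2).sum(axis=-1) - n
    var = k1 * k2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - mu - 0.5) / np.sqrt(var)
    return np.where(var > 0, z, 0.0)


def stouffer_divisor(k: int) -> float:
    """Null standard deviation of the sum of the three rank-sum z-scores.

    The three tests share the observed ensemble of size ``k``; each pair of
    z-scores has null correlation ``k / (2k + 1)``, so the sum has variance
    ``3 + 6k/(2k+1)``.
    """
    rho = k / (2.0 * k + 1.0)
    return float(np.sqrt(3.0 + 6.0 * rho))


def nmfpdr_predict(
    network: HeterogeneousNetwork,
    K: int = 100,
    nmf_config: NMFConfig | None = None,
    seed: int = 0,
    keep_ensemble: bool = False,
) -> PdrResult:
    """Permutation-based NMF scoring of all drug-disease pairs.

    Runs NMF on K observed-permuted adjacencies and K adjacencies for each
    null mode (rows / columns / both), compares the per-pair score
    collections with one-sided rank-sum tests and returns the combined
    z-score matrix.  The NMF rank is selected once, on the unpermuted
    adjacency, and reused across all 4K runs for comparability.
    Deterministic for a fixed ``seed``.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    nmf_config = nmf_config or NMFConfig()
    adj = build_mf_adjacency(network)
    m_mf = adj.M_MF
    rank = _resolve_rank(m_mf, nmf_config)
    fixed = NMFConfig(
        rank=rank,
        max_iter=nmf_config.max_iter,
        tol=nmf_config.tol,
        epsilon=nmf_config.epsilon,
        seed=nmf_config.seed,
    )
    pos_mask = network.M_rd > 0

    n, m = m_mf.shape
    modes = ("observed", "rows", "columns", "both")
    stores = {mode: np.empty((n, m, K)) for mode in modes}
    children = np.random.SeedSequence(seed).spawn(4 * K)
    ci = 0
    for mode in modes:
        for t in range(K):
            perm_seed, init_seed = children[ci].spawn(2)
            ci += 1
            if mode == "observed":
                vmat = permute_observed(m_mf, pos_mask, perm_seed)
            else:
                vmat = permute_null(m_mf, mode, perm_seed)
            cfg = NMFConfig(
                rank=rank,
                max_iter=fixed.max_iter,
                tol=fixed.tol,
                epsilon=fixed.epsilon,
                seed=init_seed,
            )
            w, h, _ = nmf_factorize(vmat, cfg)
            stores[mode][:, :, t] = w @ h

    z_rows = ranksum_z(stores["observed"], stores["rows"])
    z_columns = ranksum_z(stores["observed"], stores["columns"])
    z_both = ranksum_z(stores["observed"], stores["both"])
    combined = (z_rows + z_columns + z_both) / stouffer_divisor(K)

    ensemble = None
    if keep_ensemble:
        ensemble = PermutationEnsemble(
            K=K,
            observed=stores["observed"],
            null_rows=stores["rows"],
            null_columns=stores["columns"],
            null_both=stores["both"],
            seed=seed,
        )
    return PdrResult(
        z_rows=z_rows,
        z_columns=z_columns,
        z_both=z_both,
        combined_Z=combined,
        rank_used=rank,
        ensemble=ensemble,
    )
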