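"""Data model and I/O for heterogeneous drug-disease networks.

A heterogeneous drug-disease network couples three matrices over a set of
``n`` drugs and ``m`` diseases:

* ``M_rr`` — drug-drug similarity (n x n, symmetric, unit diagonal),
* ``M_dd`` — disease-disease similarity (m x m, symmetric, unit diagonal),
* ``M_rd`` — binary drug-disease association matrix (n x m), where 1 marks a
  known therapeutic association and 0 an unknown / absent one.

Drugs always index rows and diseases index columns of ``M_rd``; every other
module inherits that orientation.

The module also ships a synthetic-network generator with planted latent
cluster structure.  Entities in the same cluster are close in a latent space,
which makes similar drugs target related diseases — the working assumption of
every downstream prediction method — so recovery of planted, held-out
associations is a meaningful end-to-end check.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "HeterogeneousNetwork",
    "DatasetSummary",
    "SyntheticSpec",
    "load_network",
    "write_network",
    "summarize",
    "generate_synthetic",
]

#: maximum tolerated asymmetry / diagonal deviation for similarity matrices
SYMMETRY_TOL = 1e-8

# file names used by write_network / load_network_dir
_DRUG_SIM = "drug_similarity"
_DISEASE_SIM = "disease_similarity"
_ASSOC = "association"


def _as_float_matrix(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={a.ndim}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    return a


def _check_similarity(s: np.ndarray, name: str) -> np.ndarray:
    """Validate a similarity matrix and return its symmetrized copy.

    Mild numerical asymmetry (below ``SYMMETRY_TOL``) is repaired by
    averaging with the transpose; anything larger is rejected.
    """
    if s.shape[0] != s.shape[1]:
        raise ValueError(f"{name} must be square, got shape {s.shape}")
    dev = float(np.max(np.abs(s - s.T))) if s.size else 0.0
    if dev > SYMMETRY_TOL:
        raise ValueError(
            f"{name} is asymmetric beyond tolerance (max deviation {dev:.3e})"
        )
    s = (s + s.T) / 2.0
    if s.size:
        diag_dev = float(np.max(np.abs(np.diag(s) - 1.0)))
        if diag_dev > SYMMETRY_TOL:
            raise ValueError(
                f"{name} diagonal deviates from 1 by {diag_dev:.3e}"
            )
    return s


def _check_association(a: np.ndarray) -> np.ndarray:
    bad = ~np.isin(a, (0.0, 1.0))
    if np.any(bad):
        vals = np.unique(a[bad])[:5]
        raise ValueError(f"non-binary association entries found: {vals}")
    return a


@dataclass
class HeterogeneousNetwork:
    """The triple (M_rr, M_dd, M_rd) plus aligned identifier lists."""

    drug_ids: list[str]
    disease_ids: list[str]
    M_rr: np.ndarray
    M_dd: np.ndarray
    M_rd: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = [str(x) for x in self.drug_ids]
        self.disease_ids = [str(x) for x in self.disease_ids]
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        self.M_rr = _check_similarity(
            _as_float_matrix(self.M_rr, "M_rr"), "M_rr"
        )
        self.M_dd = _check_similarity(
            _as_float_matrix(self.M_dd, "M_dd"), "M_dd"
        )
        self.M_rd = _check_association(_as_float_matrix(self.M_rd, "M_rd"))
        n, m = len(self.drug_ids), len(self.disease_ids)
        if self.M_rr.shape != (n, n):
            raise ValueError(
                f"M_rr shape {self.M_rr.shape} does not match {n} drugs"
            )
        if self.M_dd.shape != (m, m):
            raise ValueError(
                f"M_dd shape {self.M_dd.shape} does not match {m} diseases"
            )
        if self.M_rd.shape != (n, m):
            raise ValueError(
                f"M_rd shape {self.M_rd.shape} does not match ({n}, {m})"
            )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def copy(self) -> "HeterogeneousNetwork":
        return HeterogeneousNetwork(
            drug_ids=list(self.drug_ids),
            disease_ids=list(self.disease_ids),
            M_rr=self.M_rr.copy(),
            M_dd=self.M_dd.copy(),
            M_rd=self.M_rd.copy(),
        )


@dataclass(frozen=True)
class DatasetSummary:
    """Counts and sparsity of a drug-disease association matrix.

    ``sparsity`` is the proportion of unknown (zero) associations,
    ``1 - n_associations / size``.
    """

    n_drugs: int
    n_diseases: int
    n_associations: int
    size: int
    n_non_associations: int
    sparsity: float

    @classmethod
    def from_counts(
        cls, n_drugs: int, n_diseases: int, n_associations: int
    ) -> "DatasetSummary":
        size = n_drugs * n_diseases
        if not 0 <= n_associations <= size:
            raise ValueError("association count out of range")
        return cls(
            n_drugs=n_drugs,
            n_diseases=n_diseases,
            n_associations=n_associations,
            size=size,
            n_non_associations=size - n_associations,
            sparsity=1.0 - n_associations / size if size else 0.0,
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize(network: HeterogeneousNetwork) -> DatasetSummary:
    """Summarize a network's association matrix (counts and sparsity)."""
    return DatasetSummary.from_counts(
        network.n_drugs,
        network.n_diseases,
        int(round(float(network.M_rd.sum()))),
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SEPS = {"tsv": "\t", "csv": ","}


def _read_matrix(source, fmt: str) -> pd.DataFrame:
    sep = _SEPS.get(fmt)
    if sep is None:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'csv'")
    df = pd.read_csv(source, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _read_id_list(source) -> list[str]:
    with open(source) as fh:
        return [line.strip() for line in fh if line.strip()]


def load_network(
    drug_sim_source,
    disease_sim_source,
    assoc_source,
    fmt: str = "tsv",
    *,
    assoc_fmt: str | None = None,
    drug_ids_source=None,
    disease_ids_source=None,
) -> HeterogeneousNetwork:
    """Load and validate a heterogeneous network from delimited-text files.

    Parameters
    ----------
    drug_sim_source, disease_sim_source
        Delimited text matrices with a header row and identifiers in the
        first column.
    assoc_source
        The binary association matrix in the same dialect, or a MatrixMarket
        coordinate file when ``assoc_fmt='mtx'`` (then ``drug_ids_source``
        and ``disease_ids_source``, one identifier per line, are required).
    fmt
        ``'tsv'`` (default) or ``'csv'``.

    The identifier order of the association matrix is canonical; the
    similarity matrices are permuted to match it.
    """
    assoc_fmt = assoc_fmt or fmt
    if assoc_fmt == "mtx":
        if drug_ids_source is None or disease_ids_source is None:
            raise ValueError(
                "MTX association input requires drug_ids_source and "
                "disease_ids_source"
            )
        drug_ids = _read_id_list(drug_ids_source)
        disease_ids = _read_id_list(disease_ids_source)
        raw = scipy.io.mmread(assoc_source)
        if scipy.sparse.issparse(raw):
            raw = raw.toarray()
        m_rd = np.asarray(raw, dtype=float)
        if m_rd.shape != (len(drug_ids), len(disease_ids)):
            raise ValueError(
                f"MTX shape {m_rd.shape} does not match identifier lists "
                f"({len(drug_ids)}, {len(disease_ids)})"
            )
    else:
        assoc = _read_matrix(assoc_source, assoc_fmt)
        drug_ids = list(assoc.index)
        disease_ids = list(assoc.columns)
        m_rd = assoc.to_numpy(dtype=float)

    dsim = _read_matrix(drug_sim_source, fmt)
    if set(dsim.index) != set(drug_ids) or set(dsim.columns) != set(drug_ids):
        raise ValueError(
            "drug identifier sets of similarity and association matrices "
            "differ"
        )
    m_rr = dsim.loc[drug_ids, drug_ids].to_numpy(dtype=float)

    ssim = _read_matrix(disease_sim_source, fmt)
    if set(ssim.index) != set(disease_ids) or set(ssim.columns) != set(
        disease_ids
    ):
        raise ValueError(
            "disease identifier sets of similarity and association matrices "
            "differ"
        )
    m_dd = ssim.loc[disease_ids, disease_ids].to_numpy(dtype=float)

    return HeterogeneousNetwork(
        drug_ids=drug_ids,
        disease_ids=disease_ids,
        M_rr=m_rr,
        M_dd=m_dd,
        M_rd=m_rd,
    )


def load_network_dir(directory, fmt: str = "tsv") -> HeterogeneousNetwork:
    """Load a network from a directory written by :func:`write_network`."""
    d = Path(directory)
    if fmt == "mtx":
        return load_network(
            d / f"{_DRUG_SIM}.tsv",
            d / f"{_DISEASE_SIM}.tsv",
            d / f"{_ASSOC}.mtx",
            fmt="tsv",
            assoc_fmt="mtx",
            drug_ids_source=d / "drug_ids.txt",
            disease_ids_source=d / "disease_ids.txt",
        )
    ext = fmt
    return load_network(
        d / f"{_DRUG_SIM}.{ext}",
        d / f"{_DISEASE_SIM}.{ext}",
        d / f"{_ASSOC}.{ext}",
        fmt=fmt,
    )


def write_network(
    network: HeterogeneousNetwork, directory, fmt: str = "tsv"
) -> list[Path]:
    """Write a network to ``directory`` as delimited text.

    ``fmt='tsv'`` / ``'csv'`` writes three matrices with header row and
    identifier column; ``fmt='mtx'`` writes the association matrix as a
    MatrixMarket coordinate file plus two identifier lists while the
    similarity matrices stay TSV.  Association entries are emitted as exact
    ``0`` / ``1`` tokens.
    """
    if network.n_drugs == 0 or network.n_diseases == 0:
        raise ValueError("refusing to write an empty network")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    sim_fmt = "tsv" if fmt == "mtx" else fmt
    sep = _SEPS[sim_fmt]
    for name, mat, ids in (
        (_DRUG_SIM, network.M_rr, network.drug_ids),
        (_DISEASE_SIM, network.M_dd, network.disease_ids),
    ):
        path = d / f"{name}.{sim_fmt}"
        pd.DataFrame(mat, index=ids, columns=ids).to_csv(
            path, sep=sep, float_format="%.17g"
        )
        written.append(path)

    if fmt == "mtx":
        path = d / f"{_ASSOC}.mtx"
        scipy.io.mmwrite(
            path, scipy.sparse.coo_matrix(network.M_rd.astype(int))
        )
        written.append(path)
        for name, ids in (
            ("drug_ids.txt", network.drug_ids),
            ("disease_ids.txt", network.disease_ids),
        ):
            p = d / name
            p.write_text("\n".join(ids) + "\n")
            written.append(p)
    else:
        path = d / f"{_ASSOC}.{fmt}"
        pd.DataFrame(
            network.M_rd.astype(int),
            index=network.drug_ids,
            columns=network.disease_ids,
        ).to_csv(path, sep=_SEPS[fmt])
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# synthetic networks with planted cluster structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-cluster synthetic network generator.

    Drugs and diseases are assigned to ``n_clusters`` shared clusters.  Each
    entity receives a latent vector equal to its cluster centroid (centroids
    drawn at separation scale ``signal``) plus isotropic Gaussian noise of
    standard deviation ``noise_sd``.  Similarities are Gaussian kernels of
    latent distance; associations preferentially connect drugs and diseases
    of matching clusters at an overall density of ``1 - target_sparsity``.
    """

    n_drugs: int = 60
    n_diseases: int = 40
    n_clusters: int = 4
    latent_dim: int = 8
    signal: float = 4.0
    noise_sd: float = 0.5
    target_sparsity: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > min(self.n_drugs, self.n_diseases):
            raise ValueError("n_clusters exceeds min(n_drugs, n_diseases)")
        if not 0.0 < self.target_sparsity < 1.0:
            raise ValueError("target_sparsity must lie strictly in (0, 1)")
        if self.signal < 0 or self.noise_sd < 0:
            raise ValueError("signal and noise_sd must be nonnegative")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")


# scale of the logistic perturbation applied to pair affinities before
# thresholding; small relative to affinities in [0, 1] so the planted
# cluster signal dominates but is not noiseless
_ASSOC_NOISE_SCALE = 0.05


def _kernel_similarity(x: np.ndarray, latent_dim: int) -> np.ndarray:
    d2 = (
        np.sum(x**2, axis=1)[:, None]
        + np.sum(x**2, axis=1)[None, :]
        - 2.0 * x @ x.T
    )
    np.maximum(d2, 0.0, out=d2)
    s = np.exp(-d2 / latent_dim)
    np.fill_diagonal(s, 1.0)
    return (s + s.T) / 2.0


def generate_synthetic(spec: SyntheticSpec) -> HeterogeneousNetwork:
    """Generate a heterogeneous network with planted low-rank structure.

    Deterministic for a fixed ``spec.seed``.  The number of planted
    associations is ``round(size * (1 - target_sparsity))``, so the realized
    sparsity matches ``target_sparsity`` up to rounding (well within 0.01
    for the supported sizes).
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.n_drugs * spec.n_diseases
    n_pos = int(round(size * (1.0 - spec.target_sparsity)))
    if n_pos < 1:
        raise ValueError(
            f"target_sparsity {spec.target_sparsity} leaves no associations "
            f"for a {spec.n_drugs}x{spec.n_diseases} network"
        )

    centroids = (
        spec.signal
        * rng.standard_normal((spec.n_clusters, spec.latent_dim))
        / np.sqrt(spec.latent_dim)
    )
    drug_clusters = np.arange(spec.n_drugs) % spec.n_clusters
    disease_clusters = np.arange(spec.n_diseases) % spec.n_clusters
    x_drug = centroids[drug_clusters] + spec.noise_sd * rng.standard_normal(
        (spec.n_drugs, spec.latent_dim)
    )
    x_dis = centroids[disease_clusters] + spec.noise_sd * rng.standard_normal(
        (spec.n_diseases, spec.latent_dim)
    )

    m_rr = _kernel_similarity(x_drug, spec.latent_dim)
    m_dd = _kernel_similarity(x_dis, spec.latent_dim)

    # cross affinity in (0, 1]: high for matched clusters, low otherwise
    d2 = (
        np.sum(x_drug**2, axis=1)[:, None]
        + np.sum(x_dis**2, axis=1)[None, :]
        - 2.0 * x_drug @ x_dis.T
    )
    np.maximum(d2, 0.0, out=d2)
    affinity = np.exp(-d2 / spec.latent_dim)

    # logistic-noise utility model: associate the n_pos pairs of highest
    # perturbed affinity, i.e. a logistic association model conditioned on
    # the total number of associations
    utility = affinity + rng.logistic(
        loc=0.0, scale=_ASSOC_NOISE_SCALE, size=affinity.shape
    )
    flat = utility.ravel()
    cutoff = np.partition(flat, size - n_pos)[size - n_pos]
    m_rd = (utility >= cutoff).astype(float)
    # ties at the cutoff are broken by keeping the first occurrences
    excess = int(m_rd.sum()) - n_pos
    if excess > 0:
        tied = np.flatnonzero((utility == cutoff).ravel())
        m_rd.ravel()[tied[:excess]] = 0.0

    return HeterogeneousNetwork(
        drug_ids=[f"drug{i:03d}" for i in range(spec.n_drugs)],
        disease_ids=[f"disease{j:03d}" for j in range(spec.n_diseases)],
        M_rr=m_rr,
        M_dd=m_dd,
        M_rd=m_rd,
    )
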