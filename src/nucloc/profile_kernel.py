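"""The profile string kernel: counting k-mers conserved in an evolutionary profile.

A profile assigns each position a non-negative cost per amino acid (low =
conserved). A k-mer ``a1..ak`` is *conserved* at position ``p`` when the sum
of its per-position costs falls strictly below the threshold ``sigma``. The
feature map sends a profile to the 20^k-dimensional integer vector counting,
for every k-mer, the number of positions at which it is conserved; the kernel
is the (optionally normalized) dot product of two such vectors.

Because costs are non-negative, the conserved set at one position can be
enumerated by a depth-first search that abandons any prefix whose partial
cost already reaches sigma; the result is identical to exhaustive
enumeration over all 20^k strings.

k-mers are indexed base-20 with digit order ``ARNDCQEGHILKMFPSTWYV``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_formats import Profile
from .vocabulary import AA_INDEX, AMINO_ACIDS

__all__ = [
    "KernelParams",
    "FeatureVector",
    "kmer_index",
    "index_to_kmer",
    "conserved_kmers_at",
    "feature_map",
    "kernel",
    "kernel_matrix",
    "cross_kernel_matrix",
    "feature_matrix",
    "write_feature_vector_tsv",
    "write_kernel_matrix_tsv",
]


@dataclass(frozen=True)
class KernelParams:
    """k-mer length, conservation threshold sigma, and normalization flag."""

    k: int = 4
    sigma: float = 6.0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class FeatureVector:
    """Sparse 20^k-dimensional count vector of conserved k-mers."""

    counts: dict[int, int] = field(default_factory=dict)
    k: int = 4

    @property
    def dim(self) -> int:
        return len(AMINO_ACIDS) ** self.k

    def self_kernel(self) -> float:
        return float(sum(c * c for c in self.counts.values()))


def kmer_index(kmer: str) -> int:
    """Base-20 index of an amino-acid k-mer string."""
    idx = 0
    for aa in kmer:
        idx = idx * 20 + AA_INDEX[aa]
    return idx


def index_to_kmer(index: int, k: int) -> str:
    out = []
    for _ in range(k):
        index, digit = divmod(index, 20)
        out.append(AMINO_ACIDS[digit])
    return "".join(reversed(out))


def conserved_kmers_at(profile: Profile, pos: int, params: KernelParams) -> set[int]:
    """All k-mer indices with summed cost < sigma in the window at ``pos`` (0-based).

    Depth-first enumeration over residues in increasing cost order per
    position; a branch is pruned as soon as its partial sum reaches sigma,
    which is exact because costs are non-negative.
    """
    k, sigma = params.k, params.sigma
    if pos < 0 or pos > profile.length - k:
        raise IndexError(
            f"position {pos} out of range for profile {profile.id!r} "
            f"(length {profile.length}, k={k})"
        )
    window = profile.scores[pos : pos + k]
    order = np.argsort(window, axis=1, kind="stable")
    sorted_costs = np.take_along_axis(window, order, axis=1)
    result: set[int] = set()

    def descend(depth: int, prefix: int, cost: float) -> None:
        if depth == k:
            result.add(prefix)
            return
        row_order = order[depth]
        row_costs = sorted_costs[depth]
        for j in range(20):
            total = cost + row_costs[j]
            if total >= sigma:
                break
            descend(depth + 1, prefix * 20 + int(row_order[j]), total)

    descend(0, 0, 0.0)
    return result


def feature_map(profile: Profile, params: KernelParams) -> FeatureVector:
    """Count, over all windows, how often each k-mer is conserved."""
    counts: dict[int, int] = {}
    if profile.length < params.k:
        warnings.warn(
            f"profile {profile.id!r} shorter than k={params.k}; empty feature vector"
        )
        return FeatureVector({}, params.k)
    for pos in range(profile.length - params.k + 1):
        for m in conserved_kmers_at(profile, pos, params):
            counts[m] = counts.get(m, 0) + 1
    return FeatureVector(counts, params.k)


def kernel(u: FeatureVector, v: FeatureVector, normalize: bool = True) -> float:
    """Sparse dot product, optionally cosine-normalized (0 if a self-kernel is 0)."""
    if u.k != v.k:
        raise ValueError(f"mismatched k: {u.k} != {v.k}")
    small, large = (u.counts, v.counts) if len(u.counts) <= len(v.counts) else (v.counts, u.counts)
    dot = float(sum(c * large.get(m, 0) for m, c in small.items()))
    if not normalize:
        return dot
    uu, vv = u.self_kernel(), v.self_kernel()
    if uu == 0.0 or vv == 0.0:
        return 0.0
    return dot / np.sqrt(uu * vv)


def feature_matrix(vectors: list[FeatureVector]) -> sp.csr_matrix:
    """Stack feature vectors into a sparse (n x 20^k) count matrix."""
    if not vectors:
        raise ValueError("empty feature-vector list")
    k = vectors[0].k
    dim = vectors[0].dim
    data, indices, indptr = [], [], [0]
    for fv in vectors:
        if fv.k != k:
            raise ValueError("mixed k in feature-vector list")
        keys = sorted(fv.counts)
        indices.extend(keys)
        data.extend(fv.counts[m] for m in keys)
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.array(data, dtype=float), np.array(indices, dtype=np.int64), np.array(indptr)),
        shape=(len(vectors), dim),
    )


def _gram(vectors: list[FeatureVector], normalize: bool) -> np.ndarray:
    X = feature_matrix(vectors)
    K = np.asarray((X @ X.T).todense(), dtype=float)
    if normalize:
        d = np.sqrt(np.diag(K))
        with np.errstate(divide="ignore", invalid="ignore"):
            K = np.where(np.outer(d, d) > 0, K / np.outer(d, d), 0.0)
    return K


def kernel_matrix(
    profiles: list[Profile],
    params: KernelParams,
    vectors: list[FeatureVector] | None = None,
) -> np.ndarray:
    """Symmetric Gram matrix over profiles (unit diagonal when normalized).

    Feature vectors are computed once and the Gram matrix is formed by a
    single sparse product; pass precomputed ``vectors`` to reuse a cache.
    """
    if not profiles and not vectors:
        raise ValueError("empty profile list")
    if vectors is None:
        vectors = [feature_map(p, params) for p in profiles]
    return _gram(vectors, params.normalize)


def cross_kernel_matrix(
    rows: list[FeatureVector], cols: list[FeatureVector], normalize: bool = True
) -> np.ndarray:
    """Rectangular kernel matrix K[i, j] = kernel(rows[i], cols[j])."""
    Xr, Xc = feature_matrix(rows), feature_matrix(cols)
    K = np.asarray((Xr @ Xc.T).todense(), dtype=float)
    if normalize:
        dr = np.sqrt(np.array([fv.self_kernel() for fv in rows]))
        dc = np.sqrt(np.array([fv.self_kernel() for fv in cols]))
        with np.errstate(divide="ignore", invalid="ignore"):
            K = np.where(np.outer(dr, dc) > 0, K / np.outer(dr, dc), 0.0)
    return K


def write_feature_vector_tsv(fv: FeatureVector, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#kmer\tcount\n")
        for m in sorted(fv.counts):
            fh.write(f"{index_to_kmer(m, fv.k)}\t{fv.counts[m]}\n")


def write_kernel_matrix_tsv(K: np.ndarray, ids: list[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#id\t" + "\t".join(ids) + "\n")
        for i, pid in enumerate(ids):
            fh.write(pid + "\t" + "\t".join(f"{x:.12g}" for x in K[i]) + "\n")
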