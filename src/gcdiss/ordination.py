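"""Ordination and group-separation statistics on distance matrices.

Principal coordinates analysis (PCoA) embeds a distance matrix into
Euclidean coordinates by eigendecomposition of the Gower-centred matrix
B = -1/2 * J D^2 J, J = I - 11'/n. Negative eigenvalues (non-Euclidean
input) are reported but excluded from the coordinates; no Cailliez or
Lingoes correction is applied.

The multi-response permutation procedure (MRPP) tests whether an a-priori
grouping of the strains is tighter than chance: the observed statistic is
the group-size-weighted mean within-group distance

    delta = sum_g (n_g / N) * mean{ d(x, y) : x, y in group g, x != y }

and the p-value is the add-one permutation estimate
p = (1 + #{delta_perm <= delta_obs}) / (1 + n_perm), with labels shuffled
by a seeded generator. The chance-corrected effect size is
A = 1 - delta_obs / E[delta], with E[delta] the mean permuted delta;
A > 0 means within-group distances are smaller than expected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.linalg

from .dissimilarity import DistanceMatrix

_EIG_TOL_FACTOR = 1e-12


@dataclass
class PCoAResult:
    """Coordinates and spectrum of a principal coordinates embedding."""

    labels: list[str]
    coordinates: np.ndarray  # (n_strains, n_axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per retained axis, over positive mass
    negative_eigenvalue_mass: float  # sum |negative| / sum |all|


@dataclass
class MRPPResult:
    delta_observed: float
    delta_expected: float
    effect_size_A: float
    p_value: float
    n_permutations: int
    seed: int
    group_sizes: dict[str, int]


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Principal coordinates analysis of a dissimilarity matrix.

    Parameters
    ----------
    dm
        A dissimilarity-kind :class:`DistanceMatrix` (symmetry is enforced
        by its constructor).
    n_axes
        Number of axes to keep; defaults to every axis with a positive
        eigenvalue. Coordinates are eigenvectors scaled by sqrt(lambda),
        ordered by descending eigenvalue.
    """
    if dm.kind != "dissimilarity":
        raise ValueError("PCoA requires a dissimilarity-kind matrix")
    d = dm.values
    n = d.shape[0]
    b = -0.5 * (d * d)
    row_means = b.mean(axis=1, keepdims=True)
    b = b - row_means - row_means.T + b.mean()
    eigval, eigvec = scipy.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    total_abs = np.abs(eigval).sum()
    neg_mass = float(np.abs(eigval[eigval < 0]).sum() / total_abs) if total_abs > 0 else 0.0

    tol = _EIG_TOL_FACTOR * max(1.0, np.abs(eigval).max(initial=0.0)) * n
    pos = eigval > tol
    n_pos = int(pos.sum())
    k = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = eigvec[:, :k] * np.sqrt(eigval[:k]) if k else np.zeros((n, 0))

    pos_sum = eigval[pos].sum()
    prop = eigval[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return PCoAResult(
        labels=list(dm.labels),
        coordinates=coords,
        eigenvalues=eigval,
        proportion_explained=prop,
        negative_eigenvalue_mass=neg_mass,
    )


def _group_delta(d: np.ndarray, index_sets: list[np.ndarray], weights: np.ndarray) -> float:
    delta = 0.0
    for idx, w in zip(index_sets, weights):
        sub = d[np.ix_(idx, idx)]
        n = len(idx)
        delta += w * (sub.sum() / (n * (n - 1)))
    return delta


def mrpp(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> MRPPResult:
    """Multi-response permutation procedure on a labelled grouping.

    Requires at least two groups, each with at least two members; every
    matrix label must be assigned a group. Identical seeds give identical
    results; ties ``delta_perm <= delta_obs`` count toward the p-value.
    """
    labels = dm.labels
    missing = [s for s in labels if s not in groups]
    if missing:
        raise KeyError(f"strains without a group label: {missing}")
    group_names = sorted({groups[s] for s in labels})
    if len(group_names) < 2:
        raise ValueError("MRPP requires at least 2 groups")
    sizes = {g: sum(groups[s] == g for s in labels) for g in group_names}
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"MRPP groups need >= 2 members, too small: {small}")

    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    rng = np.random.default_rng(seed)

    d = dm.values
    n = len(labels)
    code = np.array([group_names.index(groups[s]) for s in labels])
    weights = np.array([sizes[g] for g in group_names], dtype=float) / n

    index_sets = [np.flatnonzero(code == k) for k in range(len(group_names))]
    delta_obs = _group_delta(d, index_sets, weights)

    # Permutation deltas, vectorised: within-group distance sums via
    # membership-matrix quadratic forms, one einsum per group.
    perms = np.empty((n_perm, n), dtype=np.intp)
    base = np.arange(n)
    for p in range(n_perm):
        perms[p] = rng.permutation(base)
    perm_code = code[perms]  # shuffled label vector per permutation
    deltas = np.zeros(n_perm)
    for k, w in enumerate(weights):
        mask = (perm_code == k).astype(float)  # (n_perm, n)
        n_k = mask.sum(axis=1)  # constant = sizes
        within = np.einsum("pi,ij,pj->p", mask, d, mask)
        deltas += w * within / (n_k * (n_k - 1))

    delta_expected = float(deltas.mean())
    # inclusive ties; tiny slack absorbs summation-order float noise
    tie_tol = 1e-12 * max(1.0, abs(delta_obs))
    p_value = (1 + int(np.sum(deltas <= delta_obs + tie_tol))) / (1 + n_perm)
    a = 1.0 - delta_obs / delta_expected if delta_expected > 0 else 0.0
    return MRPPResult(
        delta_observed=float(delta_obs),
        delta_expected=delta_expected,
        effect_size_A=float(a),
        p_value=float(p_value),
        n_permutations=n_perm,
        seed=seed,
        group_sizes=sizes,
    )
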