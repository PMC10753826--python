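"""Community-structure statistics: Bray-Curtis, nonmetric MDS, PERMANOVA.

All three are implemented from first principles on top of numpy/scipy
primitives:

* Bray-Curtis dissimilarity between TSS proportion vectors x, y is
  ``1 - sum_f min(x_f, y_f)`` (the count formulation reduces to this under
  total-sum scaling).
* NMDS minimises Kruskal's stress-1,
  ``sqrt(sum (dhat_ij - delta_ij)^2 / sum delta_ij^2)``, where delta are the
  configuration distances and dhat the disparities obtained by monotone
  (pool-adjacent-violators) regression of delta onto the rank order of the
  observed dissimilarities.  Optimisation is the Guttman transform, started
  from classical metric scaling plus random restarts; the best (lowest
  stress) configuration is kept.
* PERMANOVA follows Anderson's sums-of-squares decomposition of a distance
  matrix and estimates the p-value of the pseudo-F statistic by uniformly
  random label permutations.

Distances travel in a :class:`skbio.DistanceMatrix`, the field's standard
container (symmetry, hollowness and id bookkeeping come with it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .amplicon import RelAbundanceTable

__all__ = [
    "DistanceMatrix",
    "bray_curtis",
    "NmdsResult",
    "nmds",
    "PermanovaResult",
    "permanova",
]


def bray_curtis(rel: RelAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    Computed as ``1 - sum_f min(x_fi, x_fj)`` on proportion vectors; values
    lie in [0, 1] because each sample sums to 1.
    """
    values = rel.values.to_numpy(dtype=float)
    n = values.shape[1]
    if n < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(values[:, i : i + 1], values[:, i + 1 :]).sum(axis=0)
        d[i, i + 1 :] = 1.0 - shared
    d = d + d.T
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return DistanceMatrix(d, ids=rel.sample_ids)


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class NmdsResult:
    """Outcome of one NMDS fit (best configuration over all restarts)."""

    coordinates: pd.DataFrame  # samples x k
    stress: float  # Kruskal stress-1
    n_iterations: int
    converged: bool
    seed: int | None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, k = self.coordinates.shape
        return (
            f"NmdsResult(n={n}, k={k}, stress={self.stress:.4f}, "
            f"converged={self.converged})"
        )


def _config_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _stress_and_disparities(
    delta_flat: np.ndarray, order: np.ndarray
) -> tuple[float, np.ndarray]:
    """Stress-1 and PAVA disparities for configuration distances delta.

    ``order`` sorts the observed dissimilarities ascending; the disparities
    are the isotonic fit of delta (in that order) so they preserve the
    observed rank order.
    """
    dhat = np.empty_like(delta_flat)
    dhat[order] = isotonic_regression(delta_flat[order]).x
    denom = float((delta_flat**2).sum())
    if denom == 0.0:
        return 0.0, dhat
    stress = float(np.sqrt(((dhat - delta_flat) ** 2).sum() / denom))
    return stress, dhat


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    idx = np.argsort(eigval)[::-1][:k]
    lam = np.clip(eigval[idx], 0.0, None)
    return eigvec[:, idx] * np.sqrt(lam)


def _nmds_single(
    d_flat: np.ndarray,
    order: np.ndarray,
    init: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, int, bool]:
    """One monotone-regression / Guttman-transform descent from ``init``.

    The iteration is accepted only while stress decreases, so the stress
    trajectory is non-increasing by construction; an uphill step terminates
    the run at the previous configuration.
    """
    n = init.shape[0]
    coords = init.copy()
    delta = _config_distances(coords)
    stress, dhat_flat = _stress_and_disparities(squareform(delta, checks=False), order)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dhat = squareform(dhat_flat, checks=False)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(delta > 0, dhat / np.where(delta > 0, delta, 1.0), 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        new_coords = (b @ coords) / n  # Guttman transform
        new_delta = _config_distances(new_coords)
        new_stress, new_dhat_flat = _stress_and_disparities(
            squareform(new_delta, checks=False), order
        )
        if new_stress > stress:  # uphill: keep previous configuration
            converged = True
            break
        improvement = stress - new_stress
        coords, delta, stress, dhat_flat = new_coords, new_delta, new_stress, new_dhat_flat
        if improvement < tol:
            converged = True
            break
    return coords, stress, it, converged


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    *,
    seed: int | None = None,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> NmdsResult:
    """Nonmetric multidimensional scaling into k dimensions.

    The first start is classical (metric) scaling of the input distances;
    the remaining ``n_starts - 1`` are random Gaussian configurations.  The
    configuration with the lowest Kruskal stress-1 is returned, centred and
    scaled to unit RMS distance from the origin.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = np.asarray(dist.data, dtype=float)  # DistanceMatrix guarantees symmetry
    n = d.shape[0]
    if n < 3:
        raise ValueError("NMDS needs at least 3 samples")
    d_flat = squareform(d, checks=False)
    order = np.argsort(d_flat, kind="stable")
    rng = np.random.default_rng(seed)

    best: tuple[np.ndarray, float, int, bool] | None = None
    for start in range(max(1, n_starts)):
        if start == 0:
            init = _classical_mds(d, k)
            if np.allclose(init, 0.0):
                init = rng.standard_normal((n, k))
        else:
            init = rng.standard_normal((n, k))
        result = _nmds_single(d_flat, order, init, max_iter, tol)
        if best is None or result[1] < best[1]:
            best = result
    coords, stress, n_iter, converged = best
    coords = coords - coords.mean(axis=0)
    rms = np.sqrt((coords**2).sum(axis=1).mean())
    if rms > 0:
        coords = coords / rms
    frame = pd.DataFrame(
        coords, index=list(dist.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return NmdsResult(frame, float(stress), n_iter, converged, seed)


def stress1(dist: DistanceMatrix, coordinates: pd.DataFrame) -> float:
    """Recompute Kruskal stress-1 of a configuration against a distance matrix."""
    d_flat = squareform(np.asarray(dist.data, dtype=float), checks=False)
    order = np.argsort(d_flat, kind="stable")
    coords = coordinates.loc[list(dist.ids)].to_numpy(dtype=float)
    delta_flat = squareform(_config_distances(coords), checks=False)
    stress, _ = _stress_and_disparities(delta_flat, order)
    return stress


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    """Pseudo-F test of group differences on a distance matrix."""

    pseudo_F: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    ss_total: float
    ss_within: float
    ss_between: float

    def summary(self) -> str:
        lines = [
            "PERMANOVA (pseudo-F permutation test)",
            f"  groups:        {len(self.group_sizes)} "
            f"({', '.join(f'{g}={n}' for g, n in self.group_sizes.items())})",
            f"  SS_between:    {self.ss_between:.6f}",
            f"  SS_within:     {self.ss_within:.6f}",
            f"  SS_total:      {self.ss_total:.6f}",
            f"  pseudo-F:      {self.pseudo_F:.4f}",
            f"  permutations:  {self.n_permutations}",
            f"  p-value:       {self.p_value:.4f}",
        ]
        return "\n".join(lines)


def _ss_within(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    total = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2 * len(idx))
    return total


def permanova(
    dist: DistanceMatrix,
    groups: Sequence[str] | pd.Series,
    *,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA of ``groups`` on a distance matrix.

    SS_total = (1/N) sum_{i<j} d_ij^2; SS_within sums (1/n_g) sum_{i<j in g}
    d_ij^2 over groups; pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)).
    The p-value is (1 + #{F* >= F}) / (1 + n_permutations) over uniformly
    random, unrestricted label permutations.
    """
    if isinstance(groups, pd.Series):
        groups = groups.loc[list(dist.ids)]
        labels = groups.to_numpy()
    else:
        labels = np.asarray(list(groups))
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError(f"got {labels.shape[0]} labels for {n} samples")
    uniq, counts = np.unique(labels, return_counts=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if counts.max() == n:
        raise ValueError("one group absorbs all samples")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    d2 = d**2
    ss_total = d2.sum() / (2 * n)
    ss_within = _ss_within(d2, labels, uniq)
    ss_between = ss_total - ss_within

    df_between = a - 1
    df_within = n - a
    if ss_within == 0.0:
        f_obs = np.inf if ss_between > 0 else 0.0
    else:
        f_obs = (ss_between / df_between) / (ss_within / df_within)

    # Vectorised permutation null: SS_within per permuted labelling via
    # one-hot group indicators Z -> sum_g (Z_g' D2 Z_g) / (2 n_g).
    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    perm_labels = labels[perm_idx]  # (B, n)
    ss_within_perm = np.zeros(n_permutations)
    for g, n_g in zip(uniq, counts):
        z = (perm_labels == g).astype(float)
        ss_within_perm += np.einsum("bi,ij,bj->b", z, d2, z) / (2 * n_g)
    ss_between_perm = ss_total - ss_within_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_between_perm / df_between) / (ss_within_perm / df_within)
    f_perm = np.where(ss_within_perm == 0.0, np.inf, f_perm)
    p = (1 + int((f_perm >= f_obs).sum())) / (1 + n_permutations)

    return PermanovaResult(
        pseudo_F=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        group_sizes={str(g): int(c) for g, c in zip(uniq, counts)},
        ss_total=float(ss_total),
        ss_within=float(ss_within),
        ss_between=float(ss_between),
    )
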