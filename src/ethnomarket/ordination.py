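"""Principal coordinates ordination and distance-based permutation tests.

The ordination is classical metric scaling (PCoA): Gower double-centering of
the squared distances followed by a symmetric eigendecomposition.  Group
structure is tested with a PERMANOVA-style pseudo-F on the distance matrix;
association with a per-market covariate (e.g. market size) with a
Mantel-style permutation correlation.  Permutation p-values use the add-one
convention ``p = (1 + #{perm >= obs}) / (1 + n_permutations)`` and never
reach zero.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .errors import ParameterError

logger = logging.getLogger("ethnomarket")


@dataclass
class OrdinationResult:
    markets: tuple[str, ...]
    coordinates: pd.DataFrame  # markets × axes
    eigenvalues: np.ndarray  # kept (non-negative) axes, decreasing
    negative_eigenvalue_mass: float  # |sum of negative eigenvalues| / sum |all|
    method: str = "PCoA"


@dataclass
class PermutationTestResult:
    statistic_name: str
    observed: float
    n_permutations: int
    p_value: float
    seed: int | None
    grouping: str
    null_mean: float = float("nan")
    null_sd: float = float("nan")


def _as_dm(d) -> DistanceMatrix:
    if isinstance(d, DistanceMatrix):
        return d
    return DistanceMatrix(np.asarray(d, dtype=float))


def pcoa(d, n_axes: int | None = None,
         lingoes_correction: bool = False) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Negative eigenvalues (non-Euclidean input) are dropped and their
    absolute mass reported; ``lingoes_correction`` instead adds the constant
    ``2|lambda_min|`` to all squared off-diagonal distances first.  Axes are
    ordered by decreasing eigenvalue and coordinates are centered.
    """
    dm = _as_dm(d)
    n = dm.shape[0]
    if n < 3:
        raise ParameterError("need at least 3 markets to ordinate")
    d2 = dm.data.astype(float) ** 2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centerer @ d2 @ centerer
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if lingoes_correction and eigval[-1] < -1e-12:
        c = abs(eigval[-1])
        d2c = d2 + 2.0 * c
        np.fill_diagonal(d2c, 0.0)
        b = -0.5 * centerer @ d2c @ centerer
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]

    tol = 1e-9 * max(1.0, float(np.abs(eigval).max()))
    neg_mass = float(np.abs(eigval[eigval < -tol]).sum())
    total_mass = float(np.abs(eigval).sum())
    keep = eigval > tol
    lams = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(lams)
    if n_axes is not None:
        if n_axes > coords.shape[1]:
            warnings.warn(
                f"requested {n_axes} axes but rank is {coords.shape[1]}; "
                "truncating", stacklevel=2)
        coords = coords[:, :n_axes]
        lams = lams[:n_axes]
    frame = pd.DataFrame(coords, index=list(dm.ids),
                         columns=[f"PCo{i + 1}" for i in range(coords.shape[1])])
    return OrdinationResult(
        markets=tuple(dm.ids), coordinates=frame, eigenvalues=lams,
        negative_eigenvalue_mass=(neg_mass / total_mass) if total_mass else 0.0,
    )


# -- PERMANOVA-style pseudo-F ---------------------------------------------

def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances and integer group codes.

    SS_total = sum_{i<j} d2_ij / n; SS_within analogously per group;
    F = (SS_between / (g - 1)) / (SS_within / (n - g)).
    """
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        n_g = int(mask.sum())
        if n_g > 1:
            ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    ss_between = ss_total - ss_within
    if ss_within <= 0.0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permutation_group_test(
    d,
    groups: Mapping[str, str] | Sequence[str],
    n_permutations: int = 9999,
    seed: int | None = None,
    exact: bool = False,
) -> PermutationTestResult:
    """Test whether markets in the same group are compositionally closer.

    ``groups`` maps market id to group label (or gives labels in matrix
    order).  With ``exact=True`` all distinct label arrangements are
    enumerated instead of sampled (feasible for small surveys) and the
    p-value is the exact exceedance fraction including the identity.
    """
    dm = _as_dm(d)
    ids = list(dm.ids)
    if isinstance(groups, Mapping):
        missing = [m for m in ids if m not in groups]
        if missing:
            raise ParameterError(f"groups missing for markets: {missing}")
        labels = [groups[m] for m in ids]
    else:
        if len(groups) != len(ids):
            raise ParameterError("label sequence length != number of markets")
        labels = list(groups)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ParameterError("need at least 2 groups (a single group equal "
                             "to the whole sample is degenerate)")
    code_of = {g: i for i, g in enumerate(uniq)}
    codes = np.array([code_of[g] for g in labels])
    d2 = dm.data.astype(float) ** 2
    observed = _pseudo_f(d2, codes, len(uniq))
    grouping = f"{len(uniq)} groups over {len(ids)} markets"

    if exact:
        perms = set(itertools.permutations(codes))
        stats = np.array([_pseudo_f(d2, np.array(p), len(uniq))
                          for p in perms])
        p = float((stats >= observed - 1e-12).sum()) / len(stats)
        return PermutationTestResult(
            statistic_name="pseudo-F", observed=float(observed),
            n_permutations=len(stats), p_value=p, seed=seed,
            grouping=grouping + " (exact enumeration)",
            null_mean=float(stats.mean()), null_sd=float(stats.std()),
        )

    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_permutations)
    work = codes.copy()
    for i in range(n_permutations):
        rng.shuffle(work)
        stats[i] = _pseudo_f(d2, work, len(uniq))
    p = (1.0 + float((stats >= observed - 1e-12).sum())) / (1.0 + n_permutations)
    return PermutationTestResult(
        statistic_name="pseudo-F", observed=float(observed),
        n_permutations=n_permutations, p_value=p, seed=seed,
        grouping=grouping,
        null_mean=float(stats.mean()), null_sd=float(stats.std()),
    )


# -- Mantel-style size association -----------------------------------------

def size_association_test(
    d,
    sizes: Mapping[str, float] | Sequence[float],
    n_permutations: int = 9999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Mantel-style test of association between composition and market size.

    The statistic is the Pearson correlation between off-diagonal distances
    and pairwise absolute size differences; the null permutes market
    identities jointly in both matrices.
    """
    dm = _as_dm(d)
    ids = list(dm.ids)
    n = len(ids)
    if n < 4:
        raise ParameterError("need at least 4 markets for the size test")
    if isinstance(sizes, Mapping):
        missing = [m for m in ids if m not in sizes]
        if missing:
            raise ParameterError(f"sizes missing for markets: {missing}")
        s = np.array([float(sizes[m]) for m in ids])
    else:
        if len(sizes) != n:
            raise ParameterError("size vector length != number of markets")
        s = np.asarray(sizes, dtype=float)
    if np.ptp(s) == 0:
        raise ParameterError("size vector has zero variance; correlation "
                             "undefined")
    size_d = np.abs(s[:, None] - s[None, :])
    iu = np.triu_indices(n, k=1)
    y = dm.data[iu]
    if np.std(y) == 0:
        raise ParameterError("distance matrix is constant; correlation "
                             "undefined")

    def corr(perm):
        x = size_d[np.ix_(perm, perm)][iu]
        sx = x.std()
        if sx == 0:
            return 0.0
        return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * y.std()))

    identity = np.arange(n)
    observed = corr(identity)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_permutations)
    for i in range(n_permutations):
        stats[i] = corr(rng.permutation(n))
    p = (1.0 + float((stats >= observed - 1e-12).sum())) / (1.0 + n_permutations)
    return PermutationTestResult(
        statistic_name="Mantel r (size)", observed=observed,
        n_permutations=n_permutations, p_value=p, seed=seed,
        grouping=f"size covariate over {n} markets",
        null_mean=float(stats.mean()), null_sd=float(stats.std()),
    )
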