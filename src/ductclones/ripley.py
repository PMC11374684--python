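"""1D Ripley K/L statistics for proliferating-cell positions along ducts.

Distances are arc lengths along the duct axis. For a pattern of N points on
a domain of length D,

    K(r) = D / (N(N-1)) * sum_{i != j} 1(|x_i - x_j| <= r),

so complete spatial randomness (CSR, a homogeneous Poisson process) gives
E[K(r)] = 2r away from the edges. The normalised L function

    L(r) = K(r)/2 - r

is ~0 under CSR, positive under clustering, negative under regularity.
Significance is assessed against a pointwise envelope of CSR simulations
with matched point count and domain length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError
from .io import CloneTable, DuctalTree, PointPattern1D, branch_level

__all__ = [
    "RipleyResult",
    "default_radii",
    "ripley_k_1d",
    "ripley_l_normalized",
    "csr_envelope",
    "ripley_analysis",
    "UniformityTestReport",
    "branch_level_uniformity",
]


@dataclass
class RipleyResult:
    radii: np.ndarray
    k_values: np.ndarray
    l_values: np.ndarray
    envelope_low: Optional[np.ndarray]
    envelope_high: Optional[np.ndarray]
    n_points: int
    domain_length: float


def default_radii(domain_length: float, n: int = 40, r_min: float = 5.0) -> np.ndarray:
    """40 log-spaced radii from 5 µm to a quarter of the domain length."""
    return np.geomspace(r_min, domain_length / 4.0, n)


def _pair_counts(x: np.ndarray, centres: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """For each r: number of (centre, x) pairs with |centre - x| <= r, self-pairs included."""
    xs = np.sort(x)
    out = np.empty(radii.size, dtype=np.int64)
    for i, r in enumerate(radii):
        hi = np.searchsorted(xs, centres + r, side="right")
        lo = np.searchsorted(xs, centres - r, side="left")
        out[i] = int((hi - lo).sum())
    return out


def ripley_k_1d(
    pattern: PointPattern1D,
    radii: Sequence[float],
    edge_correction: str = "reflect",
) -> np.ndarray:
    """Ripley's K along a 1D duct.

    ``edge_correction="reflect"`` mirrors the pattern at both domain ends so
    that windows extending past an edge are filled with the reflected points;
    ``"none"`` uses raw pair counts.
    """
    radii = np.asarray(radii, dtype=float)
    if pattern.n_points < 2:
        raise InsufficientDataError("Ripley K needs at least 2 points")
    if radii.size == 0 or (radii <= 0).any() or (np.diff(radii) < 0).any():
        raise ValueError("radii must be positive and sorted")
    x = pattern.positions
    D = pattern.domain_length
    n = pattern.n_points
    if edge_correction == "none":
        targets = x
    elif edge_correction == "reflect":
        targets = np.concatenate([x, -x, 2.0 * D - x])
    else:
        raise ValueError("edge_correction must be 'none' or 'reflect'")
    counts = _pair_counts(targets, x, radii) - n  # remove self-pairs
    return D * counts / (n * (n - 1))


def ripley_l_normalized(
    pattern: PointPattern1D,
    radii: Sequence[float],
    edge_correction: str = "reflect",
) -> np.ndarray:
    """L(r) = K(r)/2 − r: 0 under CSR, >0 clustered, <0 regular."""
    radii = np.asarray(radii, dtype=float)
    return ripley_k_1d(pattern, radii, edge_correction) / 2.0 - radii


def csr_envelope(
    n_points: int,
    domain_length: float,
    radii: Sequence[float],
    n_sim: int = 199,
    level: float = 0.95,
    seed: int = 0,
    edge_correction: str = "reflect",
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise CSR envelope of L(r) at the given level.

    Simulates ``n_sim`` uniform patterns with matched n and D and takes
    pointwise quantiles; ``level=1.0`` spans the simulation min/max.
    """
    radii = np.asarray(radii, dtype=float)
    if level < 1.0:
        needed = math.ceil(2.0 / (1.0 - level)) - 1
        if n_sim < needed:
            raise ValueError(f"n_sim >= {needed} required for level {level}")
    elif n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, radii.size))
    for s in range(n_sim):
        pts = rng.uniform(0.0, domain_length, n_points)
        pat = PointPattern1D(positions=pts, domain_length=domain_length)
        sims[s] = ripley_l_normalized(pat, radii, edge_correction)
    alpha = (1.0 - level) / 2.0
    if level >= 1.0:
        return sims.min(axis=0), sims.max(axis=0)
    low = np.quantile(sims, alpha, axis=0)
    high = np.quantile(sims, 1.0 - alpha, axis=0)
    return low, high


def ripley_analysis(
    pattern: PointPattern1D,
    radii: Optional[Sequence[float]] = None,
    edge_correction: str = "reflect",
    n_sim: int = 199,
    level: float = 0.95,
    seed: int = 0,
) -> RipleyResult:
    """K, normalised L and a CSR envelope for one point pattern."""
    if radii is None:
        radii = default_radii(pattern.domain_length)
    radii = np.asarray(radii, dtype=float)
    k = ripley_k_1d(pattern, radii, edge_correction)
    l_vals = k / 2.0 - radii
    low, high = csr_envelope(
        pattern.n_points,
        pattern.domain_length,
        radii,
        n_sim=n_sim,
        level=level,
        seed=seed,
        edge_correction=edge_correction,
    )
    return RipleyResult(
        radii=radii,
        k_values=k,
        l_values=l_vals,
        envelope_low=low,
        envelope_high=high,
        n_points=pattern.n_points,
        domain_length=pattern.domain_length,
    )


@dataclass(frozen=True)
class UniformityTestReport:
    """Chi-square test of clone positions against slot-weighted branch levels."""

    levels: tuple[int, ...]
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    chi2: float
    p_value: float
    n_mc: int
    degenerate: bool = False


def branch_level_uniformity(
    table: CloneTable,
    tree: DuctalTree,
    n_mc: int = 10_000,
    seed: int = 0,
) -> UniformityTestReport:
    """Are clones scattered over branch levels in proportion to available cells?

    Expected counts per level weight each level by its total number of cell
    slots in the tree; the chi-square statistic is calibrated by Monte-Carlo
    multinomial draws (counts per level can be small).
    """
    slot_weights: dict[int, float] = {}
    for sid in tree.segments:
        lvl = branch_level(tree, sid)
        slot_weights[lvl] = slot_weights.get(lvl, 0.0) + tree.n_cell_slots(sid)
    observed_counts: dict[int, int] = {}
    for rec in table.records:
        if rec.branch_level is None:
            continue
        observed_counts[rec.branch_level] = observed_counts.get(rec.branch_level, 0) + 1
    if not observed_counts or not (set(observed_counts) & set(slot_weights)):
        raise ValueError("no overlap between observed branch levels and the tree")
    levels = sorted(slot_weights)
    obs = np.array([observed_counts.get(l, 0) for l in levels], dtype=np.int64)
    weights = np.array([slot_weights[l] for l in levels], dtype=float)
    probs = weights / weights.sum()
    n_total = int(obs.sum())
    expected = probs * n_total
    if len(levels) < 2:
        return UniformityTestReport(
            levels=tuple(levels),
            observed=tuple(int(o) for o in obs),
            expected=tuple(expected),
            chi2=0.0,
            p_value=1.0,
            n_mc=0,
            degenerate=True,
        )
    chi2_obs = float(((obs - expected) ** 2 / np.where(expected > 0, expected, 1.0)).sum())
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_total, probs, size=n_mc)
    chi2_null = ((draws - expected) ** 2 / np.where(expected > 0, expected, 1.0)).sum(axis=1)
    p = float((1 + np.sum(chi2_null >= chi2_obs)) / (n_mc + 1))
    return UniformityTestReport(
        levels=tuple(levels),
        observed=tuple(int(o) for o in obs),
        expected=tuple(expected),
        chi2=chi2_obs,
        p_value=p,
        n_mc=n_mc,
    )
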