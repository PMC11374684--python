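"""Clone-size distribution statistics: log-moments, CCDFs, scaling collapse.

The central observation these tools support: defining C(w, t) as the
probability of finding a clone with log-size ln n larger than w, clone-size
data from different times superimpose onto a single curve once each sample
is standardised by its own log-mean μ(t) and log-s.d. σ(t). For log-normal
sizes the collapsed curve is the standard-normal upper tail,
C(x) = (1/2)·erfc(x/√2).

Moments use the population (1/N) variance, matching the moment definition
⟨(ln n − ⟨ln n⟩)²⟩; single-cell clones are retained (ln 1 = 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateSampleError, InsufficientDataError
from .io import CloneRecord, CloneTable

__all__ = [
    "MomentSummary",
    "CollapseResult",
    "log_moments",
    "LogCCDF",
    "ccdf_log",
    "rescale",
    "lognormal_scaling_function",
    "collapse_test",
    "surviving_clone_fraction",
    "group_moments",
]


@dataclass(frozen=True)
class MomentSummary:
    """Log-size moments for one stratum of clones."""

    group_keys: tuple[tuple[str, object], ...]
    n_clones: int
    mu: float
    sigma2: float
    mean_size: float
    single_cell_fraction: float

    def key(self, name: str):
        return dict(self.group_keys).get(name)


def log_moments(sizes: Sequence[int]) -> tuple[float, float]:
    """(μ, σ²) of ln(size): mean and population (1/N) variance."""
    arr = np.asarray(sizes, dtype=float)
    if arr.size == 0:
        raise ValueError("empty size sample")
    if (arr < 1).any():
        raise ValueError("all sizes must be >= 1")
    ln = np.log(arr)
    return float(ln.mean()), float(ln.var())


class LogCCDF:
    """Right-continuous step function C(w) = P(ln n > w), strict inequality."""

    def __init__(self, sizes: Sequence[int]):
        arr = np.asarray(sizes, dtype=float)
        if arr.size == 0:
            raise ValueError("empty size sample")
        if (arr < 1).any():
            raise ValueError("all sizes must be >= 1")
        self.log_sizes = np.sort(np.log(arr))
        self.n = arr.size

    def __call__(self, w) -> np.ndarray | float:
        w_arr = np.asarray(w, dtype=float)
        n_le = np.searchsorted(self.log_sizes, w_arr, side="right")
        out = (self.n - n_le) / self.n
        return float(out) if np.isscalar(w) else out

    def steps(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique step locations w and C(w) just right of each step."""
        w = np.unique(self.log_sizes)
        return w, self(w)


def ccdf_log(sizes: Sequence[int]) -> LogCCDF:
    """Empirical complementary CDF of ln(size); see :class:`LogCCDF`."""
    return LogCCDF(sizes)


def rescale(sizes: Sequence[int]) -> np.ndarray:
    """Standardised log-sizes x_i = (ln n_i − μ)/σ (mean 0, variance 1).

    Scale-invariant in log space: raising all sizes to a positive power
    leaves the output unchanged.
    """
    mu, sigma2 = log_moments(sizes)
    if sigma2 <= 0:
        raise DegenerateSampleError("constant sample cannot be rescaled (sigma2 = 0)")
    return (np.log(np.asarray(sizes, dtype=float)) - mu) / np.sqrt(sigma2)


def lognormal_scaling_function(x) -> np.ndarray | float:
    """C(x) = (1/2)·erfc(x/√2), the standard-normal upper-tail probability."""
    out = 0.5 * special.erfc(np.asarray(x, dtype=float) / np.sqrt(2.0))
    return float(out) if np.isscalar(x) else out


@dataclass
class CollapseResult:
    """Outcome of the scaling-collapse test across clone strata."""

    rescaled: dict[object, np.ndarray]
    pairwise: pd.DataFrame  # group_a, group_b, ks_stat, p_value, p_holm
    sup_deviation: dict[object, float]
    pooled_sup_deviation: float
    excluded: list[object]
    alpha: float = 0.05

    @property
    def collapses(self) -> bool:
        """True when no Holm-adjusted pairwise test rejects at ``alpha``."""
        if self.pairwise.empty:
            return True
        return bool((self.pairwise["p_holm"] > self.alpha).all())


def _sup_deviation_from_scaling(x: np.ndarray) -> float:
    # sup |empirical CCDF - (1/2)erfc(./sqrt 2)| equals the KS distance to N(0,1)
    return float(stats.ks_1samp(x, stats.norm.cdf).statistic)


def collapse_test(
    groups: Mapping[object, Sequence[int]],
    min_n: int = 20,
    alpha: float = 0.05,
) -> CollapseResult:
    """Test whether strata share one shape after per-stratum standardisation.

    Each group's sizes are rescaled to (ln n − μ)/σ; all pairwise two-sample
    Kolmogorov–Smirnov tests are run on the rescaled samples with Holm
    adjustment, and each group's sup-deviation from the log-normal scaling
    function (1/2)erfc(x/√2) is reported. Groups below ``min_n`` clones or
    with zero log-variance are excluded (error if fewer than two remain).
    """
    rescaled: dict[object, np.ndarray] = {}
    excluded: list[object] = []
    for key, sizes in groups.items():
        arr = np.asarray(sizes)
        if arr.size < min_n:
            excluded.append(key)
            continue
        try:
            rescaled[key] = rescale(arr)
        except DegenerateSampleError:
            excluded.append(key)
    if len(rescaled) < 2:
        raise InsufficientDataError(
            f"fewer than 2 usable groups (excluded: {excluded})"
        )
    keys = list(rescaled)
    rows = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            res = stats.ks_2samp(rescaled[keys[i]], rescaled[keys[j]])
            rows.append((keys[i], keys[j], res.statistic, res.pvalue))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "ks_stat", "p_value"])
    pairwise["p_holm"] = multipletests(pairwise["p_value"], method="holm")[1]
    sup_dev = {k: _sup_deviation_from_scaling(x) for k, x in rescaled.items()}
    pooled = np.concatenate(list(rescaled.values()))
    return CollapseResult(
        rescaled=rescaled,
        pairwise=pairwise,
        sup_deviation=sup_dev,
        pooled_sup_deviation=_sup_deviation_from_scaling(pooled),
        excluded=excluded,
        alpha=alpha,
    )


def surviving_clone_fraction(
    counts: Mapping[int, float], reference_day: int = 14
) -> dict[int, float]:
    """Mean clone count at each time divided by the count at the reference day."""
    if reference_day not in counts:
        raise ValueError(f"reference day {reference_day} missing from counts")
    ref = counts[reference_day]
    if ref <= 0:
        raise ValueError("reference count must be > 0")
    return {int(t): float(c) / float(ref) for t, c in counts.items()}


def group_moments(table: CloneTable, keys: Sequence[str]) -> list[MomentSummary]:
    """One :class:`MomentSummary` per distinct combination of record fields.

    ``keys=[]`` yields a single global summary. Output order is
    deterministic (sorted by key values).
    """
    valid_fields = set(CloneRecord.__dataclass_fields__)
    for k in keys:
        if k not in valid_fields:
            raise ValueError(f"unknown group key {k!r}")
    df = table.to_dataframe()
    if df.empty:
        return []
    if keys:
        grouped = df.groupby(list(keys), sort=True, dropna=False)
        items = [(combo if isinstance(combo, tuple) else (combo,), sub) for combo, sub in grouped]
    else:
        items = [((), df)]
    out = []
    for combo, sub in items:
        sizes = sub["size_cells"].to_numpy(dtype=float)
        mu, sigma2 = log_moments(sizes)
        out.append(
            MomentSummary(
                group_keys=tuple(zip(keys, combo)),
                n_clones=int(sizes.size),
                mu=mu,
                sigma2=sigma2,
                mean_size=float(sizes.mean()),
                single_cell_fraction=float((sizes == 1).mean()),
            )
        )
    return out
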