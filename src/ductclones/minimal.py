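"""Non-spatial stochastic model of mammary stem-cell (MaSC) clone fate.

Each induced confetti clone is rooted either in a MaSC (probability
``1/unit_size`` — the labelled cell happened to be the stem cell of its
~5–10-cell descendant unit) or in a short-lived descendant. Per oestrous
cycle a MaSC-rooted clone is *activated* with probability ``p_activate``
(participates in side-branch turnover); an activated clone is then either
wholly lost (probability ``loss_prob``) or expands proportionately as one
correlated unit, multiplying its size by ``expansion_factor``. Long-term
homeostasis pins the loss probability: the mean labelled-cell count is
conserved exactly when ``(1 - loss_prob) * expansion_factor = 1``.

Conditioned on survival, log clone size performs a random walk with
positive drift, so size variability is multiplicative (log-normal-like) and
both the mean and the variance of ``ln n`` grow linearly with cycle number.

Descendant-rooted clones never expand; they survive each cycle with
probability ``descendant_persistence`` (geometric lifetime), producing the
steep early drop in surviving-clone counts, with the long-term surviving
fraction approaching ``1/unit_size``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
from scipy import stats

__all__ = [
    "MinimalModelParams",
    "CloneTrajectory",
    "CloneTrajectories",
    "homeostatic_loss_prob",
    "simulate",
    "activated_loss_fraction",
    "LossFractionEstimate",
    "mean_labelled_cells",
    "lilliefors_normality_test",
]


def homeostatic_loss_prob(expansion_factor: float) -> float:
    """Loss probability q making activation neutral on average: (1-q)·f = 1.

    With f = 2 this gives q = 1/2 — half of all activated clones are lost,
    the other half doubles, conserving the mean labelled-cell count.
    """
    if expansion_factor < 1:
        raise ValueError(f"expansion_factor must be >= 1, got {expansion_factor}")
    return 1.0 - 1.0 / expansion_factor


@dataclass
class MinimalModelParams:
    """Parameters of the minimal clone-fate model.

    unit_size
        Cells per MaSC-descendant unit (u); the rooting probability of an
        induced clone in a MaSC is 1/u.
    p_activate
        Per-cycle probability a MaSC-rooted clone takes part in side-branch
        turnover (default 0.1: active roughly once per ten oestrous cycles).
    expansion_factor
        Whole-clone multiplicative growth f on surviving activation.
    loss_prob
        Probability an activated clone is wholly lost. Derived from the
        homeostasis constraint (q = 1 - 1/f) when ``homeostasis`` is true;
        must be supplied explicitly otherwise (e.g. mutant clones resistant
        to loss have q below the homeostatic value).
    descendant_persistence
        Per-cycle survival probability of a descendant-rooted clone
        (default 0.8: mean lifetime 5 cycles, i.e. the first few months).
    mouse_scale_sd
        Log-scale s.d. of the per-mouse timescale multiplier used by the
        synthetic-data generator (mouse-to-mouse variability in effective
        cycle number).
    expansion_jitter_sd
        Optional log-scale s.d. of a stochastic expansion factor (mean
        preserved at f, so homeostasis still holds). 0 = deterministic ×f.
    """

    unit_size: int = 5
    p_activate: float = 0.1
    expansion_factor: float = 2.0
    loss_prob: Optional[float] = None
    descendant_persistence: float = 0.8
    homeostasis: bool = True
    mouse_scale_sd: float = 0.3
    expansion_jitter_sd: float = 0.0

    def __post_init__(self):
        if self.unit_size < 1:
            raise ValueError("unit_size must be >= 1")
        if not 0 <= self.p_activate <= 1:
            raise ValueError("p_activate must be a probability")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        if not 0 < self.descendant_persistence <= 1:
            raise ValueError("descendant_persistence must be in (0, 1]")
        if self.mouse_scale_sd < 0 or self.expansion_jitter_sd < 0:
            raise ValueError("scale parameters must be >= 0")
        if self.homeostasis:
            q = homeostatic_loss_prob(self.expansion_factor)
            if self.loss_prob is not None and abs(self.loss_prob - q) > 1e-12:
                raise ValueError(
                    "loss_prob conflicts with the homeostasis constraint; "
                    "set homeostasis=False to free it"
                )
            self.loss_prob = q
        elif self.loss_prob is None:
            raise ValueError("loss_prob required when homeostasis=False")
        if not 0 <= self.loss_prob < 1:
            raise ValueError("loss_prob must be in [0, 1)")


@dataclass(frozen=True)
class CloneTrajectory:
    """Size history of one clone; 0 marks extinction (absorbing)."""

    rooted_in_masc: bool
    sizes_by_cycle: tuple[int, ...]
    extinction_cycle: Optional[int]


class CloneTrajectories:
    """Vectorised container for simulated clone trajectories.

    ``sizes`` has shape (n_clones, n_cycles + 1); column 0 is the induction
    size. Extinction is absorbing: once a row hits 0 it stays 0.
    """

    def __init__(self, sizes: np.ndarray, rooted_in_masc: np.ndarray):
        self.sizes = np.asarray(sizes, dtype=np.int64)
        self.rooted_in_masc = np.asarray(rooted_in_masc, dtype=bool)
        dead = self.sizes == 0
        self.extinction_cycle = np.where(
            dead.any(axis=1), dead.argmax(axis=1), -1
        )

    @property
    def n_clones(self) -> int:
        return self.sizes.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.sizes.shape[1] - 1

    def __len__(self) -> int:
        return self.n_clones

    def __iter__(self) -> Iterator[CloneTrajectory]:
        for i in range(self.n_clones):
            ext = int(self.extinction_cycle[i])
            yield CloneTrajectory(
                rooted_in_masc=bool(self.rooted_in_masc[i]),
                sizes_by_cycle=tuple(int(s) for s in self.sizes[i]),
                extinction_cycle=None if ext < 0 else ext,
            )

    def sizes_at(self, cycle: int) -> np.ndarray:
        """Sizes of clones surviving at ``cycle`` (extinct clones dropped)."""
        col = self.sizes[:, cycle]
        return col[col > 0]

    def surviving_fraction(self, cycle: int) -> float:
        return float((self.sizes[:, cycle] > 0).mean())


def _clone_uniforms(seed: int, n_clones: int, n_cycles: int) -> np.ndarray:
    """Per-clone uniform streams, one row per clone.

    Row i consumes a fixed, contiguous block of the generator stream, so
    increasing ``n_clones`` appends clones without reshuffling earlier ones.
    """
    rng = np.random.default_rng(seed)
    return rng.random((n_clones, 1 + 2 * n_cycles))


def simulate(
    params: MinimalModelParams, n_clones: int, n_cycles: int, seed: int
) -> CloneTrajectories:
    """Simulate ``n_clones`` induced clones for ``n_cycles`` oestrous cycles.

    Update per cycle for a surviving MaSC-rooted clone of size n: with
    probability ``p_activate`` the whole clone is activated; an activated
    clone is set extinct with ``loss_prob``, otherwise its size becomes
    round(n·f) (half-up, and at least n+1 — survival of activation always
    grows the clone). Non-activated cycles leave the size unchanged.
    Descendant-rooted clones survive each cycle with
    ``descendant_persistence`` and never expand. Induction size is one cell.

    Deterministic for a fixed seed; clone i's randomness is a fixed block of
    the stream, so extending ``n_clones`` preserves earlier trajectories.
    """
    if n_clones < 0 or n_cycles < 0:
        raise ValueError("n_clones and n_cycles must be >= 0")
    u = _clone_uniforms(seed, n_clones, n_cycles)
    rooted = u[:, 0] < 1.0 / params.unit_size
    sizes = np.zeros((n_clones, n_cycles + 1), dtype=np.int64)
    size = np.ones(n_clones, dtype=np.float64)
    sizes[:, 0] = 1
    q = params.loss_prob
    f = params.expansion_factor
    s = params.expansion_jitter_sd
    for t in range(1, n_cycles + 1):
        a = u[:, 2 * t - 1]
        v = u[:, 2 * t]
        alive = size > 0
        act = rooted & alive & (a < params.p_activate)
        lost = act & (v < q)
        grow = act & ~lost
        size[lost] = 0.0
        if grow.any():
            if s > 0:
                # reuse the loss uniform, conditioned on survival, as the
                # jitter source: keeps one stream block per clone-cycle
                z = stats.norm.ppf((v[grow] - q) / (1.0 - q))
                factor = f * np.exp(s * z - 0.5 * s * s)
            else:
                factor = f
            grown = np.floor(size[grow] * factor + 0.5)  # round half-up
            size[grow] = np.maximum(grown, size[grow] + 1.0)
        ddie = ~rooted & alive & (a >= params.descendant_persistence)
        size[ddie] = 0.0
        sizes[:, t] = size.astype(np.int64)
    return CloneTrajectories(sizes=sizes, rooted_in_masc=rooted)


@dataclass(frozen=True)
class LossFractionEstimate:
    fraction: float
    se: float
    n_events: int


def activated_loss_fraction(
    params: MinimalModelParams, n_events: int, seed: int
) -> LossFractionEstimate:
    """Monte-Carlo fraction of activation events ending in whole-clone loss.

    Under the homeostasis constraint with expansion factor 2, half of all
    activated clones are lost per cycle while the other half doubles.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    lost = rng.random(n_events) < params.loss_prob
    p_hat = float(lost.mean())
    se = float(np.sqrt(max(p_hat * (1.0 - p_hat), 1e-300) / n_events))
    return LossFractionEstimate(fraction=p_hat, se=se, n_events=n_events)


def mean_labelled_cells(trajectories: CloneTrajectories) -> np.ndarray:
    """Mean labelled cells per cycle over ALL clones, extinct counted as 0.

    Under homeostasis this series is a martingale (flat in expectation).
    """
    if trajectories.n_clones == 0:
        raise ValueError("empty trajectory set")
    return trajectories.sizes.mean(axis=0)


def lilliefors_normality_test(
    sample: np.ndarray, n_calibration: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Kolmogorov–Smirnov test against the fitted normal, Monte-Carlo calibrated.

    Fits mean and s.d. to the sample, computes the KS statistic against that
    normal, and calibrates the p-value by re-fitting on ``n_calibration``
    normal samples of equal size (Lilliefors-style, since parameters are
    estimated from the data). Returns ``(statistic, p_value)``.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")

    def ks_fitted(y: np.ndarray) -> float:
        sd = y.std()
        if sd == 0:
            return 1.0
        return stats.ks_1samp(y, stats.norm(y.mean(), sd).cdf).statistic

    d_obs = ks_fitted(x)
    rng = np.random.default_rng(seed)
    d_null = np.array(
        [ks_fitted(rng.standard_normal(x.size)) for _ in range(n_calibration)]
    )
    p = (1.0 + np.sum(d_null >= d_obs)) / (n_calibration + 1.0)
    return float(d_obs), float(p)
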