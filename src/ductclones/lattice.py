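"""1D lattice ("ribbon") model of ductal clone competition.

The ductal epithelium is reduced to a ring of ``n_sites`` MaSC sites. Each
oestrous cycle, ``events_per_cycle`` side-branch remodelling events occur:
an event picks a random contiguous block of ``block_length`` sites, loses
each site independently with ``site_loss_prob``, and refills the block by
proportional expansion of the surviving sites' labels in their original
left-to-right order (survivor counts scaled back to the block length by
largest-remainder apportionment). If the whole block is lost it is recolonised
from the two flanking sites. The site count is conserved exactly, and every
tracked clone remains a single contiguous run on the ring.

At intermediate times clones grow multiplicatively (log-normal-like size
statistics, as in the non-spatial minimal model); once typical sizes reach
the remodelled-block scale, growth is geometrically suppressed and the size
distribution narrows — the 1D geometry caps clonal spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateSampleError, InsufficientDataError

__all__ = [
    "LatticeParams",
    "LatticeState",
    "default_events_per_cycle",
    "init_lattice",
    "step_cycle",
    "run_lattice",
    "clone_sizes",
    "label_sizes",
    "check_contiguity",
    "neighbor_log_size_correlation",
    "variance_growth_curve",
]

BACKGROUND = 0


def default_events_per_cycle(
    n_sites: int, block_length: int, p_activate: float = 0.1
) -> int:
    """Events per cycle matching the minimal model's per-site activation rate.

    Each event touches ``block_length`` of ``n_sites`` sites, so
    ``round(p_activate * n_sites / block_length)`` events give each site an
    activation probability of about ``p_activate`` per cycle.
    """
    return int(round(p_activate * n_sites / block_length))


@dataclass
class LatticeParams:
    """Ring lattice parameters; ``events_per_cycle=None`` derives the default."""

    n_sites: int
    block_length: int
    events_per_cycle: Optional[int] = None
    site_loss_prob: float = 0.5
    label_density: float = 0.01

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if not 1 <= self.block_length <= self.n_sites:
            raise ValueError("block_length must be in [1, n_sites]")
        if not 0 <= self.site_loss_prob <= 1:
            raise ValueError("site_loss_prob must be a probability")
        if not 0 <= self.label_density <= 1:
            raise ValueError("label_density must be a probability")
        if self.events_per_cycle is None:
            self.events_per_cycle = default_events_per_cycle(
                self.n_sites, self.block_length
            )
        if self.events_per_cycle < 0:
            raise ValueError("events_per_cycle must be >= 0")


@dataclass
class LatticeState:
    """Ring of site labels (0 = untracked background) at a given cycle."""

    labels: np.ndarray
    cycle: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return int(self.labels.size)


def init_lattice(params: LatticeParams, seed: int) -> LatticeState:
    """Label each site independently with ``label_density``; labels unique."""
    rng = np.random.default_rng(seed)
    tracked = rng.random(params.n_sites) < params.label_density
    labels = np.zeros(params.n_sites, dtype=np.int64)
    labels[tracked] = np.arange(1, int(tracked.sum()) + 1)
    return LatticeState(labels=labels, cycle=0)


def _apportion(counts: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder (Hamilton) apportionment of ``total`` slots.

    Ties in the fractional remainders go to the leftmost survivor run.
    """
    quotas = counts * (total / counts.sum())
    base = np.floor(quotas).astype(np.int64)
    remainder = total - int(base.sum())
    if remainder > 0:
        # stable sort on descending fractional part -> leftmost wins ties
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:remainder]] += 1
    return base


def _refill_block(
    block: np.ndarray, survived: np.ndarray, left_label: int, right_label: int
) -> np.ndarray:
    """Refilled labels for one remodelled block (pure function).

    Surviving sites' labels expand proportionally, preserving their
    left-to-right run order; with no survivors the block is recolonised
    ceil(l/2) from the left flank and floor(l/2) from the right flank.
    """
    ell = block.size
    survivors = block[survived]
    if survivors.size == 0:
        n_left = (ell + 1) // 2
        out = np.empty(ell, dtype=np.int64)
        out[:n_left] = left_label
        out[n_left:] = right_label
        return out
    # consecutive runs of equal labels among the survivors, in order
    boundaries = np.nonzero(np.diff(survivors) != 0)[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [survivors.size]))
    run_labels = survivors[starts]
    run_counts = ends - starts
    alloc = _apportion(run_counts, ell)
    return np.repeat(run_labels, alloc)


def _step(labels: np.ndarray, params: LatticeParams, rng: np.random.Generator) -> None:
    """One cycle of remodelling events, in place."""
    L = labels.size
    ell = params.block_length
    offsets = np.arange(ell)
    for _ in range(params.events_per_cycle):
        start = int(rng.integers(L))
        idx = (start + offsets) % L
        block = labels[idx]
        survived = rng.random(ell) >= params.site_loss_prob
        left_label = int(labels[(start - 1) % L])
        right_label = int(labels[(start + ell) % L])
        labels[idx] = _refill_block(block, survived, left_label, right_label)


def step_cycle(state: LatticeState, params: LatticeParams, seed: int) -> LatticeState:
    """Advance one cycle (a fresh state; the input is not modified)."""
    labels = state.labels.copy()
    _step(labels, params, np.random.default_rng(seed))
    return LatticeState(labels=labels, cycle=state.cycle + 1)


def run_lattice(
    params: LatticeParams,
    n_cycles: int,
    seed: int,
    snapshot_every: int = 1,
) -> list[LatticeState]:
    """Simulate ``n_cycles`` cycles; returns snapshots (cycle 0 included)."""
    rng = np.random.default_rng(seed)
    state = init_lattice(params, seed=int(rng.integers(2**31)))
    snapshots = [state]
    labels = state.labels.copy()
    for t in range(1, n_cycles + 1):
        _step(labels, params, rng)
        if t % snapshot_every == 0 or t == n_cycles:
            snapshots.append(LatticeState(labels=labels.copy(), cycle=t))
    return snapshots


def _runs_on_ring(labels: np.ndarray) -> list[tuple[int, int]]:
    """(label, run length) of maximal contiguous runs on the ring, in order."""
    L = labels.size
    if L == 0:
        return []
    boundaries = np.nonzero(np.diff(labels) != 0)[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [L]))
    runs = [(int(labels[s]), int(e - s)) for s, e in zip(starts, ends)]
    if len(runs) > 1 and runs[0][0] == runs[-1][0]:  # wrap-around merge
        runs[0] = (runs[0][0], runs[0][1] + runs[-1][1])
        runs.pop()
    return runs


def clone_sizes(state: LatticeState) -> np.ndarray:
    """Sizes (in MaSC sites) of surviving tracked clones, in ring order."""
    return np.array(
        [n for lab, n in _runs_on_ring(state.labels) if lab != BACKGROUND],
        dtype=np.int64,
    )


def label_sizes(state: LatticeState) -> dict[int, int]:
    """Total sites per tracked label (contiguity makes this the run length)."""
    out: dict[int, int] = {}
    for lab, n in _runs_on_ring(state.labels):
        if lab != BACKGROUND:
            out[lab] = out.get(lab, 0) + n
    return out


def check_contiguity(state: LatticeState) -> bool:
    """True iff every tracked label occupies a single run on the ring."""
    seen: set[int] = set()
    for lab, _ in _runs_on_ring(state.labels):
        if lab == BACKGROUND:
            continue
        if lab in seen:
            return False
        seen.add(lab)
    return True


def neighbor_log_size_correlation(trajectory: Sequence[LatticeState]) -> float:
    """Pearson correlation of ln(size) across clone pairs adjacent at induction.

    Pairs are consecutive tracked clones in ring order at the initial state
    (non-overlapping: 1st with 2nd, 3rd with 4th, ...); only pairs in which
    both clones survive to the final state enter the correlation. Shared
    remodelling events make the expansion of neighbouring clones positively
    correlated, unlike independently drawn sizes.
    """
    if len(trajectory) < 2:
        raise InsufficientDataError("need at least an initial and a final state")
    initial, final = trajectory[0], trajectory[-1]
    order = [lab for lab, _ in _runs_on_ring(initial.labels) if lab != BACKGROUND]
    final_sizes = label_sizes(final)
    pairs = []
    for i in range(0, len(order) - 1, 2):
        a, b = order[i], order[i + 1]
        if a in final_sizes and b in final_sizes:
            pairs.append((final_sizes[a], final_sizes[b]))
    if len(pairs) < 20:
        raise InsufficientDataError(
            f"only {len(pairs)} surviving adjacent pairs (need >= 20)"
        )
    x = np.log([p[0] for p in pairs])
    y = np.log([p[1] for p in pairs])
    if x.std() == 0 or y.std() == 0:
        raise DegenerateSampleError("identical sizes in all pairs; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def variance_growth_curve(
    trajectory: Sequence[LatticeState],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-snapshot variance of ln(size) over surviving tracked clones.

    Returns ``(cycles, variances)``. Early on the variance grows roughly
    linearly per cycle (multiplicative phase); once typical clone sizes reach
    the remodelled-block scale the growth rate collapses (geometric
    suppression by the 1D duct).
    """
    if len(trajectory) < 2:
        raise InsufficientDataError("need a trajectory with >= 2 snapshots")
    cycles, variances = [], []
    for state in trajectory:
        sizes = clone_sizes(state)
        if sizes.size == 0:
            continue
        cycles.append(state.cycle)
        variances.append(float(np.log(sizes).var()))
    return np.array(cycles), np.array(variances)
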