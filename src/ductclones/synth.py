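"""Synthetic confetti datasets with the statistical structure the analysis assumes.

Emulates the study conditions of sparse multicolour lineage tracing in the
mouse mammary gland: recombination in roughly one cell per 100–200 (one per
400 for any single confetti colour), MaSC-descendant units of ~5–10 cells
(so a labelled cell lands in one out of 40–80 units), clone tables sampled
at 14/64/120/225 days post-induction, ~4–7-day oestrous cycles, strong
mouse-to-mouse variability in effective cycle number, and clustered vs
uniform EdU-like proliferation positions along ducts.

Every generator is a pure function of (design, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import COLORS, CloneRecord, CloneTable, DuctalTree, PointPattern1D
from .minimal import MinimalModelParams, simulate

__all__ = [
    "LabellingDesign",
    "PatternDesign",
    "per_color_density",
    "units_per_labelled_cell",
    "generate_clone_table",
    "generate_point_pattern",
    "generate_ductal_tree",
]


@dataclass(frozen=True)
class LabellingDesign:
    """Experimental design of a lineage-tracing cohort.

    Defaults mirror the study conditions: recombination in one cell per 100
    (×4 colours → one per 400 per colour), 5-cell units, observation at
    14/64/120/225 days, ~5.5 days per oestrous cycle.
    """

    recombined_per_cells: int = 100
    n_colors: int = 4
    unit_size_cells: int = 5
    n_mice: int = 6
    glands_per_mouse: int = 3
    timepoints_days: tuple[int, ...] = (14, 64, 120, 225)
    clones_per_gland_at_induction: int = 100
    days_per_cycle: float = 5.5
    side_branch_prob: float = 0.5

    def __post_init__(self):
        for name in (
            "recombined_per_cells",
            "n_colors",
            "unit_size_cells",
            "n_mice",
            "glands_per_mouse",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.clones_per_gland_at_induction < 0:
            raise ValueError("clones_per_gland_at_induction must be >= 0")
        if self.days_per_cycle <= 0:
            raise ValueError("days_per_cycle must be > 0")
        if not 0 <= self.side_branch_prob <= 1:
            raise ValueError("side_branch_prob must be a probability")


@dataclass(frozen=True)
class PatternDesign:
    """Design of a 1D proliferation point pattern (CSR or clustered)."""

    mode: str = "csr"
    domain_length_um: float = 10_000.0
    intensity_per_um: float = 0.05
    cluster_rate_per_um: float = 0.002
    points_per_cluster_mean: float = 8.0
    cluster_sd_um: float = 25.0

    def __post_init__(self):
        if self.mode not in ("csr", "clustered"):
            raise ValueError("mode must be 'csr' or 'clustered'")
        if self.domain_length_um <= 0:
            raise ValueError("domain_length_um must be > 0")
        if self.intensity_per_um < 0 or self.cluster_rate_per_um < 0:
            raise ValueError("intensities must be >= 0")
        if self.points_per_cluster_mean < 0:
            raise ValueError("points_per_cluster_mean must be >= 0")
        if self.mode == "clustered" and self.cluster_sd_um <= 0:
            raise ValueError("clustered mode requires cluster_sd_um > 0")


def per_color_density(design: LabellingDesign) -> int:
    """Cells per single-colour-labelled cell: recombined_per_cells × n_colors.

    One recombined cell per 100 with four confetti colours gives one cell of
    any given colour per 400.
    """
    if design.recombined_per_cells < 1 or design.n_colors < 1:
        raise ValueError("recombined_per_cells and n_colors must be >= 1")
    return design.recombined_per_cells * design.n_colors


def units_per_labelled_cell(design: LabellingDesign) -> float:
    """MaSC-descendant units per single-colour-labelled cell.

    At one labelled cell per 400 and units of 5–10 cells, a confetti label
    lands in one out of 40–80 units.
    """
    if design.unit_size_cells < 1:
        raise ValueError("unit_size_cells must be >= 1")
    return per_color_density(design) / design.unit_size_cells


def generate_clone_table(
    design: LabellingDesign,
    params: MinimalModelParams,
    seed: int,
    genotype: str = "WT",
    lineage: str = "luminal",
    side_branch_loss_delta: float = 0.0,
) -> CloneTable:
    """Simulate a cross-sectional clone table with the minimal model.

    For each mouse a log-normal timescale multiplier (scale
    ``params.mouse_scale_sd``) converts each nominal timepoint into a
    per-mouse effective cycle number; each induced clone (``glands_per_mouse
    × clones_per_gland_at_induction`` per mouse and timepoint) is simulated
    independently and only surviving clones are emitted. Locations are drawn
    with ``design.side_branch_prob``; a non-zero ``side_branch_loss_delta``
    shifts the loss probability of side-branch clones (mutant side-branch
    bias), off by default.
    """
    records: list[CloneRecord] = []
    n_induced = design.glands_per_mouse * design.clones_per_gland_at_induction
    for m in range(design.n_mice):
        mouse_ss = np.random.SeedSequence(entropy=(seed, m))
        mouse_rng = np.random.default_rng(mouse_ss)
        multiplier = (
            float(np.exp(params.mouse_scale_sd * mouse_rng.standard_normal()))
            if params.mouse_scale_sd > 0
            else 1.0
        )
        mouse_id = f"mouse{m:02d}"
        for ti, days in enumerate(design.timepoints_days):
            cycles = int(round(days / design.days_per_cycle * multiplier))
            tp_rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, m, ti)))
            locations = np.where(
                tp_rng.random(n_induced) < design.side_branch_prob,
                "side_branch",
                "main_duct",
            )
            colors = tp_rng.choice(COLORS, size=n_induced)
            glands = tp_rng.integers(design.glands_per_mouse, size=n_induced)
            sim_seed = int(
                np.random.SeedSequence(entropy=(seed, m, ti, 1)).generate_state(1)[0]
                % (2**31)
            )
            if side_branch_loss_delta != 0.0:
                side_params = MinimalModelParams(
                    unit_size=params.unit_size,
                    p_activate=params.p_activate,
                    expansion_factor=params.expansion_factor,
                    loss_prob=min(
                        max(params.loss_prob + side_branch_loss_delta, 0.0), 0.999
                    ),
                    descendant_persistence=params.descendant_persistence,
                    homeostasis=False,
                    mouse_scale_sd=params.mouse_scale_sd,
                    expansion_jitter_sd=params.expansion_jitter_sd,
                )
                final = np.empty(n_induced, dtype=np.int64)
                is_side = locations == "side_branch"
                final[~is_side] = simulate(params, int((~is_side).sum()), cycles, sim_seed).sizes[:, -1]
                final[is_side] = simulate(
                    side_params, int(is_side.sum()), cycles, sim_seed + 1
                ).sizes[:, -1]
            else:
                final = simulate(params, n_induced, cycles, sim_seed).sizes[:, -1]
            for i in np.nonzero(final > 0)[0]:
                records.append(
                    CloneRecord(
                        mouse_id=mouse_id,
                        gland_id=f"{mouse_id}_g{int(glands[i])}",
                        genotype=genotype,
                        lineage=lineage,
                        time_days=int(days),
                        size_cells=int(final[i]),
                        location=str(locations[i]),
                        color=str(colors[i]),
                    )
                )
    provenance = (
        f"synthetic; seed={seed}; genotype={genotype}; lineage={lineage}; "
        f"n_mice={design.n_mice}; timepoints={design.timepoints_days}"
    )
    return CloneTable(records=records, provenance=provenance)


def generate_point_pattern(design: PatternDesign, seed: int) -> PointPattern1D:
    """Homogeneous Poisson (csr) or Poisson-cluster pattern on [0, D].

    Clustered mode: Poisson cluster centres at ``cluster_rate_per_um``,
    Poisson(points_per_cluster_mean) points per centre, Gaussian
    displacements with s.d. ``cluster_sd_um`` truncated to the domain
    (points falling outside are discarded).
    """
    rng = np.random.default_rng(seed)
    D = design.domain_length_um
    if design.mode == "csr":
        n = rng.poisson(design.intensity_per_um * D)
        pts = rng.uniform(0.0, D, n)
    else:
        n_centres = rng.poisson(design.cluster_rate_per_um * D)
        centres = rng.uniform(0.0, D, n_centres)
        counts = rng.poisson(design.points_per_cluster_mean, n_centres)
        pts = np.repeat(centres, counts) + rng.normal(
            0.0, design.cluster_sd_um, int(counts.sum())
        )
        pts = pts[(pts >= 0.0) & (pts <= D)]
    return PointPattern1D(positions=pts, domain_length=D)


def generate_ductal_tree(
    n_levels: int,
    branch_prob: float,
    slots_per_segment: int,
    seed: int,
) -> DuctalTree:
    """Random ductal tree grown from the main duct.

    Each segment below the deepest level bifurcates with ``branch_prob``
    (two children) or elongates (one child); every segment carries
    ``slots_per_segment`` cell slots. ``branch_prob=0`` gives a chain of
    ``n_levels`` segments, ``branch_prob=1`` a perfect binary tree with
    2^n_levels − 1 segments.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if not 0 <= branch_prob <= 1:
        raise ValueError("branch_prob must be a probability")
    rng = np.random.default_rng(seed)
    segments: dict[str, tuple[Optional[str], int]] = {"s0": (None, slots_per_segment)}
    frontier = ["s0"]
    counter = 1
    for _ in range(1, n_levels):
        next_frontier = []
        for sid in frontier:
            n_children = 2 if rng.random() < branch_prob else 1
            for _ in range(n_children):
                child = f"s{counter}"
                counter += 1
                segments[child] = (sid, slots_per_segment)
                next_frontier.append(child)
        frontier = next_frontier
    return DuctalTree(segments=segments)
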