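"""Partially replicated (p-rep) trial design.

Two stages mirror how a national evaluation network assembles its trials:
first genotype packets are allocated to locations (check varieties replicated
everywhere, test genotypes spread as widely as seed allows, second packets
going hierarchically to key locations first), then each location's packets are
arranged on a rectangular row-column grid with two resolvable blocks, improved
by a pairwise-swap search on an A-measure (average pairwise prediction
variance of genotype effects under a working random block/row/column model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AllocationPlan",
    "DesignLayout",
    "InfeasibleAllocationError",
    "allocate_locations",
    "layout_prep",
    "a_measure",
    "percent_replication",
]


class InfeasibleAllocationError(ValueError):
    pass


@dataclass
class AllocationPlan:
    """Genotype packets per location: rows (genotype, location, n_packets in {1, 2})."""

    df: pd.DataFrame

    def packets(self, location: str) -> pd.Series:
        sub = self.df[self.df["location"] == location]
        return sub.set_index("genotype")["n_packets"]


@dataclass
class DesignLayout:
    """A row-column field layout with two blocks.

    ``grid[r, c]`` holds the genotype index planted in row r, column c;
    ``block[r, c]`` in {0, 1}.  ``genotypes`` maps index -> id.
    """

    grid: np.ndarray
    block: np.ndarray
    genotypes: list[str]

    def replication_counts(self) -> np.ndarray:
        return np.bincount(self.grid.ravel(), minlength=len(self.genotypes))

    def validate(self) -> None:
        counts = self.replication_counts()
        if not np.all((counts >= 1) & (counts <= 2)):
            raise ValueError("every genotype must appear 1 or 2 times")
        for g in np.flatnonzero(counts == 2):
            blocks = self.block[self.grid == g]
            if sorted(blocks) != [0, 1]:
                raise ValueError(f"replicated genotype {self.genotypes[g]!r} not resolvable across blocks")

    def to_frame(self, env: str = "") -> pd.DataFrame:
        rows = []
        nr, nc = self.grid.shape
        for r in range(nr):
            for c in range(nc):
                rows.append(
                    {"env": env, "row": r + 1, "col": c + 1,
                     "block": int(self.block[r, c]) + 1,
                     "genotype": self.genotypes[self.grid[r, c]]}
                )
        return pd.DataFrame(rows)


def allocate_locations(
    genotypes: pd.DataFrame,
    locations: dict[str, int],
    key_locations: list[str],
) -> AllocationPlan:
    """Allocate genotype packets to locations.

    ``genotypes`` needs columns genotype and role ("check" or "test").  Checks
    get two packets at every location.  Each test genotype gets one packet per
    location where capacity allows; second packets are then assigned
    hierarchically — key locations first (in the given order), remaining
    capacity round-robin over the other locations in deterministic order.
    """
    unknown = [k for k in key_locations if k not in locations]
    if unknown:
        raise ValueError(f"key locations not in location list: {unknown}")
    checks = list(genotypes.loc[genotypes["role"] == "check", "genotype"])
    tests = list(genotypes.loc[genotypes["role"] == "test", "genotype"])
    for loc, cap in locations.items():
        if cap < 2 * len(checks):
            raise InfeasibleAllocationError(
                f"location {loc!r} capacity {cap} cannot hold two packets of {len(checks)} checks"
            )
    packets = {loc: {g: 2 for g in checks} for loc in locations}
    remaining = {loc: cap - 2 * len(checks) for loc, cap in locations.items()}
    # first packets: spread every test genotype as widely as capacity allows
    for loc in locations:
        for g in tests:
            if remaining[loc] <= 0:
                break
            packets[loc][g] = 1
            remaining[loc] -= 1
    # second packets: key locations first, then round-robin over the rest
    ordered = key_locations + [l for l in locations if l not in key_locations]
    for loc in ordered:
        for g in tests:
            if remaining[loc] <= 0:
                break
            if packets[loc].get(g) == 1:
                packets[loc][g] = 2
                remaining[loc] -= 1
    rows = [
        {"genotype": g, "location": loc, "n_packets": n}
        for loc in locations
        for g, n in packets[loc].items()
    ]
    return AllocationPlan(pd.DataFrame(rows))


def _initial_layout(reps: np.ndarray, n_rows: int, n_cols: int, rng: np.random.Generator):
    """Random feasible start: duplicated genotypes split across the two blocks."""
    n_plots = n_rows * n_cols
    block = np.zeros((n_rows, n_cols), dtype=int)
    block[:, n_cols // 2 :] = 1  # two blocks in the column direction
    size0 = int((block == 0).sum())
    doubles = np.flatnonzero(reps == 2)
    singles = np.flatnonzero(reps == 1)
    if len(doubles) > min(size0, n_plots - size0):
        raise ValueError("more replicated genotypes than plots per block")
    pool0 = list(doubles) + list(rng.permutation(singles)[: size0 - len(doubles)])
    used = set(pool0[len(doubles):])
    pool1 = list(doubles) + [g for g in singles if g not in used]
    pool0 = rng.permutation(pool0)
    pool1 = rng.permutation(pool1)
    grid = np.empty((n_rows, n_cols), dtype=int)
    grid[block == 0] = pool0
    grid[block == 1] = pool1
    return grid, block


def _design_matrices(grid: np.ndarray, block: np.ndarray, n_geno: int):
    n_rows, n_cols = grid.shape
    n = grid.size
    g = grid.ravel()
    r_idx = np.repeat(np.arange(n_rows), n_cols)
    c_idx = np.tile(np.arange(n_cols), n_rows)
    b_idx = block.ravel()
    Xg = np.zeros((n, n_geno))
    Xg[np.arange(n), g] = 1.0
    Zb = np.zeros((n, 2))
    Zb[np.arange(n), b_idx] = 1.0
    Zr = np.zeros((n, n_rows))
    Zr[np.arange(n), r_idx] = 1.0
    Zc = np.zeros((n, n_cols))
    Zc[np.arange(n), c_idx] = 1.0
    return Xg, Zb, Zr, Zc


def a_measure(
    layout: DesignLayout,
    ratios: tuple[float, float, float] = (0.1, 0.1, 0.1),
) -> float:
    """Average pairwise prediction variance of genotype differences.

    Working model: fixed genotype means; random block, row and column effects
    with variance ratios ``ratios = (block, row, col)`` relative to a unit
    residual.  Computed from the generalized inverse of the genotype
    information matrix after projecting out the working random effects.
    Returns +inf (with a warning) for disconnected designs.
    """
    n_geno = len(layout.genotypes)
    Xg, Zb, Zr, Zc = _design_matrices(layout.grid, layout.block, n_geno)
    n = Xg.shape[0]
    V = np.eye(n)
    for Z, gamma in zip((Zb, Zr, Zc), ratios):
        if gamma > 0:
            V += gamma * Z @ Z.T
    Vinv = np.linalg.inv(V)
    C = Xg.T @ Vinv @ Xg
    # pairwise contrast variances need only the generalized inverse
    Cg = np.linalg.pinv(C, rcond=1e-10, hermitian=True)
    d = np.diag(Cg)
    pv = d[:, None] + d[None, :] - 2 * Cg
    iu = np.triu_indices(n_geno, k=1)
    # a degenerate layout (e.g. a genotype with no plot) leaves contrasts
    # inestimable: the information matrix loses rank
    if np.linalg.matrix_rank(C, tol=1e-8) < n_geno:
        warnings.warn("disconnected design: some genotype contrasts are inestimable")
        return float("inf")
    return float(pv[iu].mean())


def layout_prep(
    genotypes: list[str],
    reps: np.ndarray | list[int],
    n_rows: int,
    n_cols: int,
    seed: int = 0,
    n_iter: int = 200,
    ratios: tuple[float, float, float] = (0.1, 0.1, 0.1),
) -> DesignLayout:
    """Build a p-rep row-column layout and improve it by pairwise swaps.

    Starts from a random feasible layout (each duplicated genotype once per
    block) and proposes ``n_iter`` random within-block plot swaps, accepting a
    swap only if it lowers :func:`a_measure` — the criterion never increases.
    ``n_iter = 0`` returns the feasible random start.
    """
    reps = np.asarray(reps, dtype=int)
    if reps.sum() != n_rows * n_cols:
        raise ValueError(
            f"total replications {reps.sum()} != plots {n_rows * n_cols} ({n_rows}x{n_cols})"
        )
    if not np.all((reps == 1) | (reps == 2)):
        raise ValueError("replication targets must be 1 or 2")
    rng = np.random.default_rng(seed)
    grid, block = _initial_layout(reps, n_rows, n_cols, rng)
    layout = DesignLayout(grid, block, list(genotypes))
    layout.validate()
    if n_iter <= 0:
        return layout
    current = a_measure(layout, ratios)
    flat = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    for _ in range(n_iter):
        i1, i2 = rng.choice(len(flat), size=2, replace=False)
        p1, p2 = flat[i1], flat[i2]
        if block[p1] != block[p2] or grid[p1] == grid[p2]:
            continue
        grid[p1], grid[p2] = grid[p2], grid[p1]
        trial = a_measure(layout, ratios)
        if trial < current:
            current = trial
        else:
            grid[p1], grid[p2] = grid[p2], grid[p1]
    layout.validate()
    return layout


def percent_replication(layout: DesignLayout) -> float:
    """100 x (# genotypes with two plots) / (# genotypes)."""
    counts = layout.replication_counts()
    return 100.0 * float((counts == 2).sum()) / float(len(counts))
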