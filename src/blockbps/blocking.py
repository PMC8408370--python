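"""Rectangular blocking strategies over the d x N latent-state index grid.

A blocking strategy is a cover of [d] x [N] (spatial rows, temporal columns)
by axis-aligned rectangles.  Blocks may overlap; the per-coordinate membership
count phi speeds up the flow of coordinates shared between blocks.  Indices
are 1-based inclusive externally (matching the usual i:j x l:m block notation)
and converted to 0-based half-open slices at exactly one boundary
(:meth:`Block.slices`).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import PartitionError, StrategyError

__all__ = [
    "Block",
    "BlockingStrategy",
    "Partition",
    "PartitionSize",
    "make_temporal_strategy",
    "make_spatiotemporal_strategy",
    "compute_phi",
    "neighbors",
    "even_odd_partition",
    "four_clock_partition",
    "validate_partition",
    "min_partition_size",
]


@dataclass(frozen=True)
class Block:
    """A rectangle ``i:j x l:m`` (1-based, inclusive) of the index grid.

    ``row`` refers to the spatial axis (dimension ``d``), ``col`` to the
    temporal axis (length ``N``).
    """

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if not (1 <= self.row_start <= self.row_stop):
            raise StrategyError(f"invalid spatial range {self.row_start}:{self.row_stop}")
        if not (1 <= self.col_start <= self.col_stop):
            raise StrategyError(f"invalid temporal range {self.col_start}:{self.col_stop}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start + 1, self.col_stop - self.col_start + 1)

    @property
    def slices(self) -> tuple[slice, slice]:
        """0-based half-open numpy slices selecting this block's submatrix."""
        return (
            slice(self.row_start - 1, self.row_stop),
            slice(self.col_start - 1, self.col_stop),
        )

    def contains(self, k: int, n: int) -> bool:
        """Membership test for the 1-based coordinate (k, n)."""
        return (
            self.row_start <= k <= self.row_stop
            and self.col_start <= n <= self.col_stop
        )

    def intersects(self, other: "Block") -> bool:
        return (
            self.row_start <= other.row_stop
            and other.row_start <= self.row_stop
            and self.col_start <= other.col_stop
            and other.col_start <= self.col_stop
        )


@dataclass(frozen=True)
class BlockingStrategy:
    """An ordered list of blocks covering the full [d] x [N] grid.

    ``meta`` carries builder information (per-axis widths, overlaps and, for
    grid-structured strategies, each block's (spatial, temporal) grid cell),
    used by partition builders and serialization.
    """

    d: int
    N: int
    blocks: tuple[Block, ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.d < 1 or self.N < 1:
            raise StrategyError("grid shape must be at least 1 x 1")
        for b in self.blocks:
            if b.row_stop > self.d or b.col_stop > self.N:
                raise StrategyError(f"block {b} exceeds the {self.d} x {self.N} grid")
        if not self.blocks:
            raise StrategyError("a blocking strategy needs at least one block")
        # Cover check is O(total block area); cheap at any realistic scale.
        covered = np.zeros((self.d, self.N), dtype=bool)
        for b in self.blocks:
            covered[b.slices] = True
        if not covered.all():
            k, n = np.argwhere(~covered)[0] + 1
            raise StrategyError(f"coordinate ({k},{n}) is not covered by any block")

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self) -> Iterator[Block]:
        return iter(self.blocks)

    @property
    def is_temporal(self) -> bool:
        return all(b.row_start == 1 and b.row_stop == self.d for b in self.blocks)

    def to_json(self) -> str:
        """Serialize as a JSON object of block corner lists."""
        return json.dumps(
            {
                "d": self.d,
                "N": self.N,
                "blocks": [
                    [b.row_start, b.row_stop, b.col_start, b.col_stop]
                    for b in self.blocks
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BlockingStrategy":
        obj = json.loads(text)
        blocks = tuple(Block(*corners) for corners in obj["blocks"])
        return cls(d=obj["d"], N=obj["N"], blocks=blocks)

    def summary(self) -> str:
        phi = compute_phi(self)
        vals, counts = np.unique(phi, return_counts=True)
        hist = ", ".join(f"phi={v}: {c}" for v, c in zip(vals, counts))
        return (
            f"BlockingStrategy({self.d} x {self.N}, {len(self)} blocks; {hist})"
        )


@dataclass(frozen=True)
class Partition:
    """Grouping of a strategy's block indices into sub-strategies.

    Within each group, all blocks must be pairwise disjoint so that their
    velocity updates commute (the even-odd / four-clock assumption).
    """

    groups: tuple[tuple[int, ...], ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"group-{i}" for i in range(len(self.groups)))
            )
        if len(self.labels) != len(self.groups):
            raise PartitionError("labels and groups must have equal length")

    @property
    def K(self) -> int:
        return len(self.groups)


def _axis_starts(length: int, width: int, overlap: int) -> tuple[list[tuple[int, int]], int]:
    """Start/stop pairs (1-based inclusive) for one axis.

    Aligned starts advance by ``stride = width - overlap``.  If the aligned
    blocks fall short of the boundary, a final block is appended ending
    exactly at ``length``: full-width (end-anchored) when overlap > 0, and
    truncated when overlap == 0 so that zero-overlap strategies stay disjoint.
    """
    if width < 1:
        raise StrategyError("width must be >= 1")
    if width > length:
        raise StrategyError(f"width {width} exceeds axis length {length}")
    if not (0 <= overlap < width):
        raise StrategyError(f"overlap must satisfy 0 <= overlap < width, got {overlap}")
    stride = width - overlap
    spans = []
    start = 1
    while start + width - 1 <= length:
        spans.append((start, start + width - 1))
        start += stride
    last_stop = spans[-1][1]
    if last_stop < length:
        if overlap > 0:
            anchored = (length - width + 1, length)
            if anchored != spans[-1]:
                spans.append(anchored)
        else:
            spans.append((last_stop + 1, length))
    return spans, stride


def make_temporal_strategy(d: int, N: int, width: int, overlap: int) -> BlockingStrategy:
    """Temporal strategy of blocks ``1:d x l:m`` with given width and overlap."""
    spans, stride = _axis_starts(N, width, overlap)
    blocks = tuple(Block(1, d, l, m) for l, m in spans)
    meta = {
        "kind": "temporal",
        "t_width": width,
        "t_overlap": overlap,
        "t_stride": stride,
        "grid_shape": (1, len(blocks)),
        "grid_pos": tuple((0, j) for j in range(len(blocks))),
    }
    return BlockingStrategy(d=d, N=N, blocks=blocks, meta=meta)


def make_spatiotemporal_strategy(
    d: int,
    N: int,
    s_width: int,
    t_width: int,
    s_overlap: int = 0,
    t_overlap: int = 0,
) -> BlockingStrategy:
    """Cartesian product of per-axis span grids (each axis end-anchored).

    Block order is row-major: spatial outer, temporal inner, which fixes the
    parity used by partition builders.
    """
    s_spans, s_stride = _axis_starts(d, s_width, s_overlap)
    t_spans, t_stride = _axis_starts(N, t_width, t_overlap)
    blocks = []
    grid_pos = []
    for si, (i, j) in enumerate(s_spans):
        for ti, (l, m) in enumerate(t_spans):
            blocks.append(Block(i, j, l, m))
            grid_pos.append((si, ti))
    meta = {
        "kind": "spatiotemporal",
        "s_width": s_width,
        "t_width": t_width,
        "s_overlap": s_overlap,
        "t_overlap": t_overlap,
        "s_stride": s_stride,
        "t_stride": t_stride,
        "grid_shape": (len(s_spans), len(t_spans)),
        "grid_pos": tuple(grid_pos),
    }
    return BlockingStrategy(d=d, N=N, blocks=tuple(blocks), meta=meta)


def compute_phi(strategy: BlockingStrategy) -> np.ndarray:
    """Per-coordinate block membership counts (integer d x N matrix).

    Every entry is >= 1 because a strategy is a cover; a violation raises
    :class:`StrategyError` (cover is already enforced at construction, so
    this is a defensive re-check for hand-built strategies).
    """
    phi = np.zeros((strategy.d, strategy.N), dtype=np.int64)
    for b in strategy.blocks:
        phi[b.slices] += 1
    if phi.min() < 1:
        raise StrategyError("strategy does not cover the grid")
    return phi


def neighbors(strategy: BlockingStrategy, block_index: int) -> frozenset[int]:
    """Indices of blocks intersecting the given block (including itself)."""
    if not (0 <= block_index < len(strategy)):
        raise IndexError(f"block index {block_index} out of range")
    b = strategy.blocks[block_index]
    return frozenset(
        i for i, other in enumerate(strategy.blocks) if b.intersects(other)
    )


def validate_partition(
    strategy: BlockingStrategy, partition: Partition
) -> tuple[bool, list[str]]:
    """Check the disjointness assumption; return (ok, violation report).

    True iff the groups partition the block index list and every
    within-group pair of blocks is disjoint.
    """
    violations: list[str] = []
    seen = [i for g in partition.groups for i in g]
    if sorted(seen) != list(range(len(strategy))):
        violations.append(
            f"groups do not partition block indices 0..{len(strategy) - 1}"
        )
    for label, group in zip(partition.labels, partition.groups):
        for a, b in itertools.combinations(group, 2):
            if strategy.blocks[a].intersects(strategy.blocks[b]):
                violations.append(
                    f"{label}: blocks {a} and {b} intersect "
                    f"({strategy.blocks[a]} and {strategy.blocks[b]})"
                )
    return (not violations, violations)


def even_odd_partition(strategy: BlockingStrategy) -> Partition:
    """Alternating (odd/even) two-colouring of a temporal strategy.

    Requires that each block intersects only its immediate neighbours in
    block order; otherwise two same-parity blocks would share coordinates
    and a :class:`PartitionError` is raised.
    """
    if not strategy.is_temporal:
        raise PartitionError("even-odd partition requires a temporal strategy")
    odd = tuple(range(0, len(strategy), 2))
    even = tuple(range(1, len(strategy), 2))
    groups = (odd, even) if even else (odd,)
    labels = ("odd", "even")[: len(groups)]
    part = Partition(groups=groups, labels=labels)
    ok, report = validate_partition(strategy, part)
    if not ok:
        raise PartitionError(
            "even-odd partition infeasible (a block intersects a non-adjacent "
            "block): " + "; ".join(report)
        )
    return part


def four_clock_partition(strategy: BlockingStrategy) -> Partition:
    """2x2 checkerboard colouring of a grid-structured spatiotemporal strategy.

    Colour = (spatial parity, temporal parity) of each block's grid cell, so
    diagonal neighbours (overlapping in both axes) receive different colours.
    Requires builder metadata (``grid_pos``).
    """
    grid_pos = strategy.meta.get("grid_pos")
    if grid_pos is None:
        raise PartitionError(
            "four-clock partition requires a grid-structured strategy "
            "(built by make_spatiotemporal_strategy or make_temporal_strategy)"
        )
    groups: list[list[int]] = [[], [], [], []]
    for idx, (si, ti) in enumerate(grid_pos):
        groups[2 * (si % 2) + (ti % 2)].append(idx)
    nonempty = [(lab, g) for lab, g in zip(
        ("even-even", "even-odd", "odd-even", "odd-odd"), groups
    )]
    part = Partition(
        groups=tuple(tuple(g) for _, g in nonempty),
        labels=tuple(lab for lab, _ in nonempty),
    )
    ok, report = validate_partition(strategy, part)
    if not ok:
        raise PartitionError(
            "four-clock partition infeasible (a block intersects a "
            "non-adjacent grid cell): " + "; ".join(report)
        )
    return part


@dataclass(frozen=True)
class PartitionSize:
    """Result of :func:`min_partition_size` with the method flagged."""

    size: int
    exact: bool
    method: str

    def __int__(self) -> int:
        return self.size


def _greedy_coloring(adj: list[set[int]]) -> int:
    colors: dict[int, int] = {}
    for v in range(len(adj)):
        used = {colors[w] for w in adj[v] if w in colors}
        c = 0
        while c in used:
            c += 1
        colors[v] = c
    return max(colors.values()) + 1 if colors else 0


def _exact_chromatic(adj: list[set[int]], lower: int, upper: int) -> int:
    """Smallest k admitting a proper colouring, by backtracking."""
    n = len(adj)
    order = sorted(range(n), key=lambda v: -len(adj[v]))

    def colorable(k: int) -> bool:
        assignment: dict[int, int] = {}

        def place(pos: int) -> bool:
            if pos == n:
                return True
            v = order[pos]
            used = {assignment[w] for w in adj[v] if w in assignment}
            fresh_tried = False
            for c in range(k):
                if c in used:
                    continue
                fresh = c >= len({cc for cc in assignment.values()})
                if fresh and fresh_tried:
                    break  # all so-far-unused colours are interchangeable
                assignment[v] = c
                if place(pos + 1):
                    return True
                del assignment[v]
                if fresh:
                    fresh_tried = True
            return False

        return place(0)

    for k in range(lower, upper):
        if colorable(k):
            return k
    return upper


def min_partition_size(strategy: BlockingStrategy) -> PartitionSize:
    """Smallest feasible number of sub-strategies (chromatic number of the
    block-intersection graph).

    Exact for small strategies (<= 20 blocks, backtracking) or whenever the
    greedy upper bound meets the clique lower bound; otherwise the greedy
    bound is returned and flagged as inexact.  The clique lower bound is the
    maximum of phi: axis-aligned rectangles have the Helly property, so any
    set of pairwise-intersecting blocks shares a common grid point.
    """
    nb = len(strategy)
    adj: list[set[int]] = [set() for _ in range(nb)]
    for a, b in itertools.combinations(range(nb), 2):
        if strategy.blocks[a].intersects(strategy.blocks[b]):
            adj[a].add(b)
            adj[b].add(a)
    clique = int(compute_phi(strategy).max())
    greedy = _greedy_coloring(adj)
    if greedy == clique:
        return PartitionSize(size=greedy, exact=True, method="greedy==clique")
    if nb <= 20:
        exact = _exact_chromatic(adj, clique, greedy)
        return PartitionSize(size=exact, exact=True, method="backtracking")
    return PartitionSize(size=greedy, exact=False, method="greedy")
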