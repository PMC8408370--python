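"""Reference samplers: the global (single-block) and local (factor) BPS.

Both are specializations of the blocked engine.  A single block spanning the
whole grid recovers the standard bouncy particle sampler (phi = 1
everywhere).  The local variant runs on a non-overlapping temporal strategy:
each block's rate uses the block-restricted gradient of the full potential,
which for a Markovian model matches the factor decomposition of the
log-density up to the assignment of boundary transition terms.
"""

from __future__ import annotations

import numpy as np

from .blocking import BlockingStrategy, Block, make_temporal_strategy
from .engine import SamplerConfig, TrajectorySkeleton, simulate_blocked_bps
from .models import PotentialModel

__all__ = ["trivial_strategy", "simulate_global_bps", "simulate_local_bps"]


def trivial_strategy(d: int, N: int) -> BlockingStrategy:
    """The single all-covering block 1:d x 1:N."""
    return BlockingStrategy(
        d=d, N=N, blocks=(Block(1, d, 1, N),),
        meta={"kind": "trivial", "grid_shape": (1, 1), "grid_pos": ((0, 0),)},
    )


def simulate_global_bps(
    model: PotentialModel,
    config: SamplerConfig,
    x0: np.ndarray,
    v0: np.ndarray | None = None,
) -> TrajectorySkeleton:
    """Standard bouncy particle sampler (one block covering everything)."""
    strategy = trivial_strategy(model.d, model.N)
    return simulate_blocked_bps(model, strategy, config, x0, v0)


def simulate_local_bps(
    model: PotentialModel,
    width: int,
    config: SamplerConfig,
    x0: np.ndarray,
    v0: np.ndarray | None = None,
) -> TrajectorySkeleton:
    """Local/factor BPS: non-overlapping temporal blocks of the given width.

    phi is identically one, so the flow is the plain linear flow; the total
    event rate is the sum of the per-factor rates.  If the width does not
    divide N the final block is truncated so the strategy stays disjoint.
    """
    strategy = make_temporal_strategy(model.d, model.N, width=width, overlap=0)
    return simulate_blocked_bps(model, strategy, config, x0, v0)
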