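"""Phase-portrait reconstruction from a scalar signal.

Two reconstructions are provided:

* :func:`derivative_embed` — the pipeline default: the M-dimensional state at
  time index i is ``(s_i, s'_i, s''_i, ...)`` where each derivative is
  estimated by a forward difference of the previous column.  Repeated
  differencing shortens the usable window, so an N-sample signal yields
  exactly N - M + 1 state vectors.

* :func:`delay_embed` — Takens delay embedding for the general case where the
  model order is unknown: the state at index i is
  ``(s_i, s_{i+tau}, ..., s_{i+(m-1)tau})``.

Both return a :class:`PhasePortrait` whose ``time_index`` maps every row back
to the index of its starting sample in the source signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import SignalSeries


@dataclass
class PhasePortrait:
    """Reconstructed M-dimensional state vectors aligned to source indices."""

    vectors: np.ndarray      # (K, M)
    time_index: np.ndarray   # (K,) start index of each row in the source
    order: int
    method: str              # "derivative" | "delay"
    source_name: str
    dt: float = 1.0

    def __post_init__(self):
        if self.vectors.shape != (self.time_index.size, self.order):
            raise ValueError("vectors shape inconsistent with time_index/order")
        if np.any(np.diff(self.time_index) <= 0):
            raise ValueError("time_index must be strictly increasing")

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]


def derivative_embed(signal: SignalSeries, order: int, scale_by_dt: bool = True) -> PhasePortrait:
    """Reconstruct an order-M phase portrait by repeated differentiation.

    Column 1 holds the raw samples; column j+1 is the first forward
    difference of column j, divided by the sampling step when
    ``scale_by_dt`` (so columns are genuine derivative estimates).  All
    columns are truncated to the common length N - M + 1.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    n = len(signal)
    if n < order:
        raise ValueError(f"signal length {n} is smaller than order {order}")
    step = signal.dt if scale_by_dt else 1.0
    cols = [signal.samples]
    for _ in range(order - 1):
        cols.append(np.diff(cols[-1]) / step)
    k = n - order + 1
    vectors = np.column_stack([c[:k] for c in cols])
    return PhasePortrait(vectors=vectors, time_index=np.arange(k), order=order,
                         method="derivative", source_name=signal.name, dt=signal.dt)


def delay_embed(signal: SignalSeries, delay: int, dim: int) -> PhasePortrait:
    """Takens delay embedding: row i = (s_i, s_{i+tau}, ..., s_{i+(m-1)tau})."""
    if delay < 1:
        raise ValueError("delay must be >= 1")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    n = len(signal)
    span = (dim - 1) * delay
    if n < span + 1:
        raise ValueError(
            f"signal length {n} too short for delay {delay}, dim {dim} "
            f"(needs >= {span + 1})")
    k = n - span
    vectors = np.column_stack([signal.samples[j * delay: j * delay + k] for j in range(dim)])
    return PhasePortrait(vectors=vectors, time_index=np.arange(k), order=dim,
                         method="delay", source_name=signal.name, dt=signal.dt)
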