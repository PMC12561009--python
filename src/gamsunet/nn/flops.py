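"""Forward-pass cost metering.

Counting convention ("mac"): convolutions and linear maps contribute one
unit per multiply-accumulate; normalization, activations, pooling,
interpolation and other elementwise work contribute one unit per output
element.  Under the alternative "flop" convention each MAC counts as two
operations.  The meter hooks directly into the executed autodiff
primitives, so the accounting can never drift from the real graph.
"""

from __future__ import annotations

from contextlib import contextmanager

from . import autodiff


class FlopMeter:
    def __init__(self):
        self.macs = 0.0
        self.elementwise = 0.0

    def add(self, kind: str, amount: float) -> None:
        if kind == "mac":
            self.macs += amount
        else:
            self.elementwise += amount

    def total(self, convention: str = "mac") -> float:
        if convention == "mac":
            return self.macs + self.elementwise
        if convention == "flop":
            return 2.0 * self.macs + self.elementwise
        raise ValueError(f"unknown counting convention {convention!r}")


@contextmanager
def count_flops_in(meter: FlopMeter):
    """Attach ``meter`` to all primitives executed inside the block."""
    prev = autodiff._METER
    autodiff._METER = meter
    try:
        yield meter
    finally:
        autodiff._METER = prev
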