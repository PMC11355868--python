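"""Model-complexity accounting: trainable parameters and forward FLOPs.

FLOPs follow the convention of the standard operation-counting profilers:
one fused multiply-add in a dense/convolutional/attention matrix product
counts as one operation; layer normalisation costs 5 operations per
element, inference-mode batch normalisation 2 per element and bilinear
resampling 4 per output element (the profilers' default handler set).
Bias additions, activations and softmax carry no cost and are listed as
uncounted operation types in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .decoder import ESFPNet, build_model
from .nn import Tensor, count_macs, no_grad

__all__ = ["ComplexityReport", "count_parameters", "count_gflops", "profile_model"]

# per-element costs for non-matmul ops (inference mode); anything absent
# from this table is treated as free and reported as uncounted
ELEM_OP_FLOPS = {
    "layer_norm": 5,
    "batch_norm": 2,
    "resize_bilinear": 4,
}


def _counter_flops(counter) -> int:
    return counter.total + sum(
        ELEM_OP_FLOPS.get(op, 0) * n for op, n in counter.elem_ops.items()
    )


@dataclass
class ComplexityReport:
    """Parameter and FLOP totals with a per-component breakdown."""

    variant: str
    input_side: int | None = None
    total_params: int = 0
    params_millions: float = 0.0
    total_flops: int = 0
    gflops: float = 0.0
    breakdown: dict[str, dict[str, float]] = field(default_factory=dict)
    uncounted_ops: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "input_side": self.input_side,
            "total_params": self.total_params,
            "params_millions": self.params_millions,
            "total_flops": self.total_flops,
            "gflops": self.gflops,
            "breakdown": self.breakdown,
            "uncounted_ops": self.uncounted_ops,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def count_parameters(model: ESFPNet, report: ComplexityReport | None = None) -> ComplexityReport:
    """Count trainable parameters; millions are rounded to one decimal."""
    if report is None:
        report = ComplexityReport(variant=getattr(model, "variant", "?"))
    enc = model.encoder.num_parameters()
    dec = model.decoder.num_parameters()
    total = model.num_parameters()
    assert enc + dec == total
    report.total_params = total
    report.params_millions = round(total / 1e6, 1)
    report.breakdown.setdefault("encoder", {})["params"] = enc
    report.breakdown.setdefault("decoder", {})["params"] = dec
    return report


def count_gflops(
    model: ESFPNet, input_side: int = 352, report: ComplexityReport | None = None
) -> ComplexityReport:
    """Count forward-pass MACs for one 3 x side x side frame.

    The model is run in inference mode on a single zero frame; every matrix
    product records its multiply-accumulate count.  Encoder and decoder are
    measured separately so the breakdown sums to the total.
    """
    if report is None:
        report = ComplexityReport(variant=getattr(model, "variant", "?"))
    report.input_side = input_side
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, 3, input_side, input_side), dtype=np.float32))
    from .nn import resize_bilinear

    try:
        with no_grad():
            with count_macs() as enc_counter:
                pyramid = model.encoder(x)
            with count_macs() as dec_counter:
                fmf, _ = model.decoder(pyramid)
                resize_bilinear(fmf, input_side, input_side)
    finally:
        model.train(was_training)
    enc, dec = _counter_flops(enc_counter), _counter_flops(dec_counter)
    report.total_flops = enc + dec
    report.gflops = round((enc + dec) / 1e9, 1)
    report.breakdown.setdefault("encoder", {})["flops"] = enc
    report.breakdown.setdefault("decoder", {})["flops"] = dec
    report.uncounted_ops = sorted(
        op
        for c in (enc_counter, dec_counter)
        for op in c.elem_ops
        if op not in ELEM_OP_FLOPS
    )
    return report


def profile_model(
    variant: str = "S", input_side: int = 352, seed: int = 0
) -> ComplexityReport:
    """Build a randomly initialised model and report params + GFLOPs."""
    model = build_model(variant, seed=seed)
    report = ComplexityReport(variant=model.variant, input_side=input_side)
    count_parameters(model, report)
    count_gflops(model, input_side, report)
    return report
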