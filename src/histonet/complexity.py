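"""Analytic parameter and FLOP accounting over a :class:`NetworkDescription`.

Counting conventions (chosen to match the module-level accounting of the
standard per-layer profilers, and validated against an independent runtime
enumeration of instantiated tensors):

* conv / grouped / pointwise: params ``k_h*k_w*C_in*C_out/groups`` (+``C_out``
  bias); FLOPs ``2 * weight_macs * H_out * W_out`` — bias excluded from FLOPs.
* linear: params ``C_in*C_out + C_out``; FLOPs ``2 * (C_in*C_out + C_out)``.
* batch_norm (affine): params ``2*C``; FLOPs ``2 *`` output elements.
* activation / pool / global_pool: no params; FLOPs ``2 *`` output elements.
* channel_attention: shared no-bias MLP ``C -> C//r -> C``, params ``2*C*h``
  with ``h = C//r``; FLOPs ``2 * (4*C*h + 2*C + 2*h + C)`` (two MLP passes,
  two pooled descriptors, hidden rectifiers, sigmoid).
* spatial_attention: params ``k*k*2 + 1``; FLOPs
  ``2 * (k*k*2 + 2 + 1) * H*W`` (conv, mean/max maps, sigmoid).
* add: free.  The parameter-free split-conv fusion (pooled softmax blend) and
  the multiplicative attention gatings are functional ops and are not counted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

from .arch import ArchConfig, LayerDescriptor, NetworkDescription, build_network

_CONV_KINDS = ("conv", "grouped_conv", "pointwise_conv")


class UnsupportedLayerError(ValueError):
    pass


# ----------------------------------------------------------------- primitives
def layer_parameters(d: LayerDescriptor) -> int:
    if d.kind in _CONV_KINDS:
        kh, kw = d.kernel
        p = kh * kw * d.in_channels * d.out_channels // d.groups
        return p + (d.out_channels if d.has_bias else 0)
    if d.kind == "linear":
        return d.in_channels * d.out_channels + (d.out_channels if d.has_bias else 0)
    if d.kind == "batch_norm":
        return 2 * d.out_channels if d.affine else 0
    if d.kind == "channel_attention":
        return 2 * d.in_channels * d.hidden
    if d.kind == "spatial_attention":
        kh, kw = d.kernel
        return kh * kw * 2 * 1 + (1 if d.has_bias else 0)
    if d.kind in ("activation", "pool", "global_pool", "add"):
        return 0
    raise UnsupportedLayerError(f"unknown layer kind {d.kind!r}")


def layer_flops(d: LayerDescriptor) -> float:
    h, w = d.out_spatial
    elems = d.out_channels * h * w
    if d.kind in _CONV_KINDS:
        kh, kw = d.kernel
        macs = (kh * kw * d.in_channels * d.out_channels // d.groups) * h * w
        return 2.0 * macs
    if d.kind == "linear":
        return 2.0 * (d.in_channels * d.out_channels
                      + (d.out_channels if d.has_bias else 0))
    if d.kind in ("batch_norm", "activation", "pool"):
        return 2.0 * elems
    if d.kind == "global_pool":
        return 2.0 * d.out_channels
    if d.kind == "channel_attention":
        c, hid = d.in_channels, d.hidden
        return 2.0 * (4 * c * hid + 2 * c + 2 * hid + c)
    if d.kind == "spatial_attention":
        kh, kw = d.kernel
        return 2.0 * (kh * kw * 2 + 2 + 1) * h * w
    if d.kind == "add":
        return 0.0
    raise UnsupportedLayerError(f"unknown layer kind {d.kind!r}")


# --------------------------------------------------------------------- totals
def count_parameters(net: NetworkDescription) -> int:
    return sum(layer_parameters(d) for d in net)


def count_flops(net: NetworkDescription, input_size: Optional[int] = None) -> float:
    """Total forward-pass FLOPs in units of 1e9 (multiply and add counted
    separately, i.e. 2x multiply-accumulates for weight layers)."""
    first = next((d for d in net if d.kind in _CONV_KINDS), None)
    if input_size is not None and first is not None:
        expect = input_size // first.stride
        if first.out_spatial != (expect, expect):
            raise ValueError(
                f"description was built for a different input size "
                f"(stem emits {first.out_spatial}, expected {(expect, expect)})"
            )
    return sum(layer_flops(d) for d in net) / 1e9


@dataclass
class ComplexityReport:
    rows: List[Tuple[str, str, int, float]] = field(default_factory=list)
    # (name, kind, params, flops)

    @property
    def total_params(self) -> int:
        return sum(r[2] for r in self.rows)

    @property
    def params_millions(self) -> float:
        return round(self.total_params / 1e6, 2)

    @property
    def flops_giga(self) -> float:
        return round(sum(r[3] for r in self.rows) / 1e9, 2)

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("layer,kind,params,flops\n")
        for name, kind, p, f in self.rows:
            buf.write(f"{name},{kind},{p},{f:.0f}\n")
        return buf.getvalue()


def complexity_report(net: NetworkDescription) -> ComplexityReport:
    return ComplexityReport(
        rows=[(d.name, d.kind, layer_parameters(d), layer_flops(d)) for d in net]
    )


_VARIANT_LABELS = {
    "baseline": "Baseline",
    "res_cba": "ResCBANet",
    "res_sp": "ResSPNet",
    "htrec": "HTRecNet",
}


def complexity_table(cfgs: Iterable[ArchConfig]) -> str:
    """TSV table (Model, Params(M), FLOPs(G)) for a list of variant configs."""
    lines = ["Model\tParams(M)\tFLOPs(G)"]
    for cfg in cfgs:
        net = build_network(cfg).describe()
        p = count_parameters(net) / 1e6
        f = count_flops(net, cfg.input_size)
        label = _VARIANT_LABELS.get(cfg.variant, cfg.variant)
        lines.append(f"{label}\t{p:.2f}\t{f:.2f}")
    return "\n".join(lines) + "\n"


# ------------------------------------------------------------------ calibration
def cbam_parameter_delta(cfg: ArchConfig, reduction: int) -> int:
    """Parameters added by per-block attention at a given reduction ratio."""
    total = 0
    for width, depth in zip(cfg.stage_widths, cfg.stage_depths):
        c = 4 * width
        hidden = c // reduction
        k = cfg.cbam_spatial_kernel
        total += depth * (2 * c * hidden + (k * k * 2 + 1))
    return total


def calibrate_reduction(cfg: ArchConfig, base_params: int, target_millions: float,
                        r_range: Tuple[int, int] = (2, 256)) -> Tuple[Optional[int], dict]:
    """Scan integer reduction ratios for one whose attention-augmented total
    rounds (2 d.p., in millions) to ``target_millions``.

    Returns ``(matching_r_or_None, {r: params_millions})``.  The printed
    complexity table does not state the reduction ratio, so it has to be
    recovered by search; r=42 is the unique match for the default backbone.
    """
    table = {}
    match = None
    for r in range(r_range[0], r_range[1] + 1):
        if 4 * cfg.base_width // r < 1:
            break
        total = base_params + cbam_parameter_delta(cfg, r)
        m = round(total / 1e6, 2)
        table[r] = m
        if m == round(target_millions, 2) and match is None:
            match = r
    return match, table
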