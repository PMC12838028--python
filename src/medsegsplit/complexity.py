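"""Trainable-parameter and MAC accounting per sub-model role.

MACs (multiply-accumulates) use the additive convolution estimator
``k^2 * C_in * C_out * H_out * W_out`` (grouped convolutions divide by the
group count; transpose convolutions count ``k^2 * C_in * C_out * H_in *
W_in``, their exact multiply count).  Elementwise operations, bias
additions and pooling are excluded, consistent with common MAC counters,
so comparisons are apples-to-apples only for convolution-dominated nets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import SplitSegmentationModel, build_model
from .nn.layers import mac_recorder

ROLES = ("FE", "SS", "BE")


def count_params(model: SplitSegmentationModel) -> dict[str, int]:
    """Exact trainable-parameter counts per role, plus the total."""
    out = {role: sum(p.size for p in params.values()) for role, params in model.role_parameters().items()}
    out["total"] = sum(out[r] for r in ROLES)
    return out


def estimate_macs(model: SplitSegmentationModel, input_size: int = 240) -> dict[str, int]:
    """Per-role MACs for one image at ``input_size`` squared, via a probe
    forward pass that records every convolution's output geometry."""
    if input_size % model.pool_factor:
        raise ValueError(
            f"input_size must be divisible by the pooling factor {model.pool_factor}"
        )
    in_ch = getattr(model.fe, "in_channels", 3)
    x = np.zeros((1, in_ch, input_size, input_size), dtype=np.float32)
    out: dict[str, int] = {}
    mac_recorder.start()
    fe_pkt = model.fe.forward(x)
    out["FE"] = mac_recorder.stop()
    mac_recorder.start()
    ss_out = model.ss.forward(fe_pkt.main)
    out["SS"] = mac_recorder.stop()
    mac_recorder.start()
    model.be.forward(ss_out, fe_pkt.side)
    out["BE"] = mac_recorder.stop()
    out["total"] = sum(out[r] for r in ROLES)
    return out


@dataclass
class ComplexityReport:
    """Per-model complexity rows with ratios to an anchor model."""

    table: pd.DataFrame
    anchor: str
    input_size: int


def complexity_table(
    models: dict[str, SplitSegmentationModel],
    anchor: str = "unet",
    input_size: int = 240,
) -> ComplexityReport:
    """Tabulate parameters and MACs per model and role, with each model's
    totals expressed as plain ratios to the anchor model."""
    if anchor not in models:
        raise ValueError(f"anchor model {anchor!r} not among the models")
    rows = []
    for name, model in models.items():
        params = count_params(model)
        macs = estimate_macs(model, input_size)
        row = {"model": name}
        for role in ROLES:
            row[f"params_{role}"] = params[role]
            row[f"macs_{role}"] = macs[role]
        row["params_total"] = params["total"]
        row["macs_total"] = macs["total"]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("model")
    anchor_params = df.loc[anchor, "params_total"]
    anchor_macs = df.loc[anchor, "macs_total"]
    df["tp_ratio_to_anchor"] = (df["params_total"] / anchor_params).round(3)
    df["mac_ratio_to_anchor"] = (df["macs_total"] / anchor_macs).round(3)
    return ComplexityReport(table=df.reset_index(), anchor=anchor, input_size=input_size)


def pinned_unet_params_millions(num_classes: int = 2, base_width: int = 32) -> float:
    """Total trainable parameters of the pinned split UNet, in millions
    rounded to 2 decimals."""
    model = build_model("unet", num_classes=num_classes, base_width=base_width)
    return round(count_params(model)["total"] / 1e6, 2)
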