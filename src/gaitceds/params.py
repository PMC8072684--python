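"""Analytic per-layer parameter accounting.

Counts are computed from the architecture description alone, never from
instantiated weight arrays, so they serve as an independent cross-check
of the training engine's own array-size counter.  Conventions:

* convolution: kH*kW*Cin*Cout weights + Cout biases
* depthwise convolution: kH*kW*C weights + C biases
* batch normalization: 4 per channel (gamma, beta, moving mean, moving
  variance — trainable and moving statistics both counted)
* context encoding layer: K*C codeword entries + K smoothing factors
* dense: in*out weights + out biases
* squeeze-and-excitation: C*(C/r) + C/r + (C/r)*C + C
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ModelConfig, flatten_width, BACKBONE_MAPS


@dataclass
class ParamRow:
    layer: str
    weights: int
    biases: int
    bn: int

    @property
    def total(self) -> int:
        return self.weights + self.biases + self.bn


@dataclass
class ParamReport:
    rows: list[ParamRow]

    @property
    def total(self) -> int:
        return sum(r.total for r in self.rows)

    def as_table(self) -> str:
        lines = [f"{'layer':<12}{'weights':>10}{'biases':>8}{'bn':>8}{'total':>10}"]
        for r in self.rows:
            lines.append(
                f"{r.layer:<12}{r.weights:>10,}{r.biases:>8,}{r.bn:>8,}{r.total:>10,}"
            )
        lines.append(f"{'TOTAL':<12}{'':>10}{'':>8}{'':>8}{self.total:>10,}")
        return "\n".join(lines)

    def as_csv(self) -> str:
        lines = ["layer,weights,biases,bn,total"]
        for r in self.rows:
            lines.append(f"{r.layer},{r.weights},{r.biases},{r.bn},{r.total}")
        lines.append(f"TOTAL,,,,{self.total}")
        return "\n".join(lines)


def count_parameters(cfg: ModelConfig) -> ParamReport:
    """Per-layer parameter counts for a full classifier configuration."""
    rows: list[ParamRow] = []
    in_ch = cfg.input_shape[2]
    c1, c2, c3, c4 = cfg.conv_specs

    def conv_row(spec, cin):
        kh, kw = spec.kernel
        rows.append(ParamRow(spec.name, kh * kw * cin * spec.filters, spec.filters, 0))
        return spec.filters

    ch = conv_row(c1, in_ch)
    rows.append(ParamRow("BN1", 0, 0, 4 * ch))
    ch = conv_row(c2, ch)
    ch = conv_row(c3, ch)
    rows.append(ParamRow("BN2", 0, 0, 4 * ch))
    ch = conv_row(c4, ch)
    rows.append(ParamRow("BN3", 0, 0, 4 * ch))

    c = BACKBONE_MAPS["Conv4"][2]
    if cfg.attention == "ceds":
        k = cfg.ceds.n_codewords
        rows.append(ParamRow("CEL", k * cfg.ceds.codeword_dim, k, 0))
        kh, kw = cfg.ceds.dw_kernel
        rows.append(ParamRow("DWConv", kh * kw * c, c, 0))
        rows.append(ParamRow("AttnBN1", 0, 0, 4 * c))
        rows.append(ParamRow("AttnBN2", 0, 0, 4 * c))
    elif cfg.attention == "se":
        hidden = c // cfg.se_reduction
        rows.append(ParamRow("SE", c * hidden + hidden * c, hidden + c, 0))

    width = flatten_width(cfg)
    rows.append(ParamRow("Head", width * cfg.n_classes, cfg.n_classes, 0))
    return ParamReport(rows=rows)


def average_reduction(ours: list[int], reference: list[int]) -> float:
    """Mean complexity reduction over paired models, in percent (1 d.p.).

    For each pair the reduction is (1 - ours/reference) * 100.
    """
    if len(ours) != len(reference) or not ours:
        raise ValueError("ours and reference must be equal-length non-empty lists")
    if any(r == 0 for r in reference):
        raise ValueError("reference counts must be non-zero")
    vals = [(1.0 - o / r) * 100.0 for o, r in zip(ours, reference)]
    return round(sum(vals) / len(vals), 1)
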