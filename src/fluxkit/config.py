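"""Shared run configuration for the command-line interface.

Every CLI output embeds the configuration that produced it as comment
lines, so any table can be traced back to its solver tolerances, constraint
band, thresholds and seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

from .model import ModelError


@dataclass
class RunConfig:
    lp_tolerance: float = 1e-9
    band: float = 0.05  # relative band on measured exchange rates
    variation_threshold: float = 0.25
    correlated_threshold: float = 0.3
    anti_correlated_threshold: float = -0.3
    seed: int = 0
    outdir: str = "."

    def __post_init__(self):
        if self.lp_tolerance <= 0:
            raise ModelError("lp_tolerance must be > 0")
        if self.band < 0:
            raise ModelError("band must be >= 0")
        if self.variation_threshold < 0:
            raise ModelError("variation_threshold must be >= 0")

    def header_lines(self) -> list[str]:
        items = ", ".join(f"{k}={v}" for k, v in asdict(self).items())
        return [f"fluxkit config: {items}"]
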