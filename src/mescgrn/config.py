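"""Run configuration and reproducibility plumbing.

A :class:`RunConfig` captures everything needed to re-execute a run:
model variant and parameter file, medium preset, simulation sizes, seeds
and the output directory.  Every CLI command writes a JSON manifest next
to its outputs; re-running from the manifest reproduces the files
byte-for-byte because all randomness flows from the recorded seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .network import (
    MediumInputs,
    NetworkModel,
    build_full_network,
    default_params,
    load_model,
    make_variant,
)

__all__ = ["RunConfig", "build_model", "write_manifest", "write_table"]

PRESETS = ("serum", "2i", "2i-unreduced-noise")


@dataclass
class RunConfig:
    preset: str = "serum"
    variant: str | None = None
    params_file: str | None = None
    pd_level: float | None = None
    chiron_level: float | None = None
    n_cells: int = 1000
    repeats: int = 50
    t_end: float = 100.0
    dt: float = 0.01
    seed: int = 0
    outdir: str = "."
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.preset not in PRESETS and (self.pd_level is None or self.chiron_level is None):
            raise ValueError(
                f"preset must be one of {PRESETS} or explicit --pd/--chiron levels given"
            )
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.dt <= 0 or self.t_end < self.dt:
            raise ValueError("require dt > 0 and t_end >= dt")


def build_model(cfg: RunConfig) -> NetworkModel:
    """Materialise the network described by a run configuration."""
    cfg.validate()
    params = default_params() if cfg.params_file is None else None
    if cfg.params_file is not None:
        import yaml

        with open(cfg.params_file) as fh:
            params = yaml.safe_load(fh)

    if cfg.pd_level is not None and cfg.chiron_level is not None:
        model = build_full_network(
            params, inputs=MediumInputs(cfg.pd_level, cfg.chiron_level)
        )
    elif cfg.preset == "serum":
        model = build_full_network(params, inputs=MediumInputs.serum())
    elif cfg.preset == "2i":
        model = build_full_network(params, inputs=MediumInputs.two_i())
        model.noise["NANOG"] *= 0.8
        model.variant_tag = "full/2i"
    else:  # 2i-unreduced-noise
        level = float(
            (params.get("variant_params", {}) or {}).get("two_i_unreduced_input", 3.6)
        )
        model = build_full_network(params, inputs=MediumInputs.two_i(level))
        model.variant_tag = "full/2i-unreduced-noise"
    if cfg.variant:
        model = make_variant(model, cfg.variant)
    return model


def write_manifest(cfg: RunConfig, outputs: list[str], path: Path) -> None:
    manifest = {
        "tool": "mescgrn",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
        "config": asdict(cfg),
        "outputs": outputs,
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
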