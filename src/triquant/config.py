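"""Run configuration for the command-line workflows.

A flat set of keys mirroring the knobs of the pipeline: seed, noise
level, spectral windows, measurement wavelengths, design level sets and
ANN hyperparameters.  Configs load from YAML; CLI flags override file
values.  Every report written by the CLI embeds the config hash and seed
so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ann import AnnHyper
from .design import DEFAULT_LEVELS
from .spectra import ANN_WINDOW, PLATEAU_WINDOW, SpectralWindow

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    noise_sd_au: float = 0.0
    window: SpectralWindow = field(default_factory=lambda: ANN_WINDOW)
    plateau: SpectralWindow = field(default_factory=lambda: PLATEAU_WINDOW)
    wavelengths: dict = field(
        default_factory=lambda: {"aml_nm": 359.0, "hct_nm": 315.0, "iso_nm": 260.5})
    design_levels: dict = field(default_factory=lambda: dict(DEFAULT_LEVELS))
    ann: AnnHyper = field(default_factory=AnnHyper)
    outdir: str = "triquant_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = [self.window.start_nm, self.window.end_nm, self.window.closed]
        d["plateau"] = [self.plateau.start_nm, self.plateau.end_nm, self.plateau.closed]
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the scientifically meaningful settings (the output
        directory does not change any number, so it is excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key in ("window", "plateau"):
            if key in kwargs and not isinstance(kwargs[key], SpectralWindow):
                vals = kwargs[key]
                kwargs[key] = SpectralWindow(float(vals[0]), float(vals[1]),
                                             bool(vals[2]) if len(vals) > 2 else True)
        if "ann" in kwargs and not isinstance(kwargs["ann"], AnnHyper):
            kwargs["ann"] = AnnHyper(**kwargs["ann"])
        if "design_levels" in kwargs:
            kwargs["design_levels"] = {
                k: tuple(float(x) for x in v)
                for k, v in kwargs["design_levels"].items()
            }
        return cls(**kwargs)
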