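"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .synthetic import GeneratorConfig


@dataclass
class InputPaths:
    """Paths to pre-existing delimited-text inputs."""

    cohort: str
    features: str
    exposures: str | None = None
    manifest: str | None = None
    catalogue: str | None = None


@dataclass
class RunConfig:
    """Full-run configuration.

    Exactly one of ``inputs`` (paths to CSV tables) or ``generator``
    (synthetic-cohort settings) must be provided. ``mode`` selects
    full-sample ("pooled") vs per-fold ("strict") residualization;
    confound sets are explicit and default to the reference analysis
    (height+weight for the feature model; age+height+weight for the
    association stages).
    """

    outdir: str = "heartage_run"
    seed: int = 0
    k: int = 10
    mode: str = "pooled"
    bias_mode: str = "nested"
    alpha: float = 0.05
    feature_confounds: tuple[str, ...] = ("height", "weight")
    association_confounds: tuple[str, ...] = ("height", "weight", "age")
    inputs: InputPaths | None = None
    generator: GeneratorConfig | None = None
    run_profile: bool = True
    run_phewas: bool = True

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.generator is None):
            raise ValueError("provide exactly one of inputs= or generator=")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.mode not in ("pooled", "strict"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.bias_mode not in ("nested", "in_sample"):
            raise ValueError(f"unknown bias_mode {self.bias_mode!r}")

    def subseed(self, name: str) -> int:
        """Named sub-seed derived from the master seed.

        A fixed name registry keeps stages re-runnable in isolation:
        the same master seed always yields the same sub-seed per stage.
        """
        names = ("generate", "folds_female", "folds_male", "extra")
        if name not in names:
            raise KeyError(f"unknown seed stream {name!r}")
        child = np.random.SeedSequence(self.seed).spawn(len(names))[names.index(name)]
        return int(child.generate_state(1)[0] % (2**31))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "inputs" in raw and raw["inputs"] is not None:
            raw["inputs"] = InputPaths(**raw["inputs"])
        if "generator" in raw and raw["generator"] is not None:
            gen = dict(raw["generator"])
            for key in ("age_range", "feature_age_loading_range", "confound_loading_range"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            raw["generator"] = GeneratorConfig(**gen)
        for key in ("feature_confounds", "association_confounds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.generator is not None:
            d["generator"].pop("catalogue", None)
        return d
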