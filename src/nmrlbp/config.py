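"""Run configuration: one YAML file mapped 1:1 onto the stage specs.

All randomness flows from the single top-level ``seed``: each stage draws
its own seed from a named ``SeedSequence`` child so stages are independently
reproducible (``derive_seed``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from .classify import ClassifierSpec
from .errors import ParameterError
from .imaging import RenderSpec
from .preprocess import SOLVENT_EXCLUSIONS, PreprocessSpec
from .synth import Peak, SynthParams
from .texture import LBPConfig

# fixed per-stage indices for seed derivation
_STAGES = {"synth": 0, "folds": 1, "classifier": 2, "cluster": 3, "projection": 4}


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    if stage not in _STAGES:
        raise ParameterError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    synth: SynthParams = field(default_factory=SynthParams)
    preprocess: PreprocessSpec = field(
        default_factory=lambda: PreprocessSpec(exclusions=SOLVENT_EXCLUSIONS)
    )
    render: RenderSpec = field(default_factory=RenderSpec)
    lbp: LBPConfig = field(default_factory=LBPConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    cv_k: int = 5
    seed: int = 101
    outdir: Path = Path("nmrlbp_out")

    def __post_init__(self) -> None:
        if self.cv_k < 2:
            raise ParameterError(f"cv_k must be >= 2, got {self.cv_k}")
        self.outdir = Path(self.outdir)

    def with_seed(self, seed: int) -> "RunConfig":
        """Propagate a new top-level seed into the seeded sub-specs."""
        cfg = replace(
            self,
            seed=seed,
            synth=replace(self.synth, seed=derive_seed(seed, "synth")),
            classifier=replace(self.classifier, seed=derive_seed(seed, "classifier")),
        )
        return cfg

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, Peak):
                return [obj.center, obj.width, obj.amplitude]
            if hasattr(obj, "__dataclass_fields__"):
                return {f.name: plain(getattr(obj, f.name)) for f in fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [plain(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            return obj

        return {
            "synth": plain(self.synth),
            "preprocess": {
                "crop": [self.preprocess.crop.lo, self.preprocess.crop.hi],
                "exclusions": [[e.lo, e.hi] for e in self.preprocess.exclusions],
            },
            "render": plain(self.render),
            "lbp": plain(self.lbp),
            "classifier": plain(self.classifier),
            "cv_k": self.cv_k,
            "seed": self.seed,
            "outdir": str(self.outdir),
        }


def _build(cls, d: dict, **coerce):
    valid = {f.name for f in fields(cls)}
    unknown = set(d) - valid
    if unknown:
        raise ParameterError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kw = dict(d)
    for k, fn in coerce.items():
        if k in kw:
            kw[k] = fn(kw[k])
    return cls(**kw)


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d or {})
    kw: dict = {}
    if "synth" in d:
        sd = dict(d.pop("synth"))
        kw["synth"] = _build(
            SynthParams,
            sd,
            axis_range=tuple,
            sugar_region=tuple,
            peaks=lambda ps: tuple(Peak(*p) for p in ps),
        )
    if "preprocess" in d:
        pd_ = dict(d.pop("preprocess"))
        kw["preprocess"] = PreprocessSpec(
            crop=tuple(pd_.get("crop", (0.50, 9.50))),
            exclusions=tuple(tuple(e) for e in pd_.get("exclusions", [])),
        )
    if "render" in d:
        kw["render"] = _build(RenderSpec, dict(d.pop("render")))
    if "lbp" in d:
        kw["lbp"] = _build(LBPConfig, dict(d.pop("lbp")))
    if "classifier" in d:
        kw["classifier"] = _build(ClassifierSpec, dict(d.pop("classifier")))
    for key in ("cv_k", "seed", "outdir"):
        if key in d:
            kw[key] = d.pop(key)
    if d:
        raise ParameterError(f"unknown config keys: {sorted(d)}")
    return RunConfig(**kw)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})
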