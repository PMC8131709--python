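"""Run configuration with strict schema validation.

A run is described by a nested YAML document with blocks ``acoustics``,
``simulate``, ``nfd``, ``cv``, ``forest``, ``paths`` and a top-level
``seed``.  Unknown keys are rejected so that a typo cannot silently fall
back to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcousticsConfig(_Strict):
    f_start: float = 90e3
    f_end: float = 170e3
    nominal_f: float = 120e3
    pulse_duration: float = 0.512e-3
    sample_rate: float = 1.5e6
    ramp_wavelengths: int = 2
    sound_speed: float = 1450.0


class SimulateConfig(_Strict):
    responses_per_target: int = 10
    n_train_stickleback: int = 74
    n_train_whitefish: int = 66
    n_test_stickleback: int = 27
    n_test_whitefish: int = 20
    train_days: tuple[int, int] = (1, 3)
    test_day: int = 2
    noise_sd: float = 0.005
    acoustic_chain: bool = True
    identical_species: bool = False


class NFDConfigBlock(_Strict):
    n_bands: int = 8
    min_depth_db: float = 3.0


class CVConfigBlock(_Strict):
    n_repeats: int = 30
    holdout_fraction_of_fish: float = Field(0.10, gt=0.0, lt=1.0)
    stratify_by_species: bool = True


class ForestConfigBlock(_Strict):
    n_trees: int = 5000
    m_try: int | None = None


class PathsConfig(_Strict):
    output_dir: str = "echospecies_out"


class RunConfig(_Strict):
    seed: int = 0
    acoustics: AcousticsConfig = AcousticsConfig()
    simulate: SimulateConfig = SimulateConfig()
    nfd: NFDConfigBlock = NFDConfigBlock()
    cv: CVConfigBlock = CVConfigBlock()
    forest: ForestConfigBlock = ForestConfigBlock()
    paths: PathsConfig = PathsConfig()

    def chirp_config(self):
        from .pulse import ChirpConfig

        a = self.acoustics
        return ChirpConfig(
            f_start=a.f_start, f_end=a.f_end, nominal_f=a.nominal_f,
            pulse_duration=a.pulse_duration, sample_rate=a.sample_rate,
            ramp_wavelengths=a.ramp_wavelengths,
        )

    def mesocosm_design(self):
        from .simulate import MesocosmDesign

        s = self.simulate
        return MesocosmDesign(
            responses_per_target=s.responses_per_target,
            n_train_stickleback=s.n_train_stickleback,
            n_train_whitefish=s.n_train_whitefish,
            n_test_stickleback=s.n_test_stickleback,
            n_test_whitefish=s.n_test_whitefish,
            train_days=tuple(s.train_days),
            test_day=s.test_day,
            seed=self.seed,
            noise_sd=s.noise_sd,
            acoustic_chain=s.acoustic_chain,
        )

    def forest_config(self):
        from .classify import ForestConfig

        return ForestConfig(
            n_trees=self.forest.n_trees, m_try=self.forest.m_try, seed=self.seed
        )

    def cv_config(self):
        from .classify import CVConfig

        return CVConfig(
            n_repeats=self.cv.n_repeats,
            holdout_fraction_of_fish=self.cv.holdout_fraction_of_fish,
            stratify_by_species=self.cv.stratify_by_species,
            seed=self.seed,
        )

    def nfd_config(self):
        from .features import NFDConfig

        return NFDConfig(n_bands=self.nfd.n_bands, min_depth_db=self.nfd.min_depth_db)


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load a YAML run configuration; missing file means all defaults."""
    if path is None:
        config = RunConfig()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        config = RunConfig.model_validate(raw)
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    return config


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a configuration, for run logs."""
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
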