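"""Run configuration: one validated, serializable object driving the pipeline.

Every pipeline run writes its resolved configuration next to its outputs so
any output file can be regenerated byte-identically from config + seed.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .phenotype import PHENOTYPES, Phenotype
from .popsim import OBSERVED_PK, PREDICTED_PK


class PKTargets(BaseModel):
    """Per-phenotype calibration target: population means of CL/F (L/h),
    AUC(0−∞) (µg·h/mL) and Cmax (ng/mL)."""

    mean_cl: float = Field(gt=0)
    mean_auc: float = Field(gt=0)
    mean_cmax: float = Field(gt=0)


class Design(BaseModel):
    n_trials: int = Field(gt=0)
    n_per_trial: int = Field(gt=0)


class RunConfig(BaseModel):
    dose_mg: float = 600.0
    sampling_times_h: list[float] = [2.0, 4.0, 8.0, 12.0, 24.0]
    dense_grid_h: tuple[float, float, float] = (0.0, 72.0, 0.5)  # start, stop, step

    bin_width: float = 100.0
    smoothing: float = 0.5
    guard_bins: int = 2
    priors: Optional[dict[str, float]] = None  # None → uniform

    train_design: Design = Design(n_trials=10, n_per_trial=500)  # per phenotype
    verify_design: Design = Design(n_trials=10, n_per_trial=30)  # per phenotype
    blinded_n: int = 100
    #: Printed population phenotype frequencies (percent; normalized on use —
    #: the published triple sums to 110).
    phenotype_frequencies: dict[str, float] = {"EM": 46.0, "IM": 38.0, "PM": 26.0}

    calibration_targets: dict[str, PKTargets] = {
        ph.value: PKTargets(**PREDICTED_PK[ph]) for ph in PHENOTYPES
    }
    observed_reference: Optional[dict[str, PKTargets]] = {
        ph.value: PKTargets(**OBSERVED_PK[ph]) for ph in PHENOTYPES
    }

    cv_v: float = 0.25
    cv_ka: float = 0.30
    mean_ka: float = 0.6

    target_phenotype: str = "PM"
    seed: int = 12345
    outdir: Path = Path("efvbayes_run")

    @field_validator("sampling_times_h")
    @classmethod
    def _times_nonempty(cls, v):
        if not v:
            raise ValueError("sampling_times_h must be non-empty")
        return sorted(float(t) for t in v)

    @model_validator(mode="after")
    def _check_tokens(self):
        Phenotype(self.target_phenotype)
        for key in list(self.phenotype_frequencies) + list(self.calibration_targets):
            Phenotype(key)
        if sum(self.phenotype_frequencies.values()) <= 0:
            raise ValueError("phenotype_frequencies must have positive total")
        return self

    # ------------------------------------------------------------------
    def normalized_frequencies(self) -> dict[Phenotype, float]:
        total = sum(self.phenotype_frequencies.values())
        return {
            Phenotype(ph): w / total for ph, w in self.phenotype_frequencies.items()
        }

    def dense_times(self) -> list[float]:
        start, stop, step = self.dense_grid_h
        out, t = [], start
        while t <= stop + 1e-9:
            out.append(round(t, 6))
            t += step
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path | None = None) -> str:
        data = self.model_dump(mode="json")
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text
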