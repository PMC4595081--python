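"""Run configuration: every tunable parameter with its frozen default.

All detector and analytics parameters live in one dataclass that
round-trips losslessly through a YAML file, so a recorded configuration
fully reproduces a run.  The defaults were calibrated once on the synthetic
renderer and are not tuned per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .coarse import CoarseModelParams
from .fine import FineModelParams


@dataclass
class RunConfig:
    # geometry
    worm_width: float = 12.0        # px
    worm_length: float = 144.0      # px
    coarse_unit: int = 3            # px per coarse cell (~ width / 4)
    # edge and feature extraction
    edge_threshold: float = 5.0     # intensity difference
    feature_threshold_frac: float = 0.55
    head_threshold_frac: float = 0.7
    # coarse model
    p_high: float = 0.6
    p_med: float = 0.35
    p_low: float = 0.002
    length_prior_precision: float = 4.0   # A
    turn_penalty: float = 0.5
    alpha: float = 3.0
    head_stop: int = 2
    body_stop: int = 3
    max_candidates: int = 64
    # fine model
    p_obj: float = 0.75
    p_bg: float = 0.10
    orientation_prior_precision: float = 4.0   # B
    corridor_halfwidth: float | None = 5.0     # px (None: worm_width / 2)
    n_midline_points: int = 21
    # analytics
    coil_fraction: float = 0.05
    coil_exclusion_frac: float = 0.15
    locomotion_window_s: float = 2.0
    kmeans_k: int = 50
    kmeans_redundancy: int = 5
    fps: float = 10.0
    # orchestration
    seed: int = 0
    workers: int = 1

    def coarse_params(self) -> CoarseModelParams:
        return CoarseModelParams(
            p_high=self.p_high, p_med=self.p_med, p_low=self.p_low,
            lam=self.worm_length / self.coarse_unit,
            A=self.length_prior_precision, turn_penalty=self.turn_penalty,
            alpha=self.alpha, head_stop=self.head_stop,
            body_stop=self.body_stop, max_candidates=self.max_candidates)

    def fine_params(self) -> FineModelParams:
        return FineModelParams(
            p_obj=self.p_obj, p_bg=self.p_bg,
            B=self.orientation_prior_precision,
            corridor_halfwidth=self.corridor_halfwidth)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
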