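"""Run-wide configuration.

Defaults are the protocol's standard parameters: 200-nt folding windows
with a 150-nt maximum pair span, 50-nt co-occurrence windows spanning 200 nt
on either side of a site, 1000 permutations / 1000 sampled structures, a
5-bp reverse-complementarity filter, a 0.1 stem-score cutoff, q < 0.01
interaction calls, top/bottom-500 extreme labelling and 10x10-fold CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml


@dataclass
class RunConfig:
    window_length: int = 200        # -W: local folding window (nt)
    max_pair_span: int = 150        # -L: maximal base-pair span (nt)
    window_step: int = 1            # stride between folding-window starts
    cooccur_window: int = 50        # co-occurrence window size (nt)
    cooccur_span: int = 200         # span covered on either side of a site (nt)
    n_permutations: int = 1000
    n_structure_samples: int = 1000
    min_bp: int = 5                 # reverse-complementarity filter
    stem_score_threshold: float = 0.1
    q_alpha: float = 0.01
    extremes_k: int = 500
    cv_folds: int = 10
    cv_repeats: int = 10
    seed: int = 0
    temperature_weight: float = 1.0   # Boltzmann weight exp(pairs / tw)
    motif_similarity_threshold: float = 0.8
    flank_length: int = 200
    expressed_factors: list[str] | None = None
    excluded_transcripts: list[str] | None = None

    def __post_init__(self) -> None:
        for name in (
            "window_length", "max_pair_span", "cooccur_window", "cooccur_span",
            "n_permutations", "n_structure_samples", "min_bp", "extremes_k",
            "cv_folds", "cv_repeats", "window_step",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.q_alpha < 1):
            raise ValueError("q_alpha must be in (0,1)")
        if self.stem_score_threshold < 0:
            raise ValueError("stem_score_threshold must be >= 0")
        if self.cooccur_span % self.cooccur_window != 0:
            raise ValueError("cooccur_span must be divisible by cooccur_window")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent stream per (seed, stage-name)."""
        digest = np.frombuffer(stage.encode(), dtype=np.uint8)
        return np.random.default_rng([self.seed, *digest.tolist()])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
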