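"""Run configuration and seed management.

All tunable constants of the analysis live in :class:`RunConfig`: the lag
order of the vector autoregression, the prevalence cutoff for retaining a
genus, the bounds of the zero-replacement draw, the strong-coefficient
percentile, the short/long timescale windows, and the penalty-grid geometry
for LASSO selection.  Every source of randomness in a run derives from the
single master ``seed`` through :meth:`RunConfig.seed_for`, so each stage is
independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np


@dataclass
class RunConfig:
    lags: int = 20
    prevalence_threshold: float = 0.90
    impute_lo: float = 1e-5
    impute_hi: float = 1e-3
    strong_percentile: float = 5.0
    short_range: tuple[int, int] = (1, 5)
    long_range: tuple[int, int] = (15, 20)
    alpha: float = 0.05
    lambda_grid_size: int = 50
    lambda_ratio: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        self.short_range = tuple(int(v) for v in self.short_range)
        self.long_range = tuple(int(v) for v in self.long_range)
        self.validate()

    def validate(self) -> None:
        if not (0 < self.prevalence_threshold <= 1):
            raise ValueError("prevalence_threshold must be in (0, 1]")
        if not (0 < self.impute_lo < self.impute_hi < 1):
            raise ValueError("require 0 < impute_lo < impute_hi < 1")
        if self.lags < 1:
            raise ValueError("lags must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.lambda_grid_size < 1 or self.lambda_ratio <= 1:
            raise ValueError("need lambda_grid_size >= 1 and lambda_ratio > 1")
        for name, (lo, hi) in (("short_range", self.short_range),
                               ("long_range", self.long_range)):
            if not (1 <= lo <= hi <= self.lags):
                raise ValueError(f"{name} must be a sub-interval of [1, lags]")
        s, l = self.short_range, self.long_range
        if max(s[0], l[0]) <= min(s[1], l[1]):
            raise ValueError("short_range and long_range must be disjoint")

    def seed_for(self, stage: str, index: int = 0) -> int:
        """Derive a stage-specific 31-bit seed from the master seed.

        The mapping is a fixed hash of (master seed, stage name, index); it
        does not depend on call order, so stages can be re-run in isolation.
        """
        key = f"{self.seed}:{stage}:{index}".encode()
        return zlib.crc32(key) & 0x7FFFFFFF

    def rng_for(self, stage: str, index: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed_for(stage, index))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a plain-text key-value config (one ``key value`` or
        ``key = value`` pair per line; ``#`` starts a comment)."""
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace("=", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'key value'")
            key, vals = parts[0], parts[1:]
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            if key in ("short_range", "long_range"):
                kwargs[key] = tuple(int(v) for v in vals[:2])
            elif key in ("lags", "lambda_grid_size", "seed"):
                kwargs[key] = int(vals[0])
            else:
                kwargs[key] = float(vals[0])
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                lines.append(f"{f.name} {v[0]} {v[1]}")
            else:
                lines.append(f"{f.name} {v}")
        Path(path).write_text("\n".join(lines) + "\n")
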