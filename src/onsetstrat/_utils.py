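"""Shared helpers: seeding, validation, small numeric utilities."""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic child seed for a named stage of a run.

    The stage name is hashed (CRC32) so adding a new stage never perturbs the
    streams of existing stages.
    """
    return np.random.SeedSequence([int(master_seed) % (2**31), zlib.crc32(stage.encode())])


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


def check_probability(name: str, value: float, open_interval: bool = True) -> float:
    value = float(value)
    ok = (0.0 < value < 1.0) if open_interval else (0.0 <= value <= 1.0)
    if not ok:
        bounds = "(0, 1)" if open_interval else "[0, 1]"
        raise ValueError(f"{name} must be in {bounds}, got {value!r}")
    return value


def as_1d_float(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr
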