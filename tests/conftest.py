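"""Shared fixtures: small synthetic datasets built from package primitives."""

import numpy as np
import pytest

from dtwsom.simulate import apply_warp

T_SHORT = 144  # one day at 10-minute resolution


def gaussian_bump(T: int, centre: float, width: float,
                  height: float = 1.0) -> np.ndarray:
    t = np.arange(T)
    return height * np.exp(-0.5 * ((t - centre) / width) ** 2)


def warped_impulse_dataset(seed: int, n_days: int = 40, T: int = T_SHORT,
                           warp: float = 12.0, noise_sd: float = 0.02
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Days that are random monotone warps of one mid-day impulse prototype."""
    proto = gaussian_bump(T, T / 2, 5.0)
    rng = np.random.default_rng(seed)
    X = np.vstack([
        apply_warp(proto, warp, int(rng.integers(2 ** 31)))
        + rng.normal(0.0, noise_sd, T)
        for _ in range(n_days)])
    return X, proto


def seasonal_prototypes(T: int = T_SHORT) -> list[np.ndarray]:
    """Three smooth noon-peaked diurnal curves with season-like level shifts,
    on the 20:00-anchored grid, values roughly in [0, 1]."""
    step = 1440.0 / T
    clock = (1200 + np.arange(T) * step) % 1440
    phase = np.pi * (clock - 360) / 720
    diurnal = np.where((clock >= 360) & (clock <= 1080),
                       np.clip(np.sin(phase), 0, None), 0.0)
    return [base + amp * diurnal
            for base, amp in ((0.10, 0.20), (0.35, 0.35), (0.55, 0.40))]


def warped_prototype_dataset(seed: int, n_days: int = 200, T: int = T_SHORT,
                             warp: float = 12.0, noise_sd: float = 0.02
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Days drawn from three seasonal prototypes, each randomly warped."""
    protos = seasonal_prototypes(T)
    rng = np.random.default_rng(seed)
    which = rng.integers(0, len(protos), size=n_days)
    X = np.vstack([
        apply_warp(protos[k], warp, int(rng.integers(2 ** 31)))
        + rng.normal(0.0, noise_sd, T)
        for k in which])
    return X, which


@pytest.fixture
def rng():
    return np.random.default_rng(42)
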