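"""Shared fixtures: small synthetic datasets and hand-built toys.

All fixture datasets use short gesture holds so the suite stays fast; the
generator's default 15–25 s holds are exercised explicitly where the
protocol arithmetic depends on them.
"""

from __future__ import annotations

import numpy as np
import pytest

from fmg_chansel import FMGDataset, GeneratorConfig, generate_dataset
from fmg_chansel.dataio import GESTURES


def make_gesture_coded_dataset(
    n_channels: int,
    coding_channels: dict[int, float],
    noise: float = 0.05,
    n_reps: int = 5,
    samples_per_gesture: int = 30,
    seed: int = 0,
    base: float = 5.0,
) -> FMGDataset:
    """Hand-built dataset where chosen channels equal gesture index × gain.

    ``coding_channels`` maps channel index → gain (channel carries
    ``base + gain * gesture_index``) or → a callable of the gesture index
    (channel carries ``base + f(gesture_index)``); all other channels are
    pure noise around ``base``.  Perfectly separable for gain ≫ noise.
    """
    rng = np.random.default_rng(seed)
    blocks, gests, reps, times = [], [], [], []
    for r in range(1, n_reps + 1):
        t0 = 0.0
        for gi, g in enumerate(GESTURES):
            block = base + rng.normal(0, noise, size=(samples_per_gesture, n_channels))
            for c, gain in coding_channels.items():
                block[:, c] += gain(gi) if callable(gain) else gain * gi
            blocks.append(block)
            gests.extend([g] * samples_per_gesture)
            reps.extend([r] * samples_per_gesture)
            times.append(t0 + np.arange(samples_per_gesture) / 10.0)
            t0 += samples_per_gesture / 10.0
    return FMGDataset(
        values=np.clip(np.vstack(blocks), 0, None),
        gesture=np.array(gests, dtype=object),
        repetition=np.array(reps, dtype=int),
        time_s=np.concatenate(times),
        channel_ids=tuple(f"ch{i:02d}" for i in range(n_channels)),
    )


@pytest.fixture(scope="session")
def small_synth():
    """12-channel generated dataset with planted truth (short holds)."""
    cfg = GeneratorConfig(
        n_channels=12, n_informative=5, n_redundant=3,
        hold_seconds=(4.0, 5.0), seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_synth():
    """6-channel generated dataset for oracle-equivalence tests."""
    cfg = GeneratorConfig(
        n_channels=6, n_informative=3, n_redundant=1,
        hold_seconds=(2.5, 3.5), seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def separable_toy():
    """5 channels; channel 2 alone encodes the gesture perfectly."""
    return make_gesture_coded_dataset(5, {2: 3.0}, noise=0.05, seed=4)
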