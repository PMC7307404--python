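"""Shared builders for engine-level test objects."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from milotask.engine import DisplayConfig, TrialSpec, generate_layout

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


def build_spec(
    rng: np.random.Generator,
    n: int = 8,
    *,
    trial_id: int = 1,
    condition: str = "vanish",
    shuffle: bool = False,
    identical: bool = False,
    order_mode: str = "single",
    preview_ms: int = 0,
    config: DisplayConfig | None = None,
) -> TrialSpec:
    """A concrete trial spec with a freshly generated layout."""
    config = config or DisplayConfig()
    if order_mode != "single":
        half = n // 2
        seqs = (
            tuple(chr(ord("A") + i) for i in range(half)),
            tuple(str(i + 1) for i in range(n - half)),
        )
    elif identical:
        seqs = (tuple(f"o{i}" for i in range(1, n + 1)),)
    else:
        seqs = (tuple("12345678"[:n]) if n <= 8 else tuple(f"s{i}" for i in range(n)),)
    items = [s for q in seqs for s in q]
    pos = generate_layout(config, len(items), rng)
    layout = {s: (int(x), int(y)) for s, (x, y) in zip(items, pos)}
    return TrialSpec(
        trial_id=trial_id,
        sequences=seqs,
        layout=layout,
        condition=condition,
        shuffle=shuffle,
        identical_mode=identical,
        order_mode=order_mode,
        preview_ms=preview_ms,
        seed=int(rng.integers(2**31 - 1)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
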