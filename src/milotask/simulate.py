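"""Virtual participant: generative latencies for the MILO task.

The generative model is deliberately simple — a deterministic mean latency
per response position and context, multiplied by lognormal trial noise —
because serial reaction times (SRTs) are right-skewed and the toolkit's
analyses use medians.  The default parameters encode the canonical response
structure of sequential touch search:

* the first response (T1) is slow: about 600 ms of display-registration and
  motor-initiation cost, plus about 60 ms per additional item when the
  display contains an ordered sequence to plan through;
* with identical (unordered) targets, T1 stays at ~600 ms regardless of set
  size and every later cancellation tap takes ~200 ms;
* in ordered sequences, T2..TN fall along a monotone-decreasing profile with
  an early plateau (mean ~426 ms for an 8-item digit sequence);
* keeping selected items on screen (Remain) adds a small constant (~19 ms)
  from T2 onward;
* shuffling future target identities abolishes planning, leaving latencies
  that track the physically remaining set size;
* in dual-sequence trials the first item of the second sequence carries a
  ~360 ms switch cost.

Latency draws are lognormal with *median* equal to the model mean, so
``sigma_log = 0`` reproduces the means exactly.  Out-of-sequence errors are
rare independent per-touch events.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .engine import (
    DEFAULT_TOUCH_RADIUS,
    SessionDesign,
    TouchEvent,
    TrialResult,
    TrialSpec,
    new_trial,
    replace_error_trial,
    schedule_session,
    step,
)
from .io import SessionHeader, SessionLog

__all__ = ["ParticipantModel", "mean_srt", "sample_srt", "simulate_trial", "simulate_cohort"]

# T2..T8 median SRTs (ms) for an 8-item ordered sequence: 2-3 item plateau
# then steady decline; mean is 426 ms.
DEFAULT_SRT_PROFILE = (540.0, 525.0, 490.0, 435.0, 380.0, 330.0, 282.0)


@dataclass(frozen=True)
class ParticipantModel:
    """Generative response-time parameters for one virtual participant."""

    t1_base_ms: float = 600.0
    t1_slope_ms_per_item: float = 60.0
    cancel_tap_ms: float = 200.0
    srt_profile: tuple[float, ...] = DEFAULT_SRT_PROFILE
    remain_offset_ms: float = 19.0
    shuffle_floor_ms: float = 180.0
    shuffle_slope_ms_per_item: float = 105.0
    switch_cost_ms: float = 360.0
    sawtooth_ms: float = 0.0  # optional pair-start cost in interleaved trials
    sigma_log: float = 0.15
    p_error: float = 0.001
    between_sd_log: float = 0.08  # lognormal sd of the participant speed factor

    def __post_init__(self) -> None:
        for name in (
            "t1_base_ms",
            "cancel_tap_ms",
            "shuffle_floor_ms",
            "switch_cost_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.srt_profile):
            raise ValueError("srt_profile entries must be positive")
        if not 0 <= self.p_error < 1:
            raise ValueError("p_error must lie in [0, 1)")
        if self.sigma_log < 0 or self.between_sd_log < 0:
            raise ValueError("dispersions must be non-negative")


def _profile_at(model: ParticipantModel, position: int, n_items: int) -> float:
    """Mean SRT for position >= 2 of an n-item ordered sequence.

    The stored profile covers positions 2..8; other sequence lengths map
    their positions linearly onto the stored curve and interpolate, so a
    12-item trial keeps the same plateau-then-decline shape.
    """
    prof = np.asarray(model.srt_profile, dtype=float)
    k = len(prof)
    if n_items <= 2 or k == 1:
        return float(prof[0])
    # map position 2..n_items onto stored index 0..k-1
    u = (position - 2) * (k - 1) / (n_items - 2)
    return float(np.interp(u, np.arange(k), prof))


def mean_srt(
    model: ParticipantModel,
    position: int,
    *,
    condition: str = "vanish",
    mode: str = "sequence",
    n_items: int = 8,
    set_size_remaining: int | None = None,
    is_switch: bool = False,
) -> float:
    """Deterministic mean latency for one response position and context.

    ``mode`` is one of ``sequence``, ``identical``, ``shuffle``,
    ``interleaved``; ``set_size_remaining`` defaults to
    ``n_items - position + 1``.
    """
    if position < 1:
        raise ValueError("position must be >= 1")
    if set_size_remaining is None:
        set_size_remaining = n_items - position + 1
    if mode == "identical":
        mu = model.t1_base_ms if position == 1 else model.cancel_tap_ms
    elif mode == "shuffle":
        mu = model.shuffle_floor_ms + model.shuffle_slope_ms_per_item * set_size_remaining
    elif mode in ("sequence", "interleaved"):
        if position == 1:
            mu = model.t1_base_ms + model.t1_slope_ms_per_item * (n_items - 1)
        else:
            mu = _profile_at(model, position, n_items)
        if mode == "interleaved" and position >= 3 and position % 2 == 1:
            mu += model.sawtooth_ms
    else:
        raise ValueError(f"unknown context mode {mode!r}")
    if condition == "remain" and position >= 2:
        mu += model.remain_offset_ms
    if is_switch:
        mu += model.switch_cost_ms
    return mu


def sample_srt(
    model: ParticipantModel,
    position: int,
    context: dict,
    rng: np.random.Generator,
) -> float:
    """One lognormal latency draw whose median equals the contextual mean."""
    mu = mean_srt(model, position, **context)
    if model.sigma_log == 0:
        return mu
    return mu * float(np.exp(model.sigma_log * rng.standard_normal()))


def _context_for(spec: TrialSpec, position: int) -> dict:
    if spec.identical_mode:
        mode = "identical"
    elif spec.shuffle:
        mode = "shuffle"
    elif spec.order_mode == "interleaved_dual":
        mode = "interleaved"
    else:
        mode = "sequence"
    is_switch = (
        spec.order_mode == "sequential_dual" and position == len(spec.sequences[0]) + 1
    )
    return {
        "condition": spec.condition,
        "mode": mode,
        "n_items": spec.n_items,
        "set_size_remaining": spec.n_items - position + 1,
        "is_switch": is_switch,
    }


_TOUCH_SCATTER = 45.0  # px; keeps every touch safely inside the 49-px radius


def _touch_at(centre: tuple[int, int], rng: np.random.Generator) -> tuple[int, int]:
    r = _TOUCH_SCATTER * np.sqrt(rng.random())
    th = rng.uniform(0, 2 * np.pi)
    return int(round(centre[0] + r * np.cos(th))), int(round(centre[1] + r * np.sin(th)))


def simulate_trial(
    model: ParticipantModel,
    spec: TrialSpec,
    rng: np.random.Generator,
) -> tuple[list[TouchEvent], TrialResult]:
    """Generate the touch stream for one trial by driving the engine.

    Each touch is aimed at the centre of the intended item (re-resolved
    against the engine's current identity/position mapping, so shuffles are
    honoured) and scattered uniformly within the touch radius.  With
    probability ``p_error`` per touch, a still-required item other than the
    current target is touched instead, ending the trial in error.
    """
    state = new_trial(spec)
    events: list[TouchEvent] = []
    t = float(spec.preview_ms)
    for position in range(1, spec.n_items + 1):
        lat = sample_srt(model, position, _context_for(spec, position), rng)
        t = max(t + lat, (events[-1].t_ms + 1) if events else 0.0)
        remaining = state.remaining
        if spec.identical_mode:  # any order allowed; cancel one at random
            target = remaining[int(rng.integers(len(remaining)))]
            wrong_pool: list[str] = []
        else:
            target = remaining[0]
            wrong_pool = remaining[1:]
        if wrong_pool and rng.random() < model.p_error:
            target = wrong_pool[int(rng.integers(len(wrong_pool)))]
        x, y = _touch_at(state.positions[target], rng)
        ev = TouchEvent(t_ms=int(round(t)), x=x, y=y)
        events.append(ev)
        step(state, ev)
        if state.status in ("completed", "error"):
            break
    result = TrialResult(
        spec=spec,
        selections=tuple(state.selected),
        status=state.status if state.status in ("completed", "error") else "incomplete",
        total_ms=state.total_ms,
        error_info=state.error_info,
    )
    return events, result


def _personalise(model: ParticipantModel, rng: np.random.Generator) -> ParticipantModel:
    """Draw one participant's parameters: a shared lognormal speed factor."""
    if model.between_sd_log == 0:
        return model
    g = float(np.exp(model.between_sd_log * rng.standard_normal()))
    prof = tuple(v * g for v in model.srt_profile)
    return dataclasses.replace(
        model,
        t1_base_ms=model.t1_base_ms * g,
        t1_slope_ms_per_item=model.t1_slope_ms_per_item * g,
        cancel_tap_ms=model.cancel_tap_ms * g,
        srt_profile=prof,
        remain_offset_ms=model.remain_offset_ms * g,
        shuffle_floor_ms=model.shuffle_floor_ms * g,
        shuffle_slope_ms_per_item=model.shuffle_slope_ms_per_item * g,
        switch_cost_ms=model.switch_cost_ms * g,
    )


def simulate_cohort(
    model: ParticipantModel,
    design: SessionDesign,
    n_participants: int,
    seed: int,
) -> list[SessionLog]:
    """Simulate a full cohort through the scheduler, engine and error rule.

    Every error trial is immediately followed by a replacement from the
    same condition with a fresh layout, exactly as the session rule
    prescribes, so each log contains the scheduled number of *correct*
    trials plus any error attempts.  Fully reproducible from ``seed``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    master = np.random.default_rng(seed)
    logs: list[SessionLog] = []
    for p in range(1, n_participants + 1):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        pmodel = _personalise(model, rng)
        pending = schedule_session(design, rng)
        trials: list[tuple[TrialSpec, list[TouchEvent], TrialResult]] = []
        next_id = max((s.trial_id for s in pending), default=0) + 1
        i = 0
        while i < len(pending):
            spec = pending[i]
            events, result = simulate_trial(pmodel, spec, rng)
            trials.append((spec, events, result))
            if result.status == "error":
                repl = replace_error_trial(design, spec, rng, trial_id=next_id)
                next_id += 1
                pending.insert(i + 1, repl)
            i += 1
        header = SessionHeader(
            participant_id=f"P{p:02d}",
            label=design.name,
            device="simulated",
            screen_w=design.display.screen_w,
            screen_h=design.display.screen_h,
            seed=seed,
            design=design.name,
            timestamp="",
            recording=True,
        )
        logs.append(SessionLog(header=header, trials=tuple(trials)))
    return logs
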