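"""Deterministic trial state machine and session scheduling for the MILO task.

The Multi-Item Localization (MILO) task presents a set of symbols (e.g. the
digits 1-8) scattered on a touchscreen; the participant must touch them in
sequence as fast as possible.  This module models one trial as an explicit
state machine driven by timed touch events, together with the standard
manipulations: Vanish vs. Remain (does a selected item disappear), Shuffle
(identities of future targets permuted after every response), Identical mode
(all items share one symbol and may be cancelled in any order), a preview
delay before responses are enabled, and dual-sequence trials (two sequences
completed consecutively or interleaved, as in Trail-Making-Test part B).

Everything here is pure logic: no rendering, no wall clock, no file I/O.
Given the same ``DisplayConfig``, ``SessionDesign`` and seed, every layout,
interleaving and shuffle permutation is reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CapacityError",
    "LayoutError",
    "SequencingError",
    "ModeError",
    "ConfigError",
    "DisplayConfig",
    "TouchEvent",
    "TrialSpec",
    "TrialState",
    "TrialResult",
    "BlockDesign",
    "SessionDesign",
    "generate_layout",
    "hit_test",
    "new_trial",
    "step",
    "shuffle_remaining",
    "schedule_session",
    "replace_error_trial",
    "run_trial",
    "named_design",
    "DESIGNS",
]

DEFAULT_TOUCH_RADIUS = 49.0  # px; half the default 98-px item diameter

LETTERS = tuple("ABCDEFGH")
DIGITS = tuple("12345678")


class CapacityError(ValueError):
    """More items requested than the grid has cells."""


class LayoutError(RuntimeError):
    """Non-overlap could not be satisfied within the resampling budget."""


class SequencingError(RuntimeError):
    """An event arrived that the trial state cannot accept."""


class ModeError(ValueError):
    """Operation incompatible with the trial's mode flags."""


class ConfigError(ValueError):
    """Invalid design or configuration value."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DisplayConfig:
    """Screen geometry of the task display.

    Items are placed at the centres of cells of an invisible grid whose
    centres span ``[offset_x, screen_w - offset_x]`` horizontally and
    ``[offset_y, screen_h - offset_y]`` vertically, then jittered uniformly
    by up to ``jitter_x`` / ``jitter_y`` pixels in each direction.
    Coordinates use the touchscreen convention: origin top-left, y grows
    downward, integer pixels.
    """

    screen_w: int = 1024
    screen_h: int = 768
    grid_rows: int = 4
    grid_cols: int = 4
    offset_x: int = 200
    offset_y: int = 150
    jitter_x: int = 80
    jitter_y: int = 30
    item_diameter: int = 98

    def __post_init__(self) -> None:
        for name in ("screen_w", "screen_h", "grid_rows", "grid_cols", "item_diameter"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.jitter_x < 0 or self.jitter_y < 0:
            raise ConfigError("jitter must be non-negative")
        if 2 * self.offset_x >= self.screen_w or 2 * self.offset_y >= self.screen_h:
            raise ConfigError("offsets leave no room for the grid on screen")

    @property
    def n_cells(self) -> int:
        return self.grid_rows * self.grid_cols

    def cell_centres(self) -> np.ndarray:
        """Nominal (un-jittered) cell centres, shape (rows*cols, 2), row-major."""
        if self.grid_cols > 1:
            xs = self.offset_x + np.arange(self.grid_cols) * (
                (self.screen_w - 2 * self.offset_x) / (self.grid_cols - 1)
            )
        else:
            xs = np.array([self.screen_w / 2.0])
        if self.grid_rows > 1:
            ys = self.offset_y + np.arange(self.grid_rows) * (
                (self.screen_h - 2 * self.offset_y) / (self.grid_rows - 1)
            )
        else:
            ys = np.array([self.screen_h / 2.0])
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True, order=True)
class TouchEvent:
    """One timed touch: milliseconds since display onset plus screen pixels."""

    t_ms: int
    x: int
    y: int

    def __post_init__(self) -> None:
        if self.t_ms < 0:
            raise ValueError("t_ms must be non-negative")


@dataclass(frozen=True)
class TrialSpec:
    """Complete, immutable description of one trial.

    ``sequences`` holds one tuple of symbol-instance tokens for a single
    sequence, or two tuples for dual-sequence trials.  ``layout`` maps each
    instance token to its (x, y) centre in pixels.  ``seed`` drives the
    trial's internal randomness (shuffle permutations) so that a logged
    trial can be replayed bit-exactly.
    """

    trial_id: int
    sequences: tuple[tuple[str, ...], ...]
    layout: dict[str, tuple[int, int]]
    order_mode: str = "single"  # single | sequential_dual | interleaved_dual
    condition: str = "vanish"  # vanish | remain
    shuffle: bool = False
    identical_mode: bool = False
    preview_ms: int = 0
    seed: int = 0
    block: int = 0

    def __post_init__(self) -> None:
        if self.order_mode not in ("single", "sequential_dual", "interleaved_dual"):
            raise ConfigError(f"unknown order_mode {self.order_mode!r}")
        if self.condition not in ("vanish", "remain"):
            raise ConfigError(f"unknown condition {self.condition!r}")
        if self.identical_mode and self.shuffle:
            raise ConfigError("identical_mode excludes shuffle")
        if self.preview_ms < 0:
            raise ConfigError("preview_ms must be >= 0")
        if self.order_mode == "single" and len(self.sequences) != 1:
            raise ConfigError("single mode needs exactly one sequence")
        if self.order_mode != "single" and len(self.sequences) != 2:
            raise ConfigError("dual modes need exactly two sequences")
        all_items = [s for seq in self.sequences for s in seq]
        if len(set(all_items)) != len(all_items):
            raise ConfigError("symbol instances must be unique")
        if set(self.layout) != set(all_items):
            raise ConfigError("layout keys must equal the trial's symbol instances")

    @property
    def n_items(self) -> int:
        return sum(len(s) for s in self.sequences)

    def required_order(self) -> tuple[str, ...]:
        """The enforced selection order (arbitrary-order trials still return
        a canonical listing of instances)."""
        if self.order_mode == "single":
            return tuple(self.sequences[0])
        if self.order_mode == "sequential_dual":
            return tuple(self.sequences[0]) + tuple(self.sequences[1])
        # interleaved: A, 1, B, 2, ... starting with the first list
        a, b = self.sequences
        out: list[str] = []
        for i in range(max(len(a), len(b))):
            if i < len(a):
                out.append(a[i])
            if i < len(b):
                out.append(b[i])
        return tuple(out)


@dataclass
class TrialState:
    """Mutable state of a trial in progress."""

    spec: TrialSpec
    order: tuple[str, ...]
    positions: dict[str, tuple[int, int]]  # current identity -> centre mapping
    pointer: int = 0
    visible: set[str] = field(default_factory=set)
    selected: list[tuple[str, int, int, int]] = field(default_factory=list)
    ignored: list[tuple[TouchEvent, str]] = field(default_factory=list)
    status: str = "running"  # previewing | running | completed | error
    error_info: str | None = None
    total_ms: int | None = None
    last_t: int = -1
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def remaining(self) -> list[str]:
        if self.spec.identical_mode:
            done = {s for s, *_ in self.selected}
            return [s for s in self.order if s not in done]
        return list(self.order[self.pointer :])


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one trial: the ordered selections and terminal status."""

    spec: TrialSpec
    selections: tuple[tuple[str, int, int, int], ...]
    status: str  # completed | error | incomplete
    total_ms: int | None
    # human-readable detail; not serialised, so excluded from equality
    error_info: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.status == "completed" and len(self.selections) != self.spec.n_items:
            raise ValueError("completed trial must select every item")


# ---------------------------------------------------------------------------
# layout generation and hit testing
# ---------------------------------------------------------------------------

_MAX_LAYOUT_ATTEMPTS = 1000


def generate_layout(
    config: DisplayConfig, n_items: int, rng: np.random.Generator
) -> np.ndarray:
    """Place ``n_items`` on distinct grid cells with uniform jitter.

    Cells are drawn uniformly without replacement; each item's centre is its
    cell centre plus independent uniform jitter in
    ``[-jitter_x, +jitter_x] x [-jitter_y, +jitter_y]``, rounded to integer
    pixels.  Jitter is resampled (cells kept) until no two centres are
    closer than ``item_diameter`` and every item lies fully on screen, up to
    1000 attempts.

    Returns an (n_items, 2) integer array of centres.
    """
    if n_items > config.n_cells:
        raise CapacityError(
            f"{n_items} items do not fit a {config.grid_rows}x{config.grid_cols} grid"
        )
    if n_items < 1:
        raise ConfigError("n_items must be >= 1")
    centres = config.cell_centres()
    cells = rng.choice(config.n_cells, size=n_items, replace=False)
    base = centres[cells]
    r = config.item_diameter / 2.0
    for _ in range(_MAX_LAYOUT_ATTEMPTS):
        jit = np.column_stack(
            [
                rng.uniform(-config.jitter_x, config.jitter_x, n_items),
                rng.uniform(-config.jitter_y, config.jitter_y, n_items),
            ]
        )
        pos = np.rint(base + jit).astype(int)
        on_screen = (
            (pos[:, 0] - r >= 0)
            & (pos[:, 0] + r <= config.screen_w)
            & (pos[:, 1] - r >= 0)
            & (pos[:, 1] + r <= config.screen_h)
        )
        if not on_screen.all():
            continue
        if n_items > 1:
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            d[np.diag_indices(n_items)] = np.inf
            if d.min() < config.item_diameter:
                continue
        return pos
    raise LayoutError("could not satisfy non-overlap within the resampling budget")


def hit_test(
    layout: dict[str, tuple[int, int]],
    event: TouchEvent,
    radius: float = DEFAULT_TOUCH_RADIUS,
) -> str | None:
    """Return the item whose centre is within ``radius`` of the touch.

    Ties (several items within radius) go to the nearest centre; returns
    ``None`` for a background touch.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    best: str | None = None
    best_d = float(radius)
    for sym, (cx, cy) in layout.items():
        d = float(np.hypot(event.x - cx, event.y - cy))
        if d <= best_d:
            best, best_d = sym, d
    return best


# ---------------------------------------------------------------------------
# trial state machine
# ---------------------------------------------------------------------------


def new_trial(spec: TrialSpec) -> TrialState:
    """Initialise the state machine for ``spec`` (fresh rng from its seed)."""
    return TrialState(
        spec=spec,
        order=spec.required_order(),
        positions=dict(spec.layout),
        visible=set(spec.layout),
        status="previewing" if spec.preview_ms > 0 else "running",
        rng=np.random.default_rng(spec.seed),
    )


def shuffle_remaining(state: TrialState, rng: np.random.Generator | None = None) -> TrialState:
    """Permute the identities of not-yet-selected targets over their positions.

    The position multiset is untouched — only which symbol sits where
    changes (the identity permutation is allowed).  Already-selected items
    keep their identity and position.
    """
    if state.spec.identical_mode:
        raise ModeError("shuffle is undefined for identical-mode trials")
    rng = state.rng if rng is None else rng
    remaining = state.remaining
    if not remaining:
        raise ModeError("no targets remain to shuffle")
    slots = [state.positions[s] for s in remaining]
    perm = rng.permutation(len(remaining))
    for sym, k in zip(remaining, perm):
        state.positions[sym] = slots[k]
    return state


def step(state: TrialState, event: TouchEvent, rng: np.random.Generator | None = None) -> TrialState:
    """Advance the trial by one touch event.

    Background touches and touches on already-selected (Remain) items are
    logged as ignored; touching the current required target records a
    selection, advances the pointer, hides the item iff the condition is
    vanish, and reshuffles future identities when the shuffle flag is set;
    touching any other still-required item ends the trial in error.
    """
    if state.status in ("completed", "error"):
        raise SequencingError(f"event after terminal status {state.status!r}")
    if event.t_ms < state.last_t:
        raise ValueError("touch events must have non-decreasing t_ms")
    state.last_t = event.t_ms

    spec = state.spec
    if state.status == "previewing":
        if event.t_ms < spec.preview_ms:
            state.ignored.append((event, "preview"))
            return state
        state.status = "running"

    hit = hit_test({s: state.positions[s] for s in state.visible}, event)
    already = {s for s, *_ in state.selected}
    if hit is None or hit in already:
        state.ignored.append((event, "ignored"))
        return state

    if spec.identical_mode:
        correct = True  # any unselected item may be cancelled
    else:
        correct = hit == state.order[state.pointer]

    if not correct:
        state.status = "error"
        state.error_info = f"out-of-sequence selection of {hit!r}"
        state.ignored.append((event, "error"))
        return state

    state.selected.append((hit, event.t_ms, event.x, event.y))
    state.pointer += 1
    if spec.condition == "vanish":
        state.visible.discard(hit)
    if state.pointer == spec.n_items:
        state.status = "completed"
        state.total_ms = event.t_ms - spec.preview_ms
    elif spec.shuffle:
        shuffle_remaining(state, rng)
    return state


def run_trial(
    spec: TrialSpec,
    events: list[TouchEvent],
    rng: np.random.Generator | None = None,
) -> TrialResult:
    """Fold :func:`step` over an ordered event stream and return the outcome.

    A stream that ends before the trial completes yields status
    ``"incomplete"``; shuffle permutations are reproduced from
    ``spec.seed`` so replaying a logged stream is deterministic.
    """
    last = -1
    for ev in events:
        if ev.t_ms < last:
            raise ValueError("events must be time-ordered")
        last = ev.t_ms
    state = new_trial(spec)
    for ev in events:
        step(state, ev, rng)
        if state.status in ("completed", "error"):
            break
    if state.status in ("previewing", "running"):
        status = "incomplete"
        error_info = "incomplete: event stream ended before trial completion"
    else:
        status = state.status
        error_info = state.error_info
    return TrialResult(
        spec=spec,
        selections=tuple(state.selected),
        status=status,
        total_ms=state.total_ms,
        error_info=error_info,
    )


# ---------------------------------------------------------------------------
# session scheduling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockDesign:
    """One block: (template, count) pairs interleaved in constrained-random order.

    A template is a dict of TrialSpec fields (condition, shuffle, sequences,
    order_mode, identical_mode, preview_ms); layout, ids and seeds are
    assigned at scheduling time.  ``interleave=False`` keeps templates in
    listed order (used for fixed-order blocks).
    """

    templates: tuple[tuple[dict, int], ...]
    interleave: bool = True


@dataclass(frozen=True)
class SessionDesign:
    name: str
    blocks: tuple[BlockDesign, ...]
    display: DisplayConfig = field(default_factory=DisplayConfig)


def _validated_template(tpl: dict) -> dict:
    tpl = dict(tpl)
    cond = tpl.get("condition", "vanish")
    if cond not in ("vanish", "remain"):
        raise ConfigError(f"unknown condition label {cond!r}")
    tpl.setdefault("sequences", (DIGITS,))
    tpl["sequences"] = tuple(tuple(s) for s in tpl["sequences"])
    return tpl


def _spec_from_template(
    tpl: dict,
    trial_id: int,
    block: int,
    design: SessionDesign,
    rng: np.random.Generator,
) -> TrialSpec:
    tpl = _validated_template(tpl)
    items = [s for seq in tpl["sequences"] for s in seq]
    pos = generate_layout(design.display, len(items), rng)
    layout = {s: (int(x), int(y)) for s, (x, y) in zip(items, pos)}
    return TrialSpec(
        trial_id=trial_id,
        layout=layout,
        seed=int(rng.integers(0, 2**31 - 1)),
        block=block,
        **tpl,
    )


def schedule_session(design: SessionDesign, rng: np.random.Generator) -> list[TrialSpec]:
    """Expand a session design into concrete trial specs.

    Each block lists its per-condition trial counts; trials are interleaved
    by random permutation (unless the block is fixed-order), every spec gets
    a fresh layout and shuffle seed, and the whole schedule is a
    deterministic function of the design and the generator state.
    """
    specs: list[TrialSpec] = []
    trial_id = 1
    for b, block in enumerate(design.blocks, start=1):
        expanded: list[dict] = []
        for tpl, count in block.templates:
            if count < 0:
                raise ConfigError("trial counts must be non-negative")
            expanded.extend([tpl] * count)
        if block.interleave and len(expanded) > 1:
            order = rng.permutation(len(expanded))
            expanded = [expanded[i] for i in order]
        for tpl in expanded:
            specs.append(_spec_from_template(tpl, trial_id, b, design, rng))
            trial_id += 1
    return specs


def replace_error_trial(
    design: SessionDesign,
    failed_spec: TrialSpec,
    rng: np.random.Generator,
    *,
    status: str = "error",
    trial_id: int | None = None,
) -> TrialSpec:
    """Build the immediate replacement for an error trial.

    The replacement keeps every condition flag and the sequence symbols of
    the failed trial but draws a new layout and shuffle seed, mirroring the
    task rule that error trials are repeated from the same condition with a
    new arrangement.
    """
    if status != "error":
        raise SequencingError("only error trials are replaced")
    tpl = {
        "sequences": failed_spec.sequences,
        "order_mode": failed_spec.order_mode,
        "condition": failed_spec.condition,
        "shuffle": failed_spec.shuffle,
        "identical_mode": failed_spec.identical_mode,
        "preview_ms": failed_spec.preview_ms,
    }
    return _spec_from_template(
        tpl,
        failed_spec.trial_id if trial_id is None else trial_id,
        failed_spec.block,
        design,
        rng,
    )


# ---------------------------------------------------------------------------
# named designs
# ---------------------------------------------------------------------------


def _instances(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i}" for i in range(1, n + 1))


def _exp1(sequence: str = "digits") -> SessionDesign:
    seq = DIGITS if sequence == "digits" else LETTERS
    block = BlockDesign(
        templates=(
            ({"condition": "vanish", "sequences": (seq,)}, 10),
            ({"condition": "remain", "sequences": (seq,)}, 10),
        )
    )
    return SessionDesign(name=f"exp1-{sequence}", blocks=(block, block))


def _exp2() -> SessionDesign:
    vanish = BlockDesign(
        templates=(({"condition": "vanish", "sequences": (DIGITS,)}, 20),),
        interleave=False,
    )
    shuf = BlockDesign(
        templates=(({"condition": "vanish", "shuffle": True, "sequences": (DIGITS,)}, 20),),
        interleave=False,
    )
    return SessionDesign(name="exp2", blocks=(vanish, shuf))


def _dual(order_mode: str) -> SessionDesign:
    seqs = (tuple("ABCDEF"), tuple("123456"))
    block = BlockDesign(
        templates=(
            ({"condition": "vanish", "sequences": seqs, "order_mode": order_mode}, 10),
            ({"condition": "remain", "sequences": seqs, "order_mode": order_mode}, 10),
        )
    )
    return SessionDesign(name=f"dual-{order_mode}", blocks=(block, block))


def _identical() -> SessionDesign:
    # set size varies randomly 1-6 from trial to trial
    templates = tuple(
        ({"identical_mode": True, "sequences": (_instances("o", n),)}, 5)
        for n in range(1, 7)
    )
    block = BlockDesign(templates=templates)
    return SessionDesign(name="identical", blocks=(block, block))


def _preview() -> SessionDesign:
    blocks = tuple(
        BlockDesign(
            templates=(
                ({"condition": "vanish", "sequences": (DIGITS,), "preview_ms": p}, 20),
            ),
            interleave=False,
        )
        for p in (0, 2000, 4000, 6000)
    )
    return SessionDesign(name="preview", blocks=blocks)


DESIGNS = {
    "exp1": lambda: _exp1("digits"),
    "exp1-letters": lambda: _exp1("letters"),
    "exp2": _exp2,
    "dual-seq": lambda: _dual("sequential_dual"),
    "dual-interleaved": lambda: _dual("interleaved_dual"),
    "identical": _identical,
    "preview": _preview,
}


def named_design(name: str) -> SessionDesign:
    """Look up one of the built-in session designs by name."""
    try:
        return DESIGNS[name]()
    except KeyError:
        raise ConfigError(
            f"unknown design {name!r}; available: {', '.join(sorted(DESIGNS))}"
        ) from None
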