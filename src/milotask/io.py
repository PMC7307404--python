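"""The ``.milo`` session-log text format and tidy tabular export.

A session log is a line-oriented, integer-only text file: ``#`` header
lines, one ``TRIAL`` line per trial (all parameter settings plus the
layout), one ``EVENT`` line per touch, and one ``END`` line per trial.
The dialect is frozen by golden-file tests; write -> read -> write is
byte-identical, which is what makes logged sessions fully replayable.

Example::

    # participant_id: P01
    TRIAL 1 block=1 cond=vanish shuffle=0 mode=single identical=0 \
preview=0 seed=911 seq=1,2 layout=1:236:141;2:804:585
    EVENT 1 1212 240 150 1 ok
    EVENT 1 1650 801 590 2 ok
    END 1 completed 1650
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .engine import TouchEvent, TrialResult, TrialSpec

__all__ = [
    "ParseError",
    "SessionHeader",
    "SessionLog",
    "write_session",
    "read_session",
    "to_tidy",
    "TIDY_COLUMNS",
]


class ParseError(ValueError):
    """Malformed session file; the message names the offending line."""


_HEADER_KEYS = (
    "participant_id",
    "label",
    "device",
    "screen_w",
    "screen_h",
    "seed",
    "design",
    "timestamp",
    "recording",
)

# symbol-instance tokens must survive the field separators of the dialect
_SYMBOL_RE = re.compile(r"^[A-Za-z0-9_*#.+-]+$")


@dataclass(frozen=True)
class SessionHeader:
    participant_id: str = ""
    label: str = ""
    device: str = ""
    screen_w: int = 1024
    screen_h: int = 768
    seed: int = 0
    design: str = ""
    timestamp: str = ""
    recording: bool = True


@dataclass(frozen=True)
class SessionLog:
    """One recorded session: header plus (spec, events, result) per trial."""

    header: SessionHeader
    trials: tuple[tuple[TrialSpec, tuple[TouchEvent, ...], TrialResult], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "trials",
            tuple(
                (spec, tuple(events), result) for spec, events, result in self.trials
            ),
        )


def _check_symbols(spec: TrialSpec) -> None:
    for seq in spec.sequences:
        for s in seq:
            if not _SYMBOL_RE.match(s):
                raise ValueError(f"symbol token {s!r} not representable in .milo format")


def _trial_line(spec: TrialSpec) -> str:
    _check_symbols(spec)
    seq = "|".join(",".join(s) for s in spec.sequences)
    order = [s for sq in spec.sequences for s in sq]
    layout = ";".join(f"{s}:{spec.layout[s][0]}:{spec.layout[s][1]}" for s in order)
    return (
        f"TRIAL {spec.trial_id} block={spec.block} cond={spec.condition} "
        f"shuffle={int(spec.shuffle)} mode={spec.order_mode} "
        f"identical={int(spec.identical_mode)} preview={spec.preview_ms} "
        f"seed={spec.seed} seq={seq} layout={layout}"
    )


def write_session(log: SessionLog, path: str | Path) -> Path:
    """Serialise a session log to its canonical text form."""
    path = Path(path)
    lines: list[str] = []
    h = log.header
    for key in _HEADER_KEYS:
        val = getattr(h, key)
        if key == "recording":
            val = int(val)
        lines.append(f"# {key}: {val}".rstrip())
    for spec, events, result in log.trials:
        lines.append(_trial_line(spec))
        outcomes = _event_outcomes(spec, events, result)
        for ev, (hit, outcome) in zip(events, outcomes):
            hit_s = hit if hit is not None else "-"
            lines.append(f"EVENT {spec.trial_id} {ev.t_ms} {ev.x} {ev.y} {hit_s} {outcome}")
        total = result.total_ms if result.total_ms is not None else "-"
        lines.append(f"END {spec.trial_id} {result.status} {total}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _event_outcomes(
    spec: TrialSpec, events: tuple[TouchEvent, ...], result: TrialResult
) -> list[tuple[str | None, str]]:
    """Label each event with (hit symbol, outcome) by replaying the trial."""
    from .engine import new_trial, step  # local import to avoid cycle at module load

    state = new_trial(spec)
    out: list[tuple[str | None, str]] = []
    for ev in events:
        if state.status in ("completed", "error"):
            out.append((None, "ignored"))
            continue
        n_sel, n_ign = len(state.selected), len(state.ignored)
        step(state, ev)
        if len(state.selected) > n_sel:
            out.append((state.selected[-1][0], "ok"))
        elif len(state.ignored) > n_ign:
            ev_, label = state.ignored[-1]
            out.append((None, label))
        else:  # pragma: no cover - every branch above fires
            out.append((None, "ignored"))
    return out


_TRIAL_RE = re.compile(
    r"^TRIAL (\d+) block=(\d+) cond=(\w+) shuffle=([01]) mode=(\w+) "
    r"identical=([01]) preview=(\d+) seed=(\d+) seq=(\S+) layout=(\S+)$"
)
_EVENT_RE = re.compile(r"^EVENT (\d+) (\d+) (-?\d+) (-?\d+) (\S+) (\w+)$")
_END_RE = re.compile(r"^END (\d+) (\w+) (\d+|-)$")
_HEADER_RE = re.compile(r"^# (\w+): ?(.*)$")


def read_session(path: str | Path) -> SessionLog:
    """Parse a ``.milo`` file back into an equal :class:`SessionLog`.

    A truncated trial (events but no ``END`` line) is kept with status
    ``incomplete`` and a warning rather than rejected, so partially
    recorded sessions remain usable.
    """
    path = Path(path)
    header_kwargs: dict = {}
    trials: list[tuple[TrialSpec, tuple[TouchEvent, ...], TrialResult]] = []
    cur_spec: TrialSpec | None = None
    cur_events: list[TouchEvent] = []
    cur_last_t = -1

    def close_trial(end: re.Match | None, lineno: int) -> None:
        nonlocal cur_spec, cur_events, cur_last_t
        if cur_spec is None:
            return
        if end is None:
            warnings.warn(
                f"{path.name}: trial {cur_spec.trial_id} has no END line; "
                "marked incomplete",
                stacklevel=3,
            )
            status, total = "incomplete", None
        else:
            status = end.group(2)
            total = None if end.group(3) == "-" else int(end.group(3))
            if status not in ("completed", "error", "incomplete"):
                raise ParseError(f"{path.name}:{lineno}: unknown status {status!r}")
        selections = tuple(
            (hit, ev.t_ms, ev.x, ev.y)
            for ev, (hit, outcome) in zip(
                cur_events, _event_outcomes(cur_spec, tuple(cur_events), None)
            )
            if outcome == "ok"
        )
        trials.append(
            (
                cur_spec,
                tuple(cur_events),
                TrialResult(
                    spec=cur_spec, selections=selections, status=status, total_ms=total
                ),
            )
        )
        cur_spec, cur_events, cur_last_t = None, [], -1

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            m = _HEADER_RE.match(line)
            if not m:
                raise ParseError(f"{path.name}:{lineno}: malformed header line")
            key, val = m.group(1), m.group(2)
            if key in ("screen_w", "screen_h", "seed"):
                header_kwargs[key] = int(val)
            elif key == "recording":
                header_kwargs[key] = bool(int(val))
            elif key in _HEADER_KEYS:
                header_kwargs[key] = val
            continue
        if line.startswith("TRIAL"):
            close_trial(None, lineno) if cur_spec is not None else None
            m = _TRIAL_RE.match(line)
            if not m:
                raise ParseError(f"{path.name}:{lineno}: malformed TRIAL line")
            sequences = tuple(
                tuple(part.split(",")) for part in m.group(9).split("|")
            )
            layout: dict[str, tuple[int, int]] = {}
            for item in m.group(10).split(";"):
                try:
                    sym, xs, ys = item.rsplit(":", 2)
                    layout[sym] = (int(xs), int(ys))
                except ValueError:
                    raise ParseError(
                        f"{path.name}:{lineno}: malformed layout entry {item!r}"
                    ) from None
            try:
                cur_spec = TrialSpec(
                    trial_id=int(m.group(1)),
                    block=int(m.group(2)),
                    condition=m.group(3),
                    shuffle=bool(int(m.group(4))),
                    order_mode=m.group(5),
                    identical_mode=bool(int(m.group(6))),
                    preview_ms=int(m.group(7)),
                    seed=int(m.group(8)),
                    sequences=sequences,
                    layout=layout,
                )
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
            continue
        if line.startswith("EVENT"):
            m = _EVENT_RE.match(line)
            if not m:
                raise ParseError(f"{path.name}:{lineno}: malformed EVENT line")
            if cur_spec is None:
                raise ParseError(f"{path.name}:{lineno}: EVENT before any TRIAL")
            if int(m.group(1)) != cur_spec.trial_id:
                raise ParseError(
                    f"{path.name}:{lineno}: EVENT trial id does not match open TRIAL"
                )
            t = int(m.group(2))
            if t < cur_last_t:
                raise ParseError(
                    f"{path.name}:{lineno}: non-monotone t_ms within trial"
                )
            cur_last_t = t
            cur_events.append(TouchEvent(t_ms=t, x=int(m.group(3)), y=int(m.group(4))))
            continue
        if line.startswith("END"):
            m = _END_RE.match(line)
            if not m:
                raise ParseError(f"{path.name}:{lineno}: malformed END line")
            if cur_spec is None or int(m.group(1)) != cur_spec.trial_id:
                raise ParseError(f"{path.name}:{lineno}: END without matching TRIAL")
            close_trial(m, lineno)
            continue
        raise ParseError(f"{path.name}:{lineno}: unrecognised line {line!r}")

    if cur_spec is not None:
        close_trial(None, lineno)
    return SessionLog(header=SessionHeader(**header_kwargs), trials=tuple(trials))


TIDY_COLUMNS = [
    "participant",
    "trial",
    "block",
    "condition",
    "sequence_type",
    "order_mode",
    "shuffle",
    "set_size",
    "target_index",
    "symbol",
    "srt_ms",
    "t_ms",
    "x",
    "y",
    "trial_status",
]


def _sequence_type(spec: TrialSpec) -> str:
    if spec.identical_mode:
        return "identical"
    if len(spec.sequences) > 1:
        return "mixed"
    syms = "".join(spec.sequences[0])
    if syms.isdigit():
        return "digit"
    if syms.isalpha():
        return "letter"
    return "other"


def to_tidy(logs: list[SessionLog]) -> pd.DataFrame:
    """One row per valid selection, with its serial reaction time.

    The SRT of the first selection is measured from response onset (display
    onset shifted by any preview period); later SRTs are inter-selection
    intervals.  Ignored touches and the terminating error touch contribute
    no rows; an error trial therefore contributes exactly its completed
    selections.
    """
    if not logs:
        return pd.DataFrame(columns=TIDY_COLUMNS)
    rows: list[dict] = []
    seen: set[tuple[str, int]] = set()
    for log in logs:
        pid = log.header.participant_id
        for spec, _events, result in log.trials:
            key = (pid, spec.trial_id)
            if key in seen:
                raise ValueError(f"duplicate participant/trial key {key}")
            seen.add(key)
            prev_t = spec.preview_ms
            for idx, (sym, t, x, y) in enumerate(result.selections, start=1):
                rows.append(
                    {
                        "participant": pid,
                        "trial": spec.trial_id,
                        "block": spec.block,
                        "condition": spec.condition,
                        "sequence_type": _sequence_type(spec),
                        "order_mode": spec.order_mode,
                        "shuffle": spec.shuffle,
                        "set_size": spec.n_items,
                        "target_index": idx,
                        "symbol": sym,
                        "srt_ms": t - prev_t,
                        "t_ms": t,
                        "x": x,
                        "y": y,
                        "trial_status": result.status,
                    }
                )
                prev_t = t
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)
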