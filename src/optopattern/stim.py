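"""Bytecode DSL for LED illumination schedules.

LED boards used for optogenetic stimulation run a tiny 1 Hz firmware program
with four instructions, one byte each:

========  =============================================
byte      meaning
========  =============================================
0x00-7E   turn the LED on for (byte + 1) seconds (1-127)
0x80-FE   turn the LED off for (byte - 0x80 + 1) seconds
0x7F      repeat the whole pattern from the start
0xFF      halt (LED stays off)
========  =============================================

A program is a sequence of ON/OFF steps terminated by REPEAT or HALT; a
program given without a terminator is canonicalized with an implicit HALT.
This module decodes/encodes the byte form, parses a human-readable mnemonic
form (``ON 5`` / ``OFF 20`` / ``REPEAT``), and simulates programs into
second-resolution illumination timelines from which duty cycles and
cumulative light doses are derived. The dose is what couples a stimulation
schedule to induction strength in the synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "Instruction",
    "StimProgram",
    "IlluminationTimeline",
    "decode",
    "encode",
    "parse_mnemonic",
    "to_mnemonic",
    "simulate",
    "duty_cycle",
    "dose",
    "read_program",
    "write_program",
]

MAX_DURATION = 127

_REPEAT_BYTE = 0x7F
_HALT_BYTE = 0xFF


class StimFormatError(ValueError):
    """Raised for malformed stimulation programs or byte streams."""


@dataclass(frozen=True)
class Instruction:
    kind: str  # ON | OFF | REPEAT | HALT
    duration_s: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind in ("ON", "OFF"):
            if self.duration_s is None or not 1 <= self.duration_s <= MAX_DURATION:
                raise StimFormatError(
                    f"{self.kind} duration must be in [1, {MAX_DURATION}] s, "
                    f"got {self.duration_s}"
                )
        elif self.kind in ("REPEAT", "HALT"):
            if self.duration_s is not None:
                raise StimFormatError(f"{self.kind} takes no duration")
        else:
            raise StimFormatError(f"unknown instruction kind {self.kind!r}")

    def __repr__(self) -> str:
        if self.kind in ("ON", "OFF"):
            return f"{self.kind} {self.duration_s}"
        return self.kind


@dataclass(frozen=True)
class StimProgram:
    """A canonical stimulation program.

    The last instruction is always REPEAT or HALT (an implicit HALT is
    appended at construction if absent); neither may occur elsewhere.
    """

    instructions: tuple[Instruction, ...]

    def __post_init__(self) -> None:
        instrs = tuple(self.instructions)
        if not instrs:
            raise StimFormatError("empty program")
        if instrs[-1].kind not in ("REPEAT", "HALT"):
            instrs = instrs + (Instruction("HALT"),)
        for ins in instrs[:-1]:
            if ins.kind in ("REPEAT", "HALT"):
                raise StimFormatError(
                    f"{ins.kind} may only appear as the last instruction"
                )
        object.__setattr__(self, "instructions", instrs)

    @property
    def terminator(self) -> str:
        return self.instructions[-1].kind

    @property
    def steps(self) -> tuple[Instruction, ...]:
        """The ON/OFF steps, without the terminator."""
        return self.instructions[:-1]

    def __repr__(self) -> str:
        return "StimProgram[" + " / ".join(map(repr, self.instructions)) + "]"

    @classmethod
    def from_steps(cls, *specs: tuple[str, int] | str) -> "StimProgram":
        """Build a program from shorthand, e.g. ``from_steps(("ON", 5), ("OFF", 20), "REPEAT")``."""
        instrs = []
        for s in specs:
            if isinstance(s, str):
                instrs.append(Instruction(s))
            else:
                instrs.append(Instruction(s[0], s[1]))
        return cls(tuple(instrs))


def decode(data: bytes | Iterable[int]) -> StimProgram:
    """Decode a byte sequence into a :class:`StimProgram`.

    Bytes after a REPEAT/HALT terminator are a format error; a stream that
    ends without a terminator yields a program with an implicit HALT.
    """
    data = bytes(data)
    if not data:
        raise StimFormatError("empty byte sequence")
    instrs: list[Instruction] = []
    terminated = False
    for b in data:
        if terminated:
            raise StimFormatError(f"byte 0x{b:02X} after program terminator")
        if b == _REPEAT_BYTE:
            instrs.append(Instruction("REPEAT"))
            terminated = True
        elif b == _HALT_BYTE:
            instrs.append(Instruction("HALT"))
            terminated = True
        elif b <= 0x7E:
            instrs.append(Instruction("ON", b + 1))
        else:  # 0x80..0xFE
            instrs.append(Instruction("OFF", b - 0x80 + 1))
    return StimProgram(tuple(instrs))


def encode(program: StimProgram) -> bytes:
    """Encode a program to bytes (inverse of :func:`decode`)."""
    out = bytearray()
    for ins in program.instructions:
        if ins.kind == "ON":
            out.append(ins.duration_s - 1)
        elif ins.kind == "OFF":
            out.append(0x80 + ins.duration_s - 1)
        elif ins.kind == "REPEAT":
            out.append(_REPEAT_BYTE)
        else:
            out.append(_HALT_BYTE)
    return bytes(out)


def parse_mnemonic(text: str) -> StimProgram:
    """Parse the mnemonic text form: one instruction per line or ``/``-separated.

    ``# comments`` and blank lines are ignored. Example::

        ON 5
        OFF 20
        REPEAT
    """
    tokens = []
    for raw_line in text.replace("/", "\n").splitlines():
        line = raw_line.split("#", 1)[0].strip()
        if line:
            tokens.append(line)
    if not tokens:
        raise StimFormatError("no instructions in mnemonic text")
    instrs = []
    for tok in tokens:
        parts = tok.split()
        kind = parts[0].upper()
        if kind in ("ON", "OFF"):
            if len(parts) != 2:
                raise StimFormatError(f"{kind} needs a duration: {tok!r}")
            try:
                dur = int(parts[1])
            except ValueError:
                raise StimFormatError(f"bad duration in {tok!r}") from None
            instrs.append(Instruction(kind, dur))
        elif kind in ("REPEAT", "HALT") and len(parts) == 1:
            instrs.append(Instruction(kind))
        else:
            raise StimFormatError(f"cannot parse instruction {tok!r}")
    return StimProgram(tuple(instrs))


def to_mnemonic(program: StimProgram) -> str:
    return "\n".join(repr(ins) for ins in program.instructions) + "\n"


def read_program(path: str | Path) -> StimProgram:
    """Read a program from a ``.bin`` byte file or ``.stim`` mnemonic file."""
    path = Path(path)
    if path.suffix.lower() == ".stim":
        return parse_mnemonic(path.read_text())
    return decode(path.read_bytes())


def write_program(program: StimProgram, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".stim":
        path.write_text(to_mnemonic(program))
    else:
        path.write_bytes(encode(program))


@dataclass(frozen=True)
class IlluminationTimeline:
    """One boolean LED state per second."""

    ticks: np.ndarray
    duration_s: int

    def __post_init__(self) -> None:
        ticks = np.asarray(self.ticks, dtype=bool)
        if ticks.shape != (self.duration_s,):
            raise ValueError("timeline length must equal duration_s")
        object.__setattr__(self, "ticks", ticks)

    @property
    def on_seconds(self) -> int:
        return int(self.ticks.sum())


def simulate(program: StimProgram, duration_s: int) -> IlluminationTimeline:
    """Run a program at 1 Hz for ``duration_s`` seconds.

    REPEAT loops the whole step list; HALT leaves the LED off for the
    remainder. A bare REPEAT with no steps is an empty loop (always off).
    """
    if duration_s < 1:
        raise ValueError("duration_s must be >= 1")
    cycle: list[bool] = []
    for ins in program.steps:
        cycle.extend([ins.kind == "ON"] * ins.duration_s)
    if program.terminator == "REPEAT" and cycle:
        reps = -(-duration_s // len(cycle))  # ceil
        ticks = np.tile(np.asarray(cycle, dtype=bool), reps)[:duration_s]
    else:
        ticks = np.zeros(duration_s, dtype=bool)
        n = min(len(cycle), duration_s)
        ticks[:n] = cycle[:n]
    return IlluminationTimeline(ticks=ticks, duration_s=duration_s)


def duty_cycle(program: StimProgram, duration_s: int) -> float:
    """Fraction of seconds the LED is on over ``duration_s``."""
    if duration_s < 1:
        raise ValueError("duration_s must be >= 1")
    return simulate(program, duration_s).on_seconds / duration_s


def dose(program: StimProgram, duration_s: int, power: float) -> float:
    """Cumulative light dose: ``power`` (per-second units) x on-seconds."""
    if power < 0:
        raise ValueError("power must be non-negative")
    return power * simulate(program, duration_s).on_seconds
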