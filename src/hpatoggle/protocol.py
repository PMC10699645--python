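"""Piecewise-constant stimulation protocols.

A :class:`Protocol` is an ordered, contiguous list of segments, each holding
a constant stress input ``u`` and treatment factor ``D``, plus optional
instantaneous injection events (an exogenous CRH bolus or a DEX dose).
Times are in days.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .params import ConfigError

LIGANDS = ("CRH_ex", "DEX")

_TIME_TOL = 1e-9


@dataclass(frozen=True)
class Segment:
    t_start: float
    t_end: float
    u: float
    D: float = 1.0


@dataclass(frozen=True)
class Injection:
    time: float
    ligand: str       # one of LIGANDS
    amount: float     # normalized units; may be negative to end a square pulse


@dataclass(frozen=True)
class Protocol:
    segments: tuple[Segment, ...]
    events: tuple[Injection, ...] = ()

    def __post_init__(self) -> None:
        if not self.segments:
            raise ConfigError("protocol needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "events", tuple(self.events))
        prev_end = None
        for seg in self.segments:
            if not seg.t_end > seg.t_start:
                raise ConfigError(
                    f"segment [{seg.t_start}, {seg.t_end}] has no duration")
            if prev_end is not None and abs(seg.t_start - prev_end) > _TIME_TOL:
                raise ConfigError(
                    f"protocol gap: segment starts at {seg.t_start} but the "
                    f"previous one ends at {prev_end}")
            if not seg.u > 0:
                raise ConfigError(f"stress input u must be positive, got {seg.u}")
            if not seg.D >= 1:
                raise ConfigError(f"treatment factor D must be >= 1, got {seg.D}")
            prev_end = seg.t_end
        t0, t1 = self.span
        for ev in self.events:
            if ev.ligand not in LIGANDS:
                raise ConfigError(
                    f"unknown ligand {ev.ligand!r}; valid: {LIGANDS}")
            if ev.amount == 0:
                raise ConfigError("injection amount must be nonzero")
            if not (t0 - _TIME_TOL <= ev.time <= t1 + _TIME_TOL):
                raise ConfigError(
                    f"injection at t={ev.time} outside protocol span "
                    f"[{t0}, {t1}]")

    @property
    def span(self) -> tuple[float, float]:
        return self.segments[0].t_start, self.segments[-1].t_end

    def _segment_at(self, t: float) -> Segment:
        t0, t1 = self.span
        if not (t0 - _TIME_TOL <= t <= t1 + _TIME_TOL):
            raise ConfigError(f"time {t} outside protocol span [{t0}, {t1}]")
        starts = [s.t_start for s in self.segments]
        i = bisect.bisect_right(starts, t) - 1
        return self.segments[max(i, 0)]

    def u(self, t: float) -> float:
        return self._segment_at(t).u

    def D(self, t: float) -> float:
        return self._segment_at(t).D

    # -- builders -----------------------------------------------------------

    @classmethod
    def constant(cls, u: float = 1.0, D: float = 1.0,
                 t_start: float = 0.0, t_end: float = 100.0,
                 events: tuple[Injection, ...] = ()) -> "Protocol":
        return cls((Segment(t_start, t_end, u, D),), events)

    @classmethod
    def pulse(cls, u_base: float, u_pulse: float, t_on: float,
              duration: float, total: float, D_base: float = 1.0,
              D_pulse: float | None = None) -> "Protocol":
        """Baseline conditions with one [t_on, t_on+duration) pulse window."""
        D_pulse = D_base if D_pulse is None else D_pulse
        t_off = t_on + duration
        if not 0.0 <= t_on < t_off <= total:
            raise ConfigError("pulse window must lie inside [0, total]")
        segs: list[Segment] = []
        if t_on > 0:
            segs.append(Segment(0.0, t_on, u_base, D_base))
        segs.append(Segment(t_on, t_off, u_pulse, D_pulse))
        if t_off < total:
            segs.append(Segment(t_off, total, u_base, D_base))
        return cls(tuple(segs))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"t_start": s.t_start, "t_end": s.t_end, "u": s.u, "D": s.D}
                for s in self.segments],
            "events": [
                {"time": e.time, "ligand": e.ligand, "amount": e.amount}
                for e in self.events],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Protocol":
        unknown = set(data) - {"segments", "events"}
        if unknown:
            raise ConfigError(f"unknown protocol key(s): {sorted(unknown)}")
        seg_keys = {"t_start", "t_end", "u", "D"}
        segs = []
        for raw in data.get("segments", []):
            bad = set(raw) - seg_keys
            if bad:
                raise ConfigError(f"unknown segment key(s): {sorted(bad)}")
            segs.append(Segment(**raw))
        ev_keys = {"time", "ligand", "amount"}
        events = []
        for raw in data.get("events", []):
            bad = set(raw) - ev_keys
            if bad:
                raise ConfigError(f"unknown event key(s): {sorted(bad)}")
            events.append(Injection(**raw))
        return cls(tuple(segs), tuple(events))
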