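"""Named parameter/subject presets.

``susceptible`` and ``resilient`` differ only in the baseline stress input
(u = 1 versus u = 0.4): the former sits in the bistable window with three
fixed points, the latter below it with a single euthymic point.  The
subject presets park a full-model individual at the euthymic (control) or
depressed (mdd) fixed point at baseline stress.
"""

from __future__ import annotations

from .config import RunConfig
from .params import ConfigError, ModelParameters
from .protocol import Protocol
from .scenarios import Subject, make_subject

PRESET_NAMES = ("susceptible", "resilient", "control-subject", "mdd-subject")


def preset(name: str) -> RunConfig | Subject:
    """Return a preset RunConfig (regimes) or Subject (individuals)."""
    params = ModelParameters()
    if name == "susceptible":
        return RunConfig(parameters=params,
                         protocol=Protocol.constant(u=1.0, t_end=200.0))
    if name == "resilient":
        return RunConfig(parameters=params,
                         protocol=Protocol.constant(u=0.4, t_end=200.0))
    if name == "control-subject":
        return make_subject("control", 1.0, params)
    if name == "mdd-subject":
        return make_subject("MDD", 1.0, params)
    raise ConfigError(
        f"unknown preset {name!r}; valid presets: {PRESET_NAMES}")
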