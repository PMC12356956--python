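"""Shipped worked-example fixtures.

Two risk tables encode the published worked-example numbers of the road
safety case study so the framework's headline quantities can be recomputed
without any external dataset:

* ``scenario_two_factor`` — two-factor DUI/snow example on the delta scale
  (baseline entered as 0, so table lookups yield the published deltas
  0.895, 0.018 and combined 0.997 directly);
* ``scenario_three_factor`` — three-factor DUI/snow/no-seatbelt example with
  published percentage-scale fatal risks (baseline 0.259, singles 0.277 /
  0.273 / 4.793, all-risk 5.193, DUI+snow-with-belt 0.297).

These tables are published summary values, not outputs of any network
shipped in this package.
"""

from __future__ import annotations

import json
from importlib import resources

from .effects import RiskTable
from .io import risk_table_from_dict

FIXTURE_NAMES = ("scenario_two_factor", "scenario_three_factor")


def fixture_dict(name: str) -> dict:
    """Raw JSON content of a shipped fixture."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    text = resources.files("synrisk.data").joinpath(f"{name}.json").read_text()
    return json.loads(text)


def load_risk_table(name: str) -> RiskTable:
    """A shipped worked-example risk table by name."""
    return risk_table_from_dict(fixture_dict(name))
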