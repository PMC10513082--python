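"""Accessor for the packaged externally reported summary statistics."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

__all__ = ["reported_results"]


@lru_cache(maxsize=1)
def reported_results() -> dict:
    """Published base-case summaries and complication breakdowns (read-only).

    These are reference values shipped with the package for arithmetic
    consistency checks (net-monetary-benefit identity, breakdown row sums);
    nothing in the simulation reads them.
    """
    text = resources.files("glp1ce.data").joinpath("reference_results.json").read_text()
    return json.loads(text)
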