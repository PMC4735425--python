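"""Loader for the vendored circuit parameter file."""

from __future__ import annotations

import copy
from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=1)
def _raw() -> dict:
    ref = resources.files("bgqsp.data").joinpath("circuit_params.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def circuit_params() -> dict:
    """A deep copy of the circuit parameter tree (channel constants, synapse
    kinetics, wiring in-degrees, noise magnitudes)."""
    return copy.deepcopy(_raw())
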