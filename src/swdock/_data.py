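"""Access to the packaged default parameter tables."""

from __future__ import annotations

import functools
from importlib import resources

import yaml


@functools.lru_cache(maxsize=1)
def load_defaults() -> dict:
    text = resources.files("swdock").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)
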