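"""Canonical constants, loaded from the packaged ``defaults.yaml``.

The YAML file is the single place where model and analysis constants are
surfaced for inspection and override; the dataclass defaults across the
package mirror it (the test suite asserts they stay in sync).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

__all__ = ["load_defaults"]


@lru_cache(maxsize=1)
def load_defaults() -> dict:
    """Parsed contents of the packaged defaults.yaml."""
    text = resources.files("consonance").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)
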