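"""Access to the study-reported reference values packaged with the model.

These are the original publication's summary surfaces -- the observed cost
ledger per arm and the base-case strategy outcomes per instrument -- kept as
inputs for desk-scale ratio arithmetic and synthetic-cohort calibration.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=1)
def load_reported() -> dict:
    """The packaged reference tables as a plain dict."""
    text = resources.files("cardiocea.data").joinpath("reported.yaml").read_text()
    return yaml.safe_load(text)
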