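"""Configuration loading for the reference parameter sets.

Reference configurations are shipped as versioned YAML files under
``angioswitch/configs`` and are the single source of truth for calibrated
parameter values.  Each file has a ``params`` section (fields of
:class:`~angioswitch.li_core.FeedbackParams`) plus analysis-specific
sections (``classify``, ``sweep``, ``scan``, ...).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Union

import yaml

from .li_core import FeedbackParams

__all__ = ["load_config", "reference_config", "params_from_config",
           "REFERENCE_NAMES"]

REFERENCE_NAMES = ("bifurcation", "matrix", "msm", "cohort")


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML configuration file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def reference_config(name: str) -> dict:
    """Load one of the shipped reference configurations by name."""
    if name not in REFERENCE_NAMES:
        raise ValueError(f"unknown reference config {name!r}; "
                         f"choose from {REFERENCE_NAMES}")
    ref = resources.files("angioswitch") / "configs" / f"{name}.yaml"
    cfg = yaml.safe_load(ref.read_text())
    return cfg


def params_from_config(cfg: dict) -> FeedbackParams:
    """Build :class:`FeedbackParams` from a config dict's ``params`` section."""
    section = cfg.get("params", cfg)
    return FeedbackParams(**section)
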