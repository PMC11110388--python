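"""Access to the data files shipped with the package.

* Four editable triage-tool fixture specs (three grouped four-step tools and
  one ungrouped checklist).  Their variable lists are conventional
  field-triage placeholders: real deployments must supply each service's
  authentic checklist.
* A reference table of published contingency counts (observed provider
  decisions and cumulative tool steps, per service and pooled) against the
  primary consensus reference standard, used as direct input for
  counts-based estimation.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List

import pandas as pd

from .rules import TriageToolSpec, load_tool_spec

_TOOL_FILES = {"LAS": "las.yaml", "SWAS": "swas.yaml", "WMAS": "wmas.yaml", "YAS": "yas.yaml"}


def _data_root():
    return resources.files("trauma_triage") / "data"


def packaged_tool_paths() -> Dict[str, str]:
    return {label: str(_data_root() / "tools" / name) for label, name in _TOOL_FILES.items()}


def load_packaged_tools() -> List[TriageToolSpec]:
    return [load_tool_spec(path) for path in packaged_tool_paths().values()]


def observed_decision_counts() -> pd.DataFrame:
    """Published 2x2 counts (tp/fp/tn/fn) with their printed accuracy metrics."""
    with resources.as_file(_data_root() / "observed_decision_counts.csv") as path:
        return pd.read_csv(path)
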