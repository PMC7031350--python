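"""Machine-readable run reports (JSON in, JSON out)."""

from __future__ import annotations

import json
from pathlib import Path

__all__ = ["write_report", "read_report"]

_REPORT_KEYS = ("config", "stage", "early_stop", "linearity", "exploration",
                "partition", "metamodels", "global")


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path: str | Path) -> Path:
    """Serialize a pipeline report to pretty-printed JSON.

    The document always carries the full run configuration so any number in
    it can be regenerated from the report alone.
    """
    missing = [k for k in _REPORT_KEYS if k not in report]
    if missing:
        raise ValueError(f"report is missing required sections: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(report), indent=2, allow_nan=True))
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
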