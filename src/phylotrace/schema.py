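"""Structural validation of JSON reports against the published schema.

The schema (``report_schema.json``) lists, per report kind, the keys a
report must carry.  Validation is structural only — key presence plus a
few type checks — which is all the stability contract promises.
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = ["load_schema", "validate_report"]


def load_schema() -> dict:
    with resources.files("phylotrace").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def _require(obj: dict, keys: list, where: str) -> None:
    missing = [k for k in keys if k not in obj]
    if missing:
        raise ValueError(f"report {where}: missing keys {missing}")


def validate_report(report: dict, kind: str = "analyze") -> None:
    """Raise ValueError if ``report`` does not match the published schema."""
    schema = load_schema()
    if kind not in ("analyze", "compare"):
        raise ValueError(f"unknown report kind {kind!r}")
    spec = schema[kind]
    _require(report, spec["required"], kind)
    if report["schema_version"] != schema["schema_version"]:
        raise ValueError("schema_version mismatch")
    if kind == "analyze":
        _require(report["burnin"], spec["burnin"]["required"], "burnin")
        for name, p in report["parameters"].items():
            _require(p, spec["parameter"]["required"], f"parameters[{name}]")
            _require(p["summary"], spec["summary"]["required"], f"{name}.summary")
            if p["diagnostics"] is not None:
                _require(
                    p["diagnostics"],
                    spec["diagnostics"]["required"],
                    f"{name}.diagnostics",
                )
        for name, t in report["trees"].items():
            _require(t, spec["tree"]["required"], f"trees[{name}]")
            for e in t["entries"]:
                _require(e, spec["tree_entry"]["required"], f"trees[{name}].entries")
    else:
        for name, r in report["mann_whitney"].items():
            _require(r, spec["two_sample"]["required"], f"mann_whitney[{name}]")
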