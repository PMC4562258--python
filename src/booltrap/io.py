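"""File I/O for the ``.bnet`` dialect and JSON reports."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .approximation import ApproximationReport
from .network import BooleanNetwork, parse_network

__all__ = ["read_bnet", "write_bnet", "report_schema", "validate_report"]


def read_bnet(path) -> BooleanNetwork:
    """Parse a ``.bnet`` file (write∘read is the identity up to whitespace)."""
    text = Path(path).read_text()
    return parse_network(text)


def write_bnet(net: BooleanNetwork, path, header: bool = True) -> None:
    Path(path).write_text(net.to_bnet(header=header))


def report_schema() -> dict:
    """The published JSON schema of the analysis report."""
    text = resources.files("booltrap").joinpath("report_schema.json").read_text()
    return json.loads(text)


def validate_report(data) -> ApproximationReport:
    """Validate report JSON (dict or string) against the report contract."""
    if isinstance(data, (str, bytes)):
        data = json.loads(data)
    return ApproximationReport.model_validate(data)
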