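"""Access to the packaged default configuration files under ``data/``."""

from __future__ import annotations

from importlib import resources
from typing import IO


def open_data(name: str) -> IO[str]:
    """Open a packaged data file for text reading."""
    return resources.files("neurolabel").joinpath("data", name).open(
        "r", encoding="utf-8"
    )


def read_data(name: str) -> str:
    with open_data(name) as fh:
        return fh.read()
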