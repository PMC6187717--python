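"""Run manifests: every stochastic output is traceable to a recorded seed."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    seed: int | None
    config: dict
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    inputs: dict = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def record_output(self, path: str | Path) -> None:
        self.outputs[Path(path).name] = file_sha256(path)

    def record_input(self, path: str | Path) -> None:
        self.inputs[Path(path).name] = file_sha256(path)

    def write(self, path: str | Path) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
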