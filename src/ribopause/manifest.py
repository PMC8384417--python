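"""Provenance stamps for CLI runs.

Every output directory receives exactly one ``run_manifest.yaml`` recording
the subcommand, resolved parameters, SHA-256 hashes of the inputs, library
versions, a timestamp, and the seed, so a run can be reproduced bit-exactly
for the exact-mode operations.
"""

from __future__ import annotations

import hashlib
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

MANIFEST_NAME = "run_manifest.yaml"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _versions() -> dict:
    import numpy, pandas, scipy
    import ribopause
    return {
        "ribopause": ribopause.__version__,
        "python": sys.version.split()[0],
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }


def write_manifest(out_dir: Path, command: str, parameters: Mapping,
                   inputs: Optional[Sequence[Path]] = None,
                   seed: Optional[int] = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {
        "command": command,
        "parameters": {k: (str(v) if isinstance(v, Path) else v)
                       for k, v in dict(parameters).items()},
        "input_hashes": {str(p): _sha256(Path(p)) for p in (inputs or []) if Path(p).exists()},
        "library_versions": _versions(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path
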