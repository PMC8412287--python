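"""Plain-text readers/writers for the pipeline artifacts.

Registry tables are tab-separated with header
``paternal  maternal  ses_raw  block``; knowledge graphs use the
standard triplet format ``head<TAB>relation<TAB>tail`` (one per line),
with an optional weights sidecar carrying a fourth column. All writers
are deterministic: fixed column order, fixed float formatting, sorted
keys in JSON/YAML sidecars.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .errors import ParameterError
from .synthetic import IndividualRecord, RegistryParams

__all__ = [
    "write_registry", "read_registry",
    "write_triplets", "read_triplets",
    "write_weighted_triplets", "read_weighted_triplets",
    "write_yaml", "read_yaml", "write_json",
]

_REGISTRY_HEADER = ["paternal", "maternal", "ses_raw", "block"]


def write_registry(records, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("\t".join(_REGISTRY_HEADER) + "\n")
        for r in records:
            fh.write(f"{r.paternal}\t{r.maternal}\t{r.ses_raw:.6f}\t{r.block}\n")


def read_registry(path) -> list[IndividualRecord]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _REGISTRY_HEADER:
            raise ParameterError(f"unexpected registry header {header!r}")
        out = []
        for line in fh:
            p, m, s, b = line.rstrip("\n").split("\t")
            out.append(IndividualRecord(paternal=p, maternal=m, ses_raw=float(s), block=b))
    return out


def write_triplets(triplets, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for h, r, t in triplets:
            fh.write(f"{h}\t{r}\t{t}\n")


def read_triplets(path) -> list[tuple[str, str, str]]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            h, r, t = line.split("\t")
            out.append((h, r, t))
    return out


def write_weighted_triplets(triplets_with_weights, path) -> None:
    """Rows of (head, relation, tail, weight)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for h, r, t, w in triplets_with_weights:
            fh.write(f"{h}\t{r}\t{t}\t{w}\n")


def read_weighted_triplets(path):
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            h, r, t, w = line.split("\t")
            out.append((h, r, t, int(w)))
    return out


def write_yaml(obj, path) -> None:
    if isinstance(obj, RegistryParams):
        obj = asdict(obj)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=True, default_flow_style=False))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
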