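"""YAML (de)serialisation of the package's configuration dataclasses.

Handles the nesting that actually occurs in practice: lists of
``AccessionParams`` inside a ``GrowthSeriesSpec`` and the per-class
``BlobClassParams`` map inside an ``OrganelleSpec``; everything else is
flat.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from . import synthetic_data as syn


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def dump_yaml(obj, path) -> None:
    """Serialise a config dataclass to a YAML file."""
    Path(path).write_text(yaml.safe_dump(_to_plain(obj), sort_keys=False))


_NESTED = {
    (syn.GrowthSeriesSpec, "accessions"):
        lambda v: None if v is None else [syn.AccessionParams(**d) for d in v],
    (syn.GrowthSeriesSpec, "soil_base_color"): tuple,
    (syn.OrganelleSpec, "class_params"):
        lambda v: None if v is None else {
            k: syn.BlobClassParams(**{kk: tuple(vv) for kk, vv in d.items()})
            for k, d in v.items()
        },
}


def load_yaml(path, cls):
    """Load a YAML file written by :func:`dump_yaml` back into ``cls``."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    for (owner, field), conv in _NESTED.items():
        if cls is owner and field in data:
            data[field] = conv(data[field])
    return cls(**data)
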