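"""The frozen, versioned feature-name catalog (108 names, 7 families)."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources


@lru_cache(maxsize=1)
def load_catalog() -> dict:
    """Return {"version": str, "families": {family: [names...]}}."""
    with resources.files(__package__).joinpath("catalog.json").open() as fh:
        return json.load(fh)


def catalog_version() -> str:
    return load_catalog()["version"]


def family_names(family: str) -> list[str]:
    return list(load_catalog()["families"][family])


@lru_cache(maxsize=1)
def all_feature_names() -> tuple[str, ...]:
    """Full ordered catalog as '<family>_<Name>' qualified names."""
    names = []
    for family, feats in load_catalog()["families"].items():
        names.extend(f"{family}_{f}" for f in feats)
    return tuple(names)
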