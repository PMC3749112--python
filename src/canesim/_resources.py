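"""Access to packaged parameter files and fixture tables."""

from __future__ import annotations

from importlib import resources

import yaml


def _data_path(name: str):
    return resources.files("canesim").joinpath("data", name)


def load_packaged_yaml(name: str) -> dict:
    with _data_path(name).open("r") as fh:
        return yaml.safe_load(fh)


def packaged_csv_path(name: str):
    return _data_path(name)
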