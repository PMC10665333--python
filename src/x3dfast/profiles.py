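"""Named model profiles shipped as YAML files under ``x3dfast/profiles/``."""

from __future__ import annotations

from importlib import resources

import yaml

from .model import ModelConfig

__all__ = ["load_profile", "profile_names", "save_profile"]


def profile_names() -> list[str]:
    pkg = resources.files(__name__.rsplit(".", 1)[0]) / "profiles"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_profile(name_or_path: str) -> ModelConfig:
    """Load a packaged profile by name ('full', 'tiny') or a YAML file by path."""
    pkg = resources.files(__name__.rsplit(".", 1)[0]) / "profiles" / f"{name_or_path}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        with open(name_or_path) as fh:
            text = fh.read()
    return ModelConfig.from_dict(yaml.safe_load(text))


def save_profile(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
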