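"""Run configuration: a YAML file describing a deployable system.

Recognized keys (all optional):

``mode``            "indirect" | "direct"
``seed``            integer master seed
``subjects``        registry size
``sites``           number of sites
``docs_per_subject``  [lo, hi]
``encrypt_master``  bool, master-data encryption at rest on the primary
``url_max_len``     request-line limit for fragmentation
``rbac``            role -> data class -> list of operations (overrides
                    the default matrix for the declared roles)
``site_restricted_roles``  list of roles limited to their own site

Values given in the file take precedence over command-line flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .tokens import DEFAULT_MAX_REQUEST_LINE


class ConfigFileError(ValueError):
    pass


@dataclass
class RunConfig:
    mode: str = "indirect"
    seed: int = 0
    subjects: int = 10
    sites: int = 3
    docs_per_subject: tuple[int, int] = (2, 2)
    encrypt_master: bool = True
    url_max_len: int = DEFAULT_MAX_REQUEST_LINE
    rbac: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    site_restricted_roles: list[str] = field(default_factory=lambda: ["physician", "lab"])

    def validate(self) -> None:
        if self.mode not in ("indirect", "direct"):
            raise ConfigFileError(f"mode must be direct or indirect, got {self.mode!r}")
        if self.subjects < 0 or self.sites < 1:
            raise ConfigFileError("subjects must be >= 0 and sites >= 1")
        if self.url_max_len < 64:
            raise ConfigFileError("url_max_len too small to carry framing")

    def rbac_matrix(self):
        """Default matrix with the file's per-role overrides applied."""
        from .backends import DEFAULT_RBAC

        matrix = {role: dict(classes) for role, classes in DEFAULT_RBAC.items()}
        for role, classes in self.rbac.items():
            matrix[role] = {dc: frozenset(ops) for dc, ops in classes.items()}
        return matrix


def load_config(path: str | Path) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    except yaml.YAMLError as exc:
        raise ConfigFileError(f"malformed config file: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigFileError("config root must be a mapping")
    cfg = RunConfig()
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ConfigFileError(f"unknown config key {key!r}")
        if key == "docs_per_subject":
            value = tuple(value)
        setattr(cfg, key, value)
    cfg.validate()
    return cfg
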