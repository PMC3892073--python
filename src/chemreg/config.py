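"""YAML configuration: store location, fingerprint parameters, planner
thresholds, search defaults, the security permission map and logging.

CLI flags override config values; the fingerprint parameters are part of
the config so stored fingerprints are reproducible across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .matching import FingerprintParams

__all__ = ["AppConfig", "SecurityConfig", "load_config"]


@dataclass
class SecurityConfig:
    enabled: bool = False
    # entity kind -> operation -> list of roles
    permissions: dict = field(default_factory=dict)


@dataclass
class AppConfig:
    store_path: str = "chemreg.db"
    fingerprint: FingerprintParams = field(default_factory=FingerprintParams)
    planner_tau: float = 0.05
    planner_n_max: int = 5000
    distinct_default: bool = True
    page_size_default: int = 4
    store_canonical_smiles: bool = True
    security: SecurityConfig = field(default_factory=SecurityConfig)
    log_level: str = "WARNING"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def load_config(path: str | None) -> AppConfig:
    if path is None:
        return AppConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = AppConfig()
    if "store_path" in raw:
        cfg.store_path = str(raw["store_path"])
    if "fingerprint" in raw:
        fp = raw["fingerprint"] or {}
        cfg.fingerprint = FingerprintParams(
            n_bits=int(fp.get("n_bits", 2048)),
            max_path_atoms=int(fp.get("max_path_atoms", 7)))
    for key in ("planner_tau", "planner_n_max", "distinct_default",
                "page_size_default", "store_canonical_smiles", "log_level"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "security" in raw:
        sec = raw["security"] or {}
        cfg.security = SecurityConfig(
            enabled=bool(sec.get("enabled", False)),
            permissions=sec.get("permissions", {}) or {})
    return cfg
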