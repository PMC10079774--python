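"""Configuration loading and plain-text serialization with provenance.

All artifacts are diffable text: radial profiles as CSV with commented
header lines carrying the generating configuration, seed, config hash
and package version; summaries as schema-checked JSON. Every file on
disk is reproducible from its embedded configuration and seed.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .montecarlo import RadialReflectance

__all__ = [
    "RunConfig",
    "ConfigError",
    "ProfileParseError",
    "load_config",
    "save_config",
    "config_hash",
    "write_profile",
    "read_profile",
    "write_summary",
    "validate_summary",
]


class ConfigError(ValueError):
    """Raised for unparseable configuration files or unknown keys."""


class ProfileParseError(ValueError):
    """Raised when a profile CSV is malformed; carries the offending line."""


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration with the package defaults.

    Covers the boundary (n_in/n_out), the diffusion-coefficient
    convention, the inversion AC frequency, the validity-filter mode,
    integration truncation limits, and the Monte Carlo geometry/budget.
    """

    n_in: float = 1.33
    n_out: float = 1.00
    diffusion_coefficient: str = "mus_plus_mua"
    f_ac: float = 0.5
    filter_mode: str = "literal"
    z0_max: float = 100.0
    rho_max: float = 500.0
    n_photons: int = 1_000_000
    bin_width: float = 0.004
    n_bins: int = 100_000
    repeats: int = 3
    seed: int = 12345
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the canonical JSON form of a config."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML or JSON config; defaults fill missing keys.

    Unknown keys are rejected with a close-match suggestion so typos
    never silently fall back to defaults.
    """
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text) if text.strip() else {}
        else:
            data = tomllib.loads(text)
    except (json.JSONDecodeError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in data:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {key!r}{extra}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")


def write_profile(
    path: str | Path, rr: RadialReflectance, cfg: Optional[RunConfig] = None
) -> None:
    """Write a radial profile as CSV with a commented provenance header."""
    from . import __version__

    lines = [f"# sfdikit_version: {__version__}"]
    if cfg is not None:
        lines.append(f"# config_hash: {config_hash(cfg)}")
    for key, val in rr.meta.items():
        lines.append(f"# {key}: {val}")
    lines.append(f"# bin_width: {rr.bin_width!r}")
    lines.append(f"# absorbed_fraction: {rr.absorbed_fraction!r}")
    lines.append(f"# overflow_fraction: {rr.overflow_fraction!r}")
    lines.append("rho_mm,R_per_mm2")
    body = "\n".join(
        f"{r:.6g},{v:.10g}" for r, v in zip(rr.bin_centers, rr.values)
    )
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_profile(path: str | Path) -> RadialReflectance:
    """Read a profile CSV written by :func:`write_profile`."""
    path = Path(path)
    meta: dict = {}
    header_rows = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                header_rows += 1
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
            else:
                break
    try:
        df = pd.read_csv(path, skiprows=header_rows)
    except Exception as exc:
        raise ProfileParseError(f"cannot parse {path}: {exc}") from exc
    for col in ("rho_mm", "R_per_mm2"):
        if col not in df.columns:
            raise ProfileParseError(
                f"{path}: missing column {col!r} on line {header_rows + 1}"
            )
    centers = df["rho_mm"].to_numpy(float)
    width = float(meta.get("bin_width", centers[1] - centers[0] if centers.size > 1 else 0))
    return RadialReflectance(
        bin_centers=centers,
        values=df["R_per_mm2"].to_numpy(float),
        bin_width=width,
        n_photons=int(meta.get("n_photons", 0) or 0),
        absorbed_fraction=float(meta.get("absorbed_fraction", np.nan)),
        overflow_fraction=float(meta.get("overflow_fraction", np.nan)),
        meta=meta,
    )


#: Required shape of a study summary JSON document.
SUMMARY_SCHEMA = {
    "models": dict,  # model name -> {median, q25, q75, n_points}
    "seed": int,
    "config_hash": str,
}


def validate_summary(doc: dict) -> None:
    """Check a summary document against :data:`SUMMARY_SCHEMA`."""
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in doc:
            raise ValueError(f"summary missing required key {key!r}")
        if not isinstance(doc[key], typ):
            raise ValueError(f"summary key {key!r} must be {typ.__name__}")
    for name, stats in doc["models"].items():
        for stat in ("median", "q25", "q75", "n_points"):
            if stat not in stats:
                raise ValueError(f"summary model {name!r} missing {stat!r}")


def write_summary(path: str | Path, doc: dict) -> None:
    """Schema-validate and write a summary JSON document."""
    validate_summary(doc)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {o!r}")

    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=default) + "\n")
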