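"""Layered run configuration.

Every tunable of the pipeline is addressed by a flat dotted key
(``section.key``). Values resolve with precedence flags > file > defaults,
and each resolved value carries a provenance tag so a run can be audited
and reproduced. The file format is a flat ``section.key: value`` mapping
(YAML-compatible).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import DomainError
from .morph_snake import MsParams
from .preprocessing import SCHEMES, ClaheParams, SwfParams

__all__ = ["Config", "DEFAULTS", "resolve_config", "segment_kwargs"]

# key -> (default value, type). dispatch_override is "R,ITERS" or None.
DEFAULTS: dict[str, tuple[object, type]] = {
    "preprocess.scheme": ("clahe_swf", str),
    "clahe.clip_limit": (2.0, float),
    "clahe.tiles": (8, int),
    "swf.radius": (3, int),
    "swf.kernel": ("box", str),
    "swf.iterations": (5, int),
    "ms.balloon": (-1.0, float),
    "ms.theta": (0.3, float),
    "ms.alpha": (20000.0, float),
    "ms.sigma": (2.0, float),
    "ms.smooth_passes": (1, int),
    "ams.dispatch_override": (None, str),
    "select.fast_threshold": (96, int),
}


@dataclass(frozen=True)
class Config:
    values: dict
    provenance: dict

    def __getitem__(self, key: str):
        return self.values[key]

    def dump(self, path: str | Path) -> None:
        """Write the resolved configuration; re-running with this file
        reproduces the run."""
        lines = [
            f"{k}: {v}" for k, v in sorted(self.values.items()) if v is not None
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _coerce(key: str, value: object) -> object:
    default, typ = DEFAULTS[key]
    if value is None:
        return None
    if typ is float:
        try:
            return float(value)
        except (TypeError, ValueError):
            raise DomainError(f"config key {key!r} expects a float, got {value!r}")
    if typ is int:
        if isinstance(value, bool) or (isinstance(value, float) and value != int(value)):
            raise DomainError(f"config key {key!r} expects an integer, got {value!r}")
        try:
            return int(value)
        except (TypeError, ValueError):
            raise DomainError(f"config key {key!r} expects an integer, got {value!r}")
    return str(value)


def resolve_config(
    file: str | Path | None = None, flags: dict[str, object] | None = None
) -> Config:
    """Resolve flags > file > defaults into a fully specified Config;
    unknown keys are rejected by name."""
    values = {k: v for k, (v, _) in DEFAULTS.items()}
    provenance = {k: "default" for k in DEFAULTS}
    if file is not None:
        raw = yaml.safe_load(Path(file).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise DomainError(f"config file {file} must be a flat key: value mapping")
        for key, val in raw.items():
            if key not in DEFAULTS:
                raise DomainError(f"unknown config key {key!r}")
            values[key] = _coerce(key, val)
            provenance[key] = "file"
    for key, val in (flags or {}).items():
        if key not in DEFAULTS:
            raise DomainError(f"unknown config key {key!r}")
        values[key] = _coerce(key, val)
        provenance[key] = "flag"
    if values["preprocess.scheme"] not in SCHEMES:
        raise DomainError(
            f"config key 'preprocess.scheme' must be one of {SCHEMES}"
        )
    return Config(values=values, provenance=provenance)


def _parse_dispatch(value: str | None) -> tuple[int, int] | None:
    if value in (None, "", "none"):
        return None
    try:
        r, it = (int(x) for x in str(value).split(","))
    except ValueError:
        raise DomainError(
            "config key 'ams.dispatch_override' expects 'RADIUS,ITERATIONS'"
        )
    return (r, it)


def segment_kwargs(config: Config) -> dict:
    """Translate a resolved Config into amsmw_segment keyword arguments."""
    v = config.values
    return {
        "scheme": v["preprocess.scheme"],
        "clahe_params": ClaheParams(
            clip_limit=v["clahe.clip_limit"],
            tile_rows=v["clahe.tiles"],
            tile_cols=v["clahe.tiles"],
        ),
        "swf_params": SwfParams(
            radius=v["swf.radius"],
            kernel=v["swf.kernel"],
            iterations=v["swf.iterations"],
        ),
        "ms_params": MsParams(
            balloon=v["ms.balloon"],
            theta=v["ms.theta"],
            alpha=v["ms.alpha"],
            sigma=v["ms.sigma"],
            smooth_passes=v["ms.smooth_passes"],
        ),
        "dispatch_override": _parse_dispatch(v["ams.dispatch_override"]),
        "fast_threshold": v["select.fast_threshold"],
    }
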