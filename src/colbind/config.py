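"""Flat key-value run configuration with scale/policy overrides.

Recognized keys::

    kt_ref = 0.693
    temperature_celsius = 25
    ph_list = 2,4,7,9
    seed = 1
    scale.<state_label> = <kcal/mol>        # e.g. scale.H+ = 2.33
    electroneg.<state_label> = -1|0|1
    ph_policy.<residue>.<ph> = <labels>     # e.g. ph_policy.D.4 = D0,D-

Unknown keys are rejected so typos fail loudly before any scan runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ColbindError
from .scale import (
    KT_REF,
    HydropathyScale,
    ProtonationPolicy,
    default_policy,
    load_default_scale,
)

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    ph_list: list[float] = field(default_factory=lambda: [2.0, 4.0, 7.0, 9.0])
    temperature_celsius: float = 25.0
    kt_ref: float = KT_REF
    scale_overrides: dict[str, float] = field(default_factory=dict)
    electroneg_overrides: dict[str, int] = field(default_factory=dict)
    policy_overrides: dict[tuple[str, float], tuple[str, ...]] = field(default_factory=dict)
    seed: int | None = None

    def build_scale(self) -> HydropathyScale:
        scale = load_default_scale()
        if self.scale_overrides or self.electroneg_overrides:
            scale = scale.with_overrides(
                dg=self.scale_overrides,
                electroneg=self.electroneg_overrides,
                name=scale.name + "+overrides",
            )
        return scale

    def build_policy(self) -> ProtonationPolicy:
        policy = default_policy()
        for (residue, ph), labels in self.policy_overrides.items():
            policy = policy.with_override(residue, ph, labels)
        return policy


def load_config(path) -> RunConfig:
    """Parse a flat ``key = value`` file ('#' starts a comment line)."""
    cfg = RunConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ColbindError(f"{path}: line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        try:
            _apply(cfg, key, value)
        except ColbindError:
            raise
        except ValueError:
            raise ColbindError(
                f"{path}: line {lineno}: cannot parse value {value!r} for {key!r}"
            ) from None
    return cfg


def _apply(cfg: RunConfig, key: str, value: str) -> None:
    if key == "kt_ref":
        cfg.kt_ref = float(value)
    elif key == "temperature_celsius":
        cfg.temperature_celsius = float(value)
    elif key == "ph_list":
        cfg.ph_list = [float(p) for p in value.split(",") if p.strip()]
    elif key == "seed":
        cfg.seed = int(value)
    elif key.startswith("scale."):
        cfg.scale_overrides[key[len("scale."):]] = float(value)
    elif key.startswith("electroneg."):
        sign = int(value)
        if sign not in (-1, 0, 1):
            raise ColbindError(f"electroneg sign must be -1, 0 or 1, got {value!r}")
        cfg.electroneg_overrides[key[len("electroneg."):]] = sign
    elif key.startswith("ph_policy."):
        parts = key.split(".")
        if len(parts) != 3:
            raise ColbindError(f"bad policy key {key!r} (want ph_policy.<residue>.<ph>)")
        labels = tuple(lab.strip() for lab in value.split(",") if lab.strip())
        cfg.policy_overrides[(parts[1].upper(), float(parts[2]))] = labels
    else:
        raise ColbindError(f"unknown config key {key!r}")
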