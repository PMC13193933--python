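"""Packaged athlete baseline-RFD profiles."""

from __future__ import annotations

import json
from importlib import resources

from .model import AthleteProfile

__all__ = ["load_profiles", "get_profile"]


def load_profiles() -> list[AthleteProfile]:
    """Return the packaged athlete profiles (validated on load).

    Includes group-average IMTP baselines for national-caliber male
    (16652 N·s⁻¹) and female (7663 N·s⁻¹) weightlifters, plus the model's
    conceptual 15000 N·s⁻¹ default.
    """
    raw = resources.files("rfdmodel").joinpath("data/profiles.json").read_text("utf-8")
    return [
        AthleteProfile(
            label=entry["label"],
            baseline_rfd=float(entry["baseline_rfd"]),
            description=entry.get("description", ""),
        )
        for entry in json.loads(raw)
    ]


def get_profile(label: str) -> AthleteProfile:
    """Look up a packaged profile by exact label, unique prefix, or unique substring."""
    profiles = load_profiles()
    exact = [p for p in profiles if p.label == label]
    if exact:
        return exact[0]
    matches = [p for p in profiles if p.label.startswith(label)]
    if not matches:
        matches = [p for p in profiles if label in p.label]
    if len(matches) == 1:
        return matches[0]
    known = ", ".join(p.label for p in profiles)
    if not matches:
        raise KeyError(f"no profile matching {label!r}; known profiles: {known}")
    raise KeyError(
        f"profile label {label!r} is ambiguous "
        f"({', '.join(p.label for p in matches)}); known profiles: {known}"
    )
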