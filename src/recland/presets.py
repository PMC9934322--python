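"""Shipped parameter presets: one calibration per rice chromosome.

Each preset is the parameter set obtained by calibrating the model on that
chromosome of the IR64 x Azucena cross.  Calibrations transfer: predictions
made with any one preset on the other chromosomes perform equivalently, so
``chr01`` (the longest chromosome, hence the largest calibration set) is the
conventional default.
"""

from __future__ import annotations

from importlib import resources

from .model import ModelParams

PRESET_NAMES = tuple(f"chr{i:02d}" for i in range(1, 13))


def load_preset(name: str) -> ModelParams:
    """Load a shipped calibration preset by chromosome name (e.g. 'chr01')."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {list(PRESET_NAMES)}")
    text = (
        resources.files("recland").joinpath("presets", f"{name}.json").read_text()
    )
    return ModelParams.from_json(text)
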