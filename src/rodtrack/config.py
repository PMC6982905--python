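"""Flat key-value configuration files mirroring every parameter set.

Format: one ``section.key = value`` per line; ``#`` starts a comment.
Sections: ``seg`` (segmentation chain), ``kalman``, ``ninepoint``,
``highlight``, ``tracker``.  Unknown keys raise, so typos fail loudly.

Example::

    seg.binarize_threshold = 100
    ninepoint.spacing = 30
    tracker.gate = 150
"""

from __future__ import annotations

import ast
from dataclasses import fields
from pathlib import Path

from .highlight import HighlightParams
from .kalman import KalmanParams
from .ninepoint import NinePointParams
from .seglabel import SegParams
from .tracker import TrackerConfig

_SECTIONS = {
    "seg": SegParams,
    "kalman": KalmanParams,
    "ninepoint": NinePointParams,
    "highlight": HighlightParams,
    "tracker": TrackerConfig,
}


def parse_value(text: str):
    text = text.strip()
    try:
        return ast.literal_eval(text)
    except (ValueError, SyntaxError):
        return text  # bare string (e.g. mode names)


def load_config(path=None) -> dict:
    """Parse a config file into parameter objects; defaults when path is None.

    Returns ``{"seg": SegParams, "kalman": KalmanParams, "ninepoint":
    NinePointParams, "highlight": HighlightParams, "tracker": TrackerConfig}``
    with the tracker config wired to the kalman/ninepoint objects.
    """
    raw: dict = {name: {} for name in _SECTIONS}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'section.key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if "." not in key:
                raise ValueError(f"{path}:{lineno}: key {key!r} needs a section prefix")
            section, name = key.split(".", 1)
            if section not in _SECTIONS:
                raise ValueError(f"{path}:{lineno}: unknown section {section!r}")
            valid = {f.name for f in fields(_SECTIONS[section])}
            if name not in valid:
                raise ValueError(f"{path}:{lineno}: unknown key {name!r} in section {section!r}")
            raw[section][name] = parse_value(value)

    out = {name: cls(**raw[name]) for name, cls in _SECTIONS.items() if name != "tracker"}
    tracker_kwargs = dict(raw["tracker"])
    tracker_kwargs.setdefault("kalman", out["kalman"])
    tracker_kwargs.setdefault("ninepoint", out["ninepoint"])
    out["tracker"] = TrackerConfig(**tracker_kwargs)
    return out
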