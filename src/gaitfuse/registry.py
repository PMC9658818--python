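"""Canonical registries: kinematic channels and gait-transition classes.

The recognition problem is fixed: 22 sagittal/coronal-plane kinematic
parameters recorded at 100 Hz, and 8 transition classes covering the
level <-> stair and level <-> ramp locomotion-mode changes. Everything
downstream (feature naming, ablation grouping, the D-S recognition
frame) keys off these two tables, so they live in one place.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ChannelSpec:
    """One kinematic parameter (a virtual sensor channel)."""

    id: int
    abbreviation: str
    description: str


@dataclass(frozen=True)
class GaitClass:
    """One gait-pattern transition class."""

    id: int
    abbreviation: str
    description: str


CHANNELS: tuple[ChannelSpec, ...] = (
    ChannelSpec(1, "rt aa", "right hip angular acceleration"),
    ChannelSpec(2, "lt aa", "left hip angular acceleration"),
    ChannelSpec(3, "rs aa", "right knee angular acceleration"),
    ChannelSpec(4, "ls aa", "left knee angular acceleration"),
    ChannelSpec(5, "rf aa", "right ankle angular acceleration"),
    ChannelSpec(6, "lf aa", "left ankle angular acceleration"),
    ChannelSpec(7, "rt av", "right hip angular velocity"),
    ChannelSpec(8, "lt av", "left hip angular velocity"),
    ChannelSpec(9, "rs av", "right knee angular velocity"),
    ChannelSpec(10, "ls av", "left knee angular velocity"),
    ChannelSpec(11, "rf av", "right ankle angular velocity"),
    ChannelSpec(12, "lf av", "left ankle angular velocity"),
    ChannelSpec(13, "ls v", "left shank velocity"),
    ChannelSpec(14, "lt v", "left thigh velocity"),
    ChannelSpec(15, "ls a", "left shank acceleration"),
    ChannelSpec(16, "lt a", "left thigh acceleration"),
    ChannelSpec(17, "rt a", "right thigh acceleration"),
    ChannelSpec(18, "rs a", "right shank acceleration"),
    ChannelSpec(19, "rt v", "right thigh velocity"),
    ChannelSpec(20, "rs v", "right shank velocity"),
    ChannelSpec(21, "trunk a", "trunk acceleration"),
    ChannelSpec(22, "trunk v", "trunk velocity"),
)

GAIT_CLASSES: tuple[GaitClass, ...] = (
    GaitClass(1, "L-R UP", "level walking to up-ramp walking transition"),
    GaitClass(2, "R-L DOWN", "down-ramp walking to level walking transition"),
    GaitClass(3, "L-S UP", "level walking to up-stair walking transition"),
    GaitClass(4, "S-L DOWN", "down-stair walking to level walking transition"),
    GaitClass(5, "R-L UP", "up-ramp walking to level walking transition"),
    GaitClass(6, "L-R DOWN", "level walking to down-ramp walking transition"),
    GaitClass(7, "S-L UP", "up-stair walking to level walking transition"),
    GaitClass(8, "L-S DOWN", "level walking to down-stair walking transition"),
)

N_CHANNELS = len(CHANNELS)
N_CLASSES = len(GAIT_CLASSES)

CHANNEL_ABBRS: tuple[str, ...] = tuple(c.abbreviation for c in CHANNELS)
CLASS_IDS: tuple[int, ...] = tuple(g.id for g in GAIT_CLASSES)

_CHANNEL_BY_ABBR = {c.abbreviation: c for c in CHANNELS}
_CLASS_BY_ID = {g.id: g for g in GAIT_CLASSES}


def channel_by_abbr(abbr: str) -> ChannelSpec:
    try:
        return _CHANNEL_BY_ABBR[abbr]
    except KeyError:
        raise KeyError(f"unknown channel abbreviation: {abbr!r}") from None


def gait_class(class_id: int) -> GaitClass:
    try:
        return _CLASS_BY_ID[class_id]
    except KeyError:
        raise KeyError(f"unknown gait class id: {class_id!r}") from None
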