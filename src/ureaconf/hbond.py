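"""Geometric hydrogen-bond counting over coordinate frames.

A donor-H...acceptor contact counts as a hydrogen bond when the
donor-heavy-atom to acceptor-heavy-atom distance is at most ``max_dist``
(default 3.0 A) and the donor-H-acceptor angle is at least ``min_angle``
(default 135 deg) — the standard geometric criteria used by trajectory
analysis tools.  Contacts are credited to named groups (e.g. the solute
carbonyl acceptor, the solute amide donors) via labels carried by the
donor/acceptor sites; unlabelled sites (e.g. solvent) contribute geometry
but no group of their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["Donor", "Acceptor", "Frame", "hbond_count"]


@dataclass
class Donor:
    """A donor heavy atom with its bonded hydrogen (explicit coordinates)."""

    heavy: np.ndarray
    hydrogen: np.ndarray
    group: Optional[str] = None


@dataclass
class Acceptor:
    pos: np.ndarray
    group: Optional[str] = None


@dataclass
class Frame:
    donors: list = field(default_factory=list)
    acceptors: list = field(default_factory=list)


def _contact(donor: Donor, acceptor: Acceptor, max_dist: float, min_angle: float) -> bool:
    d = np.asarray(donor.heavy, dtype=float)
    h = np.asarray(donor.hydrogen, dtype=float)
    a = np.asarray(acceptor.pos, dtype=float)
    if np.linalg.norm(a - d) > max_dist:
        return False
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angle >= min_angle


def hbond_count(
    frames: Sequence[Frame], max_dist: float = 3.0, min_angle: float = 135.0
) -> tuple[dict, float]:
    """Mean hydrogen-bond counts per labelled group across frames.

    Returns ``(means, total)`` where ``means`` maps each group label to the
    average number of contacts involving a site of that group per frame and
    ``total`` is the sum of the group means.  A contact whose donor and
    acceptor are both labelled is credited to both groups.  Frames with no
    annotated sites contribute zero counts and trigger a warning.
    """
    groups: dict[str, list] = {}
    per_frame: list[dict] = []
    for frame in frames:
        if not frame.donors and not frame.acceptors:
            warnings.warn("frame without donor/acceptor annotations; counting zero")
        counts: dict[str, int] = {}
        for donor in frame.donors:
            for acceptor in frame.acceptors:
                if _contact(donor, acceptor, max_dist, min_angle):
                    for grp in (donor.group, acceptor.group):
                        if grp is not None:
                            counts[grp] = counts.get(grp, 0) + 1
        per_frame.append(counts)
        for grp in counts:
            groups.setdefault(grp, [])
    n = len(frames)
    means = {
        grp: sum(c.get(grp, 0) for c in per_frame) / n for grp in sorted(groups)
    }
    return means, float(sum(means.values()))
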