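"""Jaw lever arms and mechanical advantage from landmark coordinates.

The mandible is modeled as a lever pivoting at the tip of the condyle, taken
as the midpoint between the two condylar landmarks. Each muscle moment arm
is the straight-line distance from that pivot to the landmark standing for
the extreme point of the muscle's insertion; the resistance arm (RI) runs
from the pivot to the antero-dorsal border of the incisive alveolus (the
incisor tip itself is too worn to be reliable). Mechanical advantage is the
ratio moment arm / RI — dimensionless, hence scale-free.

Muscle labels follow the sciurid masticatory nomenclature: MT and MT2' for
the ventral and dorsal temporalis fibers, MSM8'/MSM9' for the ventral and
dorsal superficial-masseter fibers, MADM for the anterior deep masseter.
The landmark behind each label is configurable; the defaults place MT2' at
the coronoid tip, MT at the coronoid base (the surrogate used for
reconstructed shapes), MSM at the angular process, and MADM at the anterior
end of the masseteric ridge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

ARM_NAMES = ("MT2p", "MT", "MSM8p", "MSM9p", "MADM")


@dataclass(frozen=True)
class MuscleMap:
    """1-based landmark indices for pivot, resistance point and insertions."""

    condyle_pair: tuple[int, int] = (7, 8)
    incisor: int = 1
    insertions: Mapping[str, int] = field(
        default_factory=lambda: {
            "MT2p": 5,
            "MT": 4,
            "MSM8p": 11,
            "MSM9p": 10,
            "MADM": 14,
        }
    )

    def validate(self, k: int) -> None:
        idx = [*self.condyle_pair, self.incisor, *self.insertions.values()]
        bad = [i for i in idx if not 1 <= i <= k]
        if bad:
            raise ValueError(f"landmark indices {bad} out of range 1..{k}")
        if self.condyle_pair[0] == self.condyle_pair[1]:
            raise ValueError("condyle landmark pair must be distinct")


@dataclass
class LeverArms:
    pivot: np.ndarray  # (2,)
    resistance_arm: float  # RI
    moment_arms: dict[str, float]
    mechanical_advantages: dict[str, float]


def compute_lever_arms(shape: np.ndarray, muscle_map: MuscleMap = MuscleMap()) -> LeverArms:
    """Moment arms, resistance arm, and mechanical advantages of one shape.

    Invariant to rigid motion of the configuration; the advantages are also
    invariant to uniform scaling. A warning (not an error) is issued when a
    moment arm exceeds the resistance arm — real mandibles have RI longer
    than every moment arm, but arbitrary shapes need not.
    """
    coords = np.asarray(shape, dtype=float)
    if coords.ndim == 1:
        coords = coords.reshape(-1, 2)
    muscle_map.validate(coords.shape[0])
    i, j = muscle_map.condyle_pair
    pivot = (coords[i - 1] + coords[j - 1]) / 2.0
    ri = float(np.linalg.norm(coords[muscle_map.incisor - 1] - pivot))
    if ri == 0.0:
        raise ValueError("resistance arm is zero: pivot coincides with the incisor landmark")
    arms = {
        name: float(np.linalg.norm(coords[lm - 1] - pivot))
        for name, lm in muscle_map.insertions.items()
    }
    if any(a > ri for a in arms.values()):
        warnings.warn(
            "a moment arm exceeds the incisor resistance arm; mechanical "
            "advantages > 1 are anatomically unexpected",
            RuntimeWarning,
        )
    return LeverArms(
        pivot=pivot,
        resistance_arm=ri,
        moment_arms=arms,
        mechanical_advantages={name: a / ri for name, a in arms.items()},
    )


def advantage_table(
    shapes: Mapping[str, np.ndarray],
    muscle_map: MuscleMap = MuscleMap(),
    decimals: int | None = None,
) -> pd.DataFrame:
    """Mechanical-advantage table: one row per named shape.

    Accepts any collection of k x 2 configurations — taxon means, dietary
    group means, shapes reconstructed at ordination scores, or
    allometry-predicted shapes at chosen centroid sizes. ``decimals=2``
    reproduces the conventional 2-decimal presentation.
    """
    ks = {np.asarray(s).reshape(-1, 2).shape[0] for s in shapes.values()}
    if len(ks) > 1:
        raise ValueError(f"mixed landmark counts across shapes: {sorted(ks)}")
    rows = {}
    for name, shape in shapes.items():
        la = compute_lever_arms(shape, muscle_map)
        rows[name] = {arm: la.mechanical_advantages[arm] for arm in muscle_map.insertions}
    table = pd.DataFrame.from_dict(rows, orient="index")
    if decimals is not None:
        table = table.round(decimals)
    return table
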