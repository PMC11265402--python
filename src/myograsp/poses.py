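"""Hand-pose taxonomy for sEMG grasp-intent control.

Five classes: relaxation (R), three grasp poses (transverse volar grip,
lateral pinch, extension grip) and the open-hand extension pose (E).
The fixed class order R < TVG < LP < EG < E is load-bearing: it defines
row/column order of confusion matrices, one-hot target encoding, and the
deterministic tie-break of every argmax in the pipeline.
"""

from __future__ import annotations

import enum


class PoseClass(enum.IntEnum):
    """Hand-pose class; integer value is the fixed canonical order."""

    R = 0    # relaxation — never commanded to the exoskeleton
    TVG = 1  # transverse volar grip (cylinder/jar grasp)
    LP = 2   # lateral pinch (key grasp)
    EG = 3   # extension grip (plate/envelope grasp)
    E = 4    # extension — open hand; gateway pose between grasps

    @property
    def code(self) -> str:
        return self.name

    @classmethod
    def from_code(cls, code: str) -> "PoseClass":
        try:
            return cls[code.strip()]
        except KeyError:
            raise ValueError(f"unknown pose class code {code!r}") from None


CLASS_ORDER: tuple[PoseClass, ...] = (
    PoseClass.R,
    PoseClass.TVG,
    PoseClass.LP,
    PoseClass.EG,
    PoseClass.E,
)
N_CLASSES: int = len(CLASS_ORDER)

#: Poses that close the hand around an object; direct transitions between
#: two of these are forbidden by the controller's extension gate.
GRASP_POSES: frozenset[PoseClass] = frozenset(
    {PoseClass.TVG, PoseClass.LP, PoseClass.EG}
)

#: Poses the controller may command (R is excluded by design: detected
#: relaxation holds the current pose instead of releasing it).
COMMANDABLE_POSES: tuple[PoseClass, ...] = (
    PoseClass.TVG,
    PoseClass.LP,
    PoseClass.EG,
    PoseClass.E,
)


def is_grasp(pose: PoseClass | int) -> bool:
    return PoseClass(pose) in GRASP_POSES
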