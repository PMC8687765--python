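"""The five AAMI heartbeat classes (ANSI/AAMI EC57).

N  normal / bundle-branch-block / escape beats
S  supraventricular ectopic beats
V  ventricular ectopic beats
F  fusion of ventricular and normal beats
Q  paced / unclassifiable beats
"""

from __future__ import annotations

import enum


class AAMIClass(enum.IntEnum):
    N = 0
    S = 1
    V = 2
    F = 3
    Q = 4


#: Canonical class order used everywhere (confusion matrices, probability vectors).
CLASS_ORDER: tuple[AAMIClass, ...] = (
    AAMIClass.N,
    AAMIClass.S,
    AAMIClass.V,
    AAMIClass.F,
    AAMIClass.Q,
)

CLASS_NAMES: tuple[str, ...] = tuple(c.name for c in CLASS_ORDER)

N_CLASSES = len(CLASS_ORDER)


def as_class(value) -> AAMIClass:
    """Coerce an AAMIClass, its name, or its integer index to AAMIClass."""
    if isinstance(value, AAMIClass):
        return value
    if isinstance(value, str):
        try:
            return AAMIClass[value]
        except KeyError:
            raise ValueError(f"unknown AAMI class name: {value!r}") from None
    return AAMIClass(int(value))
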