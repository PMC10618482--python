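"""The eight-class spore-layer label scheme.

A segmented TEM micrograph of an endospore distinguishes, from the centre
outward: core, cortex, coat, interspace, exosporium and nap (short hair-like
surface fibres), plus background and a "bad region" class for debris or
unresolvable areas.  Label value 0 is reserved for unannotated pixels and is
excluded from training and scoring everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ClassDef",
    "LabelScheme",
    "DEFAULT_SCHEME",
    "BADREG",
    "COAT",
    "CORE",
    "CORTEX",
    "EXOSPORIUM",
    "INTERSPACE",
    "NAP",
    "BACKGROUND",
    "N_CLASSES",
    "SPORE_BODY_CLASSES",
]

N_CLASSES = 8

BADREG = 1
COAT = 2
CORE = 3
CORTEX = 4
EXOSPORIUM = 5
INTERSPACE = 6
NAP = 7
BACKGROUND = 8

#: classes that belong to the spore body (everything except background/Badreg)
SPORE_BODY_CLASSES = (COAT, CORE, CORTEX, EXOSPORIUM, INTERSPACE, NAP)


@dataclass(frozen=True)
class ClassDef:
    index: int
    name: str
    display_color: str


@dataclass(frozen=True)
class LabelScheme:
    """Ordered list of the 8 segmentation classes.

    Invariants: exactly 8 entries, indices 1..8 with no gaps, unique names.
    """

    classes: tuple[ClassDef, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.classes) != N_CLASSES:
            raise ValueError(f"expected {N_CLASSES} classes, got {len(self.classes)}")
        indices = [c.index for c in self.classes]
        if indices != list(range(1, N_CLASSES + 1)):
            raise ValueError(f"class indices must be 1..{N_CLASSES} in order, got {indices}")
        names = [c.name for c in self.classes]
        if len(set(names)) != N_CLASSES:
            raise ValueError("class names must be unique")

    def name_of(self, index: int) -> str:
        return self.classes[index - 1].name

    def index_of(self, name: str) -> int:
        for c in self.classes:
            if c.name == name:
                return c.index
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.classes]


DEFAULT_SCHEME = LabelScheme(
    (
        ClassDef(BADREG, "Badreg", "darkblue"),
        ClassDef(COAT, "coat", "blue"),
        ClassDef(CORE, "core", "lightblue"),
        ClassDef(CORTEX, "cortex", "green"),
        ClassDef(EXOSPORIUM, "exosporium", "yellow"),
        ClassDef(INTERSPACE, "interspace", "orange"),
        ClassDef(NAP, "nap", "red"),
        ClassDef(BACKGROUND, "background", "violet"),
    )
)
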