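"""The 33-landmark craniofacial catalog.

Landmarks fall into three groups:

* ``conventional`` — classical cephalometric points inherited from 2D
  analysis (Nasion, Orbitale, Porion, Gonion, ...);
* ``foraminal`` — points on craniofacial foramina (infraorbital, mental and
  internal acoustic foramina), proposed as more reliable 3D alternatives;
* ``dental`` — incisor edges/apexes and molar occlusal points (FDI tooth
  numbering).

Bilateral landmarks carry a ``-L``/``-R`` suffix and a ``laterality`` of
``left``/``right``; midline landmarks are ``midline``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

from .exceptions import ValidationError

GROUPS = ("conventional", "foraminal", "dental")
LATERALITIES = ("left", "right", "midline")


@dataclass(frozen=True)
class LandmarkDefinition:
    """A single named anatomical point."""

    name: str
    full_name: str
    group: str
    laterality: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r} for landmark {self.name!r}")
        if self.laterality not in LATERALITIES:
            raise ValidationError(
                f"unknown laterality {self.laterality!r} for landmark {self.name!r}"
            )


@dataclass
class LandmarkCatalog:
    """An ordered collection of unique landmark definitions."""

    definitions: list[LandmarkDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [d.name for d in self.definitions]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate landmark names in catalog: {dupes}")

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self) -> Iterator[LandmarkDefinition]:
        return iter(self.definitions)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __getitem__(self, name: str) -> LandmarkDefinition:
        for d in self.definitions:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.definitions]

    def group(self, group: str) -> list[LandmarkDefinition]:
        """All definitions belonging to one of the three groups."""
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return [d for d in self.definitions if d.group == group]

    def to_json(self, path=None) -> str:
        """Serialize the catalog (for documentation / interchange)."""
        payload = json.dumps(
            [
                {
                    "name": d.name,
                    "full_name": d.full_name,
                    "group": d.group,
                    "laterality": d.laterality,
                    "description": d.description,
                }
                for d in self.definitions
            ],
            indent=2,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "LandmarkCatalog":
        return cls([LandmarkDefinition(**entry) for entry in json.loads(text)])


def _bilateral(stem, full, group, desc):
    return [
        LandmarkDefinition(f"{stem}-L", f"{full} Left", group, "left", desc),
        LandmarkDefinition(f"{stem}-R", f"{full} Right", group, "right", desc),
    ]


_CONVENTIONAL = [
    LandmarkDefinition("Na", "Nasion", "conventional", "midline",
                       "Medial (and upper) point of the frontonasal suture"),
    *_bilateral("Or", "Orbitale", "conventional", "Lowest point of the orbital rim"),
    LandmarkDefinition("ANS", "Anterior Nasal Spine", "conventional", "midline",
                       "Medial and most anterior point of the nasal spine"),
    LandmarkDefinition("A", "A Point", "conventional", "midline",
                       "Medial and most posterior point of the maxilla"),
    LandmarkDefinition("B", "B Point", "conventional", "midline",
                       "Medial and most posterior point of the mandible"),
    LandmarkDefinition("Pog", "Pogonion", "conventional", "midline",
                       "Medial and most anterior point of the mandible"),
    LandmarkDefinition("Gn", "Gnathion", "conventional", "midline",
                       "Medial midpoint between pogonion and menton"),
    LandmarkDefinition("Me", "Menton", "conventional", "midline",
                       "Medial and lowest point of the mandible"),
    *_bilateral("Go", "Gonion", "conventional", "Midpoint of the gonial angle"),
    *_bilateral("Po", "Porion", "conventional",
                "External and uppermost point of the auditory canal"),
    LandmarkDefinition("PNS", "Posterior Nasal Spine", "conventional", "midline",
                       "Medial and most distal point of the osseous palate"),
    LandmarkDefinition("S", "Sella", "conventional", "midline",
                       "Central point of the sella turcica"),
]

_FORAMINAL = [
    *_bilateral("IF", "Infraorbital Foramen", "foraminal",
                "External and most distal point of the infraorbital foramen"),
    *_bilateral("MF", "Mental Foramen", "foraminal",
                "External and most mesial point of the mental foramen"),
    *_bilateral("IAF", "Internal Acoustic Foramen", "foraminal",
                "External, most mesial and posterior point of the internal acoustic foramen"),
]

_DENTAL = [
    LandmarkDefinition("11E", "11 Edge", "dental", "right", "Midpoint of the 11 incisal edge"),
    LandmarkDefinition("21E", "21 Edge", "dental", "left", "Midpoint of the 21 incisal edge"),
    LandmarkDefinition("31E", "31 Edge", "dental", "left", "Midpoint of the 31 incisal edge"),
    LandmarkDefinition("41E", "41 Edge", "dental", "right", "Midpoint of the 41 incisal edge"),
    LandmarkDefinition("11A", "11 Apex", "dental", "right", "Root apex of 11"),
    LandmarkDefinition("21A", "21 Apex", "dental", "left", "Root apex of 21"),
    LandmarkDefinition("31A", "31 Apex", "dental", "left", "Root apex of 31"),
    LandmarkDefinition("41A", "41 Apex", "dental", "right", "Root apex of 41"),
    LandmarkDefinition("16O", "16 Occlusal", "dental", "right",
                       "Summit of the mesio-palatal cusp of 16"),
    LandmarkDefinition("26O", "26 Occlusal", "dental", "left",
                       "Summit of the mesio-palatal cusp of 26"),
    LandmarkDefinition("36O", "36 Occlusal", "dental", "left", "Central fossa of 36"),
    LandmarkDefinition("46O", "46 Occlusal", "dental", "right", "Central fossa of 46"),
]


def default_catalog() -> LandmarkCatalog:
    """The default 33-landmark catalog: 15 conventional, 6 foraminal, 12 dental."""
    return LandmarkCatalog(list(_CONVENTIONAL) + list(_FORAMINAL) + list(_DENTAL))
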