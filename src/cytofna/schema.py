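"""The 17-category cell class schema and its 9-role reduction.

Thyroid FNA cytology annotation distinguishes 17 cell categories C1..C17.
Three of them are papillary-carcinoma epithelial classes (PTCA/PTCB/PTCC,
single cells, small groups, larger groups), three are their benign follicular
counterparts (TFECA/TFECB/TFECC), one carries nuclear grooves (NUCLEAR) and one
intranuclear pseudo-inclusions (INCIS) — both hallmarks of papillary thyroid
carcinoma. The remaining classes (macrophages, lymphocytes, colloid, debris,
...) are collapsed into a single OTHER role for slide-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CLASS_IDS = tuple(f"C{i}" for i in range(1, 18))

ROLES = ("PTCA", "PTCB", "PTCC", "TFECA", "TFECB", "TFECC",
         "NUCLEAR", "INCIS", "OTHER")

#: default class -> role correspondence; configurable through ClassSchema
DEFAULT_ROLE_MAP = {
    "C1": "PTCA", "C2": "PTCB", "C3": "PTCC",
    "C4": "NUCLEAR", "C5": "INCIS",
    "C6": "TFECA", "C7": "TFECB", "C8": "TFECC",
    **{f"C{i}": "OTHER" for i in range(9, 18)},
}

DISPLAY_NAMES = {
    "C1": "PTC single cell", "C2": "PTC small group", "C3": "PTC large group",
    "C4": "nuclear groove", "C5": "pseudo-inclusion",
    "C6": "follicular single cell", "C7": "follicular small group",
    "C8": "follicular large group",
    "C9": "macrophage", "C10": "lymphocyte", "C11": "neutrophil",
    "C12": "histiocyte", "C13": "colloid", "C14": "hurthle cell",
    "C15": "squamous cell", "C16": "blood debris", "C17": "other debris",
}

#: classes whose presence counts toward the malignant (atypical) fraction
ATYPICAL_CLASSES = ("C1", "C2", "C3", "C4", "C5")
#: epithelial classes considered for adequacy / fraction denominators
EPITHELIAL_CLASSES = ("C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8")
#: classes re-tested by the dual-model agreement gate
GATED_CLASSES = ("C1", "C2", "C3", "C6", "C7", "C8")

REJECTED = "REJECTED"


@dataclass(frozen=True)
class ClassSchema:
    """Ordered 17-class schema with a total role map."""

    class_ids: tuple = CLASS_IDS
    role_map: dict = field(default_factory=lambda: dict(DEFAULT_ROLE_MAP))
    display_names: dict = field(default_factory=lambda: dict(DISPLAY_NAMES))

    def __post_init__(self):
        if len(self.class_ids) != 17:
            raise ValueError("schema must contain exactly 17 class ids")
        missing = [c for c in self.class_ids if c not in self.role_map]
        if missing:
            raise ValueError(f"role map is not total; missing {missing}")
        bad = set(self.role_map.values()) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles {bad}")

    def role(self, class_id: str) -> str:
        return self.role_map[class_id]

    def index(self, class_id: str) -> int:
        return self.class_ids.index(class_id)


DEFAULT_SCHEMA = ClassSchema()
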