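"""Lexicon driving the synthetic pseudo-clinical note generator.

The lexicon holds, per diagnostic class, the Italian-style keyword phrases
(including abbreviations such as "oma") that make a class recognizable, plus
the linguistic material that makes classification hard in real notes:
negated otitis mentions, references to other doctors' diagnoses, and
atypical descriptions of tympanic perforation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .classes import OtitisClass

_DEFAULT_CLASS_KEYWORDS: dict[str, list[str]] = {
    "no_otitis": [
        "controllo di crescita otoscopia negativa",
        "vaccinazione esavalente orecchie nella norma",
        "faringite streptococcica timpani integri",
        "bronchite asmatica otoscopia nella norma",
        "visita di controllo orecchie indenni",
    ],
    "otitis_not_media": [
        "otite esterna",
        "otite del condotto uditivo",
        "otite esterna dx",
        "otite esterna bilaterale",
    ],
    "om_not_acute": [
        "otite media catarrale",
        "otite media sierosa",
        "otite media effusiva",
        "otite media secretiva bilaterale",
    ],
    "aom": [
        "otite media acuta",
        "oma bilaterale",
        "otite media acuta dx",
        "oma sx iperemica",
    ],
    "aom_perforation": [
        "otite media acuta perforata",
        "oma perforata dx",
        "otite media acuta con perforazione timpanica",
    ],
    "aom_recurrent": [
        "otite media acuta ricorrente",
        "oma ricorrente",
        "otite ricorrente bilaterale",
    ],
}

_DEFAULT_BACKGROUND = (
    "bambino visitato per febbre da giorni tosse secca in buone condizioni generali "
    "mucose rosee faringe roseo respiro regolare addome trattabile cute integra "
    "alvo e diuresi nella norma peso regolare auscultazione negativa "
    "torace libero linfonodi non palpabili idratazione buona appetito conservato"
).split()

_DEFAULT_PRESCRIPTIONS = [
    "amoxicillina 50 mg per kg in 3 dosi",
    "paracetamolo 250 mg supposte al bisogno",
    "amoxicillina clavulanato 400 mg sospensione per 7 giorni",
    "ibuprofene 100 mg ogni 8 ore",
    "nessuna terapia al momento",
]

_DEFAULT_NEGATIONS = [
    "non otite",
    "si esclude otite media",
    "niente otite alle orecchie",
    "membrane timpaniche normali non otite media acuta",
]

_DEFAULT_OTHER_DOCTOR = [
    "il collega del pronto soccorso riferisce otite media",
    "la madre riferisce diagnosi di otite fatta altrove",
    "visita specialistica orl richiesta per sospetta otite",
]

_DEFAULT_ATYPICAL_PERFORATION = [
    "oma con otorrea purulenta abbondante",
    "otite media acuta timpano lacerato con secrezione",
    "otite media acuta membrana timpanica rotta",
]


@dataclass
class Lexicon:
    """Per-class keyword phrases plus confounder templates.

    Invariant: no class's keyword set is a subset of another's, so classes
    stay distinguishable when no noise is injected.
    """

    class_keywords: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_CLASS_KEYWORDS.items()}
    )
    background: list[str] = field(default_factory=lambda: list(_DEFAULT_BACKGROUND))
    prescriptions: list[str] = field(default_factory=lambda: list(_DEFAULT_PRESCRIPTIONS))
    negation_templates: list[str] = field(default_factory=lambda: list(_DEFAULT_NEGATIONS))
    other_doctor_templates: list[str] = field(
        default_factory=lambda: list(_DEFAULT_OTHER_DOCTOR)
    )
    atypical_perforation_terms: list[str] = field(
        default_factory=lambda: list(_DEFAULT_ATYPICAL_PERFORATION)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c.label for c in OtitisClass if c.label not in self.class_keywords]
        if missing:
            raise ValueError(f"lexicon missing classes: {missing}")
        for label, kws in self.class_keywords.items():
            if not kws:
                raise ValueError(f"lexicon class {label!r} has an empty keyword list")
        labels = list(self.class_keywords)
        for a in labels:
            for b in labels:
                if a != b and set(self.class_keywords[a]) <= set(self.class_keywords[b]):
                    raise ValueError(
                        f"keyword set of class {a!r} is a subset of {b!r}; "
                        "classes would be indistinguishable at zero noise"
                    )

    def keywords_for(self, cls: OtitisClass) -> list[str]:
        try:
            return self.class_keywords[cls.label]
        except KeyError:
            raise ValueError(f"class {cls.label!r} missing from lexicon") from None

    def to_yaml(self, path) -> None:
        obj = {
            "class_keywords": self.class_keywords,
            "background": self.background,
            "prescriptions": self.prescriptions,
            "negation_templates": self.negation_templates,
            "other_doctor_templates": self.other_doctor_templates,
            "atypical_perforation_terms": self.atypical_perforation_terms,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(obj, fh, allow_unicode=True, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            obj = yaml.safe_load(fh)
        return cls(**obj)


def default_lexicon() -> Lexicon:
    return Lexicon()
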