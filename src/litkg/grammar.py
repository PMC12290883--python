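"""Shared template grammar for the synthetic corpus and its mock extractor.

The synthetic generator emits sentences of the forms::

    <SURFACE_A> <relation-phrase> <SURFACE_B> in <organ>.
    <SURFACE_B> <passive-phrase> <SURFACE_A>.
    <SURFACE> is defined as <definition>.

Both the generator and the deterministic mock extraction backend are bound
to the lexicon below, so extraction on synthetic corpora is exact by
construction.  Live backends ignore this module entirely.
"""

from __future__ import annotations

import re
from dataclasses import dataclass


@dataclass(frozen=True)
class RelationFamily:
    """A canonical relation verb with its surface variants and passive form.

    The first entry of ``variants`` is the canonical surface; generation
    draws the canonical form more often than the others, mirroring the
    skewed tense/number usage of real abstracts.
    """

    canonical: str
    variants: tuple[str, ...]
    passive: str | None


RELATION_FAMILIES: tuple[RelationFamily, ...] = (
    RelationFamily("regulates", ("regulates", "regulate", "regulated"), "is regulated by"),
    RelationFamily("activates", ("activates", "activate", "activated"), "is activated by"),
    RelationFamily("represses", ("represses", "repress", "repressed"), "is repressed by"),
    RelationFamily("binds", ("binds", "bind"), "is bound by"),
    RelationFamily("causes", ("causes", "cause", "caused"), "is caused by"),
    RelationFamily("interacts with", ("interacts with", "interact with"), None),
)

#: Weight of the canonical (first) variant; remaining mass is uniform.
CANONICAL_VARIANT_WEIGHT = 0.6

ORGANS: tuple[str, ...] = ("root", "leaf", "flower", "seed", "stem")

#: Passive participles whose active form is not recovered by the regular
#: "-ed by" -> "-es" rule.  Editable configuration for the canonicalizer.
PASSIVE_IRREGULARS: dict[str, str] = {"bound": "binds"}

#: Detects a passive relation phrase such as "is regulated by".
PASSIVE_RELATION_RE = re.compile(r"^(?:is|are|was|were)\s+(?P<participle>\w+)\s+by$")

DEFINITION_CONNECTIVE = "is defined as"

AGI_ID_RE = re.compile(r"^[Aa][Tt][1-5CMcm][Gg]\d{5}s?$")

ALIAS_ADJECTIVES: tuple[str, ...] = (
    "heat", "cold", "drought", "salt", "light", "shade", "iron", "zinc",
    "sugar", "wax", "pollen", "petal", "xylem", "phloem", "stomatal",
    "vascular", "floral", "apical", "basal", "cuticle",
)
ALIAS_NOUNS: tuple[str, ...] = (
    "factor", "kinase", "synthase", "transporter", "receptor", "channel",
    "ligase", "oxidase", "reductase", "helicase", "phosphatase", "esterase",
    "hydrolase", "transferase", "isomerase",
)
PROCESSES: tuple[str, ...] = (
    "flowering", "germination", "photosynthesis", "cell wall biosynthesis",
    "stomatal closure", "lateral organ growth", "hormone signalling",
    "stress acclimation", "nutrient uptake", "senescence",
)


def passive_to_active(phrase: str) -> str | None:
    """Return the active form of a passive relation phrase, or None.

    ``"is regulated by"`` -> ``"regulates"``; irregular participles are
    looked up in :data:`PASSIVE_IRREGULARS`; anything else passes through
    (returns None) and is left to the caller to log.
    """
    m = PASSIVE_RELATION_RE.match(phrase.strip())
    if m is None:
        return None
    participle = m.group("participle")
    if participle in PASSIVE_IRREGULARS:
        return PASSIVE_IRREGULARS[participle]
    if participle.endswith("ed"):
        return participle[:-1] + "s"  # regulated -> regulates
    return None


def active_relation_surfaces() -> tuple[str, ...]:
    """All active relation surfaces, longest first (for regex alternation)."""
    surfaces = [v for fam in RELATION_FAMILIES for v in fam.variants]
    return tuple(sorted(surfaces, key=lambda s: (-len(s), s)))


def passive_relation_surfaces() -> tuple[str, ...]:
    return tuple(fam.passive for fam in RELATION_FAMILIES if fam.passive)


def classify_entity_type(name: str) -> str:
    """Entity typing rule used by the mock backend at extraction time."""
    if AGI_ID_RE.match(name):
        return "gene identifier"
    if name.lower() in ORGANS:
        return "organ"
    return "gene"
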