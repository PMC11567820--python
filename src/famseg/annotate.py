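"""Consequence classification and damaging-variant prioritization.

A variant qualifies as damaging if it is loss-of-function (stopgain,
stoploss, frameshift, or a canonical splice acceptor/donor change) or a
missense change with CADD phred strictly above the threshold (default 20).
Splice-region and other non-canonical splice annotations do not count as
LoF. Missense without a CADD score cannot qualify and is logged.
"""

from __future__ import annotations

import enum
import logging
from pathlib import Path
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .variants import VariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "ConsequenceClass",
    "DamagingCall",
    "LOF_CLASSES",
    "DEFAULT_SYNONYMS",
    "load_synonym_map",
    "classify_consequence",
    "is_damaging",
]


class ConsequenceClass(enum.Enum):
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT = "frameshift"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_DONOR = "splice_donor"
    MISSENSE = "missense"
    OTHER = "other"


LOF_CLASSES = frozenset(
    {
        ConsequenceClass.STOPGAIN,
        ConsequenceClass.STOPLOSS,
        ConsequenceClass.FRAMESHIFT,
        ConsequenceClass.SPLICE_ACCEPTOR,
        ConsequenceClass.SPLICE_DONOR,
    }
)


class DamagingCall(enum.Enum):
    LOF = "LOF"
    DAMAGING_MISSENSE = "DAMAGING_MISSENSE"
    NOT_DAMAGING = "NOT_DAMAGING"


# Common spellings across annotation dialects (Sequence Ontology / ANNOVAR /
# printed table labels), lower-cased with separators normalised to "_".
DEFAULT_SYNONYMS: dict[str, str] = {
    "stopgain": "stopgain",
    "stop_gained": "stopgain",
    "stop_gain": "stopgain",
    "nonsense": "stopgain",
    "stoploss": "stoploss",
    "stop_lost": "stoploss",
    "stop_loss": "stoploss",
    "frameshift": "frameshift",
    "frameshift_variant": "frameshift",
    "frameshift_deletion": "frameshift",
    "frameshift_insertion": "frameshift",
    "splice_acceptor": "splice_acceptor",
    "splice_acceptor_variant": "splice_acceptor",
    "splice_donor": "splice_donor",
    "splice_donor_variant": "splice_donor",
    "missense": "missense",
    "missense_variant": "missense",
    "nonsynonymous_snv": "missense",
}


def load_synonym_map(path: str | Path) -> dict[str, str]:
    """Load a user consequence-synonym map (YAML: spelling -> class value)."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {c.value for c in ConsequenceClass}
    out = dict(DEFAULT_SYNONYMS)
    for key, value in raw.items():
        if value not in valid:
            raise ValueError(f"synonym map target {value!r} is not a consequence class")
        out[_normalise(str(key))] = value
    return out


def _normalise(text: str) -> str:
    return text.strip().lower().replace(" ", "_").replace("-", "_")


def classify_consequence(
    annotation: str, synonym_map: dict[str, str] | None = None
) -> ConsequenceClass:
    """Map an annotation spelling onto the consequence enum; unknown -> other."""
    if not isinstance(annotation, str):
        return ConsequenceClass.OTHER
    table = synonym_map if synonym_map is not None else DEFAULT_SYNONYMS
    value = table.get(_normalise(annotation))
    return ConsequenceClass(value) if value else ConsequenceClass.OTHER


def is_damaging(site: "VariantSite", cadd_threshold: float = 20.0) -> DamagingCall:
    """Prioritize a site: LoF always qualifies; missense needs CADD > threshold."""
    if site.consequence in LOF_CLASSES:
        return DamagingCall.LOF
    if site.consequence is ConsequenceClass.MISSENSE:
        if site.cadd_phred is None:
            logger.warning("missense %s lacks a CADD score; not prioritized",
                           site.key)
            return DamagingCall.NOT_DAMAGING
        if site.cadd_phred > cadd_threshold:
            return DamagingCall.DAMAGING_MISSENSE
    return DamagingCall.NOT_DAMAGING
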