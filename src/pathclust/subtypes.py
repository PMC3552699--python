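"""IHC receptor status and breast cancer subtype assignment.

Clinical practice approximates the intrinsic (molecular) breast cancer
subtypes with immunohistochemical staining of three receptors measured in
the primary tumor: the estrogen receptor (ER), the progesterone receptor
(PR), and the human epidermal growth factor receptor 2 (HER2).  The rules
implemented here are the standard receptor-based surrogate definitions:

* luminal A   -- hormone-receptor positive (ER+ or PR+), HER2 negative
* luminal B   -- hormone-receptor positive (ER+ or PR+), HER2 positive
* HER2+       -- ER-, PR-, HER2 positive
* basal-like  -- triple negative (ER-, PR-, HER2-)

Patients whose receptor record does not resolve any of the four rules
(e.g. a missing HER2 stain) are carried as ``Unknown`` -- they remain part
of the cohort and of five-class prediction, but are excluded from the
four-class accuracy summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Marker",
    "ReceptorStatus",
    "Subtype",
    "SUBTYPE_ORDER",
    "assign_subtype",
    "receptor_status_for_subtype",
    "annotate_subtypes",
]


class Marker(str, Enum):
    """Trinary state of a single IHC marker."""

    POSITIVE = "+"
    NEGATIVE = "-"
    MISSING = "NA"

    @classmethod
    def coerce(cls, value: "Marker | str | None") -> "Marker":
        if isinstance(value, Marker):
            return value
        if value is None:
            return cls.MISSING
        text = str(value).strip()
        aliases = {
            "+": cls.POSITIVE,
            "positive": cls.POSITIVE,
            "pos": cls.POSITIVE,
            "-": cls.NEGATIVE,
            "negative": cls.NEGATIVE,
            "neg": cls.NEGATIVE,
            "": cls.MISSING,
            "na": cls.MISSING,
            "nan": cls.MISSING,
            "missing": cls.MISSING,
        }
        key = text.lower()
        if key not in aliases:
            raise ValueError(f"unrecognized IHC marker state: {value!r}")
        return aliases[key]


class Subtype(str, Enum):
    """Receptor-defined breast cancer subtype labels (closed enumeration)."""

    LUMINAL_A = "LuminalA"
    LUMINAL_B = "LuminalB"
    HER2_PLUS = "HER2Plus"
    BASAL_LIKE = "BasalLike"
    UNKNOWN = "Unknown"


#: Canonical ordering used for tie-breaking, table columns and dendrogram labels.
SUBTYPE_ORDER: tuple[Subtype, ...] = (
    Subtype.LUMINAL_A,
    Subtype.LUMINAL_B,
    Subtype.HER2_PLUS,
    Subtype.BASAL_LIKE,
    Subtype.UNKNOWN,
)


@dataclass(frozen=True)
class ReceptorStatus:
    """ER / PR / HER2 staining result for one patient."""

    er: Marker
    pr: Marker
    her2: Marker

    def __init__(self, er, pr, her2):  # type: ignore[no-untyped-def]
        object.__setattr__(self, "er", Marker.coerce(er))
        object.__setattr__(self, "pr", Marker.coerce(pr))
        object.__setattr__(self, "her2", Marker.coerce(her2))


def assign_subtype(status: ReceptorStatus) -> Subtype:
    """Map a receptor status to a subtype label.

    The function is total: any combination of ``+``/``-``/missing markers
    yields a label.  A rule fires only when its premises are decidable;
    hormone-receptor positivity is decidable as soon as ER or PR is
    positive, while hormone-receptor *negativity* requires both ER- and
    PR-.  Everything else is ``Unknown``.
    """
    er, pr, her2 = status.er, status.pr, status.her2
    hr_positive = Marker.POSITIVE in (er, pr)
    hr_negative = er == Marker.NEGATIVE and pr == Marker.NEGATIVE
    if hr_positive:
        if her2 == Marker.NEGATIVE:
            return Subtype.LUMINAL_A
        if her2 == Marker.POSITIVE:
            return Subtype.LUMINAL_B
    elif hr_negative:
        if her2 == Marker.POSITIVE:
            return Subtype.HER2_PLUS
        if her2 == Marker.NEGATIVE:
            return Subtype.BASAL_LIKE
    logger.debug("receptor status %s does not resolve a subtype rule", status)
    return Subtype.UNKNOWN


#: Canonical receptor representative per subtype, the inverse of the
#: assignment rules.  Used by the cohort simulator so that true labels are
#: exactly recoverable from the generated annotation table.
_CANONICAL_STATUS: dict[Subtype, ReceptorStatus] = {
    Subtype.LUMINAL_A: ReceptorStatus("+", "+", "-"),
    Subtype.LUMINAL_B: ReceptorStatus("+", "+", "+"),
    Subtype.HER2_PLUS: ReceptorStatus("-", "-", "+"),
    Subtype.BASAL_LIKE: ReceptorStatus("-", "-", "-"),
    Subtype.UNKNOWN: ReceptorStatus("NA", "NA", "NA"),
}


def receptor_status_for_subtype(subtype: Subtype | str) -> ReceptorStatus:
    """Return a receptor status that :func:`assign_subtype` maps back to *subtype*."""
    return _CANONICAL_STATUS[Subtype(subtype)]


def annotate_subtypes(annotation: pd.DataFrame) -> pd.DataFrame:
    """Add/overwrite a ``subtype`` column derived from ER/PR/HER2 columns.

    Healthy (non-cancer) rows receive an empty subtype.  The input frame is
    not modified.
    """
    required: Iterable[str] = ("ER", "PR", "HER2")
    missing = [c for c in required if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation table lacks receptor columns: {missing}")
    out = annotation.copy()
    labels = []
    for _, row in out.iterrows():
        if "group" in out.columns and str(row["group"]).lower() != "cancer":
            labels.append("")
            continue
        status = ReceptorStatus(row["ER"], row["PR"], row["HER2"])
        labels.append(assign_subtype(status).value)
    out["subtype"] = labels
    return out
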