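"""CYP2D6 star-allele genetics: diplotype parsing, activity scores, phenotype classes.

The CYP2D6 activity-score (AS) system assigns every star allele a function
value per copy — 0 (no function), 0.25 or 0.5 (decreased function), or 1
(normal function).  A subject's AS is the sum over both haplotypes of
function value times copy number, so gene duplications count multiply and
the gene deletion (*5) contributes nothing.  AS bins translate to
genotype-predicted metabolizer classes::

    AS = 0            -> gPM   (poor)
    0 < AS < 1.25     -> gIM   (intermediate)
    1.25 <= AS <= 2.25 -> gNM  (normal)
    AS > 2.25         -> gUM   (ultrarapid)

The NFIB rs28379954 T>C variant has been proposed to raise CYP2D6 activity
in genotypic normal metabolizers; an optional sensitivity reclassification
moves gNM carriers into gUM and leaves every other class untouched.

Diplotype strings use the ``*A/*B`` convention with an optional ``xN``
duplication suffix per haplotype, e.g. ``"*1x2/*41"``.  Alleles absent from
the function table raise rather than defaulting to normal function.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "DEFAULT_ALLELE_FUNCTION",
    "PHENOTYPE_ORDER",
    "PHENOTYPE_CODES",
    "INDETERMINATE",
    "DiplotypeParseError",
    "UnknownAlleleError",
    "HaplotypeCall",
    "Diplotype",
    "validate_allele_table",
    "parse_diplotype",
    "activity_score",
    "classify_phenotype",
    "apply_nfib_reclassification",
    "annotate_subjects",
]

#: Default per-copy function values.  Normal-function and no-function
#: assignments are uncontroversial; decreased-function alleles default to
#: 0.5 except *10 (0.25).  All values are overridable via a custom table.
DEFAULT_ALLELE_FUNCTION: dict[str, float] = {
    "*1": 1.0, "*2": 1.0, "*39": 1.0,
    "*9": 0.5, "*17": 0.5, "*29": 0.5, "*41": 0.5,
    "*59": 0.5, "*65": 0.5, "*69": 0.5, "*88": 0.5,
    "*10": 0.25,
    "*3": 0.0, "*4": 0.0, "*5": 0.0, "*6": 0.0, "*11": 0.0, "*13": 0.0,
}

_ALLOWED_FUNCTION_VALUES = (0.0, 0.25, 0.5, 1.0)

PHENOTYPE_ORDER = ("gPM", "gIM", "gNM", "gUM")
PHENOTYPE_CODES = {"gPM": 0, "gIM": 1, "gNM": 2, "gUM": 3}
INDETERMINATE = "indeterminate"


class DiplotypeParseError(ValueError):
    """Malformed diplotype string."""


class UnknownAlleleError(ValueError):
    """Star allele missing from the function table."""


def validate_allele_table(table: Mapping[str, float]) -> dict[str, float]:
    """Validate an allele -> function-value table and return a plain dict.

    Function values must lie in {0, 0.25, 0.5, 1}; the gene deletion ``*5``,
    if present, must carry value 0.
    """
    out: dict[str, float] = {}
    for name, value in table.items():
        if not name.startswith("*"):
            raise ValueError(f"allele name must start with '*': {name!r}")
        v = float(value)
        if v not in _ALLOWED_FUNCTION_VALUES:
            raise ValueError(
                f"function value for {name} must be one of {_ALLOWED_FUNCTION_VALUES}, got {v}"
            )
        out[name] = v
    if out.get("*5", 0.0) != 0.0:
        raise ValueError("gene deletion *5 must have function value 0")
    return out


_HAPLOTYPE_RE = re.compile(r"^(\*[0-9A-Za-z]+?)(?:x([0-9]+))?$")


@dataclass(frozen=True)
class HaplotypeCall:
    """A star allele with its copy number on one haplotype."""

    allele: str
    copy_number: int = 1

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise DiplotypeParseError(
                f"copy number must be >= 1, got {self.copy_number} for {self.allele}"
            )


@dataclass(frozen=True, eq=False)
class Diplotype:
    """Two haplotype calls; equality and hashing ignore haplotype order."""

    hap1: HaplotypeCall
    hap2: HaplotypeCall
    raw_string: str = ""

    def _key(self) -> tuple:
        return tuple(
            sorted((h.allele, h.copy_number) for h in (self.hap1, self.hap2))
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Diplotype):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    @property
    def haplotypes(self) -> tuple[HaplotypeCall, HaplotypeCall]:
        return (self.hap1, self.hap2)

    def __str__(self) -> str:
        return self.raw_string or "/".join(
            f"{h.allele[0]}{h.allele[1:]}" + (f"x{h.copy_number}" if h.copy_number > 1 else "")
            for h in self.haplotypes
        )


def _parse_haplotype(token: str) -> HaplotypeCall:
    m = _HAPLOTYPE_RE.match(token)
    if m is None:
        raise DiplotypeParseError(f"malformed haplotype token {token!r}")
    allele, cn = m.group(1), m.group(2)
    if allele.endswith("x"):  # dangling duplication marker, e.g. "*1x"
        raise DiplotypeParseError(f"malformed duplication suffix in {token!r}")
    copy_number = int(cn) if cn is not None else 1
    if copy_number < 1:
        raise DiplotypeParseError(f"copy number must be >= 1 in {token!r}")
    return HaplotypeCall(allele=allele, copy_number=copy_number)


def parse_diplotype(text: str) -> Diplotype:
    """Parse a ``"*A[xN]/*B[xN]"`` diplotype string.

    >>> parse_diplotype("*1x2/*5").hap1
    HaplotypeCall(allele='*1', copy_number=2)
    """
    if not isinstance(text, str):
        raise DiplotypeParseError(f"diplotype must be a string, got {type(text).__name__}")
    parts = text.strip().split("/")
    if len(parts) != 2:
        raise DiplotypeParseError(
            f"diplotype must contain exactly two haplotypes separated by '/': {text!r}"
        )
    return Diplotype(_parse_haplotype(parts[0]), _parse_haplotype(parts[1]), raw_string=text)


def activity_score(
    diplotype: Diplotype | str,
    table: Mapping[str, float] | None = None,
) -> float:
    """Activity score: sum over haplotypes of function value x copy number."""
    if isinstance(diplotype, str):
        diplotype = parse_diplotype(diplotype)
    tab = DEFAULT_ALLELE_FUNCTION if table is None else dict(table)
    missing = [h.allele for h in diplotype.haplotypes if h.allele not in tab]
    if missing:
        raise UnknownAlleleError(
            f"allele(s) {sorted(set(missing))} not in the function table"
        )
    return float(sum(tab[h.allele] * h.copy_number for h in diplotype.haplotypes))


def classify_phenotype(score: float) -> str:
    """Map an activity score to its metabolizer class.

    Bins: 0 -> gPM; (0, 1.25) -> gIM; [1.25, 2.25] -> gNM; > 2.25 -> gUM.
    """
    s = float(score)
    if math.isnan(s):
        raise ValueError("activity score is NaN; phenotype indeterminate")
    if s < 0:
        raise ValueError(f"activity score must be >= 0, got {s}")
    if s == 0:
        return "gPM"
    if s < 1.25:
        return "gIM"
    if s <= 2.25:
        return "gNM"
    return "gUM"


def apply_nfib_reclassification(
    phenotype: str, nfib_carrier: bool, enabled: bool = True
) -> str:
    """Sensitivity reclassification: gNM carriers of NFIB rs28379954 -> gUM.

    All other (phenotype, carrier) combinations pass through unchanged, as
    does everything when ``enabled`` is False.
    """
    if phenotype not in PHENOTYPE_ORDER and phenotype != INDETERMINATE:
        raise ValueError(f"unknown phenotype class {phenotype!r}")
    if enabled and phenotype == "gNM" and bool(nfib_carrier):
        return "gUM"
    return phenotype


def annotate_subjects(
    subjects: pd.DataFrame,
    allele_table: Mapping[str, float] | None = None,
    diplotype_col: str = "diplotype",
    nfib_col: str = "nfib_carrier",
    nfib_reclass: bool = False,
) -> pd.DataFrame:
    """Append ``activity_score`` and ``phenotype`` columns to a subject table.

    Subjects with a missing/blank diplotype get an NaN score and the
    ``indeterminate`` class.  When ``nfib_reclass`` is True and the table has
    an ``nfib_carrier`` column, gNM carriers are moved to gUM.
    """
    if diplotype_col not in subjects.columns:
        raise KeyError(f"subject table lacks a {diplotype_col!r} column")
    tab = validate_allele_table(allele_table or DEFAULT_ALLELE_FUNCTION)
    out = subjects.copy()
    scores: list[float] = []
    classes: list[str] = []
    for raw in out[diplotype_col]:
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
            scores.append(float("nan"))
            classes.append(INDETERMINATE)
            continue
        s = activity_score(str(raw), tab)
        scores.append(s)
        classes.append(classify_phenotype(s))
    out["activity_score"] = scores
    out["phenotype"] = classes
    if nfib_reclass:
        if nfib_col not in out.columns:
            raise KeyError(f"nfib_reclass requested but no {nfib_col!r} column present")
        out["phenotype"] = [
            apply_nfib_reclassification(p, c, enabled=True)
            for p, c in zip(out["phenotype"], out[nfib_col].fillna(False))
        ]
    return out
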