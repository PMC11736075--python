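"""Core domain types for multi-allele SSR genotype data.

An SSR (microsatellite) fingerprint is, per sample, a map from marker name to
a *set* of allele fragment lengths (AFLs, in base pairs).  Allele calls are
sets of distinct AFLs rather than multisets: copy number is unobservable from
fragment sizing — a homozygote, a null allele and an unmeasured second allele
all present as a single peak — so both ``"221:221"`` and ``"221:0"`` normalize
to ``{221}``.  The empty set encodes a null call (no amplification), written
``"0"`` in tabular data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

#: Plausibility bounds for allele fragment lengths in bp.  Capillary sizing
#: with 500-size ladders cannot size fragments outside roughly this range, so
#: out-of-range values are treated as data errors rather than warnings.
AFL_MIN = 50
AFL_MAX = 600

#: Admissible trueness-to-type codes.  "R" (reference cultivar) is substituted
#: by "1" during aggregation.
TRUENESS_CODES = frozenset({"0", "1", "2", "3", "4", "5", "R"})

#: A genotype profile: marker name -> frozenset of AFLs (empty = null call).
GenotypeProfile = dict


class Cohort(str, Enum):
    """Sampling project block a sample belongs to."""

    P2009_2014 = "P2009_2014"
    P2017_2021 = "P2017_2021"


class MalformedFieldError(ValueError):
    """An allele cell could not be parsed into a valid AFL set."""


class SchemaError(ValueError):
    """A genotype table is missing required columns."""


class DuplicateSampleError(ValueError):
    """A sample identifier occurs more than once in a table."""


def parse_allele_field(text, *, row=None, column=None) -> frozenset:
    """Parse a colon-separated allele cell into a frozenset of AFLs.

    ``"0"``, ``""`` and whitespace-only cells encode a null call and map to
    the empty set.  Duplicate values (homozygote notation ``"x:x"``) are
    deduplicated.  Zero tokens inside a multi-allele cell (``"221:0"``) encode
    an absent second allele and are dropped.

    Raises
    ------
    MalformedFieldError
        On non-integer tokens, negative values, or values outside
        [AFL_MIN, AFL_MAX]; the message names the offending row/column when
        given.
    """
    where = ""
    if row is not None or column is not None:
        where = f" (row={row!r}, column={column!r})"
    if text is None:
        return frozenset()
    s = str(text).strip()
    if s == "" or s == "0":
        return frozenset()
    alleles = set()
    for token in s.split(":"):
        token = token.strip()
        if token == "" or token == "0":
            continue
        try:
            value = int(token)
        except ValueError:
            raise MalformedFieldError(
                f"non-integer allele token {token!r}{where}"
            ) from None
        if value < 0:
            raise MalformedFieldError(f"negative AFL {value}{where}")
        if not (AFL_MIN <= value <= AFL_MAX):
            raise MalformedFieldError(
                f"AFL {value} outside plausible range [{AFL_MIN}, {AFL_MAX}]{where}"
            )
        alleles.add(value)
    return frozenset(alleles)


def format_allele_field(alleles) -> str:
    """Serialize an AFL set to the colon-joined ascending notation.

    The empty set serializes as ``"0"``.  Inverse of :func:`parse_allele_field`
    on every valid AFL set.
    """
    if not alleles:
        return "0"
    return ":".join(str(a) for a in sorted(alleles))


@dataclass
class SampleRecord:
    """One analysed leaf sample with metadata and its genotype profile.

    ``putative_cultivar`` is the name the collection holder supplied;
    ``pomological_cultivar`` is the expert determination.  ``ploidy`` is
    carried as metadata only and is never inferred from allele counts.
    """

    sample_id: str
    profile: GenotypeProfile
    tree_id: str = ""
    location: str = ""
    cohort: Optional[Cohort] = None
    putative_cultivar: Optional[str] = None
    pomological_cultivar: Optional[str] = None
    trueness: Optional[str] = None
    ploidy: Optional[int] = None

    def __post_init__(self):
        if self.trueness is not None and self.trueness not in TRUENESS_CODES:
            raise ValueError(
                f"invalid trueness code {self.trueness!r} for sample "
                f"{self.sample_id!r}; expected one of {sorted(TRUENESS_CODES)}"
            )
        if self.ploidy is not None and self.ploidy not in (2, 3, 4):
            raise ValueError(
                f"invalid ploidy {self.ploidy!r} for sample {self.sample_id!r}"
            )


@dataclass
class MolecularGroup:
    """A cluster of samples treated as one cultivar.

    ``group_id`` follows the ``MD_####`` convention (MD for *Malus* x
    *domestica*, then a zero-padded running number); it is ``None`` until
    identifiers are assigned.
    """

    member_sample_ids: list
    group_id: Optional[str] = None


@dataclass
class ConsensusProfile:
    """One representative AFL set per marker for a molecular group.

    ``flags`` records every rule firing as ``"<marker>:<flag>"`` strings with
    flags from {heterozygous-preference, missing-filled, ploidy-adjusted,
    unresolved}, so any deviation from the plain modal call is auditable.
    """

    group_id: str
    cultivar_name: str
    calls: GenotypeProfile
    trueness: Optional[str] = None
    ploidy: Optional[int] = None
    munq: Optional[str] = None
    flags: list = field(default_factory=list)
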