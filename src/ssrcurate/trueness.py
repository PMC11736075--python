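"""Trueness-to-type aggregation and reciprocal consensus validation.

Trueness-to-type codes express whether an accession is authentically the
named cultivar: "1" true-to-type (pomologically and molecularly assessed),
"2" true-to-type group/mutant, "5" true-to-type with reservations, "3" not
determined, "4" not assessed, "0" tree deceased, "R" reference cultivar
(equivalent to "1").  Per-sample codes aggregate to one code per cultivar:
any true-to-type assessment dominates, with preference "1" > "5" > "2";
failing that, the most common of {"3", "4"} is taken; "0" is dominated by
any other code since any surviving assessment supersedes a deceased tree.

The reciprocal match validates consensus building: a consensus genotype is
*assignable* when it is identical — exact set equality at every marker, no
tolerance — to at least one individual sample profile, i.e. it points at an
actual accession rather than being a synthetic optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import TRUENESS_CODES


@dataclass
class MatchReport:
    assignable: list = field(default_factory=list)
    synthetic: list = field(default_factory=list)

    @property
    def fraction_assignable(self) -> float:
        total = len(self.assignable) + len(self.synthetic)
        return len(self.assignable) / total if total else 0.0


def aggregate_trueness(codes) -> str:
    """Aggregate per-sample trueness codes to one cultivar-level code.

    Order-invariant and idempotent.  Raises on an empty list and on
    inadmissible codes.
    """
    if not codes:
        raise ValueError("cannot aggregate an empty list of trueness codes")
    bad = [c for c in codes if c not in TRUENESS_CODES]
    if bad:
        raise ValueError(f"inadmissible trueness code(s) {bad}")
    s = {"1" if c == "R" else c for c in codes}
    for preferred in ("1", "5", "2"):
        if preferred in s:
            return preferred
    n3 = sum(1 for c in codes if c == "3")
    n4 = sum(1 for c in codes if c == "4")
    if n3 or n4:
        return "4" if n4 > n3 else "3"
    return "0"


def _profile_key(profile, markers):
    return tuple(tuple(sorted(profile[m])) for m in markers)


def reciprocal_match(consensus, samples) -> MatchReport:
    """Classify each consensus genotype as assignable (identical to at least
    one individual profile at all markers) or synthetic."""
    if not consensus:
        return MatchReport()
    markers = list(consensus[0].calls.keys())
    observed = {_profile_key(s.profile, markers) for s in samples}
    report = MatchReport()
    for p in consensus:
        if _profile_key(p.calls, markers) in observed:
            report.assignable.append(p.group_id)
        else:
            report.synthetic.append(p.group_id)
    return report
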