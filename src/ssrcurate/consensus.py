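"""Consensus genotype construction for molecular groups.

One representative AFL set per marker is compiled from all replicate samples
of a group by the most-frequent-call rule, adjusted by three curation rules
that mirror how replicate SSR data actually fails:

* **Fill rule** — when the modal call is null but at least one sample shows
  alleles, the most frequent non-null call wins (amplification dropout in
  the majority must not erase an observed genotype).
* **Heterozygous preference** — when a minority call is a strict superset of
  the modal call and each extra allele lies more than the tolerance away
  from every modal allele, the superset wins: the extra allele is a real
  second (or, at multi-locus markers, third) allele that dropped out or went
  unmeasured in most samples, not a +/-1 bp sizing artefact.
* **Ploidy-aware artefact removal** — at single-locus markers, a diploid
  consensus carrying more than two alleles is screened against a census of
  all consensus genotypes: an allele unique to this one genotype, sitting
  within a small window (default 1 bp) of a widespread allele in the same
  call, is removed as a chromatogram-processing artefact.  Multi-locus
  markers are exempt, and ploidy is never inferred from allele counts.

Every deviation from the plain modal call leaves a flag, so curators can
review exactly which rule fired where.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .model import ConsensusProfile
from .panel import LocusType
from .distance import common_allele_count
from .trueness import aggregate_trueness


@dataclass
class ConsensusParams:
    """Tolerance used by the heterozygous-preference rule, the census window
    for ploidy-aware artefact removal, and per-group window overrides
    ({group_id: {marker: window_bp}}) sourced from adjust_allele directives."""

    tolerance_bp: int = 1
    census_window_bp: int = 1
    window_overrides: dict = field(default_factory=dict)


def tally_calls(samples, marker):
    """Exact multiplicity count of each distinct observed call at ``marker``,
    in first-seen order; the null call counts as its own category."""
    counts = {}
    for s in samples:
        call = s.profile.get(marker, frozenset())
        counts[call] = counts.get(call, 0) + 1
    return counts


def _equivalent(a, b, tol) -> bool:
    # Same-size calls whose alleles pair off entirely within tolerance are
    # sizing variants of one another.
    return len(a) == len(b) and common_allele_count(a, b, tol) == len(a)


def consensus_alleles(counts, tolerance_bp=1):
    """Resolve one marker's tallied calls into a consensus AFL set.

    Returns ``(call, flags)`` with flags from {unresolved, missing-filled,
    heterozygous-preference}.  Ties between equally frequent calls collapse
    to the variant with the smaller AFLs when the tied calls are within
    tolerance of each other (a sizing artefact); otherwise the first-seen
    modal call is kept.  Either way the tie is flagged unresolved for manual
    review.  The fill rule applies before the heterozygous preference, and
    the superset promotion iterates so chained supersets resolve fully.
    """
    if not counts:
        raise ValueError("no calls tallied")
    flags = []
    items = list(counts.items())
    top = max(c for _, c in items)
    tied = [call for call, c in items if c == top]
    modal = tied[0]
    if len(tied) > 1:
        if all(_equivalent(tied[0], t, tolerance_bp) for t in tied[1:]):
            modal = min(tied, key=lambda c: tuple(sorted(c)))
        flags.append("unresolved")

    if not modal:
        non_null = [(call, c) for call, c in items if call]
        if non_null:
            best = max(c for _, c in non_null)
            modal = next(call for call, c in non_null if c == best)
            flags.append("missing-filled")

    promoted = False
    while True:
        candidates = [
            (call, c)
            for call, c in items
            if call > modal
            and all(
                abs(extra - m) > tolerance_bp for extra in call - modal for m in modal
            )
        ]
        if not candidates:
            break
        best = max(c for _, c in candidates)
        modal = next(call for call, c in candidates if c == best)
        promoted = True
    if promoted:
        flags.append("heterozygous-preference")
    return modal, flags


def build_census(profiles):
    """Per-marker count of how many consensus genotypes carry each AFL.

    Dataset uniqueness for the artefact-removal rule is defined over
    consensus genotypes, not over individual samples.
    """
    census = {}
    for p in profiles:
        for marker, call in p.calls.items():
            c = census.setdefault(marker, Counter())
            for a in call:
                c[a] += 1
    return census


def ploidy_adjust(profile, dataset_afl_census, panel, params=None) -> ConsensusProfile:
    """Remove dataset-unique sizing artefacts from over-full diploid calls.

    Only applies to genotypes of known ploidy 2, at single-locus markers
    whose consensus call holds more than two alleles.  An allele is removed
    iff it occurs in no other consensus genotype (census count 1) and lies
    within the comparison window of a non-unique allele of the same call.
    Unique alleles are removed in ascending order until two remain; if the
    removable alleles cannot resolve the excess the call is left intact and
    flagged unresolved.  Triploid calls and multi-locus markers are exempt.
    """
    params = params or ConsensusParams()
    if profile.ploidy != 2:
        return profile
    calls = dict(profile.calls)
    flags = list(profile.flags)
    touched = False
    for mdef in panel:
        if mdef.locus_type is not LocusType.SINGLE:
            continue
        call = calls.get(mdef.name, frozenset())
        if len(call) <= 2:
            continue
        window = params.window_overrides.get(profile.group_id, {}).get(
            mdef.name, params.census_window_bp
        )
        marker_census = dataset_afl_census.get(mdef.name, Counter())
        non_unique = {a for a in call if marker_census.get(a, 0) > 1}
        removable = sorted(
            a
            for a in call
            if marker_census.get(a, 0) <= 1
            and any(0 < abs(a - b) <= window for b in non_unique)
        )
        kept = set(call)
        for a in removable:
            if len(kept) <= 2:
                break
            kept.discard(a)
        if len(kept) == len(call) or len(kept) > 2:
            flags.append(f"{mdef.name}:unresolved")
        else:
            calls[mdef.name] = frozenset(kept)
            flags.append(f"{mdef.name}:ploidy-adjusted")
            touched = True
    if not touched and flags == profile.flags:
        return profile
    return ConsensusProfile(
        group_id=profile.group_id,
        cultivar_name=profile.cultivar_name,
        calls=calls,
        trueness=profile.trueness,
        ploidy=profile.ploidy,
        munq=profile.munq,
        flags=flags,
    )


def _modal_value(values):
    """Most common non-empty value, first-seen on ties; None if none."""
    counts = {}
    for v in values:
        if v:
            counts[v] = counts.get(v, 0) + 1
    if not counts:
        return None
    best = max(counts.values())
    return next(v for v, c in counts.items() if c == best)


def _cultivar_name(members, group_id):
    # Naming precedence: pomological determination > holder's original name
    # > the molecular group id as a stand-in.
    name = _modal_value([s.pomological_cultivar for s in members])
    if name:
        return name
    name = _modal_value([s.putative_cultivar for s in members])
    if name:
        return name
    return group_id


def build_consensus(groups, samples, panel, params=None):
    """Build one consensus profile per molecular group.

    Runs tally -> :func:`consensus_alleles` per marker, aggregates trueness
    and ploidy metadata, then applies :func:`ploidy_adjust` against a census
    computed over the freshly built consensus genotypes.  Deterministic for
    a given input order.
    """
    params = params or ConsensusParams()
    by_id = {s.sample_id: s for s in samples}
    profiles = []
    for g in groups:
        members = [by_id[sid] for sid in g.member_sample_ids if sid in by_id]
        if not members:
            continue
        calls = {}
        flags = []
        for marker in panel.names:
            call, marker_flags = consensus_alleles(
                tally_calls(members, marker), params.tolerance_bp
            )
            calls[marker] = call
            flags.extend(f"{marker}:{f}" for f in marker_flags)
        codes = [s.trueness for s in members if s.trueness]
        profiles.append(
            ConsensusProfile(
                group_id=g.group_id,
                cultivar_name=_cultivar_name(members, g.group_id),
                calls=calls,
                trueness=aggregate_trueness(codes) if codes else None,
                ploidy=_modal_value([s.ploidy for s in members]),
                flags=flags,
            )
        )
    census = build_census(profiles)
    return [ploidy_adjust(p, census, panel, params) for p in profiles]
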