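"""Cross-cohort AFL harmonization and replayable curation directives.

Two kinds of corrections precede consensus building:

* **Shift correction** — one marker (CH02g09 in the default panel) shows a
  systematic 2 bp sizing offset between project cohorts, predominantly at
  AFLs 122-140 bp.  An affected-cohort value is shifted only when a group
  mate from the other cohort exhibits the shifted value at the same marker
  (within-group evidence), never blanket-shifted across the window.

* **Curation directives** — the manual curation steps (removing swapped or
  failed samples, reassigning samples to their correct group, splitting
  groups that merged closely related di-/triploid cultivars, and per-group
  allele-window overrides) expressed as a declarative YAML file replayed on
  every run, making the curation reproducible and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

from .distance import next_group_index
from .model import MolecularGroup

#: Pomological determinations excluded from the collection by default.
DEFAULT_EXCLUSIONS = ("rootstock", "crab apple", "wild apple")

VERBS = {"remove_sample", "reassign_sample", "split_group", "adjust_allele"}


class DirectiveError(ValueError):
    """A directive references an unknown target or is malformed."""


@dataclass
class CurationDirective:
    verb: str
    target: str
    args: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.verb not in VERBS:
            raise DirectiveError(f"unknown directive verb {self.verb!r}")


@dataclass
class ShiftEdit:
    sample_id: str
    marker: str
    old_afl: int
    new_afl: int


@dataclass
class ShiftReport:
    edits: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": e.sample_id,
                    "marker": e.marker,
                    "old_afl": e.old_afl,
                    "new_afl": e.new_afl,
                }
                for e in self.edits
            ],
            columns=["sample_id", "marker", "old_afl", "new_afl"],
        )

    def write(self, path):
        self.to_frame().to_csv(path, index=False)


def load_directives(path):
    """Load a YAML list of ``{verb, target, args}`` directives."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or []
    return [
        CurationDirective(
            verb=d["verb"], target=str(d["target"]), args=d.get("args") or {}
        )
        for d in data
    ]


def shift_correct(samples, groups, marker_def):
    """Correct the inter-cohort sizing offset at ``marker_def``'s marker.

    For every group containing samples from both cohorts, an affected-cohort
    AFL ``a`` inside the rule window is replaced by ``a + shift`` iff some
    other-cohort group mate shows ``a + shift`` at the same marker and no
    other-cohort mate shows ``a`` itself (a corroborated value needs no
    correction, which also makes the operation idempotent).  Returns the
    edited samples (input untouched) and a :class:`ShiftReport`.
    No-op when the marker has no shift rule.
    """
    rule = marker_def.shift_rule
    if rule is None:
        return list(samples), ShiftReport()
    marker = marker_def.name
    by_id = {s.sample_id: s for s in samples}
    edited = {}
    report = ShiftReport()

    for g in groups:
        members = [by_id[sid] for sid in g.member_sample_ids if sid in by_id]
        affected = [s for s in members if s.cohort == rule.affected_cohort]
        others = [s for s in members if s.cohort is not None and s.cohort != rule.affected_cohort]
        if not affected or not others:
            continue
        other_alleles = set()
        for s in others:
            other_alleles.update(s.profile.get(marker, frozenset()))
        for s in affected:
            call = s.profile.get(marker, frozenset())
            moves = [
                a
                for a in sorted(call)
                if rule.window_low_bp <= a <= rule.window_high_bp
                and (a + rule.shift_bp) in other_alleles
                and a not in other_alleles
            ]
            if not moves:
                continue
            new_call = set(call)
            for a in moves:
                new_call.discard(a)
                new_call.add(a + rule.shift_bp)
                report.edits.append(ShiftEdit(s.sample_id, marker, a, a + rule.shift_bp))
            new_profile = dict(s.profile)
            new_profile[marker] = frozenset(new_call)
            edited[s.sample_id] = replace(s, profile=new_profile)

    out = [edited.get(s.sample_id, s) for s in samples]
    return out, report


def make_exclusion_directives(samples, vocabulary=DEFAULT_EXCLUSIONS):
    """Generate remove_sample directives for samples whose pomological
    determination matches the exclusion vocabulary (rootstocks, crab apples,
    wild apples by default)."""
    vocab = tuple(v.lower() for v in vocabulary)
    out = []
    for s in samples:
        name = (s.pomological_cultivar or "").lower()
        if name and any(term in name for term in vocab):
            out.append(
                CurationDirective(
                    verb="remove_sample",
                    target=s.sample_id,
                    args={"reason": f"pomological exclusion: {s.pomological_cultivar}"},
                )
            )
    return out


def ploidy_window_overrides(directives):
    """Collect ``adjust_allele`` directives into a per-group, per-marker
    census-window override map consumed at the consensus stage."""
    overrides = {}
    for d in directives:
        if d.verb != "adjust_allele":
            continue
        marker = d.args.get("marker")
        window = d.args.get("window_bp")
        if marker is None or window is None:
            raise DirectiveError(
                f"adjust_allele on {d.target!r} needs args marker and window_bp"
            )
        overrides.setdefault(d.target, {})[str(marker)] = int(window)
    return overrides


def apply_directives(samples, groups, directives):
    """Replay curation directives over the dataset.

    * ``remove_sample`` deletes the record (and its group membership; groups
      emptied by removals are dropped).
    * ``reassign_sample`` moves a sample to the named existing group.
    * ``split_group`` partitions a group into the member sets listed under
      ``args['parts']``; the parts get fresh sequential MD numbers and the
      old id is retired (old -> new mapping in the audit log).
    * ``adjust_allele`` defers to the consensus stage (see
      :func:`ploidy_window_overrides`); it is only logged here.

    Returns ``(samples', groups', audit)`` where ``audit`` is an ordered list
    of human-readable mutation records.  Raises :class:`DirectiveError` on
    unknown targets or split parts that do not partition the group.
    """
    samples = list(samples)
    groups = [
        MolecularGroup(member_sample_ids=list(g.member_sample_ids), group_id=g.group_id)
        for g in groups
    ]
    audit = []

    def find_group(gid, lineno):
        for g in groups:
            if g.group_id == gid:
                return g
        raise DirectiveError(f"directive {lineno}: unknown group {gid!r}")

    for lineno, d in enumerate(directives, start=1):
        if d.verb == "remove_sample":
            matching = [s for s in samples if s.sample_id == d.target]
            if not matching:
                raise DirectiveError(
                    f"directive {lineno}: unknown sample {d.target!r}"
                )
            samples = [s for s in samples if s.sample_id != d.target]
            for g in groups:
                if d.target in g.member_sample_ids:
                    g.member_sample_ids.remove(d.target)
            groups = [g for g in groups if g.member_sample_ids]
            reason = d.args.get("reason", "")
            audit.append(
                f"remove_sample {d.target}" + (f" ({reason})" if reason else "")
            )
        elif d.verb == "reassign_sample":
            if not any(s.sample_id == d.target for s in samples):
                raise DirectiveError(
                    f"directive {lineno}: unknown sample {d.target!r}"
                )
            new_gid = d.args.get("group")
            dest = find_group(new_gid, lineno)
            old = None
            for g in groups:
                if d.target in g.member_sample_ids and g is not dest:
                    g.member_sample_ids.remove(d.target)
                    old = g.group_id
            if d.target not in dest.member_sample_ids:
                dest.member_sample_ids.append(d.target)
            groups = [g for g in groups if g.member_sample_ids]
            audit.append(f"reassign_sample {d.target}: {old} -> {new_gid}")
        elif d.verb == "split_group":
            g = find_group(d.target, lineno)
            parts = [list(p) for p in d.args.get("parts", [])]
            flat = [sid for p in parts for sid in p]
            if sorted(flat) != sorted(g.member_sample_ids) or len(parts) < 2:
                raise DirectiveError(
                    f"directive {lineno}: split parts do not partition "
                    f"group {d.target!r}"
                )
            nxt = next_group_index(groups)
            new_groups = []
            pos = groups.index(g)
            for k, p in enumerate(parts):
                gid = f"MD_{nxt + k:04d}"
                new_groups.append(MolecularGroup(member_sample_ids=p, group_id=gid))
                audit.append(
                    f"split_group {d.target} -> {gid}: members {','.join(p)}"
                )
            groups[pos : pos + 1] = new_groups
        elif d.verb == "adjust_allele":
            audit.append(
                f"adjust_allele {d.target}: marker={d.args.get('marker')} "
                f"window_bp={d.args.get('window_bp')} (applied at consensus stage)"
            )
    return samples, groups, audit
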