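"""Readers and writers for genotype sample tables, group membership and
consensus tables.

All tables are delimited text (CSV, or TSV for ``.tsv``/``.txt`` paths) with
a header row.  Allele cells use the colon-joined ascending notation with
``"0"`` for a null call; parsing and serialization are exact inverses, so a
read-write cycle is lossless.
"""

from __future__ import annotations

import pandas as pd

from .model import (
    Cohort,
    ConsensusProfile,
    DuplicateSampleError,
    MolecularGroup,
    SampleRecord,
    SchemaError,
    format_allele_field,
    parse_allele_field,
)

METADATA_COLUMNS = [
    "sample_id",
    "tree_id",
    "location",
    "cohort",
    "putative_cultivar",
    "pomological_cultivar",
    "trueness",
    "ploidy",
]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _opt(value):
    s = str(value).strip()
    return s if s else None


def read_sample_table(path, panel):
    """Read a sample table into a list of :class:`SampleRecord`, in file order.

    File order is preserved because downstream group-identifier assignment is
    defined by first appearance.

    Raises
    ------
    SchemaError
        If ``sample_id`` or any panel marker column is missing.
    DuplicateSampleError
        If a sample_id occurs twice.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'sample_id'")
    missing = [m for m in panel.names if m not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing marker column(s) {missing}")

    records = []
    seen = set()
    for idx, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        if sid in seen:
            raise DuplicateSampleError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        profile = {
            m: parse_allele_field(row[m], row=sid, column=m) for m in panel.names
        }
        cohort = _opt(row["cohort"]) if "cohort" in df.columns else None
        ploidy = _opt(row["ploidy"]) if "ploidy" in df.columns else None
        records.append(
            SampleRecord(
                sample_id=sid,
                profile=profile,
                tree_id=_opt(row.get("tree_id", "")) or "",
                location=_opt(row.get("location", "")) or "",
                cohort=Cohort(cohort) if cohort else None,
                putative_cultivar=_opt(row.get("putative_cultivar", "")),
                pomological_cultivar=_opt(row.get("pomological_cultivar", "")),
                trueness=_opt(row.get("trueness", "")),
                ploidy=int(ploidy) if ploidy else None,
            )
        )
    return records


def write_sample_table(samples, path, panel):
    """Write samples to a delimited table (inverse of :func:`read_sample_table`)."""
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "tree_id": s.tree_id,
            "location": s.location,
            "cohort": s.cohort.value if s.cohort else "",
            "putative_cultivar": s.putative_cultivar or "",
            "pomological_cultivar": s.pomological_cultivar or "",
            "trueness": s.trueness or "",
            "ploidy": s.ploidy if s.ploidy is not None else "",
        }
        for m in panel.names:
            row[m] = format_allele_field(s.profile[m])
        rows.append(row)
    pd.DataFrame(rows, columns=METADATA_COLUMNS + panel.names).to_csv(
        path, sep=_sep_for(path), index=False
    )


def write_membership(groups, path):
    """Write sample -> group membership as a two-column CSV."""
    rows = [
        {"sample_id": sid, "group_id": g.group_id}
        for g in groups
        for sid in g.member_sample_ids
    ]
    pd.DataFrame(rows, columns=["sample_id", "group_id"]).to_csv(path, index=False)


def read_membership(path):
    """Read a membership CSV back into a list of :class:`MolecularGroup`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if not {"sample_id", "group_id"}.issubset(df.columns):
        raise SchemaError(f"{path}: membership table needs sample_id and group_id")
    order = []
    members = {}
    for _, row in df.iterrows():
        gid = row["group_id"]
        if gid not in members:
            members[gid] = []
            order.append(gid)
        members[gid].append(row["sample_id"])
    return [MolecularGroup(member_sample_ids=members[g], group_id=g) for g in order]


CONSENSUS_META = ["cultivar_name", "group_id", "trueness", "ploidy", "munq"]


def write_consensus_table(profiles, path, panel):
    """Write consensus profiles, mirroring the deposited-table column roles:
    cultivar name, group id, trueness, ploidy, MUNQ, then one column per
    marker with colon-joined ascending AFLs (``"0"`` for a null call)."""
    if not profiles:
        raise ValueError("no consensus profiles to write")
    rows = []
    for p in profiles:
        row = {
            "cultivar_name": p.cultivar_name,
            "group_id": p.group_id,
            "trueness": p.trueness or "",
            "ploidy": p.ploidy if p.ploidy is not None else "",
            "munq": p.munq or "",
        }
        for m in panel.names:
            row[m] = format_allele_field(p.calls[m])
        rows.append(row)
    pd.DataFrame(rows, columns=CONSENSUS_META + panel.names).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_consensus_table(path, panel):
    """Re-parse a written consensus table (lossless round trip)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [m for m in panel.names if m not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing marker column(s) {missing}")
    profiles = []
    for _, row in df.iterrows():
        ploidy = _opt(row.get("ploidy", ""))
        profiles.append(
            ConsensusProfile(
                group_id=row["group_id"],
                cultivar_name=row["cultivar_name"],
                calls={
                    m: parse_allele_field(row[m], row=row["group_id"], column=m)
                    for m in panel.names
                },
                trueness=_opt(row.get("trueness", "")),
                ploidy=int(ploidy) if ploidy else None,
                munq=_opt(row.get("munq", "")),
            )
        )
    return profiles


def write_flags(profiles, path):
    """Write per-marker review flags (one row per rule firing) as CSV."""
    rows = []
    for p in profiles:
        for flag in p.flags:
            marker, _, kind = flag.partition(":")
            rows.append({"group_id": p.group_id, "marker": marker, "flag": kind})
    pd.DataFrame(rows, columns=["group_id", "marker", "flag"]).to_csv(
        path, index=False
    )
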