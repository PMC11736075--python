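"""End-to-end orchestration: distance -> cluster -> harmonize -> consensus
-> trueness -> reciprocal match, with a run manifest for provenance.

Every stage writes plain CSV/JSON so each output is independently testable,
and rerunning with identical inputs, parameters and seed yields byte-
identical data artifacts.  Rule firings (consensus cases, shift edits,
directive applications) are logged at INFO so the audit trail mirrors the
manual-inspection narrative the directives replace.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .consensus import ConsensusParams, build_consensus
from .distance import ClusterParams, assign_group_ids, cluster, distance_matrix
from .harmonize import (
    apply_directives,
    load_directives,
    make_exclusion_directives,
    ploidy_window_overrides,
    shift_correct,
)
from .io import (
    read_sample_table,
    write_consensus_table,
    write_flags,
    write_membership,
)
from .panel import default_panel, load_panel
from .trueness import reciprocal_match

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    out_dir: str = "ssrcurate_out"
    panel_path: str = None
    directives_path: str = None
    tolerance_bp: int = 1
    cutoff: float = 0.25
    shift_marker: str = "CH02g09"
    census_window_bp: int = 1
    apply_exclusions: bool = True
    seed: int = 0
    force: bool = False
    extra: dict = field(default_factory=dict)


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(samples_path, config: RunConfig) -> dict:
    """Run every stage on a sample table and write the output bundle.

    Outputs under ``config.out_dir``: ``membership.csv``,
    ``shift_report.csv``, ``audit.log``, ``consensus.csv``, ``flags.csv``,
    ``trueness.csv``, ``match_report.csv`` and ``manifest.json``.  Returns
    a dict of output paths.  Refuses to overwrite a non-empty output
    directory unless ``config.force`` is set.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise PipelineError(
            f"output directory {out} is not empty (use force to overwrite)"
        )
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage attribution
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    panel = stage(
        "panel",
        lambda: load_panel(config.panel_path) if config.panel_path else default_panel(),
    )
    samples = stage("read", lambda: read_sample_table(samples_path, panel))
    cparams = ClusterParams(tolerance_bp=config.tolerance_bp, cutoff=config.cutoff)

    dm = stage("distance", lambda: distance_matrix(samples, cparams))
    groups = stage(
        "cluster", lambda: assign_group_ids(cluster(dm, cparams))
    )
    log.info("clustered %d samples into %d molecular groups", len(samples), len(groups))

    # Harmonization: inter-cohort shift correction, then curation directives
    # (auto-generated pomological exclusions first, then the user's file).
    shift_def = panel.get(config.shift_marker) if config.shift_marker else None
    if shift_def is not None:
        samples, shift_report = stage(
            "shift", lambda: shift_correct(samples, groups, shift_def)
        )
        for e in shift_report.edits:
            log.info(
                "shift edit: %s %s %d -> %d", e.sample_id, e.marker, e.old_afl, e.new_afl
            )
    else:
        from .harmonize import ShiftReport

        shift_report = ShiftReport()

    directives = []
    if config.apply_exclusions:
        directives.extend(make_exclusion_directives(samples))
    directive_hash = None
    if config.directives_path:
        directives.extend(load_directives(config.directives_path))
        directive_hash = _sha256_file(config.directives_path)
    samples, groups, audit = stage(
        "directives", lambda: apply_directives(samples, groups, directives)
    )
    for line in audit:
        log.info("directive: %s", line)

    consensus_params = ConsensusParams(
        tolerance_bp=config.tolerance_bp,
        census_window_bp=config.census_window_bp,
        window_overrides=ploidy_window_overrides(directives),
    )
    profiles = stage(
        "consensus", lambda: build_consensus(groups, samples, panel, consensus_params)
    )
    for p in profiles:
        for f in p.flags:
            log.info("consensus flag: %s %s", p.group_id, f)
    report = stage("match", lambda: reciprocal_match(profiles, samples))
    log.info(
        "reciprocal match: %d/%d consensus genotypes assignable (%.1f%%)",
        len(report.assignable),
        len(report.assignable) + len(report.synthetic),
        100.0 * report.fraction_assignable,
    )

    paths = {
        "membership": out / "membership.csv",
        "shift_report": out / "shift_report.csv",
        "audit": out / "audit.log",
        "consensus": out / "consensus.csv",
        "flags": out / "flags.csv",
        "trueness": out / "trueness.csv",
        "match_report": out / "match_report.csv",
        "manifest": out / "manifest.json",
    }
    write_membership(groups, paths["membership"])
    shift_report.write(paths["shift_report"])
    paths["audit"].write_text("\n".join(audit) + ("\n" if audit else ""), encoding="utf-8")
    write_consensus_table(profiles, paths["consensus"], panel)
    write_flags(profiles, paths["flags"])
    pd.DataFrame(
        [
            {
                "group_id": p.group_id,
                "cultivar_name": p.cultivar_name,
                "trueness": p.trueness or "",
            }
            for p in profiles
        ],
        columns=["group_id", "cultivar_name", "trueness"],
    ).to_csv(paths["trueness"], index=False)
    pd.DataFrame(
        [{"group_id": g, "status": "assignable"} for g in report.assignable]
        + [{"group_id": g, "status": "synthetic"} for g in report.synthetic],
        columns=["group_id", "status"],
    ).to_csv(paths["match_report"], index=False)

    params = {
        "tolerance_bp": config.tolerance_bp,
        "cutoff": config.cutoff,
        "shift_marker": config.shift_marker,
        "census_window_bp": config.census_window_bp,
        "apply_exclusions": config.apply_exclusions,
        "seed": config.seed,
    }
    manifest = {
        "ssrcurate_version": __version__,
        "input": str(samples_path),
        "input_sha256": _sha256_file(samples_path),
        "panel": config.panel_path or "builtin:panel_malus17",
        "directives": config.directives_path,
        "directives_sha256": directive_hash,
        "params": params,
        "params_sha256": _params_hash(params),
        "n_samples": len(samples),
        "n_groups": len(groups),
        "fraction_assignable": report.fraction_assignable,
        "outputs": {k: str(v) for k, v in paths.items() if k != "manifest"},
    }
    paths["manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {k: str(v) for k, v in paths.items()}
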