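"""Consensus genotype construction: modal calls, the fill rule, heterozygous
preference, tie resolution and ploidy-aware artefact removal."""

import random
from collections import Counter

import pytest

from ssrcurate import (
    ConsensusParams,
    ConsensusProfile,
    MolecularGroup,
    SimConfig,
    build_census,
    build_consensus,
    consensus_alleles,
    emit_samples,
    generate_truth,
    ploidy_adjust,
    tally_calls,
)

from conftest import make_sample


def fs(*alleles):
    return frozenset(alleles)


def test_tally_counts_distinct_calls(panel):
    samples = [
        make_sample("A", {"COL": {221}}, panel),
        make_sample("B", {"COL": {221}}, panel),
        make_sample("C", {"COL": {221, 231}}, panel),
    ]
    assert tally_calls(samples, "COL") == {fs(221): 2, fs(221, 231): 1}
    assert tally_calls(samples, "CH01h01") == {fs(100, 120): 3}


@pytest.mark.parametrize(
    "counts, expected, expected_flags",
    [
        # minority two-allele call beats the modal single-allele call when
        # the extra allele is >1 bp away (dropout, not a sizing artefact)
        ({fs(221): 3, fs(221, 231): 2}, fs(221, 231), ["heterozygous-preference"]),
        # same promotion for a three-allele multi-locus call
        ({fs(115, 150): 4, fs(109, 115, 150): 2}, fs(109, 115, 150), ["heterozygous-preference"]),
        # a mostly-null marker is filled from the minority non-null call
        ({fs(): 5, fs(140): 1}, fs(140), ["missing-filled"]),
        # equally frequent within-tolerance variants collapse to the smaller
        ({fs(200): 3, fs(201): 3}, fs(200), ["unresolved"]),
        # a within-tolerance extra allele is NOT promoted
        ({fs(221): 3, fs(221, 222): 2}, fs(221), []),
        # disjoint minority call can never overwrite the majority
        ({fs(221): 3, fs(300): 2}, fs(221), []),
        # plain majority
        ({fs(120, 130): 5, fs(120): 1}, fs(120, 130), []),
        # all null stays null
        ({fs(): 4}, fs(), []),
        # out-of-tolerance tie keeps the first-seen call but flags it
        ({fs(200): 2, fs(240): 2}, fs(200), ["unresolved"]),
    ],
)
def test_consensus_alleles_rules(counts, expected, expected_flags):
    call, flags = consensus_alleles(counts, tolerance_bp=1)
    assert call == expected
    assert flags == expected_flags


def test_fill_then_superset_promotion_compose():
    # modal null -> filled with {221}, then promoted to the superset {221,231}
    call, flags = consensus_alleles({fs(): 3, fs(221): 2, fs(221, 231): 1})
    assert call == fs(221, 231)
    assert flags == ["missing-filled", "heterozygous-preference"]


def test_chained_superset_promotion():
    call, flags = consensus_alleles({fs(221): 4, fs(221, 231): 3, fs(221, 231, 241): 1})
    assert call == fs(221, 231, 241)
    assert flags == ["heterozygous-preference"]


def test_consensus_alleles_requires_calls():
    with pytest.raises(ValueError):
        consensus_alleles({})


def _profile_with(panel, marker, alleles, ploidy=2, gid="MD_0001"):
    calls = {m: frozenset({100, 110}) for m in panel.names}
    calls[marker] = frozenset(alleles)
    return ConsensusProfile(group_id=gid, cultivar_name="x", calls=calls, ploidy=ploidy)


def test_ploidy_adjust_removes_unique_artefact_allele(panel):
    # over-full diploid call at a single-locus marker: the dataset-unique 222
    # sits 2 bp from the widespread 224 and is dropped under a 2 bp window
    profile = _profile_with(panel, "CH04f10", {222, 224, 245})
    census = {"CH04f10": Counter({222: 1, 224: 12, 245: 5})}
    params = ConsensusParams(window_overrides={"MD_0001": {"CH04f10": 2}})
    out = ploidy_adjust(profile, census, panel, params)
    assert out.calls["CH04f10"] == fs(224, 245)
    assert "CH04f10:ploidy-adjusted" in out.flags


def test_ploidy_adjust_default_window_is_one_bp(panel):
    profile = _profile_with(panel, "CH04f10", {222, 224, 245})
    census = {"CH04f10": Counter({222: 1, 224: 12, 245: 5})}
    out = ploidy_adjust(profile, census, panel)  # 222 is 2 bp away: kept
    assert out.calls["CH04f10"] == fs(222, 224, 245)
    assert "CH04f10:unresolved" in out.flags


def test_ploidy_adjust_exempts_multi_locus_markers(panel):
    profile = _profile_with(panel, "Hi02c07", {109, 115, 150})
    census = {"Hi02c07": Counter({109: 1, 115: 9, 150: 9})}
    out = ploidy_adjust(profile, census, panel, ConsensusParams(census_window_bp=2))
    assert out.calls["Hi02c07"] == fs(109, 115, 150)


def test_ploidy_adjust_flags_widespread_excess_instead_of_altering(panel):
    profile = _profile_with(panel, "CH04f10", {200, 250, 300})
    census = {"CH04f10": Counter({200: 5, 250: 5, 300: 5})}
    out = ploidy_adjust(profile, census, panel)
    assert out.calls["CH04f10"] == fs(200, 250, 300)
    assert "CH04f10:unresolved" in out.flags


def test_ploidy_adjust_leaves_triploids_and_unknown_ploidy_alone(panel):
    census = {"CH04f10": Counter({222: 1, 224: 12, 245: 5})}
    tri = _profile_with(panel, "CH04f10", {222, 224, 245}, ploidy=3)
    assert ploidy_adjust(tri, census, panel).calls["CH04f10"] == fs(222, 224, 245)
    unk = _profile_with(panel, "CH04f10", {222, 224, 245}, ploidy=None)
    assert ploidy_adjust(unk, census, panel).calls["CH04f10"] == fs(222, 224, 245)


def test_census_counts_genotypes_not_samples(panel):
    p1 = _profile_with(panel, "CH04f10", {222, 224}, gid="MD_0001")
    p2 = _profile_with(panel, "CH04f10", {224, 245}, gid="MD_0002")
    census = build_census([p1, p2])
    assert census["CH04f10"][224] == 2
    assert census["CH04f10"][222] == 1
    assert census["CH01h01"][100] == 2


@pytest.mark.parametrize("k", [1, 2, 5])
def test_consensus_of_identical_copies_is_identity(panel, k):
    rng = random.Random(3)
    calls = {m: set(rng.sample(range(100, 200), 2)) for m in panel.names}
    calls["GD147"] = set()  # an all-null marker stays null, unflagged
    samples = [make_sample(f"S{i}", calls, panel, trueness="1") for i in range(k)]
    groups = [MolecularGroup(member_sample_ids=[s.sample_id for s in samples],
                             group_id="MD_0001")]
    [profile] = build_consensus(groups, samples, panel)
    assert profile.calls == {m: frozenset(v) for m, v in calls.items()}
    assert profile.flags == []
    assert profile.trueness == "1"


def test_build_consensus_composes_rules_and_flags(panel):
    # one marker exercises the heterozygous preference, another the fill rule
    samples = (
        [make_sample(f"A{i}", {"COL": {221}, "GD147": set()}, panel) for i in range(3)]
        + [make_sample(f"B{i}", {"COL": {221, 231}, "GD147": set()}, panel) for i in range(2)]
        + [make_sample("C", {"COL": {221}, "GD147": {140}}, panel)]
    )
    groups = [MolecularGroup([s.sample_id for s in samples], "MD_0001")]
    [profile] = build_consensus(groups, samples, panel)
    assert profile.calls["COL"] == fs(221, 231)
    assert profile.calls["GD147"] == fs(140)
    assert sorted(profile.flags) == ["COL:heterozygous-preference", "GD147:missing-filled"]


def test_cultivar_naming_precedence(panel):
    samples = [
        make_sample("A", {}, panel, pomological_cultivar="Jakob Fischer",
                    putative_cultivar="unknown red"),
        make_sample("B", {}, panel, putative_cultivar="unknown red"),
    ]
    groups = [MolecularGroup(["A", "B"], "MD_0001"),]
    [profile] = build_consensus(groups, samples, panel)
    assert profile.cultivar_name == "Jakob Fischer"
    # without any name, the group id stands in
    samples2 = [make_sample("C", {}, panel)]
    [p2] = build_consensus([MolecularGroup(["C"], "MD_0002")], samples2, panel)
    assert p2.cultivar_name == "MD_0002"


def test_many_replicates_with_dropout_recover_the_true_genotype(panel):
    """73 replicates of one cultivar with 5% per-marker dropout: the modal
    and fill rules reconstruct the true genotype exactly."""
    cfg = SimConfig(
        n_cultivars=1,
        samples_per_cultivar=(73, 73),
        jitter_prob=0.0,
        dropout_prob=0.05,
        swap_prob=0.0,
        mutant_prob=0.0,
        simulate_shift=False,
        seed=21,
    )
    truth = generate_truth(cfg, panel)
    samples = emit_samples(truth, cfg)
    assert len(samples) == 73
    groups = [MolecularGroup([s.sample_id for s in samples], "MD_0001")]
    [profile] = build_consensus(groups, samples, panel)
    [genotype] = truth.genotypes.values()
    assert profile.calls == genotype
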