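"""Inter-cohort shift correction and replayable curation directives."""

import pytest
import yaml

from ssrcurate import (
    Cohort,
    CurationDirective,
    DirectiveError,
    MolecularGroup,
    apply_directives,
    load_directives,
    make_exclusion_directives,
    ploidy_window_overrides,
    shift_correct,
)

from conftest import make_sample


@pytest.fixture
def shift_setup(panel):
    # One group mixing both cohorts; early-cohort sample reports 130 where a
    # late-cohort mate reports 132 at CH02g09.
    samples = [
        make_sample("A", {"CH02g09": {130, 150}, "CH01h01": {130}}, panel,
                    cohort=Cohort.P2009_2014),
        make_sample("B", {"CH02g09": {132, 150}}, panel, cohort=Cohort.P2017_2021),
    ]
    groups = [MolecularGroup(member_sample_ids=["A", "B"], group_id="MD_0001")]
    return samples, groups


def test_shift_applies_inside_window_with_group_evidence(shift_setup, panel):
    samples, groups = shift_setup
    out, report = shift_correct(samples, groups, panel.get("CH02g09"))
    assert out[0].profile["CH02g09"] == frozenset({132, 150})
    assert [(e.sample_id, e.old_afl, e.new_afl) for e in report.edits] == [("A", 130, 132)]
    # 150 is outside the 122-140 window: untouched even though B shows 152? no
    assert 150 in out[0].profile["CH02g09"]
    # the rule is marker-specific: CH01h01 untouched despite the 130 value
    assert out[0].profile["CH01h01"] == frozenset({130})
    # input records are not mutated
    assert samples[0].profile["CH02g09"] == frozenset({130, 150})


def test_shift_requires_other_cohort_evidence(panel):
    samples = [
        make_sample("A", {"CH02g09": {130}}, panel, cohort=Cohort.P2009_2014),
        make_sample("B", {"CH02g09": {136}}, panel, cohort=Cohort.P2017_2021),
    ]
    groups = [MolecularGroup(member_sample_ids=["A", "B"], group_id="MD_0001")]
    out, report = shift_correct(samples, groups, panel.get("CH02g09"))
    assert out[0].profile["CH02g09"] == frozenset({130})  # no 132 among mates
    assert report.edits == []


def test_shift_does_not_touch_unaffected_cohort(panel):
    samples = [
        make_sample("A", {"CH02g09": {130}}, panel, cohort=Cohort.P2017_2021),
        make_sample("B", {"CH02g09": {132}}, panel, cohort=Cohort.P2017_2021),
    ]
    groups = [MolecularGroup(member_sample_ids=["A", "B"], group_id="MD_0001")]
    out, report = shift_correct(samples, groups, panel.get("CH02g09"))
    assert report.edits == []
    assert out[0].profile["CH02g09"] == frozenset({130})


def test_shift_correction_is_idempotent(shift_setup, panel):
    samples, groups = shift_setup
    once, report1 = shift_correct(samples, groups, panel.get("CH02g09"))
    twice, report2 = shift_correct(once, groups, panel.get("CH02g09"))
    assert report1.edits and not report2.edits
    assert [s.profile for s in twice] == [s.profile for s in once]


def test_shift_noop_without_rule(shift_setup, panel):
    samples, groups = shift_setup
    out, report = shift_correct(samples, groups, panel.get("CH01h01"))
    assert report.edits == []
    assert [s.profile for s in out] == [s.profile for s in samples]


@pytest.fixture
def directive_setup(panel):
    samples = [make_sample(f"S{i}", {}, panel) for i in range(1, 11)]
    groups = [
        MolecularGroup(member_sample_ids=["S1", "S2", "S3"], group_id="MD_0010"),
        MolecularGroup(member_sample_ids=["S4", "S5"], group_id="MD_0007"),
        MolecularGroup(
            member_sample_ids=["S6", "S7", "S8", "S9", "S10"], group_id="MD_0003"
        ),
    ]
    return samples, groups


def test_remove_sample_bookkeeping(directive_setup):
    samples, groups = directive_setup
    out_s, out_g, audit = apply_directives(
        samples, groups, [CurationDirective("remove_sample", "S7")]
    )
    assert len(out_s) == 9
    assert len(audit) == 1
    assert all("S7" not in g.member_sample_ids for g in out_g)
    assert len(samples) == 10  # input untouched


def test_reassign_sample_moves_to_single_group(directive_setup):
    samples, groups = directive_setup
    _, out_g, _ = apply_directives(
        samples,
        groups,
        [CurationDirective("reassign_sample", "S3", {"group": "MD_0007"})],
    )
    holders = [g.group_id for g in out_g if "S3" in g.member_sample_ids]
    assert holders == ["MD_0007"]


def test_split_group_preserves_union_and_numbers_fresh(directive_setup):
    samples, groups = directive_setup
    _, out_g, audit = apply_directives(
        samples,
        groups,
        [
            CurationDirective(
                "split_group", "MD_0010", {"parts": [["S1", "S2"], ["S3"]]}
            )
        ],
    )
    ids = [g.group_id for g in out_g]
    assert "MD_0010" not in ids
    assert "MD_0011" in ids and "MD_0012" in ids  # fresh numbers past the max
    new_members = [
        set(g.member_sample_ids) for g in out_g if g.group_id in ("MD_0011", "MD_0012")
    ]
    assert new_members == [{"S1", "S2"}, {"S3"}]
    assert any("MD_0010" in line for line in audit)


def test_split_must_partition(directive_setup):
    samples, groups = directive_setup
    with pytest.raises(DirectiveError, match="partition"):
        apply_directives(
            samples,
            groups,
            [CurationDirective("split_group", "MD_0010", {"parts": [["S1"], ["S3"]]})],
        )


@pytest.mark.parametrize(
    "directive",
    [
        CurationDirective("remove_sample", "S99"),
        CurationDirective("reassign_sample", "S99", {"group": "MD_0007"}),
        CurationDirective("reassign_sample", "S1", {"group": "MD_9999"}),
        CurationDirective("split_group", "MD_9999", {"parts": [["S1"], ["S2"]]}),
    ],
)
def test_unknown_targets_raise(directive_setup, directive):
    samples, groups = directive_setup
    with pytest.raises(DirectiveError):
        apply_directives(samples, groups, [directive])


def test_directives_round_trip_through_yaml(tmp_path):
    path = tmp_path / "directives.yaml"
    path.write_text(
        yaml.safe_dump(
            [
                {"verb": "remove_sample", "target": "S1"},
                {
                    "verb": "adjust_allele",
                    "target": "MD_0760",
                    "args": {"marker": "CH04f10", "window_bp": 2},
                },
            ]
        )
    )
    directives = load_directives(path)
    assert [d.verb for d in directives] == ["remove_sample", "adjust_allele"]
    assert ploidy_window_overrides(directives) == {"MD_0760": {"CH04f10": 2}}


def test_exclusion_vocabulary_generates_removals(panel):
    samples = [
        make_sample("S1", {}, panel, pomological_cultivar="Boskoop"),
        make_sample("S2", {}, panel, pomological_cultivar="Rootstock M9"),
        make_sample("S3", {}, panel, pomological_cultivar="wild apple seedling"),
    ]
    directives = make_exclusion_directives(samples)
    assert [d.target for d in directives] == ["S2", "S3"]
    assert all(d.verb == "remove_sample" for d in directives)
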