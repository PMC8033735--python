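"""ACMG-AMP combining engine, label mappings, and reportability selection."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carrierfreq import (
    Classification,
    EvidenceSet,
    Scheme,
    combine_acmg_evidence,
    parse_acmg_codes,
    reportable_from_clinvar,
    reportable_from_hgmd,
    select_reportable,
)
from carrierfreq.classify import CLASS_ORDER


# ---------------------------------------------------------------------------
# Independent rule-table oracle: literally enumerates the qualifying
# combinations of the 2015 guideline, one tuple template per rule.

def oracle_classify(ev):
    pathogenic = (
        (ev.pvs1 and ev.ps >= 1)
        or (ev.pvs1 and ev.pm >= 2)
        or (ev.pvs1 and ev.pm == 1 and ev.pp >= 1)
        or (ev.pvs1 and ev.pp >= 2)
        or ev.ps >= 2
        or (ev.ps == 1 and ev.pm >= 3)
        or (ev.ps == 1 and ev.pm == 2 and ev.pp >= 2)
        or (ev.ps == 1 and ev.pm == 1 and ev.pp >= 4)
    )
    likely = (
        (ev.pvs1 and ev.pm >= 1)
        or (ev.ps == 1 and ev.pm >= 1)
        or (ev.ps == 1 and ev.pp >= 2)
        or ev.pm >= 3
        or (ev.pm == 2 and ev.pp >= 2)
        or (ev.pm == 1 and ev.pp >= 4)
    )
    benign = ev.ba1 or ev.bs >= 2
    likely_benign = (ev.bs == 1 and ev.bp >= 1) or ev.bp >= 2
    if (pathogenic or likely) and (benign or likely_benign):
        return Classification.UNCERTAIN
    if pathogenic:
        return Classification.PATHOGENIC
    if likely:
        return Classification.LIKELY_PATHOGENIC
    if benign:
        return Classification.BENIGN
    if likely_benign:
        return Classification.LIKELY_BENIGN
    return Classification.UNCERTAIN


def evidence_grid():
    for pvs1, ba1 in itertools.product([False, True], repeat=2):
        for ps, pm, pp, bs, bp in itertools.product(range(5), repeat=5):
            yield EvidenceSet(pvs1=pvs1, ps=ps, pm=pm, pp=pp, ba1=ba1, bs=bs, bp=bp)


class TestCombineEngine:
    def test_pvs1_plus_one_strong_is_pathogenic(self):
        assert combine_acmg_evidence(EvidenceSet(pvs1=True, ps=1)) is Classification.PATHOGENIC

    def test_no_evidence_is_uncertain(self):
        assert combine_acmg_evidence(EvidenceSet()) is Classification.UNCERTAIN

    def test_pvs1_alone_is_uncertain(self):
        assert combine_acmg_evidence(EvidenceSet(pvs1=True)) is Classification.UNCERTAIN

    def test_exhaustive_grid_matches_rule_table_oracle(self):
        for ev in evidence_grid():
            assert combine_acmg_evidence(ev) is oracle_classify(ev), ev

    def test_contradictory_evidence_is_uncertain(self):
        ev = EvidenceSet(pvs1=True, ps=2, ba1=True, bs=2)
        assert combine_acmg_evidence(ev) is Classification.UNCERTAIN

    @given(
        ps=st.integers(0, 3), pm=st.integers(0, 5), pp=st.integers(0, 4),
        bs=st.integers(0, 3), bp=st.integers(0, 6),
        pvs1=st.booleans(), ba1=st.booleans(),
    )
    @settings(max_examples=300, derandomize=True)
    def test_adding_pathogenic_evidence_never_moves_toward_benign(
        self, ps, pm, pp, bs, bp, pvs1, ba1
    ):
        base = EvidenceSet(pvs1=pvs1, ps=ps, pm=pm, pp=pp, ba1=ba1, bs=bs, bp=bp)
        rank = CLASS_ORDER.index
        for bumped in (
            EvidenceSet(pvs1=True, ps=ps, pm=pm, pp=pp, ba1=ba1, bs=bs, bp=bp),
            EvidenceSet(pvs1=pvs1, ps=ps + 1, pm=pm, pp=pp, ba1=ba1, bs=bs, bp=bp),
            EvidenceSet(pvs1=pvs1, ps=ps, pm=pm + 1, pp=pp, ba1=ba1, bs=bs, bp=bp),
            EvidenceSet(pvs1=pvs1, ps=ps, pm=pm, pp=pp + 1, ba1=ba1, bs=bs, bp=bp),
        ):
            assert rank(combine_acmg_evidence(bumped)) >= rank(combine_acmg_evidence(base))
        for bumped in (
            EvidenceSet(pvs1=pvs1, ps=ps, pm=pm, pp=pp, ba1=True, bs=bs, bp=bp),
            EvidenceSet(pvs1=pvs1, ps=ps, pm=pm, pp=pp, ba1=ba1, bs=bs + 1, bp=bp),
            EvidenceSet(pvs1=pvs1, ps=ps, pm=pm, pp=pp, ba1=ba1, bs=bs, bp=bp + 1),
        ):
            assert rank(combine_acmg_evidence(bumped)) <= rank(combine_acmg_evidence(base))


class TestCodeParsing:
    def test_codes_tally_by_strength(self):
        ev = parse_acmg_codes("PVS1,PM2,PP3")
        assert ev == EvidenceSet(pvs1=True, pm=1, pp=1)

    def test_unknown_code_raises(self):
        with pytest.raises(ValueError, match="PX9"):
            parse_acmg_codes("PVS1,PX9")

    def test_count_ranges_enforced(self):
        with pytest.raises(ValueError):
            EvidenceSet(pp=6)


class TestClinvarLabels:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("Pathogenic", True),
            ("Likely_pathogenic", True),
            ("Pathogenic/Likely_pathogenic", True),
            ("pathogenic/likely_pathogenic", True),
            ("Uncertain_significance", False),
            ("Conflicting_interpretations_of_pathogenicity", False),
            ("Pathogenic/Uncertain_significance", False),
            ("Benign", False),
            ("not_provided", False),
        ],
    )
    def test_aggregate_labels(self, label, expected):
        assert reportable_from_clinvar(label) is expected

    def test_unrecognized_label_warns_and_is_not_reportable(self):
        with pytest.warns(UserWarning):
            assert reportable_from_clinvar("totally-novel-category") is False


class TestHgmdLabels:
    @pytest.mark.parametrize(
        "label,expected",
        [("DM", True), ("DM?", False), ("DP", False), ("DFP", False), ("FP", False), ("R", False)],
    )
    def test_six_category_vocabulary(self, label, expected):
        assert reportable_from_hgmd(label) is expected

    def test_unknown_class_warns(self):
        with pytest.warns(UserWarning):
            assert reportable_from_hgmd("XX") is False


class TestSelectReportable:
    def test_empty_annotation_map_selects_nothing(self, dhcr7_records):
        with pytest.warns(UserWarning, match="non-reportable"):
            assert select_reportable(dhcr7_records, Scheme.ACMG2015, {}) == []

    def test_selection_is_order_preserving(self, dhcr7_records, dhcr7_annotations):
        selected = select_reportable(dhcr7_records, "HGMD", dhcr7_annotations["HGMD"])
        positions = [dhcr7_records.index(r) for r in selected]
        assert positions == sorted(positions)

    def test_evidence_sets_accepted_directly(self, dhcr7_records):
        annotations = {r.hgvs_c: EvidenceSet(pvs1=True, ps=1) for r in dhcr7_records[:3]}
        with pytest.warns(UserWarning):
            selected = select_reportable(dhcr7_records, Scheme.ACMG2015, annotations)
        assert len(selected) == 3
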