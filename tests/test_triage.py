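"""Triage: region resolution, SV rules, CNV threshold, the conjunction."""

from __future__ import annotations

import pytest

from fusiontriage import (
    FusionCandidate,
    TriageConfig,
    ValidationError,
    classify_all,
    classify_fusion,
    collect_cnv_evidence,
    collect_sv_evidence,
    resolve_regions,
)
from fusiontriage.records import CNVSegment, SVCall
from fusiontriage.triage import build_cnv_index, build_sv_breakend_index

from _oracles import brute_classify, hits_as_ids


def _fusion(gene5="ALPHA", gene3="BETA", sample=None):
    return FusionCandidate(gene5=gene5, gene3=gene3, sample_id=sample)


class TestResolveRegions:
    def test_padding_arithmetic(self, tiny_genes):
        cfg = TriageConfig(padding_bp=50_000)
        r5, r3 = resolve_regions(_fusion(), tiny_genes, cfg)
        assert (r5.start, r5.end) == (950_000, 1_100_000)
        assert (r3.start, r3.end) == (1_950_000, 2_090_000)

    def test_floor_at_coordinate_one(self, tiny_genes):
        tiny_genes["low"] = type(tiny_genes["alpha"])("LOW", "4", 10_000, 20_000, "+")
        cfg = TriageConfig(padding_bp=50_000)
        r5, _ = resolve_regions(_fusion(gene5="LOW"), tiny_genes, cfg)
        assert r5.start == 1

    def test_missing_symbol_yields_none(self, tiny_genes):
        r5, r3 = resolve_regions(_fusion(gene5="NOSUCHGENE"), tiny_genes, TriageConfig())
        assert r5 is None and r3 is not None

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            TriageConfig(padding_bp=-1)
        with pytest.raises(ValidationError):
            TriageConfig(sv_rule="strictest")


class TestSVRules:
    @pytest.fixture()
    def setup(self, tiny_genes):
        cfg = TriageConfig(padding_bp=10_000)
        fusion = _fusion()
        regions = resolve_regions(fusion, tiny_genes, cfg)
        return fusion, regions, cfg

    def test_either_rule_counts_single_breakend(self, setup):
        fusion, regions, cfg = setup
        # breakend1 inside ALPHA's window, breakend2 elsewhere
        call = SVCall("S", "1", 1_010_000, "+", "9", 5_000_000, "-", "translocation")
        hits = collect_sv_evidence(fusion, regions, build_sv_breakend_index([call]), cfg)
        assert [(h.partner, h.breakend) for h in hits] == [(5, 1)]

    def test_linked_rule_rejects_one_sided_call(self, setup):
        fusion, regions, cfg = setup
        call = SVCall("S", "1", 1_010_000, "+", "9", 5_000_000, "-", "translocation")
        cfg_linked = TriageConfig(padding_bp=10_000, sv_rule="linked")
        hits = collect_sv_evidence(
            fusion, regions, build_sv_breakend_index([call]), cfg_linked
        )
        assert hits == []

    def test_linked_rule_accepts_joining_call(self, setup):
        fusion, regions, _ = setup
        call = SVCall("S", "1", 1_010_000, "+", "2", 2_020_000, "-", "translocation")
        cfg_linked = TriageConfig(padding_bp=10_000, sv_rule="linked")
        hits = collect_sv_evidence(
            fusion, regions, build_sv_breakend_index([call]), cfg_linked
        )
        assert {(h.partner, h.breakend) for h in hits} == {(5, 1), (3, 2)}

    def test_both_rule_requires_each_window(self, setup):
        fusion, regions, _ = setup
        cfg_both = TriageConfig(padding_bp=10_000, sv_rule="both")
        one_sided = SVCall("S", "1", 1_010_000, "+", "9", 5_000_000, "-", "translocation")
        other_side = SVCall("S", "2", 2_010_000, "+", "9", 6_000_000, "-", "translocation")
        only5 = collect_sv_evidence(
            fusion, regions, build_sv_breakend_index([one_sided]), cfg_both
        )
        assert only5 == []
        both = collect_sv_evidence(
            fusion, regions, build_sv_breakend_index([one_sided, other_side]), cfg_both
        )
        assert {h.partner for h in both} == {5, 3}

    def test_rule_nesting_on_random_inputs(self):
        from conftest import random_instance

        for seed in range(5):
            fusions, sv, cnv, genes = random_instance(seed)
            idx = build_sv_breakend_index(sv)
            for fusion in fusions:
                regions = resolve_regions(fusion, genes, TriageConfig(sample_scoped=False))
                hit_sets = {}
                for rule in ("either", "both", "linked"):
                    cfg = TriageConfig(sv_rule=rule, sample_scoped=False)
                    hits = collect_sv_evidence(fusion, regions, idx, cfg)
                    hit_sets[rule] = {(id(h.call), h.partner, h.breakend) for h in hits}
                assert hit_sets["linked"] <= hit_sets["both"] <= hit_sets["either"]


class TestCNVEvidence:
    def test_threshold_and_direction(self, tiny_genes):
        fusion = _fusion()
        cfg = TriageConfig(padding_bp=10_000, cnv_abs_threshold=0.2)
        regions = resolve_regions(fusion, tiny_genes, cfg)
        segs = [
            CNVSegment("S", "1", 1_000_000, 1_050_000, "1", 0.8),   # hit, gain
            CNVSegment("S", "1", 1_000_000, 1_050_000, "2", 0.1),   # below threshold
            CNVSegment("S", "2", 2_000_000, 2_040_000, "3", -0.5),  # hit, loss
        ]
        hits = collect_cnv_evidence(fusion, regions, build_cnv_index(segs), cfg)
        assert [(h.partner, h.direction) for h in hits] == [(5, "gain"), (3, "loss")]
        assert all(h.overlap_bp >= 1 for h in hits)

    def test_zero_threshold_still_excludes_exact_zero(self, tiny_genes):
        fusion = _fusion()
        cfg = TriageConfig(padding_bp=0, cnv_abs_threshold=0.0)
        regions = resolve_regions(fusion, tiny_genes, cfg)
        segs = [
            CNVSegment("S", "1", 1_000_000, 1_050_000, "1", 0.0),
            CNVSegment("S", "1", 1_000_000, 1_050_000, "2", 0.01),
        ]
        hits = collect_cnv_evidence(fusion, regions, build_cnv_index(segs), cfg)
        assert [h.segment.probe_field for h in hits] == ["2"]

    def test_overlap_bp_closed_arithmetic(self, tiny_genes):
        fusion = _fusion()
        cfg = TriageConfig(padding_bp=0)
        regions = resolve_regions(fusion, tiny_genes, cfg)
        seg = CNVSegment("S", "1", 999_000, 1_000_000, "1", 0.5)  # touches window start
        hits = collect_cnv_evidence(fusion, regions, build_cnv_index([seg]), cfg)
        assert hits[0].overlap_bp == 1


class TestConjunction:
    def _sv_hit(self):
        call = SVCall("S", "1", 100, "+", "2", 200, "-", "deletion")
        from fusiontriage.triage import SVHit

        return SVHit(call, 5, 1)

    def _cnv_hit(self):
        from fusiontriage.triage import CNVHit

        seg = CNVSegment("S", "1", 1, 100, "1", 0.5)
        return CNVHit(seg, 3, 50, "gain")

    def test_both_evidence_types_is_driver(self):
        call = classify_fusion(_fusion(), [self._sv_hit()], [self._cnv_hit()])
        assert call.status == "Driver"
        assert call.sv_classes == {"deletion"}
        assert (call.cnv_direction_5, call.cnv_direction_3) == ("none", "gain")

    @pytest.mark.parametrize(
        "with_sv, with_cnv", [(False, False), (True, False), (False, True)]
    )
    def test_missing_either_side_is_passenger(self, with_sv, with_cnv):
        call = classify_fusion(
            _fusion(),
            [self._sv_hit()] if with_sv else [],
            [self._cnv_hit()] if with_cnv else [],
        )
        assert call.status == "Passenger"

    def test_unresolved_is_always_passenger(self):
        call = classify_fusion(
            _fusion(), [self._sv_hit()], [self._cnv_hit()], unresolved=True
        )
        assert call.status == "Passenger" and call.unresolved


class TestClassifyAll:
    def test_verdict_conjunction_invariant(self, calls7):
        for call in calls7:
            is_driver = bool(call.evidence.sv_hits) and bool(call.evidence.cnv_hits)
            assert (call.status == "Driver") == (is_driver and not call.unresolved)

    def test_empty_fusion_list(self, bundle7):
        assert classify_all([], bundle7.sv, bundle7.cnv, bundle7.genes) == []

    def test_no_sv_means_all_passenger(self, bundle7):
        calls = bundle7.classify()
        calls_no_sv = classify_all(
            bundle7.fusions, [], bundle7.cnv, bundle7.genes, compute_correlation=False
        )
        assert len(calls_no_sv) == len(calls)
        assert all(c.status == "Passenger" for c in calls_no_sv)

    def test_deterministic_rerun(self, bundle7):
        import io as _io

        from fusiontriage import write_driver_report

        bufs = []
        for _ in range(2):
            buf = _io.StringIO()
            write_driver_report(bundle7.classify(), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_sample_scoping_excludes_other_samples(self, tiny_genes):
        fusion = _fusion(sample="T1")
        sv = [SVCall("OTHER", "1", 1_010_000, "+", "9", 5_000_000, "-", "translocation")]
        cnv = [CNVSegment("OTHER", "1", 1_000_000, 1_050_000, "1", 0.9)]
        (call,) = classify_all(
            [fusion], sv, cnv, tiny_genes, compute_correlation=False
        )
        assert call.status == "Passenger"
        (pooled,) = classify_all(
            [fusion], sv, cnv, tiny_genes,
            cfg=TriageConfig(sample_scoped=False), compute_correlation=False,
        )
        assert pooled.status == "Driver"

    @pytest.mark.parametrize("rule", ["either", "both", "linked"])
    def test_matches_bruteforce_classifier(self, rule):
        from conftest import random_instance

        for seed in range(10):
            fusions, sv, cnv, genes = random_instance(seed)
            cfg = TriageConfig(sv_rule=rule)
            calls = classify_all(
                fusions, sv, cnv, genes, cfg=cfg, compute_correlation=False
            )
            expected = brute_classify(fusions, sv, cnv, genes, cfg)
            for call, want in zip(calls, expected):
                sv_ids, cnv_ids = hits_as_ids(call, sv, cnv)
                assert call.status == want["status"]
                assert sv_ids == want["sv_hits"]
                assert cnv_ids == want["cnv_hits"]


class TestMonotonicity:
    def test_padding_never_demotes(self, bundle7):
        base = {
            c.fusion.fusion_id: c.status
            for c in bundle7.classify(TriageConfig(padding_bp=50_000))
        }
        wide = {
            c.fusion.fusion_id: c.status
            for c in bundle7.classify(TriageConfig(padding_bp=200_000))
        }
        for fid, status in base.items():
            if status == "Driver":
                assert wide[fid] == "Driver"

    def test_threshold_never_promotes(self, bundle7):
        base = {
            c.fusion.fusion_id: c.status
            for c in bundle7.classify(TriageConfig(cnv_abs_threshold=0.2))
        }
        strict = {
            c.fusion.fusion_id: c.status
            for c in bundle7.classify(TriageConfig(cnv_abs_threshold=0.6))
        }
        for fid, status in base.items():
            if status == "Passenger":
                assert strict[fid] == "Passenger"
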