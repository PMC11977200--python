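"""Generators: determinism, conservation, zero-noise adjointness, and
ground-truth recovery by the callers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import karyomorph as km
from karyomorph import morphometrics as mm
from karyomorph import rearrangements as ra
from karyomorph import simulate
from karyomorph.types import (
    ConfigError,
    FishSignal,
    KaryotypeTemplate,
    MarkerLocus,
    MarkerMap,
    ScenarioError,
    SimulationConfig,
    TemplateRow,
)


def random_template(rng: np.random.Generator, n_types: int = 6) -> KaryotypeTemplate:
    l = rng.uniform(1.0, 5.0, size=n_types)
    l = l / (2 * l.sum()) * 100.0
    rows = [
        TemplateRow(
            type_label=f"{k + 1}L",
            l_pct_median=float(l[k]),
            i_median=float(rng.uniform(5.0, 50.0)),
            category="m",
        )
        for k in range(n_types)
    ]
    return KaryotypeTemplate(rows=rows, ploidy_copies=2)


class TestGenerateMetaphases:
    def test_same_seed_reproduces_byte_identical_tables(self, template, tmp_path):
        cfg = SimulationConfig(template=template, seed=5, n_metaphases=3)
        rec1, truth1 = simulate.generate_metaphases(cfg)
        rec2, truth2 = simulate.generate_metaphases(cfg)
        assert rec1 == rec2
        assert truth1.equals(truth2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        km.io.write_measurements(rec1, p1)
        km.io.write_measurements(rec2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self, template):
        cfg1 = SimulationConfig(template=template, seed=1, n_metaphases=1)
        cfg2 = SimulationConfig(template=template, seed=2, n_metaphases=1)
        assert simulate.generate_metaphases(cfg1)[0] != simulate.generate_metaphases(cfg2)[0]

    def test_truth_l_fractions_sum_to_100(self, template):
        cfg = SimulationConfig(template=template, seed=1, n_metaphases=2)
        _, truth = simulate.generate_metaphases(cfg)
        for _, g in truth.groupby("metaphase_id"):
            total = (g["p_true"] + g["q_true"]).sum()
            l_pct = 100 * (g["p_true"] + g["q_true"]) / total
            assert l_pct.sum() == pytest.approx(100.0, abs=1e-9)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_zero_noise_pipeline_inverts_generator(self, seed):
        # generator and measurement pipeline are adjoint at zero noise
        rng = np.random.default_rng(seed)
        tpl = random_template(rng)
        cfg = SimulationConfig(
            template=tpl, seed=seed, n_metaphases=1,
            scale_cv=0, arm_noise_cv=0, chromatid_noise_cv=0,
        )
        records, truth = simulate.generate_metaphases(cfg)
        metrics = mm.metaphase_metrics(records)
        labels = {
            (r.metaphase_id, r.object_id): r.type_label for r in truth.itertuples()
        }
        by_type = {}
        for m in metrics:
            by_type.setdefault(labels[(m.metaphase_id, m.object_id)], []).append(m)
        for row in tpl.rows:
            for m in by_type[row.type_label]:
                assert m.l_pct == pytest.approx(row.l_pct_median, abs=1e-9)
                assert m.i == pytest.approx(row.i_median, abs=1e-9)

    def test_invalid_template_index_rejected(self):
        tpl = KaryotypeTemplate(
            rows=[TemplateRow("1L", 50.0, 60.0, "m")], ploidy_copies=2
        )
        with pytest.raises(ConfigError):
            SimulationConfig(template=tpl)


class TestMarkerScenarios:
    def test_empty_scenario_duplicates_reference(self, reference_map):
        target, truth = km.generate_marker_scenario(reference_map, [])
        assert truth == []
        assert len(target.loci) == 2 * len(reference_map.loci)
        assert {l.chromosome for l in target.loci} == {
            "2L", "2S", "9L", "9S", "10L", "10S"
        }

    def test_fusion_scenario_reproduces_study_arm_pattern(self, reference_map):
        target, truth = km.generate_marker_scenario(
            reference_map, [km.Fuse("9", "q", "10", "q", retained="10")]
        )
        by_gene = {
            (l.gene, l.chromosome[-1]): l for l in target.loci
        }
        for gene in ("fn1", "ndufs1", "sf3b1", "nomo3"):
            assert by_gene[(gene, "L")].arm == "q"
        assert by_gene[("bmp7", "L")].arm == "p"
        # q-arm order from the centromere: retained 10q block, then the
        # lost chromosome's q genes reversed, then its p genes
        q_order = sorted(
            (l for l in target.loci if l.chromosome == "9_10L" and l.arm == "q"),
            key=lambda l: l.rank,
        )
        assert [l.gene for l in q_order] == ["sox9", "fn1", "ndufs1", "sf3b1", "nomo3"]

    def test_inversion_scenario_moves_pericentromeric_block(self, reference_map):
        target, _ = km.generate_marker_scenario(
            reference_map, [km.Invert("2", p_depth=2, q_depth=0, copy="S")]
        )
        arms = {
            (l.gene, l.chromosome): l.arm for l in target.loci
            if l.gene in ("cept1", "gyg2")
        }
        assert arms[("cept1", "2L")] == "p" and arms[("cept1", "2S")] == "q"
        assert arms[("gyg2", "2L")] == "p" and arms[("gyg2", "2S")] == "q"

    def test_unknown_gene_raises(self, reference_map):
        with pytest.raises(ScenarioError):
            km.generate_marker_scenario(
                reference_map, [km.Translocate("nope", "2")]
            )

    def test_detectors_recover_single_spec_scenarios(self, reference_map):
        groups = ra.build_synteny_groups(reference_map)
        target, truth = km.generate_marker_scenario(
            reference_map,
            [km.Translocate("sf3b1", "2", copy="S")],
        )
        calls = [
            c for c in ra.detect_translocation(groups, target)
            if c.kind == "translocation"
        ]
        assert len(calls) == 1
        assert calls[0].genes == ("sf3b1",) and calls[0].copy == "S"


@pytest.fixture(scope="module")
def dense_reference():
    # synthetic reference with markers on both arms of every chromosome,
    # so fusion orientation is always identifiable
    loci = []
    for chrom in "1234":
        for arm in "pq":
            for r in (1, 2):
                loci.append(MarkerLocus("ref", f"g{chrom}{arm}{r}", chrom, arm, r))
    return MarkerMap("ref", loci, role="reference")


class TestScenarioSweep:
    """Noise-free generator scenarios are exactly recovered by the callers."""

    def test_all_fusion_orientations_recovered(self, dense_reference):
        groups = ra.build_synteny_groups(dense_reference)
        for arm_a in "pq":
            for arm_b in "pq":
                for retained in ("1", "2"):
                    spec = km.Fuse("1", arm_a, "2", arm_b, retained=retained)
                    target, truth = km.generate_marker_scenario(
                        dense_reference, [spec], copy_tags=("L",)
                    )
                    calls = [
                        c for c in ra.detect_fusion(groups, target)
                        if c.kind == "fusion"
                    ]
                    assert len(calls) == 1, (arm_a, arm_b, retained)
                    call = calls[0]
                    expect = truth[0]
                    assert call.details["centromere_lost"] == expect["centromere_lost"]
                    assert (
                        call.details["centromere_retained"]
                        == expect["centromere_retained"]
                    )
                    assert call.details["fused_arms"] == expect["fused_arms"]
                    assert call.conflicts == ()

    def test_random_scenario_sweep(self, dense_reference):
        rng = np.random.default_rng(1)
        groups = ra.build_synteny_groups(dense_reference)
        genes = sorted(dense_reference.genes)
        chroms = ["1", "2", "3", "4"]
        for trial in range(500):
            kind = rng.integers(0, 3)
            copy = rng.choice(["L", "S"])
            if kind == 0:
                gene = genes[rng.integers(len(genes))]
                src = gene[1]
                dest = chroms[rng.integers(len(chroms))]
                if dest == src:
                    continue
                spec = km.Translocate(gene, dest, copy=copy)
                target, _ = km.generate_marker_scenario(dense_reference, [spec])
                calls = [
                    c for c in ra.detect_translocation(groups, target)
                    if c.kind == "translocation"
                ]
                assert len(calls) == 1, (trial, spec)
                assert calls[0].genes == (gene,)
                assert calls[0].copy == copy
                assert calls[0].reference_chromosomes == (src, dest)
            elif kind == 1:
                a, b = rng.choice(chroms, size=2, replace=False)
                arm_a, arm_b = rng.choice(["p", "q"], size=2)
                retained = a if rng.random() < 0.5 else b
                spec = km.Fuse(a, arm_a, b, arm_b, retained=retained, copy=copy)
                target, truth = km.generate_marker_scenario(dense_reference, [spec])
                calls = [
                    c for c in ra.detect_fusion(groups, target)
                    if c.kind == "fusion"
                ]
                assert len(calls) == 1, (trial, spec)
                call = calls[0]
                assert call.copy == copy
                assert call.details["centromere_lost"] == truth[0]["centromere_lost"]
                assert call.details["fused_arms"] == truth[0]["fused_arms"]
                assert call.conflicts == ()
            else:
                chrom = chroms[rng.integers(len(chroms))]
                spec = km.Invert(chrom, p_depth=2, q_depth=0, copy=copy)
                target, _ = km.generate_marker_scenario(dense_reference, [spec])
                calls = [
                    c for c in ra.detect_inversion(target, dense_reference)
                    if c.kind == "inversion"
                ]
                assert len(calls) == 1, (trial, spec)
                assert calls[0].target_chromosome == f"{chrom}{copy}"
                assert calls[0].details["inversion_type"] == "pericentromeric"

    def test_no_rearrangement_gives_no_calls(self, dense_reference):
        groups = ra.build_synteny_groups(dense_reference)
        target, _ = km.generate_marker_scenario(dense_reference, [])
        assert all(
            c.kind == "none" for c in ra.detect_translocation(groups, target)
        )
        assert all(c.kind == "none" for c in ra.detect_fusion(groups, target))
        assert all(
            c.kind == "none" for c in ra.detect_inversion(target, dense_reference)
        )


class TestGenerateSignals:
    def test_zero_dropout_is_identity(self, template, rdna_signals):
        out = simulate.generate_signals(template, rdna_signals, dropout_prob=0.0)
        assert out == list(rdna_signals)
        assert ra.summarize_rdna(out, template).nor_count == 1

    def test_full_dropout_is_empty(self, template, rdna_signals):
        assert simulate.generate_signals(template, rdna_signals, 1.0, seed=1) == []

    def test_dropout_rate_within_binomial_ci(self, template, rdna_signals):
        n_rows = len(rdna_signals)
        kept = sum(
            len(simulate.generate_signals(template, rdna_signals, 0.1, seed=s))
            for s in range(1000)
        )
        total = 1000 * n_rows
        lo, hi = sps.binom.interval(0.99, total, 0.9)
        assert lo <= kept <= hi

    def test_unknown_placement_rejected(self, template):
        with pytest.raises(ScenarioError):
            simulate.generate_signals(
                template, [FishSignal("5S", "99X", "q", "telomeric")], 0.0
            )


class TestParameterRecovery:
    def test_medians_recovered_within_two_percent(self, template):
        cfg = SimulationConfig(
            template=template, seed=1, n_metaphases=200, arm_noise_cv=0.05
        )
        records, _ = km.generate_metaphases(cfg)
        consensus, _, _ = km.analyze_karyotype(records, template)
        tn = simulate.normalized_template(template)
        for row in tn.rows:
            l_hat = consensus.summary.get(row.type_label, "l_pct").q2
            i_hat = consensus.summary.get(row.type_label, "i").q2
            assert abs(l_hat - row.l_pct_median) / row.l_pct_median <= 0.02
            assert abs(i_hat - row.i_median) / row.i_median <= 0.02
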