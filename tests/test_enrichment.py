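"""The four-stage filtration: fold changes, tail calling, the paired-t
volcano, annotation and back-mapping filters, and whole-pipeline
properties.  Statistical results are checked against independent oracles
(exact hypergeometric enumeration, scipy's one-sample t, a hand-written
Benjamini-Hochberg step-up)."""

import json
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from proxiglyc.enrichment import (
    PipelineConfig,
    TailAssessment,
    annotation_filter,
    assess_tail,
    backmap_filter,
    compute_log2fc,
    paired_t_volcano,
    run_pipeline,
    select_significant,
)
from proxiglyc.errors import (
    ConfigurationError,
    InsufficientDataError,
    PipelineError,
)
from proxiglyc.synthetic import SimConfig, generate_experiment
from proxiglyc.tables_io import (
    AnnotationRecord,
    Bait,
    CCClass,
    Multimer,
    ProteinQuantRecord,
    ProteinQuantTable,
    SampleDesign,
    read_table1_fixture,
)

DESIGN_1 = [
    SampleDesign("b1", "d1", Bait.ACTIVE_SN, Multimer.IN_SOLUTION, 1),
    SampleDesign("c1", "d1", Bait.CONTROL_R97A, Multimer.IN_SOLUTION, 1),
]


def quant_of(rows, sample_ids):
    """rows: list of (protein_id, {sample: intensity-or-None})."""
    return ProteinQuantTable(
        records=[
            ProteinQuantRecord(protein_id=pid, intensity_by_sample=dict(cells))
            for pid, cells in rows
        ],
        sample_ids=list(sample_ids),
    )


class TestComputeLog2fc:
    def test_exact_ratios(self):
        quant = quant_of(
            [
                ("P1", {"b1": 8e6, "c1": 1e6}),
                ("P2", {"b1": 5e5, "c1": 5e5}),
            ],
            ["b1", "c1"],
        )
        fc = compute_log2fc(quant, DESIGN_1)
        assert fc.log2fc.at["P1", "d1"] == pytest.approx(3.0, abs=1e-12)
        assert fc.log2fc.at["P2", "d1"] == pytest.approx(0.0, abs=1e-12)
        assert not fc.imputed.at["P1", "d1"]

    def test_noise_floor_imputation_of_missing_control(self):
        # floor at percentile 0 = the smallest quantified control intensity
        quant = quant_of(
            [
                ("P1", {"b1": 1e6, "c1": None}),
                ("P2", {"b1": 2e4, "c1": 1e4}),
                ("P3", {"b1": 3e5, "c1": 8e5}),
            ],
            ["b1", "c1"],
        )
        cfg = PipelineConfig(noise_floor_percentile=0.0)
        fc = compute_log2fc(quant, DESIGN_1, cfg)
        assert fc.log2fc.at["P1", "d1"] == pytest.approx(math.log2(1e6 / 1e4))
        assert fc.log2fc.at["P1", "d1"] == pytest.approx(6.644, abs=1e-3)
        assert fc.imputed.at["P1", "d1"]

    def test_missing_both_sides_gives_no_entry(self):
        quant = quant_of(
            [("P1", {"b1": None, "c1": None}), ("P2", {"b1": 1e5, "c1": 1e5})],
            ["b1", "c1"],
        )
        fc = compute_log2fc(quant, DESIGN_1)
        assert np.isnan(fc.log2fc.at["P1", "d1"])

    def test_dataset_missing_sample_is_configuration_error(self):
        quant = quant_of([("P1", {"b1": 1.0})], ["b1"])
        with pytest.raises(ConfigurationError):
            compute_log2fc(quant, DESIGN_1)


def _exact_hypergeom_tail(k, M, K, n):
    """P(X >= k) for X ~ Hypergeom(M, K, n) by exact enumeration."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(M - K, n - j), math.comb(M, n))
    return float(total)


def _membrane_ann(ids_membrane, ids_other):
    return [
        AnnotationRecord(pid, CCClass.MEMBRANE, True, 2, 1) for pid in ids_membrane
    ] + [AnnotationRecord(pid, CCClass.CYTOPLASM, False, 0, 0) for pid in ids_other]


class TestAssessTail:
    def _fc_table(self, values_by_protein, dataset="d1"):
        import pandas as pd

        index = pd.Index(list(values_by_protein), name="protein_id")
        fc = pd.DataFrame({dataset: list(values_by_protein.values())}, index=index)
        imp = pd.DataFrame(False, index=index, columns=[dataset])
        from proxiglyc.enrichment import Log2FcTable

        return Log2FcTable(log2fc=fc, imputed=imp)

    def test_identical_distributions_have_no_tail(self):
        # ties at the cutoff are not counted above it (strict > rule)
        values = {f"M{i}": 1.0 for i in range(30)} | {f"O{i}": 1.0 for i in range(30)}
        fc = self._fc_table(values)
        ann = _membrane_ann([f"M{i}" for i in range(30)], [f"O{i}" for i in range(30)])
        out = assess_tail(fc, ann, "d1")
        assert out.n_above_cutoff_membrane == 0
        assert not out.has_tail

    def test_spiked_membrane_tail_detected(self, default_experiment):
        quant, design, ann, truth = default_experiment
        fc = compute_log2fc(quant, design)
        out = assess_tail(fc, ann, fc.datasets()[0])
        assert out.has_tail
        assert out.n_above_cutoff_membrane >= 20
        # hypergeometric p agrees with exact combinatorial summation
        col = fc.log2fc[out.dataset_id].dropna()
        M = len(col)
        membrane = {a.protein_id for a in ann if a.cc_class is CCClass.MEMBRANE}
        K = sum(1 for pid in col.index if pid in membrane)
        n = out.n_above_cutoff_membrane + out.n_above_cutoff_other
        expected = _exact_hypergeom_tail(out.n_above_cutoff_membrane, M, K, n)
        assert out.enrichment_p == pytest.approx(expected, rel=1e-9)

    def test_urn_example_matches_enumeration(self):
        # 100 proteins, 20 membrane; 30 above cutoff of which 10 membrane
        rng = np.random.default_rng(0)
        membrane_ids = [f"M{i}" for i in range(20)]
        other_ids = [f"O{i}" for i in range(80)]
        values = {}
        for i, pid in enumerate(membrane_ids):
            values[pid] = 10.0 if i < 10 else -abs(rng.normal())
        high_other = 30 - 10
        for i, pid in enumerate(other_ids):
            values[pid] = 10.0 if i < high_other else -abs(rng.normal())
        fc = self._fc_table(values)
        ann = _membrane_ann(membrane_ids, other_ids)
        # place the cutoff below the 10.0 spike cluster: 99th pct of the 80
        # non-membrane values lies among them because 20 are at 10.0
        out = assess_tail(fc, ann, "d1", PipelineConfig(tail_quantile=0.7))
        k, n = out.n_above_cutoff_membrane, (
            out.n_above_cutoff_membrane + out.n_above_cutoff_other
        )
        expected = _exact_hypergeom_tail(k, 100, 20, n)
        assert out.enrichment_p == pytest.approx(expected, rel=1e-9)

    def test_insufficient_data(self):
        fc = self._fc_table({f"P{i}": 0.1 for i in range(10)})
        ann = _membrane_ann([f"P{i}" for i in range(5)], [f"P{i}" for i in range(5, 10)])
        with pytest.raises(InsufficientDataError):
            assess_tail(fc, ann, "d1")


def test_hypergeometric_tail_matches_enumeration_for_small_populations():
    """scipy's survival function equals exact combinatorial summation for
    every urn with population size <= 60 (subsampled grid) — the
    enrichment p is exactly the classical tail probability."""
    rng = np.random.default_rng(42)
    checked = 0
    for M in range(2, 61):
        for _ in range(12):
            K = int(rng.integers(1, M + 1))
            n = int(rng.integers(1, M + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            exact = _exact_hypergeom_tail(k, M, K, n)
            sf = float(stats.hypergeom.sf(k - 1, M, K, n))
            assert sf == pytest.approx(exact, rel=1e-9, abs=1e-12)
            checked += 1
    assert checked >= 700


class TestPairedTVolcano:
    def _fc(self, vectors):
        """vectors: protein -> list of per-dataset log2fc (None = absent)."""
        import pandas as pd

        from proxiglyc.enrichment import Log2FcTable

        n_ds = max(len(v) for v in vectors.values())
        cols = [f"d{j}" for j in range(n_ds)]
        data = {
            pid: [v[j] if j < len(v) and v[j] is not None else np.nan for j in range(n_ds)]
            for pid, v in vectors.items()
        }
        fc = pd.DataFrame.from_dict(data, orient="index", columns=cols)
        fc.index.name = "protein_id"
        return Log2FcTable(log2fc=fc, imputed=fc.isna())

    def test_zero_mean_vector(self):
        rows = paired_t_volcano(self._fc({"P1": [1.0, -1.0, 0.0]}), ["d0", "d1", "d2"])
        assert rows[0].t_stat == pytest.approx(0.0)
        assert rows[0].p_value == pytest.approx(1.0)

    def test_textbook_example(self):
        rows = paired_t_volcano(self._fc({"P1": [2.0, 3.0, 4.0]}), ["d0", "d1", "d2"])
        assert rows[0].t_stat == pytest.approx(3.0 / (1.0 / math.sqrt(3)), rel=1e-12)
        # independent oracle: two-sided p from the t CDF with df = 2
        expected_p = 2 * (1 - stats.t.cdf(rows[0].t_stat, df=2))
        assert rows[0].p_value == pytest.approx(expected_p, rel=1e-12)
        assert rows[0].p_value == pytest.approx(0.0351, abs=2e-4)

    def test_degenerate_zero_variance(self):
        rows = paired_t_volcano(self._fc({"P1": [2.0, 2.0, 2.0]}), ["d0", "d1", "d2"])
        assert rows[0].degenerate
        assert 0.0 < rows[0].p_value < 1e-300

    def test_skips_proteins_with_single_observation(self):
        rows = paired_t_volcano(
            self._fc({"P1": [1.0, None, None], "P2": [1.0, 2.0, None]}),
            ["d0", "d1", "d2"],
        )
        assert [r.protein_id for r in rows] == ["P2"]
        assert rows[0].n_pairs == 2

    def test_bh_step_up_example(self):
        rows = paired_t_volcano(
            self._fc(
                {
                    # means/sds chosen freely; p values then overridden below
                    "P1": [1.0, 1.1],
                    "P2": [1.0, 1.2],
                    "P3": [1.0, 1.3],
                    "P4": [1.0, 1.4],
                }
            ),
            ["d0", "d1"],
        )
        # direct check of the step-up on the canonical worked example
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert list(q) == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert all(r.q_value >= r.p_value for r in rows)

    def test_agrees_with_scipy_on_random_vectors(self):
        """t and p match an independent one-sample t implementation to
        1e-10 / 1e-8 on 1000 random vectors."""
        rng = np.random.default_rng(123)
        vectors = {}
        for i in range(1000):
            n = int(rng.integers(2, 7))
            vectors[f"P{i}"] = list(rng.normal(0, 1.5, n)) + [None] * (6 - n)
        rows = paired_t_volcano(self._fc(vectors), [f"d{j}" for j in range(6)])
        assert len(rows) == 1000
        for row in rows:
            x = [v for v in vectors[row.protein_id] if v is not None]
            ref = stats.ttest_1samp(x, 0.0)
            assert row.t_stat == pytest.approx(ref.statistic, abs=1e-10)
            assert row.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_bh_matches_hand_step_up_on_random_pvalues(self):
        rng = np.random.default_rng(7)
        vectors = {
            f"P{i}": list(rng.normal(rng.normal(0, 1), 0.5, 4)) for i in range(200)
        }
        rows = paired_t_volcano(self._fc(vectors), [f"d{j}" for j in range(4)])
        p = np.array([r.p_value for r in rows])
        # hand step-up: q_(i) = min over j>=i of p_(j) * m / j
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        q_hand = np.empty(m)
        q_hand[order] = np.minimum(q_sorted, 1.0)
        got = np.array([r.q_value for r in rows])
        assert got == pytest.approx(q_hand, abs=1e-12)


class TestSelection:
    def test_positive_side_only(self):
        from proxiglyc.enrichment import VolcanoRow

        up = VolcanoRow("P1", 2.0, 5.0, 0.01, 0.02, 3)
        down = VolcanoRow("P2", -2.0, -5.0, 0.01, 0.02, 3)
        assert select_significant([up, down]) == {"P1"}

    def test_default_thresholds_keep_all_published_rows(self):
        from proxiglyc.enrichment import VolcanoRow

        rows = [
            VolcanoRow(r.gene_name, r.log2_fold_change, 0.0, r.p_value, r.p_value, 5)
            for r in read_table1_fixture()
        ]
        assert len(select_significant(rows)) == 49


class TestAnnotationFilter:
    ANN = [
        AnnotationRecord("P1", CCClass.MEMBRANE, True, 4, 1),
        AnnotationRecord("P2", CCClass.MEMBRANE, True, 0, 1),
        AnnotationRecord("P3", CCClass.MEMBRANE, False, 3, 0),
        AnnotationRecord("P4", CCClass.CYTOPLASM, False, 2, 0),
    ]

    def test_rules(self):
        assert annotation_filter({"P1", "P2", "P3", "P4", "P5"}, self.ANN) == {"P1"}

    def test_matches_set_comprehension_oracle(self, small_experiment):
        _, _, ann, _ = small_experiment
        rng = np.random.default_rng(5)
        ids = [a.protein_id for a in ann]
        for _ in range(20):
            candidates = set(rng.choice(ids, size=40, replace=False))
            expected = {
                a.protein_id
                for a in ann
                if a.protein_id in candidates
                and a.n_sequons >= 1
                and a.plasma_membrane
            }
            assert annotation_filter(candidates, ann) == expected


def _tail(ds, backmap_cutoff):
    return TailAssessment(
        dataset_id=ds,
        cutoff=backmap_cutoff + 1.0,
        backmap_cutoff=backmap_cutoff,
        n_above_cutoff_membrane=30,
        n_above_cutoff_other=1,
        enrichment_p=1e-6,
        has_tail=True,
    )


class TestBackmapFilter:
    def _fc(self, matrix, datasets):
        import pandas as pd

        from proxiglyc.enrichment import Log2FcTable

        fc = pd.DataFrame(matrix, columns=datasets)
        fc.index = pd.Index([f"P{i}" for i in range(len(fc))], name="protein_id")
        return Log2FcTable(log2fc=fc, imputed=fc.notna() & False)

    def test_above_everywhere_retained_below_once_removed(self):
        datasets = [f"d{i}" for i in range(5)]
        fc = self._fc(
            [[2.0] * 5, [2.0, 2.0, 2.0, 2.0, 0.1]],
            datasets,
        )
        tails = [_tail(d, 1.0) for d in datasets]
        assert backmap_filter({"P0", "P1"}, fc, tails) == {"P0"}

    def test_boundary_value_is_retained(self):
        fc = self._fc([[1.0, 1.0]], ["d0", "d1"])
        assert backmap_filter({"P0"}, fc, [_tail("d0", 1.0), _tail("d1", 1.0)]) == {"P0"}

    def test_absent_datasets_not_judged_by_default(self):
        fc = self._fc([[2.0, np.nan]], ["d0", "d1"])
        tails = [_tail("d0", 1.0), _tail("d1", 1.0)]
        assert backmap_filter({"P0"}, fc, tails) == {"P0"}
        strict = PipelineConfig(backmap_require_all_datasets=True)
        assert backmap_filter({"P0"}, fc, tails, strict) == set()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        datasets = [f"d{i}" for i in range(4)]
        matrix = rng.normal(1.0, 1.0, size=(50, 4))
        matrix[rng.random((50, 4)) < 0.2] = np.nan
        fc = self._fc(matrix, datasets)
        tails = [_tail(d, float(c)) for d, c in zip(datasets, rng.normal(0.8, 0.2, 4))]
        for _ in range(10):
            candidates = {f"P{i}" for i in rng.integers(0, 50, size=20)}
            expected = {
                pid
                for pid in candidates
                if all(
                    np.isnan(fc.log2fc.at[pid, t.dataset_id])
                    or fc.log2fc.at[pid, t.dataset_id] >= t.backmap_cutoff
                    for t in tails
                )
            }
            assert backmap_filter(candidates, fc, tails) == expected

    def test_dropping_a_dataset_never_shrinks_the_backmap_set(self):
        """Back-mapping is a conjunction over datasets, so removing one can
        only relax it (candidates held fixed)."""
        rng = np.random.default_rng(3)
        datasets = [f"d{i}" for i in range(5)]
        fc = self._fc(rng.normal(1.0, 1.0, size=(60, 5)), datasets)
        tails = [_tail(d, 0.8) for d in datasets]
        candidates = {f"P{i}" for i in range(60)}
        full = backmap_filter(candidates, fc, tails)
        for drop in range(5):
            subset = backmap_filter(
                candidates, fc, tails[:drop] + tails[drop + 1 :]
            )
            assert full <= subset


class TestRunPipeline:
    def test_stage_sets_nest(self, default_experiment):
        quant, design, ann, _ = default_experiment
        report = run_pipeline(quant, design, ann)
        assert report.final_set <= report.stage_sets["annotated"]
        assert report.stage_sets["annotated"] <= report.stage_sets["significant"]

    def test_audit_gives_exactly_one_reason_per_excluded_protein(
        self, default_experiment
    ):
        quant, design, ann, _ = default_experiment
        report = run_pipeline(quant, design, ann)
        excluded = set(quant.protein_ids()) - report.final_set
        assert set(report.audit) == excluded
        assert all(
            set(v) == {"stage", "reason"} for v in report.audit.values()
        )

    def test_deterministic_byte_identical_reports(self, small_experiment):
        quant, design, ann, _ = small_experiment
        a = run_pipeline(quant, design, ann).to_dict()
        b = run_pipeline(quant, design, ann).to_dict()
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_degraded_dataset_excluded_and_final_set_unchanged(self):
        cfg = SimConfig(seed=21, degraded_datasets=("on_bead_r3",))
        quant, design, ann, _ = generate_experiment(cfg)
        report = run_pipeline(quant, design, ann)
        assert "on_bead_r3" not in report.retained_datasets

        # rerun without the degraded dataset's samples at all
        keep = [s for s in design if s.dataset_id != "on_bead_r3"]
        keep_ids = {s.sample_id for s in keep}
        trimmed = ProteinQuantTable(
            records=[
                ProteinQuantRecord(
                    protein_id=r.protein_id,
                    gene_name=r.gene_name,
                    molecular_weight_kda=r.molecular_weight_kda,
                    intensity_by_sample={
                        k: v for k, v in r.intensity_by_sample.items() if k in keep_ids
                    },
                )
                for r in quant.records
            ],
            sample_ids=[s for s in quant.sample_ids if s in keep_ids],
        )
        report2 = run_pipeline(trimmed, keep, ann)
        assert report.final_set == report2.final_set

    def test_all_noise_experiment_fails_with_no_retained_datasets(self):
        quant, design, ann, _ = generate_experiment(SimConfig(n_spiked=0, seed=2))
        with pytest.raises(PipelineError, match="NO_RETAINED_DATASETS"):
            run_pipeline(quant, design, ann)
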