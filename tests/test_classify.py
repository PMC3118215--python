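import itertools

import numpy as np
import pytest

from dmrscan import (
    AdjustmentModel,
    ConsensusPeak,
    GenomicInterval,
    PipelineConfig,
    Probe,
    ProbeLayout,
    RawPeak,
    STAGES,
    TISSUES,
    classify_dsdmr,
    classify_tdmr,
    cross_tissue_overlap,
    partition_regions,
    pattern_name,
    tabulate,
    union,
)
from dmrscan.simulate import fixture_from_counts
from conftest import per_base_mask


def dense_layout(size=10_000, chrom="chr1"):
    """One probe per base so no partition atom is ever probe-empty."""
    return ProbeLayout(
        Probe(f"d{i}", GenomicInterval(chrom, i, i + 1)) for i in range(size)
    )


def cons(tissue, stage, *spans, chrom="chr1"):
    return [
        ConsensusPeak(GenomicInterval(chrom, s, e), tissue, stage, e - s)
        for s, e in spans
    ]


def raw(*spans, chrom="chr1"):
    return [
        RawPeak(GenomicInterval(chrom, s, e), "r", 2, 3.0, 3.0) for s, e in spans
    ]


class TestPartitionRegions:
    def setup_method(self):
        self.layout = dense_layout()
        self.cfg = PipelineConfig(min_subpeak_probes=2)

    def test_hand_partition_two_samples(self):
        consensus = {
            "A": cons("A", "AD", (0, 1000)),
            "B": cons("B", "AD", (500, 1500)),
        }
        raws = {
            "A": (raw((0, 1000)), raw((0, 1000))),
            "B": (raw((500, 1500)), raw((500, 1500))),
        }
        recs = partition_regions(consensus, raws, self.layout, self.cfg)
        got = {
            (r.interval.start, r.interval.end): set(r.pattern.present) for r in recs
        }
        assert got == {
            (0, 500): {"A"},
            (500, 1000): {"A", "B"},
            (1000, 1500): {"B"},
        }

    def test_single_sample_atoms_equal_consensus(self):
        consensus = {"A": cons("A", "AD", (100, 400), (2000, 2600))}
        raws = {"A": (raw((100, 400), (2000, 2600)),) * 2}
        recs = partition_regions(consensus, raws, self.layout, self.cfg)
        assert [(r.interval.start, r.interval.end) for r in recs] == [
            (100, 400),
            (2000, 2600),
        ]

    def test_single_replicate_raw_peak_makes_sample_ambiguous(self):
        consensus = {"A": cons("A", "AD", (0, 1000)), "B": []}
        raws = {
            "A": (raw((0, 1000)), raw((0, 1000))),
            "B": (raw((300, 600)), []),  # one replicate only, no consensus
        }
        (rec,) = partition_regions(consensus, raws, self.layout, self.cfg)
        assert rec.pattern.present == {"A"}
        assert rec.pattern.ambiguous == {"B"}
        assert rec.flagged
        # flagged records are excluded from headline tabulation
        table = tabulate(classify_tdmr([rec], ("A", "B")), "tdmr")
        assert table.total("all") == 0

    def test_absent_requires_no_raw_overlap(self):
        consensus = {"A": cons("A", "AD", (0, 1000)), "B": []}
        raws = {"A": (raw((0, 1000)), raw((0, 1000))), "B": ([], [])}
        (rec,) = partition_regions(consensus, raws, self.layout, self.cfg)
        assert rec.pattern.absent == {"B"} and not rec.flagged

    def test_adjacent_atoms_with_same_pattern_merge(self):
        # two abutting consensus peaks of the same sample yield one record
        consensus = {"A": cons("A", "AD", (0, 300), (300, 700))}
        raws = {"A": (raw((0, 300), (300, 700)),) * 2}
        recs = partition_regions(consensus, raws, self.layout, self.cfg)
        assert [(r.interval.start, r.interval.end) for r in recs] == [(0, 700)]

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_against_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        size = 10_000
        layout = dense_layout(size)
        cfg = PipelineConfig(min_subpeak_probes=1)
        consensus, raws = {}, {}
        for lab in "ABC":
            spans = []
            pos = 0
            while pos < size - 600:
                pos += int(rng.integers(50, 800))
                end = min(pos + int(rng.integers(30, 500)), size)
                if end > pos:
                    spans.append((pos, end))
                pos = end + 10
            consensus[lab] = cons(lab, "AD", *spans)
            raws[lab] = (raw(*spans), raw(*spans))
        recs = partition_regions(consensus, raws, layout, cfg)
        atom_mask = per_base_mask([r.interval for r in recs], size)
        cons_mask = per_base_mask(
            [p.interval for peaks in consensus.values() for p in peaks], size
        )
        assert np.array_equal(atom_mask, cons_mask)

    def test_input_order_invariance(self):
        consensus = {
            "A": cons("A", "AD", (0, 900)),
            "B": cons("B", "AD", (400, 1300)),
            "C": cons("C", "AD", (800, 2000)),
        }
        raws = {k: (raw(*[(p.interval.start, p.interval.end) for p in v]),) * 2
                for k, v in consensus.items()}
        fwd = partition_regions(consensus, raws, self.layout, self.cfg,
                                universe=("A", "B", "C"))
        rev = partition_regions(
            dict(reversed(consensus.items())),
            dict(reversed(raws.items())),
            self.layout, self.cfg, universe=("A", "B", "C"),
        )
        assert [(r.interval, r.pattern.present) for r in fwd] == [
            (r.interval, r.pattern.present) for r in rev
        ]


def make_records(present_sets, universe):
    spec = {tuple(sorted(p, key=list(universe).index)): 1 for p in present_sets}
    return fixture_from_counts(spec, universe)


class TestClassification:
    def test_tdmr_classes(self):
        recs = make_records(
            [TISSUES, ("testis",), ("brain", "heart")], TISSUES
        )
        out = classify_tdmr(recs)
        assert [r.dmr_class for r in out] == ["common", "unique", "multi"]
        assert out[1].name == "Testis unique"
        assert out[2].name == "B + H"

    def test_dsdmr_classes_and_groups(self):
        recs = make_records(
            [STAGES, ("E15", "NB"), ("AD",), ("NB", "AD"), ("E15",)], STAGES
        )
        out = classify_dsdmr(recs)
        assert [r.stage_group for r in out] == [
            "common", "UnMe-AD", "Me-AD", "Me-AD", "UnMe-AD"
        ]
        assert out[1].name == "E15+NB"
        assert out[4].name == "E15_uniq"

    def test_pattern_exhaustiveness(self):
        # every non-empty presence subset maps to exactly one class;
        # differential classes number 2^k - 2
        for universe in (TISSUES, STAGES):
            k = len(universe)
            names = set()
            for r in range(1, k + 1):
                for combo in itertools.combinations(universe, r):
                    names.add(pattern_name(combo, universe,
                                           "tissue" if k == 4 else "stage"))
            assert len(names) == 2**k - 1
            differential = names - {"Common"}
            assert len(differential) == 2**k - 2  # 14 tissue / 6 stage patterns

    def test_classification_order_invariant(self):
        recs = make_records([("brain", "testis"), ("liver",)], TISSUES)
        a = classify_tdmr(recs)
        b = classify_tdmr(list(reversed(recs)))
        assert {r.interval: r.dmr_class for r in a} == {
            r.interval: r.dmr_class for r in b
        }


class TestCrossTissueOverlap:
    def test_disjoint_sets_all_unique(self):
        sets = {
            "brain": [GenomicInterval("chr1", 0, 100)],
            "liver": [GenomicInterval("chr1", 1000, 1100)],
        }
        rep = cross_tissue_overlap(sets)
        assert rep.unique_fraction == 1.0
        assert rep.n_multi_clusters == 0

    def test_identical_sets_one_cluster_per_region(self):
        ivs = [GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(5)]
        rep = cross_tissue_overlap({"brain": list(ivs), "liver": list(ivs)})
        assert rep.n_unique == 0
        assert rep.n_multi_clusters == 5
        assert rep.unique_fraction == 0.0

    def test_requires_two_tissues(self):
        with pytest.raises(ValueError):
            cross_tissue_overlap({"brain": []})


class TestAdjustCounts:
    def model(self, rs):
        return AdjustmentModel(r_pscore={"brain": rs})

    def test_equal_concordance_is_identity(self):
        m = self.model({"E15": 0.9, "NB": 0.9, "AD": 0.9})
        recs = classify_dsdmr(make_records([("E15",), ("NB", "AD")], STAGES))
        from dmrscan import adjust_counts

        table = tabulate(recs, "dsdmr", tissue="brain")
        adj = adjust_counts(table, m)
        for p in adj.pattern_sets():
            assert adj.adjusted[p] == adj.row(p)["total"]

    def test_single_stage_ratio(self):
        m = self.model({"E15": 0.75, "NB": 0.9, "AD": 0.9})
        assert m.factor("brain", "E15") == pytest.approx(0.9 / 0.75)
        # count 100 at r=0.75 vs best 0.9 -> 120
        assert round(100 * m.factor("brain", "E15")) == 120

    def test_multi_stage_geometric_mean(self):
        m = self.model({"E15": 1.0, "NB": 1.0 / 1.08, "AD": 1.0 / 1.30})
        f = m.combined_factor("brain", ("NB", "AD"))
        assert f == pytest.approx((1.08 * 1.30) ** 0.5)
        assert round(70 * f) == round(70 * (1.08 * 1.30) ** 0.5)

    def test_nonpositive_concordance_rejected(self):
        m = self.model({"E15": -0.1, "NB": 0.9, "AD": 0.9})
        with pytest.raises(ValueError):
            m.factor("brain", "E15")


class TestTabulate:
    def test_empty_input_all_zero(self):
        table = tabulate([], "tdmr")
        assert table.total("all") == 0
        assert table.total("common") == 0

    def test_row_percentages_sum_to_100(self):
        from _study_tables import tdmr_count_spec

        recs = classify_tdmr(fixture_from_counts(tdmr_count_spec(), TISSUES))
        df = tabulate(recs, "tdmr").to_frame()
        pct_cols = [c for c in df.columns if c.endswith("_pct")]
        sums = df[pct_cols].sum(axis=1)
        for label, s in sums.items():
            assert abs(s - 100.0) <= 0.2, label

    def test_unique_plus_multi_equals_grand_total(self):
        from _study_tables import tdmr_count_spec

        recs = classify_tdmr(fixture_from_counts(tdmr_count_spec(), TISSUES))
        t = tabulate(recs, "tdmr")
        assert t.total("unique") + t.total("multi") == t.total("all")
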