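"""PRO-seq quantification: RPM/density arithmetic, activity, pausing, fold-change."""

import numpy as np
import pandas as pd
import pytest

from pausedelta.genome_model import (GenomicInterval, SignalTrack,
                                     TranscriptionUnit, derive_regions)
from pausedelta.proseq_quant import (ReplicateTracks, call_active, fold_change,
                                     pause_index, quantify_regions)


def _tracks(plus_recs=(), minus_recs=()):
    plus = SignalTrack.from_records(plus_recs, "base_counts", strand="+") \
        if plus_recs else SignalTrack("base_counts", {}, strand="+")
    minus = SignalTrack.from_records(minus_recs, "base_counts", strand="-") \
        if minus_recs else SignalTrack("base_counts", {}, strand="-")
    return plus, minus


def _quant_frame(rows):
    df = pd.DataFrame(rows).set_index("unit_id")
    df["promoter_density"] = df["promoter_rpm"] / df["promoter_length"]
    df["body_density"] = np.where(df["body_length"] > 0,
                                  df["body_rpm"] / df["body_length"], np.nan)
    return df


class TestQuantifyRegions:
    def test_rpm_and_density_arithmetic(self):
        u = TranscriptionUnit("tu1", GenomicInterval("c", 1000, 5000, "+"))
        regions = derive_regions([u])
        # 50 reads inside the promoter window [900, 1100)
        plus, minus = _tracks(plus_recs=[("c", 1020, 1021, 50.0)])
        q = quantify_regions(plus, minus, regions, library_size=2_000_000)
        assert q.loc["tu1", "promoter_rpm"] == pytest.approx(25.0)
        assert q.loc["tu1", "promoter_density"] == pytest.approx(0.125)

    def test_counts_come_from_sense_strand_only(self):
        u = TranscriptionUnit("tu1", GenomicInterval("c", 1000, 5000, "-"))
        regions = derive_regions([u])
        plus, minus = _tracks(plus_recs=[("c", 4950, 4951, 10.0)])
        q = quantify_regions(plus, minus, regions, library_size=10.0)
        assert q.loc["tu1", "promoter_raw"] == 0

    def test_matches_per_base_loop_oracle(self):
        rng = np.random.default_rng(17)
        units, recs_p, recs_m = [], [], []
        pos = 0
        for i in range(50):
            pos += int(rng.integers(300, 800))
            length = int(rng.integers(400, 2000))
            strand = str(rng.choice(["+", "-"]))
            units.append(TranscriptionUnit(
                f"u{i}", GenomicInterval("c", pos, pos + length, strand)))
            pos += length
        for _ in range(3000):
            p = int(rng.integers(0, pos))
            (recs_p if rng.random() < 0.5 else recs_m).append(
                ("c", p, p + 1, float(rng.integers(1, 5))))
        # collapse duplicate positions
        def collapse(recs):
            agg = {}
            for _, s, e, v in recs:
                agg[s] = agg.get(s, 0) + v
            return [("c", s, s + 1, v) for s, v in agg.items()]
        recs_p, recs_m = collapse(recs_p), collapse(recs_m)
        plus, minus = _tracks(recs_p, recs_m)
        regions = derive_regions(units)
        lib = 1e6
        q = quantify_regions(plus, minus, regions, library_size=lib)

        base_p = {s: v for _, s, _, v in recs_p}
        base_m = {s: v for _, s, _, v in recs_m}
        for u in units:
            base = base_p if u.strand == "+" else base_m
            row = regions.table.loc[u.id]
            prom = sum(base.get(b, 0) for b in range(row.promoter_start, row.promoter_end))
            assert q.loc[u.id, "promoter_raw"] == pytest.approx(prom)
            if not row.body_empty:
                body = sum(base.get(b, 0) for b in range(row.body_start, row.body_end))
                assert q.loc[u.id, "body_raw"] == pytest.approx(body)

    def test_replicates_are_normalized_then_averaged(self):
        u = TranscriptionUnit("tu1", GenomicInterval("c", 1000, 5000, "+"))
        regions = derive_regions([u])
        p1, m1 = _tracks(plus_recs=[("c", 1020, 1021, 10.0)])
        p2, m2 = _tracks(plus_recs=[("c", 1020, 1021, 20.0)])
        q = quantify_regions(p1, m1, regions, library_size=1e6,
                             replicates=[ReplicateTracks(p2, m2, 4e6)])
        # mean(10 RPM, 5 RPM) = 7.5; pooling raw counts would wrongly give 6
        assert q.loc["tu1", "promoter_rpm"] == pytest.approx(7.5)
        assert q.loc["tu1", "promoter_raw"] == pytest.approx(30.0)

    def test_requires_base_counts(self):
        u = TranscriptionUnit("tu1", GenomicInterval("c", 1000, 5000, "+"))
        t = SignalTrack.from_records([("c", 0, 35, 1.0)], "probe_scores")
        with pytest.raises(ValueError, match="base_counts"):
            quantify_regions(t, t, derive_regions([u]), library_size=1.0)

    def test_scale_invariance_of_rpm_density_and_pi(self):
        rng = np.random.default_rng(2)
        units = [TranscriptionUnit("u1", GenomicInterval("c", 1000, 6000, "+"))]
        recs = [("c", int(p), int(p) + 1, float(v)) for p, v in
                zip(rng.choice(np.arange(900, 6000), 200, replace=False),
                    rng.integers(1, 6, 200))]
        regions = derive_regions(units)
        plus, minus = _tracks(recs)
        q1 = quantify_regions(plus, minus, regions, library_size=1e5)
        scaled = [("c", s, e, v * 7) for c, s, e, v in recs]
        p2, m2 = _tracks(scaled)
        q2 = quantify_regions(p2, m2, regions, library_size=7e5)
        for col in ("promoter_rpm", "body_rpm", "promoter_density", "body_density"):
            np.testing.assert_allclose(q1[col], q2[col], rtol=1e-12)
        np.testing.assert_allclose(pause_index(q1), pause_index(q2), rtol=1e-12)


class TestCallActive:
    def test_inclusive_one_rpm_threshold(self):
        q = _quant_frame([
            {"unit_id": "a", "promoter_rpm": 1.0, "body_rpm": 1.0,
             "promoter_length": 200, "body_length": 1000},
            {"unit_id": "b", "promoter_rpm": 0.99, "body_rpm": 5.0,
             "promoter_length": 200, "body_length": 1000},
            {"unit_id": "c", "promoter_rpm": 5.0, "body_rpm": 0.5,
             "promoter_length": 200, "body_length": 1000},
            {"unit_id": "d", "promoter_rpm": 9.0, "body_rpm": 9.0,
             "promoter_length": 200, "body_length": 0},
        ])
        active = call_active(q)
        assert active.tolist() == [True, False, False, False]


class TestPauseIndex:
    def test_ratio_of_densities(self):
        q = _quant_frame([{"unit_id": "a", "promoter_rpm": 50.0, "body_rpm": 50.0,
                           "promoter_length": 200, "body_length": 1000}])
        assert pause_index(q).loc["a"] == pytest.approx(5.0)

    def test_zero_body_density_flagged_missing(self):
        q = _quant_frame([{"unit_id": "a", "promoter_rpm": 5.0, "body_rpm": 0.0,
                           "promoter_length": 200, "body_length": 1000}])
        assert np.isnan(pause_index(q).loc["a"])

    def test_equal_densities_give_unity(self):
        q = _quant_frame([{"unit_id": "a", "promoter_rpm": 2.0, "body_rpm": 10.0,
                           "promoter_length": 200, "body_length": 1000}])
        assert pause_index(q).loc["a"] == pytest.approx(1.0)


class TestFoldChange:
    def _pair(self):
        c = _quant_frame([{"unit_id": "a", "promoter_rpm": 10.0, "body_rpm": 20.0,
                           "promoter_length": 200, "body_length": 1000}])
        t = _quant_frame([{"unit_id": "a", "promoter_rpm": 10.0, "body_rpm": 40.0,
                           "promoter_length": 200, "body_length": 1000}])
        return c, t

    def test_identity_gives_zero(self):
        c, _ = self._pair()
        fc = fold_change(c, c.copy())
        assert np.allclose(fc.to_numpy(dtype=float), 0.0)

    def test_doubled_body_moves_body_up_and_pause_down(self):
        c, t = self._pair()
        fc = fold_change(c, t)
        assert fc.loc["a", "body_rpm_lfc"] == pytest.approx(1.0)
        assert fc.loc["a", "pause_index_lfc"] == pytest.approx(-1.0)

    def test_pseudocount_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        rows_c, rows_t = [], []
        for i in range(30):
            rows_c.append({"unit_id": f"u{i}",
                           "promoter_rpm": float(rng.uniform(0, 5)),
                           "body_rpm": float(rng.uniform(0, 5)),
                           "promoter_length": 200, "body_length": 1000})
            rows_t.append({**rows_c[-1],
                           "promoter_rpm": float(rng.uniform(0, 5)),
                           "body_rpm": float(rng.uniform(0, 5))})
        c, t = _quant_frame(rows_c), _quant_frame(rows_t)
        fc = fold_change(c, t, pseudocount=0.1)
        expect = np.log2((t["promoter_rpm"] + 0.1) / (c["promoter_rpm"] + 0.1))
        np.testing.assert_allclose(fc["promoter_rpm_lfc"], expect)

    def test_zero_without_pseudocount_is_missing(self):
        c = _quant_frame([{"unit_id": "a", "promoter_rpm": 0.0, "body_rpm": 1.0,
                           "promoter_length": 200, "body_length": 1000}])
        t = _quant_frame([{"unit_id": "a", "promoter_rpm": 2.0, "body_rpm": 1.0,
                           "promoter_length": 200, "body_length": 1000}])
        assert np.isnan(fold_change(c, t).loc["a", "promoter_rpm_lfc"])

    def test_mismatched_unit_sets_rejected(self):
        c, t = self._pair()
        t = t.rename(index={"a": "b"})
        with pytest.raises(ValueError, match="unit sets"):
            fold_change(c, t)


def test_replicate_correlation_is_high_on_synthetic_data(study):
    assert study.summary["replicate_pearson_r"] > 0.95
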