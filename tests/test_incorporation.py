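import numpy as np
import pytest

from brickseq.design import Design
from brickseq.incorporation import (
    FLAG_BELOW_THRESHOLD,
    FLAG_EXCLUDED_ROLE,
    FLAG_LOW_READS,
    FLAG_OK,
    IncorporationError,
    N_BINS,
    apply_min_reads_filter,
    build_sri_table,
    compute_sri,
    presence_threshold,
    qc_sequence_correlates,
    read_fractions,
)
from brickseq.matching import CountTable
from brickseq.simulate import random_canvas

from conftest import make_strand, random_seq


class TestReadFractions:
    def test_normalization(self):
        t = CountTable("s", counts={"a": 2, "b": 3, "c": 5})
        rf = read_fractions(t)
        assert rf.fractions == {"a": 0.2, "b": 0.3, "c": 0.5}

    def test_single_strand(self):
        rf = read_fractions(CountTable("s", counts={"a": 7}))
        assert rf.fractions == {"a": 1.0}

    def test_sums_to_one_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            counts = {f"s{i}": int(c) + 1
                      for i, c in enumerate(rng.integers(0, 1000, n))}
            rf = read_fractions(CountTable("s", counts=counts))
            assert sum(rf.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_assigned_reads_is_an_error(self):
        with pytest.raises(IncorporationError, match="empty"):
            read_fractions(CountTable("empty", counts={}))

    def test_design_strands_missing_from_counts_get_zero(self, small_design):
        rf = read_fractions(CountTable("s", counts={"s0": 5}), small_design)
        assert rf.fractions["s3"] == 0.0


class TestComputeSri:
    @pytest.mark.parametrize("P_i,M_i,P_tot,M_tot,expected", [
        (50, 0, 100, 100, 1.0),      # no monomer reads: full incorporation
        (0, 50, 100, 100, 0.0),      # no product reads: no incorporation
        (30, 10, 100, 200, 0.3 / (0.3 + 0.05)),
        (10, 20, 100, 200, 0.5),     # equal read fractions
    ])
    def test_worked_examples(self, P_i, M_i, P_tot, M_tot, expected):
        assert compute_sri(P_i, M_i, P_tot, M_tot) == pytest.approx(
            expected, abs=1e-12)

    def test_no_reads_in_either_band_is_undefined(self):
        assert compute_sri(0, 0, 100, 100) is None

    def test_negative_and_inconsistent_inputs_rejected(self):
        with pytest.raises(IncorporationError):
            compute_sri(-1, 0, 100, 100)
        with pytest.raises(IncorporationError):
            compute_sri(5, 0, 0, 100)
        with pytest.raises(IncorporationError):
            compute_sri(101, 0, 100, 100)

    def test_bounded_and_monotone_in_product_count(self, rng):
        prev = -1.0
        for P_i in range(0, 101, 5):
            v = compute_sri(P_i, 50, 200, 200)
            if v is not None:
                assert 0.0 <= v <= 1.0
                assert v > prev
                prev = v

    def test_shared_per_strand_bias_cancels_exactly(self, rng):
        """SRI depends only on P_i/M_i and P_tot/M_tot, so one multiplicative
        bias per strand applied to both bands cancels exactly."""
        for _ in range(200):
            P_i, M_i = int(rng.integers(1, 500)), int(rng.integers(1, 500))
            P_tot, M_tot = P_i + 1000, M_i + 2000
            b = float(rng.uniform(0.05, 20.0))
            base = compute_sri(P_i, M_i, P_tot, M_tot)
            biased = compute_sri(b * P_i, b * M_i, b * P_tot, b * M_tot)
            assert biased == pytest.approx(base, rel=1e-12)


def _counts_from_log2_ratio(v, canvas_ids, depth=200_000, rng=None):
    """Product/canvas count tables whose log2 read-fraction ratio tracks v."""
    w = 2.0 ** np.asarray(v)
    if rng is None:
        p = np.round(depth * w / w.sum()).astype(int)
    else:
        p = rng.multinomial(depth, w / w.sum())
    product = CountTable("p", counts=dict(zip(canvas_ids, (int(x) for x in p))))
    canvas = CountTable("c", counts={sid: 1000 for sid in canvas_ids})
    return product, canvas


@pytest.fixture(scope="module")
def threshold_canvas():
    return random_canvas(200, seed=77)


class TestPresenceThreshold:
    @pytest.fixture
    def canvas(self, threshold_canvas):
        return threshold_canvas

    def test_bimodal_separates_groups(self, canvas, rng):
        ids = sorted(canvas.strands)
        truth = np.arange(200) < 100
        v = np.where(truth, rng.normal(0, 0.25, 200), rng.normal(-6, 0.25, 200))
        product, canvas_counts = _counts_from_log2_ratio(v, ids)
        fit = presence_threshold(product, canvas_counts, canvas)
        assert len(fit.components) == 2
        assert -6 < fit.threshold < 0
        pred = np.array([sid in fit.present for sid in ids])
        assert (pred == truth).all()

    def test_unimodal_keeps_everything(self, canvas, rng):
        ids = sorted(canvas.strands)
        v = rng.normal(0, 0.25, 200)
        product, canvas_counts = _counts_from_log2_ratio(v, ids)
        fit = presence_threshold(product, canvas_counts, canvas)
        assert fit.threshold is None
        assert fit.present == frozenset(ids)

    def test_histogram_always_20_bins(self, canvas, rng):
        ids = sorted(canvas.strands)
        v = rng.normal(0, 1.0, 200)
        product, canvas_counts = _counts_from_log2_ratio(v, ids)
        fit = presence_threshold(product, canvas_counts, canvas)
        assert len(fit.bin_edges) == N_BINS + 1
        widths = np.diff(fit.bin_edges)
        assert np.allclose(widths, widths[0])

    def test_threshold_between_means_on_next_bin_edge(self, canvas, rng):
        ids = sorted(canvas.strands)
        truth = np.arange(200) < 120
        v = np.where(truth, rng.normal(0, 0.3, 200), rng.normal(-5, 0.3, 200))
        product, canvas_counts = _counts_from_log2_ratio(v, ids)
        fit = presence_threshold(product, canvas_counts, canvas)
        lo, hi = (c.mean for c in fit.components)
        assert lo < fit.threshold < hi
        assert np.isclose(fit.bin_edges - fit.threshold, 0, atol=1e-9).any()

    def test_too_few_strands_refuses_to_fit(self, small_design):
        product = CountTable("p", counts={f"s{i}": 100 for i in range(6)})
        canvas = CountTable("c", counts={f"s{i}": 100 for i in range(6)})
        fit = presence_threshold(product, canvas, small_design)
        assert fit.threshold is None
        assert fit.present == frozenset(small_design.strands)

    def test_pseudocount_makes_absent_strands_finite(self, canvas):
        ids = sorted(canvas.strands)
        product = CountTable("p", counts={sid: 1000 for sid in ids[:100]})
        canvas_counts = CountTable("c", counts={sid: 1000 for sid in ids})
        fit = presence_threshold(product, canvas_counts, canvas)
        assert all(np.isfinite(list(fit.values.values())))

    def test_classification_accuracy_at_8_sd_separation(self, canvas):
        """Modes 8 sd apart must classify >= 99% of strands correctly
        (20 independent simulations)."""
        ids = sorted(canvas.strands)
        accuracies = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            truth = np.arange(200) < 100
            sd = 0.25
            v = np.where(truth, r.normal(0, sd, 200),
                         r.normal(-8 * sd, sd, 200))
            product, canvas_counts = _counts_from_log2_ratio(v, ids, rng=r)
            fit = presence_threshold(product, canvas_counts, canvas)
            pred = np.array([sid in fit.present for sid in ids])
            accuracies.append(float((pred == truth).mean()))
        assert min(accuracies) >= 0.99


class TestSriTable:
    def _tables(self, design, product, monomer):
        return build_sri_table(
            CountTable("p", counts=product),
            CountTable("m", counts=monomer),
            design,
        )

    def test_flags_and_values(self, rng):
        strands = [
            make_strand("br", random_seq(rng, 32)),
            make_strand("hb", random_seq(rng, 32), role="half_brick"),
            make_strand("ep", random_seq(rng, 32), role="edge_protector"),
        ]
        design = Design("d", strands)
        table = self._tables(design, {"br": 60, "hb": 40, "ep": 10},
                             {"br": 30, "hb": 50, "ep": 30})
        flags = dict(zip(table.data.strand_id, table.data.flag))
        assert flags == {"br": FLAG_OK, "hb": FLAG_EXCLUDED_ROLE,
                         "ep": FLAG_EXCLUDED_ROLE}
        assert table.sri_of("br") == pytest.approx(
            compute_sri(60, 30, 110, 110))

    def test_below_threshold_flagged(self, rng):
        strands = [make_strand(f"s{i}", random_seq(rng, 32)) for i in range(3)]
        design = Design("d", strands)
        table = build_sri_table(
            CountTable("p", counts={"s0": 100, "s1": 100, "s2": 100}),
            CountTable("m", counts={"s0": 10, "s1": 10, "s2": 10}),
            design,
            present=frozenset({"s0", "s1"}),
        )
        flags = dict(zip(table.data.strand_id, table.data.flag))
        assert flags["s2"] == FLAG_BELOW_THRESHOLD
        assert np.isnan(table.sri_of("s2"))

    def test_min_reads_filter_boundary(self, rng):
        strands = [make_strand(f"s{i}", random_seq(rng, 32)) for i in range(2)]
        design = Design("d", strands)
        table = self._tables(design, {"s0": 24, "s1": 25}, {"s0": 5, "s1": 5})
        filtered = apply_min_reads_filter(table, 25)
        flags = dict(zip(filtered.data.strand_id, filtered.data.flag))
        assert flags == {"s0": FLAG_LOW_READS, "s1": FLAG_OK}
        assert np.isnan(filtered.sri_of("s0"))

    def test_zero_min_reads_is_identity(self, rng):
        strands = [make_strand(f"s{i}", random_seq(rng, 32)) for i in range(4)]
        design = Design("d", strands)
        table = self._tables(design,
                             {f"s{i}": i + 1 for i in range(4)},
                             {f"s{i}": 2 for i in range(4)})
        filtered = apply_min_reads_filter(table, 0)
        assert filtered.data.equals(table.data)

    def test_round_trip_tsv(self, tmp_path, rng):
        from brickseq.incorporation import SRITable
        strands = [make_strand(f"s{i}", random_seq(rng, 32)) for i in range(3)]
        design = Design("d", strands)
        table = self._tables(design, {"s0": 50, "s1": 30, "s2": 20},
                             {"s0": 10, "s1": 20, "s2": 5})
        p = tmp_path / "sri.tsv"
        table.write(p)
        back = SRITable.read(p)
        assert list(back.data.strand_id) == list(table.data.strand_id)
        assert np.allclose(back.data.sri, table.data.sri, atol=1e-5)


class TestQcSequenceCorrelates:
    def test_independent_sri_shows_no_correlation(self):
        rng = np.random.default_rng(123)
        canvas = random_canvas(500, seed=55)
        ids = sorted(canvas.strands)
        product = {sid: int(c) for sid, c in
                   zip(ids, rng.integers(100, 2000, 500))}
        monomer = {sid: int(c) for sid, c in
                   zip(ids, rng.integers(100, 2000, 500))}
        table = build_sri_table(CountTable("p", counts=product),
                                CountTable("m", counts=monomer), canvas)
        r, n = qc_sequence_correlates(table, canvas)
        assert n == 500
        assert abs(r) < 0.2

    def test_constant_sri_is_degenerate(self, rng):
        strands = [make_strand(f"s{i}", random_seq(rng, 32)) for i in range(5)]
        design = Design("d", strands)
        table = build_sri_table(
            CountTable("p", counts={f"s{i}": 100 for i in range(5)}),
            CountTable("m", counts={f"s{i}": 100 for i in range(5)}),
            design,
        )
        with pytest.raises(IncorporationError, match="degenerate"):
            qc_sequence_correlates(table, design)

    def test_too_few_strands_rejected(self, rng):
        strands = [make_strand(f"s{i}", random_seq(rng, 32)) for i in range(2)]
        design = Design("d", strands)
        table = build_sri_table(
            CountTable("p", counts={"s0": 100, "s1": 50}),
            CountTable("m", counts={"s0": 10, "s1": 80}),
            design,
        )
        with pytest.raises(IncorporationError, match=">= 3"):
            qc_sequence_correlates(table, design)
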