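"""Event I/O, demultiplexing and well QC."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import silscreen as ss
from silscreen.cytometry import DegenerateInputError, MissingChannelError


def _tiny_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    chans = {c: rng.gamma(2.0, 100.0, n) for c in ss.CHANNELS}
    return ss.EventTable(well_id="w", channels=chans)


class TestEventTable:
    def test_missing_channel_is_named(self):
        chans = {c: np.ones(10) for c in ss.CHANNELS if c != "BFP"}
        with pytest.raises(MissingChannelError, match="BFP.*445/60"):
            ss.EventTable(well_id="w", channels=chans)

    @pytest.mark.parametrize("bad,msg", [
        (dict(GFP=np.full(10, np.nan)), "non-finite"),
        (dict(GFP=-np.ones(10)), "negative"),
        (dict(GFP=np.ones(7)), "same length"),
    ])
    def test_invalid_intensities_rejected(self, bad, msg):
        chans = {c: np.ones(10) for c in ss.CHANNELS}
        chans.update(bad)
        with pytest.raises(ValueError, match=msg):
            ss.EventTable(well_id="w", channels=chans)

    def test_channels_are_immutable(self):
        t = _tiny_table()
        with pytest.raises(ValueError):
            t.channels["GFP"][0] = 1.0


class TestIo:
    def test_tsv_round_trip_is_exact(self, tmp_path):
        t = _tiny_table(seed=1)
        path = tmp_path / "well.tsv"
        ss.write_events(t, path)
        back = ss.read_events(path, well_id="w")
        for c in ss.CHANNELS:
            assert np.array_equal(back.channels[c], t.channels[c])

    def test_fcs_round_trip_within_float32(self, tmp_path):
        t = _tiny_table(n=1500, seed=2)
        path = tmp_path / "well.fcs"
        ss.write_events(t, path, dialect="fcs")
        back = ss.read_events(path, dialect="fcs", well_id="w")
        assert back.n_events == 1500
        for c in ss.CHANNELS:
            assert np.array_equal(back.channels[c],
                                  t.channels[c].astype(np.float32).astype(float))

    def test_fcs_reports_declared_event_count(self, tmp_path, cos12):
        cfg = ss.GeneratorConfig(n_events_per_population=7500, seed=0)
        t = ss.simulate_well(cos12, ss.StrainSpec("G", 0.0, "RFP", "COS12"), cfg)
        path = tmp_path / "well.fcs"
        ss.write_events(t, path, dialect="fcs")
        names, data, text = __import__("silscreen.fcs", fromlist=["read_fcs"]).read_fcs(path)
        assert int(text["$TOT"]) == 15000 and data.shape == (15000, 5)

    def test_channel_map_renames_on_read(self, tmp_path):
        t = _tiny_table()
        df = t.to_frame().rename(columns={"GFP": "FL1-A"})
        path = tmp_path / "w.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(MissingChannelError):
            ss.read_events(path)
        back = ss.read_events(path, channel_map={"FL1-A": "GFP"})
        assert np.array_equal(back.channels["GFP"], t.channels["GFP"])


def _well(separation=10.0, seed=0, n=10000, effect=0.0, mixing=0.5):
    cfg = ss.GeneratorConfig(
        n_events_per_population=n, mixing_fraction=mixing, seed=seed,
        marker_mu_low=3.0 - np.log10(separation))
    model = ss.LOCUS_PRESETS["COS12"]
    return ss.simulate_well(model, ss.StrainSpec("G", effect, "RFP", "COS12"),
                            cfg, return_truth=True)


class TestDemultiplex:
    def test_accuracy_at_tenfold_separation(self):
        table, is_mut = _well(separation=10.0, seed=1)
        d = ss.demultiplex(table)
        assigned = np.concatenate([d.mutant_indices, d.reference_indices])
        correct = is_mut[d.mutant_indices].sum() + (~is_mut[d.reference_indices]).sum()
        assert correct / assigned.size >= 0.999

    def test_accuracy_monotone_in_separation(self):
        accs = []
        for sep in (2.0, 5.0, 10.0):
            table, is_mut = _well(separation=sep, seed=3)
            d = ss.demultiplex(table)
            correct = is_mut[d.mutant_indices].sum() + (~is_mut[d.reference_indices]).sum()
            accs.append(correct / table.n_events)  # abstentions count against
        assert accs[0] < accs[1] < accs[2]

    def test_label_symmetry_is_exact(self):
        table, _ = _well(seed=5, n=2000)
        d = ss.demultiplex(table, threshold=0.1)
        swapped = ss.EventTable(well_id="w", channels={
            **{c: table.channels[c] for c in ("FSC", "SSC", "GFP")},
            "BFP": table.channels["RFP"], "RFP": table.channels["BFP"]})
        d2 = ss.demultiplex(swapped, threshold=-0.1)
        assert np.array_equal(d.mutant_indices, d2.reference_indices)
        assert np.array_equal(d.reference_indices, d2.mutant_indices)
        assert np.array_equal(d.unassigned_indices, d2.unassigned_indices)

    def test_two_gaussian_agrees_with_threshold_method(self):
        table, is_mut = _well(seed=7, n=3000)
        d = ss.demultiplex(table, method="two_gaussian")
        correct = is_mut[d.mutant_indices].sum() + (~is_mut[d.reference_indices]).sum()
        assert correct / (d.n_mutant + d.n_reference) >= 0.999
        d2 = ss.demultiplex(table, method="two_gaussian")
        assert np.array_equal(d.mutant_indices, d2.mutant_indices)

    def test_population_sizes_in_acquisition_range(self):
        """Default presets put 5,000-15,000 events in each assigned population."""
        table, _ = _well(seed=11, n=7500)
        d = ss.demultiplex(table)
        assert 5000 <= d.n_mutant <= 15000
        assert 5000 <= d.n_reference <= 15000

    def test_too_few_events_rejected(self):
        t = _tiny_table(n=50)
        with pytest.raises(DegenerateInputError):
            ss.demultiplex(t)

    def test_degenerate_constant_ratio_rejected(self):
        chans = {c: np.ones(500) for c in ss.CHANNELS}
        with pytest.raises(DegenerateInputError, match="identical"):
            ss.demultiplex(ss.EventTable(well_id="w", channels=chans))

    @given(st.integers(min_value=0, max_value=10_000))
    def test_assignment_partitions_events(self, seed):
        table, _ = _well(seed=seed, n=300)
        d = ss.demultiplex(table)
        parts = np.concatenate([d.mutant_indices, d.reference_indices,
                                d.unassigned_indices])
        assert np.array_equal(np.sort(parts), np.arange(table.n_events))


class TestWellQc:
    def test_balanced_well_passes(self):
        table, _ = _well(seed=2, n=12000)
        qc = ss.well_qc(ss.demultiplex(table))
        assert qc.passed and qc.reasons == ()

    def test_small_population_fails(self):
        table, _ = _well(seed=2, n=12000, mixing=0.02)
        qc = ss.well_qc(ss.demultiplex(table))
        assert not qc.passed
        assert "too_few_events" in qc.reasons
        assert "population_imbalance" in qc.reasons

    def test_all_reference_well_flags_imbalance(self):
        table, _ = _well(seed=4, n=3000, mixing=0.001)
        d = ss.demultiplex(table)
        qc = ss.well_qc(d, min_per_population=100)
        assert "population_imbalance" in qc.reasons

    def test_saturation_flag(self):
        table, _ = _well(seed=6, n=1000)
        d = ss.demultiplex(table)
        qc = ss.well_qc(d, min_per_population=100, events=table, saturation_limit=1.0)
        assert "saturated_channel" in qc.reasons

    def test_default_wells_pass_qc(self, cos12):
        """Simulator presets clear the 1,000-events-per-population gate."""
        for seed in range(30):
            cfg = ss.GeneratorConfig(seed=seed)
            t = ss.simulate_well(cos12, ss.StrainSpec("G", 0.0, "RFP", "COS12"), cfg)
            assert ss.well_qc(ss.demultiplex(t)).passed
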