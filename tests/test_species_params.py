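"""Species bookkeeping and parameter presets."""

import pytest

from celldem import (
    InteractionMatrix,
    count_enabled_interactions,
    default_parameters,
    load_adhesion_preset,
    scale_resolution,
)
from celldem.params import UnknownPresetError


class TestInteractionMatrix:
    def test_default_pair_sets(self):
        m = InteractionMatrix.default()
        assert m.pairs() == {
            ("M", "M"), ("C", "M"), ("C", "C"), ("C", "NM"),
            ("NM", "NM"), ("N", "NM"), ("N", "N"),
            ("M", "P"), ("BM", "M"),
        }

    def test_counts(self):
        m = InteractionMatrix.default()
        assert count_enabled_interactions(m, "intracell") == 7
        assert count_enabled_interactions(m, "external") == 2
        assert count_enabled_interactions(m, "all_potential") == 18
        # the potential count is independent of the enabled flags
        empty = InteractionMatrix(())
        assert count_enabled_interactions(empty, "all_potential") == 18

    def test_symmetry(self):
        m = InteractionMatrix.default()
        for a in ("M", "C", "NM", "N"):
            for b in ("M", "C", "NM", "N", "P", "BM"):
                assert m.enabled(a, b) == m.enabled(b, a)

    def test_disabled_pairs(self):
        m = InteractionMatrix.default()
        assert not m.enabled("M", "N")
        assert not m.enabled("C", "BM")
        assert not m.enabled("N", "P")

    def test_enable_disable_roundtrip(self):
        m = InteractionMatrix.default()
        m.enable("NM", "P")
        assert m.enabled("P", "NM")
        m.disable("NM", "P")
        assert not m.enabled("NM", "P")

    def test_unknown_label_rejected(self):
        m = InteractionMatrix.default()
        with pytest.raises(KeyError):
            m.enabled("M", "X")


class TestPresets:
    def test_baseline_values(self, table2):
        # membrane radius 0.15 um, cytoplasm modulus 1 kPa, uniform drag
        assert table2["M"].R == pytest.approx(0.15e-6)
        assert table2["C"].R == pytest.approx(0.25e-6)
        assert table2["M"].F_a == pytest.approx(1e-10)
        assert table2["C"].F_a == pytest.approx(5e-11)
        assert table2["C"].E == pytest.approx(1e3)
        assert table2["N"].E == pytest.approx(5e3)
        assert table2["M"].E == pytest.approx(1e7)
        for sp in ("M", "C", "NM", "N"):
            assert table2[sp].beta == pytest.approx(0.05)
            assert table2[sp].nu == pytest.approx(0.5)
            assert table2[sp].delta == pytest.approx(2e-6)
            assert table2[sp].k_a == pytest.approx(1e-8)

    def test_nucleus_calibration_presets(self):
        p30 = default_parameters("nucleus_30kPa")
        assert p30["N"].E == pytest.approx(30e3)
        assert p30["NM"].E == pytest.approx(30e3)
        assert p30["N"].F_a == pytest.approx(2.5e-11)
        assert p30["NM"].k_a == pytest.approx(5e-8)
        assert p30["N"].beta == pytest.approx(0.01)
        # fields not listed fall back to the baseline
        assert p30["C"].E == pytest.approx(1e3)
        assert p30["M"].F_a == pytest.approx(1e-10)
        p1 = default_parameters("nucleus_1kPa")
        assert p1["N"].E == pytest.approx(1e3)
        assert p1["N"].F_a == pytest.approx(5e-12)

    def test_cell_calibration_band(self):
        soft = default_parameters("round_soft")
        assert soft["C"].E == pytest.approx(100.0)
        assert soft["M"].E == pytest.approx(100.0)
        assert soft["C"].F_a == pytest.approx(5e-13)
        assert soft["M"].F_a == pytest.approx(1e-11)
        assert soft["N"].E == pytest.approx(1e3)
        stiff = default_parameters("spread_stiff")
        assert stiff["C"].E == pytest.approx(2.25e3)
        assert stiff["M"].F_a == pytest.approx(1e-10)
        assert stiff["N"].E == pytest.approx(25e3)

    @pytest.mark.parametrize(
        "preset",
        ["table2", "nucleus_1kPa", "nucleus_5kPa", "nucleus_30kPa",
         "spread_soft", "spread_stiff", "round_soft", "round_stiff"],
    )
    def test_all_presets_validate(self, preset):
        params = default_parameters(preset)
        for p in params.values():
            p.validate()

    def test_unknown_preset_raises(self):
        with pytest.raises(UnknownPresetError):
            default_parameters("no_such_preset")

    def test_adhesion_presets_load(self):
        adh = load_adhesion_preset("layer_control")
        assert adh["k_a_bm"] == pytest.approx(1e-11)
        assert adh["delta_bm"] == pytest.approx(0.3e-6)
        assert adh["k_a_m"] == pytest.approx(5e-10)
        assert adh["delta_m"] == pytest.approx(0.2e-6)
        with pytest.raises(UnknownPresetError):
            load_adhesion_preset("nope")

    def test_scale_resolution(self, table2):
        scaled = scale_resolution(table2, 3.0)
        assert scaled["C"].R == pytest.approx(3 * table2["C"].R)
        assert scaled["M"].delta == pytest.approx(3 * table2["M"].delta)
        # bulk cohesion range is physical, not discretisation-tied
        assert scaled["C"].delta == pytest.approx(table2["C"].delta)
        # force parameters untouched
        assert scaled["C"].F_a == table2["C"].F_a
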