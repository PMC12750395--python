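"""Mass arithmetic, database matching, analog propagation, in-source flags."""

import numpy as np
import pytest

from pbnet.ms_io import FeatureRecord, Peak, Spectrum
from pbnet.pb_annotation import (
    PROTON_MASS,
    Annotation,
    LossTable,
    ModificationDelta,
    PBRecord,
    count_isomer_nodes,
    default_deltas,
    default_pb_database,
    detect_insource,
    detect_signature,
    mh_from_neutral_mass,
    ms1_match,
    neutral_mass_from_mh,
    ppm_error,
    propagate_analog,
    verify_shift_consistency,
)

# monoisotopic atomic masses (CODATA/IUPAC) for the composition oracle
M_H, M_C, M_O = 1.00782503, 12.0, 15.99491462


def feature(fid, mz, rt=5.0):
    return FeatureRecord(feature_id=fid, mz=mz, rt=rt, intensities={"F1": 1.0})


def spectrum(fid, precursor, mzs, rt=5.0):
    return Spectrum(feature_id=fid, precursor_mz=precursor, charge=1, rt=rt,
                    peaks=tuple(Peak(m, 10.0) for m in mzs))


class TestMassArithmetic:
    def test_ppm_identity(self):
        assert ppm_error(643.2754, 643.2754) == 0.0

    def test_ppm_signed_value(self):
        assert ppm_error(643.2786, 643.2754) == pytest.approx(4.97, abs=0.01)

    def test_ppm_near_antisymmetric_within_10ppm(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = float(rng.uniform(100, 1000))
            b = a * (1 + rng.uniform(-1e-5, 1e-5))
            assert abs(ppm_error(a, b) + ppm_error(b, a)) < 1e-4 * abs(ppm_error(a, b) or 1)

    def test_ppm_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ppm_error(-1.0, 500.0)

    def test_neutral_mass_of_ep_pxb6_ion(self):
        assert neutral_mass_from_mh(643.2754) == pytest.approx(642.2681, abs=1e-4)

    def test_proton_maps_to_zero(self):
        assert neutral_mass_from_mh(PROTON_MASS) == pytest.approx(0.0, abs=1e-12)

    def test_mh_inverse(self):
        m = 642.2681
        assert neutral_mass_from_mh(mh_from_neutral_mass(m)) == pytest.approx(m, abs=1e-12)

    def test_only_singly_charged_supported(self):
        with pytest.raises(ValueError, match="charge"):
            mh_from_neutral_mass(642.2681, charge=2)

    @pytest.mark.parametrize(
        "value,composition",
        [
            (2.0157, {"H": 2}),                       # hydrogenation (PleB)
            (15.9949, {"O": 1}),                      # extra carbonyl
            (86.0004, {"C": 3, "H": 2, "O": 3}),      # malonyl ester
            (18.0106, {"H": 2, "O": 1}),              # water loss
            (32.0262, {"C": 1, "H": 4, "O": 1}),      # methanol loss
            (76.0160, {"C": 2, "H": 4, "O": 3}),      # methanol + CO2 loss
        ],
    )
    def test_exact_masses_match_composition_oracle(self, value, composition):
        oracle = composition.get("C", 0) * M_C + composition.get("H", 0) * M_H + composition.get("O", 0) * M_O
        assert value == pytest.approx(oracle, abs=5e-5)

    def test_delta_table_nominal_consistency(self):
        for d in default_deltas(include_disabled=True):
            assert round(d.exact_mass) == d.nominal_mass


class TestMs1Match:
    db = [PBRecord("Ep-PxB-6", "PxB", 642.2681), PBRecord("Sao-PxB", "PxB", 728.2685)]

    def test_exact_hit(self):
        hits = ms1_match(feature("n1", 643.2754), self.db, tol_ppm=5.0)
        assert [h.name for h in hits] == ["Ep-PxB-6"]
        assert abs(hits[0].ppm_error) < 0.1

    def test_no_hit(self):
        assert ms1_match(feature("n1", 650.0), self.db, tol_ppm=5.0) == []

    def test_two_hits_sorted_best_first(self):
        db = [PBRecord("far", "PxB", 642.2691), PBRecord("near", "PxB", 642.2682)]
        hits = ms1_match(feature("n1", 643.2754), db, tol_ppm=5.0)
        assert [h.name for h in hits] == ["near", "far"]

    def test_never_returns_hit_beyond_tolerance(self):
        rng = np.random.default_rng(8)
        db = [PBRecord(f"r{i}", "PxB", float(m)) for i, m in enumerate(rng.uniform(300, 900, 50))]
        for _ in range(300):
            f = feature("n", float(rng.uniform(300, 901)))
            for hit in ms1_match(f, db, tol_ppm=5.0):
                assert abs(hit.ppm_error) <= 5.0

    def test_builtin_database_contents(self):
        db = {r.name: r for r in default_pb_database()}
        assert db["Ep-PxB-6"].neutral_mass == pytest.approx(642.2681)
        assert db["Sao-PxB"].neutral_mass == pytest.approx(728.2685)
        assert db["Sao-PxB"].neutral_mass - db["Ep-PxB-6"].neutral_mass == pytest.approx(86.0004, abs=1e-4)


class TestSignature:
    def test_constructed_losses_detected(self):
        prec = 643.2754
        s = spectrum("n", prec, [prec - 32.0262, prec - 76.0160, 300.0])
        result = detect_signature(s, LossTable({"methanol": 32.0262, "methanol+CO2": 76.0160, "water": 18.0106}))
        assert result["methanol"] and result["methanol+CO2"] and not result["water"]

    def test_empty_spectrum_no_losses(self):
        s = spectrum("n", 643.2754, [])
        assert not any(detect_signature(s).values())

    def test_decoy_false_positive_rate_below_5pct(self):
        # Monte-Carlo: random 10-peak spectra, tol 0.02 Th
        rng = np.random.default_rng(99)
        table = LossTable()
        counts = {name: 0 for name in table.losses}
        n = 1000
        for _ in range(n):
            prec = float(rng.uniform(400, 900))
            s = spectrum("d", prec, sorted(rng.uniform(100, prec - 17, 10)))
            for name, hit in detect_signature(s, table, tol=0.02).items():
                counts[name] += hit
        for name, c in counts.items():
            assert c / n < 0.05


class TestAnalogPropagation:
    anchor = Annotation(node_id="a", kind="ms1_match", name="Ep-PxB-6", ppm_error=0.0)
    anchor_mz = 643.2754

    @pytest.mark.parametrize(
        "delta,modification",
        [
            (86.0004, "malonylation"),
            (2.0157, "hydrogenation"),
            (-2.0157, "dehydrogenation"),
            (15.9949, "oxygenation"),
        ],
    )
    def test_named_modifications(self, delta, modification):
        nb = feature("b", self.anchor_mz + delta)
        ann = propagate_analog(self.anchor, self.anchor_mz, nb, default_deltas(), tol_ppm=5.0)
        assert ann is not None
        assert ann.evidence["modification"] == modification
        assert ann.kind == "analog"

    def test_malonyl_neutral_mass_value(self):
        nb = feature("b", 729.2758)  # 643.2754 + 86.0004
        ann = propagate_analog(self.anchor, self.anchor_mz, nb, default_deltas(), tol_ppm=5.0)
        assert ann.evidence["neutral_mass"] == pytest.approx(728.2685, abs=1e-4)

    def test_unmatched_delta_returns_none(self):
        nb = feature("b", self.anchor_mz + 40.0)
        assert propagate_analog(self.anchor, self.anchor_mz, nb, default_deltas(), tol_ppm=5.0) is None

    def test_requires_anchor_kind(self):
        bad = Annotation(node_id="a", kind="analog", name="x")
        with pytest.raises(ValueError):
            propagate_analog(bad, self.anchor_mz, feature("b", 700.0), default_deltas())

    def test_inverse_consistency(self):
        # annotating B from A with +delta implies A from B matches -delta
        deltas = default_deltas()
        both_ways = deltas + [d.inverse() for d in deltas]
        nb = feature("b", self.anchor_mz + 86.0004)
        fwd = propagate_analog(self.anchor, self.anchor_mz, nb, both_ways, tol_ppm=5.0)
        assert fwd.evidence["delta_mass"] == pytest.approx(86.0004)
        back_anchor = Annotation(node_id="b", kind="ms1_match", name="Sao-PxB", ppm_error=0.0)
        back = propagate_analog(back_anchor, nb.mz, feature("a", self.anchor_mz), both_ways, tol_ppm=5.0)
        assert back.evidence["delta_mass"] == pytest.approx(-86.0004)

    def test_glycosylation_off_by_default(self):
        nb = feature("b", self.anchor_mz + 162.0528)
        assert propagate_analog(self.anchor, self.anchor_mz, nb, default_deltas(), tol_ppm=5.0) is None
        ann = propagate_analog(self.anchor, self.anchor_mz, nb,
                               default_deltas(include_disabled=True), tol_ppm=5.0)
        assert ann.evidence["modification"] == "glycosylation"


class TestShiftConsistency:
    def test_three_shifted_one_conserved(self):
        delta = 86.0004
        parent_prec = 643.2754
        parent_frags = [parent_prec - 32.0262, parent_prec - 76.0160, parent_prec - 210.0, 433.22]
        analog_frags = [f + delta for f in parent_frags[:3]] + [433.22]
        parent = spectrum("p", parent_prec, parent_frags)
        analog = spectrum("a", parent_prec + delta, analog_frags)
        assert verify_shift_consistency(parent, analog, delta) == (3, 1, 0)

    def test_identical_spectra_all_conserved(self):
        s = spectrum("p", 500.0, [100.0, 200.0, 300.0])
        assert verify_shift_consistency(s, s, 0.0) == (0, 3, 0)

    def test_unrelated_pair_mostly_unexplained(self):
        rng = np.random.default_rng(12)
        unexplained_fractions = []
        for _ in range(200):
            p = spectrum("p", 600.0, sorted(rng.uniform(100, 580, 8)))
            a = spectrum("a", 686.0, sorted(rng.uniform(100, 660, 8)))
            s, c, u = verify_shift_consistency(p, a, 86.0)
            unexplained_fractions.append(u / 8)
        assert np.mean(unexplained_fractions) > 0.5


class TestInsource:
    def test_coeluting_fragment_match_flagged(self):
        parent_f = feature("p", 729.2758, rt=5.00)
        parent_s = spectrum("p", 729.2758, [643.2754, 300.0], rt=5.00)
        cand = feature("c", 643.2754, rt=5.02)
        flag = detect_insource(parent_f, parent_s, cand, mz_tol_ppm=1.0, rt_tol=0.1)
        assert flag is not None and flag.kind == "insource_artifact"
        assert flag.evidence["parent"] == "p"

    def test_separated_retention_not_flagged(self):
        parent_f = feature("p", 729.2758, rt=5.0)
        parent_s = spectrum("p", 729.2758, [643.2754], rt=5.0)
        cand = feature("c", 643.2754, rt=7.0)
        assert detect_insource(parent_f, parent_s, cand) is None

    def test_no_fragment_match_not_flagged(self):
        parent_f = feature("p", 729.2758, rt=5.0)
        parent_s = spectrum("p", 729.2758, [500.0], rt=5.0)
        cand = feature("c", 643.2754, rt=5.0)
        assert detect_insource(parent_f, parent_s, cand) is None

    def test_one_ppm_window_is_tight(self):
        parent_f = feature("p", 729.2758, rt=5.0)
        parent_s = spectrum("p", 729.2758, [643.2754], rt=5.0)
        off = 643.2754 * (1 + 3e-6)  # 3 ppm away
        assert detect_insource(parent_f, parent_s, feature("c", off, rt=5.0), mz_tol_ppm=1.0) is None


class TestIsomerCount:
    def annotations(self, n, name="Ep-PxB-6"):
        return [Annotation(node_id=f"n{i}", kind="ms1_match", name=name, ppm_error=0.0) for i in range(n)]

    def features(self, n):
        return {f"n{i}": feature(f"n{i}", 643.2754, rt=5.0 + 0.3 * i) for i in range(n)}

    def test_three_isomers_not_flagged(self):
        report = count_isomer_nodes(self.annotations(3), self.features(3))
        group = report["Ep-PxB-6"]
        assert len(group.node_ids) == 3 and not group.flagged

    def test_five_nodes_flagged(self):
        report = count_isomer_nodes(self.annotations(5), self.features(5))
        assert report["Ep-PxB-6"].flagged

    def test_empty_annotations_empty_report(self):
        assert count_isomer_nodes([], {}) == {}
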