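"""Dosage calling, allele frequencies, and the MFA carrier filter."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, assume, settings
from hypothesis import strategies as st

from tetrasnp.genotyping import (
    DosageMatrix,
    GenotypeClass,
    PeakSignal,
    SnpMarker,
    apply_mfa_filter,
    call_dosage,
    call_dosage_triallelic,
    mfa_dosage,
    minor_allele_frequency,
    presence_absence_frequency,
)
from tetrasnp.simulate import simulate_dosages, simulate_peaks

BI = SnpMarker(locus="GWD", position=3452, alleles=("A", "G"))
TRI = SnpMarker(locus="PGM-3", position=441, alleles=("T", "A", "C"))


def nearest_centroid_oracle(frac):
    """Independent oracle: exhaustive search over the five expected
    minor-allele fractions."""
    centroids = [0.0, 0.25, 0.5, 0.75, 1.0]
    return min(range(5), key=lambda d: abs(frac - centroids[d]))


def brute_force_triallelic(fracs):
    """Enumerate all 15 compositions of 4 copies over 3 alleles."""
    best = None
    for c in itertools.product(range(5), repeat=3):
        if sum(c) != 4:
            continue
        dist = np.linalg.norm(np.array(fracs) - np.array(c) / 4)
        label = "A" * c[0] + "B" * c[1] + "C" * c[2]
        if best is None or (dist, label) < best[:2]:
            best = (dist, label, c)
    return best[2]


class TestMarkerIds:
    @pytest.mark.parametrize(
        "mid,locus,pos,alleles",
        [
            ("GWD-A_3452_G", "GWD", 3452, ("A", "G")),
            ("INV-8/2-T_2076_C", "INV-8/2", 2076, ("T", "C")),
            ("PGM-3-T_441_A/C", "PGM-3", 441, ("T", "A", "C")),
            ("PHO1b-A_4207_GT", "PHO1b", 4207, ("A", "GT")),  # indel allele
        ],
    )
    def test_id_round_trip(self, mid, locus, pos, alleles):
        m = SnpMarker.from_id(mid)
        assert (m.locus, m.position, m.alleles) == (locus, pos, alleles)
        assert m.id == mid

    def test_unparseable_id_rejected(self):
        with pytest.raises(ValueError):
            SnpMarker.from_id("not a marker")


class TestCallDosage:
    @pytest.mark.parametrize(
        "heights,label,dosage",
        [
            ((1.0, 0.0), "AAAA", 0),
            ((0.5, 0.5), "AABB", 2),
            ((0.26, 0.74), "ABBB", 3),
            ((0.0, 1.0), "BBBB", 4),
        ],
    )
    def test_examples(self, heights, label, dosage):
        cls = call_dosage(PeakSignal(heights=heights), BI)
        assert cls.label == label
        assert cls.alt_dosage == dosage

    def test_matches_nearest_centroid_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            h = rng.random(2) + 1e-6
            frac = h[1] / h.sum()
            assert call_dosage(PeakSignal(heights=tuple(h)), BI).alt_dosage == nearest_centroid_oracle(frac)

    @given(st.floats(0.001, 0.999))
    @settings(deadline=None)
    def test_mirror_symmetry(self, f):
        assume(min(abs(f - m) for m in (0.125, 0.375, 0.625, 0.875)) > 1e-6)
        d = call_dosage(PeakSignal(heights=(1 - f, f)), BI).alt_dosage
        d_mirror = call_dosage(PeakSignal(heights=(f, 1 - f)), BI).alt_dosage
        assert d_mirror == 4 - d

    def test_all_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            PeakSignal(heights=(0.0, 0.0))

    def test_exact_at_zero_noise_all_classes(self):
        rng = np.random.default_rng(2)
        for true_d in range(5):
            sig = simulate_peaks(true_d, 0.0, rng)
            assert call_dosage(sig, BI).alt_dosage == true_d

    def test_accuracy_degrades_with_noise(self):
        rng = np.random.default_rng(33)
        accuracies = []
        for cv in (0.0, 0.15, 0.5):
            correct = 0
            n = 400
            for _ in range(n):
                true_d = rng.integers(5)
                sig = simulate_peaks(int(true_d), cv, rng)
                correct += call_dosage(sig, BI).alt_dosage == true_d
            accuracies.append(correct / n)
        assert accuracies[0] == 1.0
        assert accuracies[0] >= accuracies[1] >= accuracies[2]


class TestTriallelic:
    @pytest.mark.parametrize(
        "fracs,label",
        [
            ((0.5, 0.25, 0.25), "AABC"),
            ((1.0, 0.0, 0.0), "AAAA"),
            ((0.0, 0.5, 0.5), "BBCC"),
        ],
    )
    def test_grid_points(self, fracs, label):
        assert call_dosage_triallelic(PeakSignal(heights=fracs), TRI).label == label

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            h = rng.random(3) + 1e-6
            fracs = tuple(h / h.sum())
            cls = call_dosage_triallelic(PeakSignal(heights=fracs), TRI)
            assert cls.dosage_vector == brute_force_triallelic(fracs)

    def test_biallelic_call_routes_triallelic_marker(self):
        cls = call_dosage(PeakSignal(heights=(0.6, 0.3, 0.1)), TRI)
        assert sum(cls.dosage_vector) == 4


class TestGenotypeClassRoundTrip:
    def test_all_biallelic_and_triallelic_classes(self):
        labels = set()
        for c in itertools.product(range(5), repeat=3):
            if sum(c) != 4:
                continue
            cls = GenotypeClass(dosage_vector=c if c[2] else c[:2])
            assert GenotypeClass.from_label(cls.label).label == cls.label
            labels.add(cls.label)
        assert len(labels) == 15
        biallelic = {lab for lab in labels if "C" not in lab}
        assert biallelic == {"AAAA", "AAAB", "AABB", "ABBB", "BBBB"}


class TestAlleleFrequency:
    def test_monomorphic_reference(self):
        col = pd.Series([0, 0, 0, 0], name="m")
        allele, freq = minor_allele_frequency(col, BI)
        assert allele == "G" and freq == 0.0

    def test_simplex_in_8_of_208_is_below_one_percent(self):
        col = pd.Series([1] * 8 + [0] * 200, name="m")
        _, freq = minor_allele_frequency(col)
        assert freq == pytest.approx(8 / 832)
        assert freq < 0.01

    def test_single_quadruplex_carrier(self):
        col = pd.Series([4, 0, 0, 0], name="m")
        _, freq = minor_allele_frequency(col)
        assert freq == 0.25

    def test_major_alt_flips_to_reference_allele(self):
        col = pd.Series([4, 4, 4, 2], name="m")
        allele, freq = minor_allele_frequency(col, BI)
        assert allele == "A"
        assert freq == pytest.approx(2 / 16)
        _, _, md = mfa_dosage(col, BI)
        assert list(md) == [0, 0, 0, 2]

    def test_frequency_bounded_and_recovers_simulated_p(self):
        rng = np.random.default_rng(40)
        p, n, reps = 0.3, 208, 300
        est = []
        for _ in range(reps):
            col = pd.Series(simulate_dosages(n, p, rng), name="m")
            _, f = minor_allele_frequency(col)
            assert 0.0 <= f <= 0.5
            est.append(f)
        se = np.sqrt(p * (1 - p) / (4 * n * reps))
        assert abs(np.mean(est) - min(p, 1 - p)) < 3 * se

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            minor_allele_frequency(pd.Series([np.nan, np.nan], name="m"))

    def test_presence_absence_two_frequencies(self):
        col = pd.Series([1, 0, 0, 0, 0, 0, 0, 0], name="m")
        carrier_frac, simplex_copy = presence_absence_frequency(col)
        assert carrier_frac == 0.125
        assert simplex_copy == 0.125 / 4


class TestMfaFilter:
    def _matrix(self, carriers, n=208):
        col = [1] * carriers + [0] * (n - carriers)
        return DosageMatrix(pd.DataFrame({"m": col}))

    def test_seven_carriers_dropped_at_discovery_threshold(self):
        assert apply_mfa_filter(self._matrix(7), 8) == []

    def test_eight_carriers_retained_at_boundary(self):
        assert apply_mfa_filter(self._matrix(8), 8) == ["m"]

    def test_monomorphic_markers_all_dropped(self):
        m = DosageMatrix(pd.DataFrame({"a": [0] * 10, "b": [4] * 10}))
        assert apply_mfa_filter(m, 3) == []

    def test_high_missing_flagging(self, small_matrix):
        values = small_matrix.values.copy()
        values.loc[values.index[:2], "GWD-A_3452_G"] = np.nan
        m = DosageMatrix(values)
        assert "GWD-A_3452_G" in m.high_missing_markers(threshold=0.2)


class TestDosageMatrixValidation:
    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            DosageMatrix(pd.DataFrame({"m": [0, 5]}))

    def test_presence_absence_range(self):
        with pytest.raises(ValueError):
            DosageMatrix(pd.DataFrame({"m": [0, 2]}), modes={"m": "presence_absence"})

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame({"m": [0, 1]}, index=["a", "a"])
        with pytest.raises(ValueError):
            DosageMatrix(df)
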