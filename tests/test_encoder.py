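import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psesplice import (
    EncoderParams,
    Label,
    LabeledDataset,
    SpliceSequence,
    builtin_table,
    dnc,
    encode_dataset,
    ktuple_composition,
    nac,
    psednc,
    theta_correlation,
    tier_factors,
)
from _oracles import bf_psednc, bf_theta, bf_tier_factors

DI = [a + b for a in "ACGT" for b in "ACGT"]

sequences = st.text(alphabet="ACGT", min_size=10, max_size=30)


class TestCompositionEncoders:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", (1, 0, 0, 0)),
            ("ACGT", (0.25, 0.25, 0.25, 0.25)),
            ("AAC", (2 / 3, 1 / 3, 0, 0)),
        ],
    )
    def test_nac(self, seq, expected):
        assert nac(seq).values == pytest.approx(expected)

    def test_nac_empty_rejected(self):
        with pytest.raises(ValueError):
            nac("")

    def test_ktuple_k1_equals_nac(self):
        assert ktuple_composition("ACGGTTA", 1).values == pytest.approx(
            nac("ACGGTTA").values
        )

    def test_ktuple_k2_homopolymer(self):
        v = ktuple_composition("AAAA", 2).values
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_ktuple_k3_has_64_components(self):
        assert len(ktuple_composition("ACGTACGT", 3)) == 64

    def test_ktuple_too_short_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ktuple_composition("AC", 3)

    def test_large_k_needs_override(self):
        seq = "ACGT" * 5
        with pytest.raises(ValueError, match="allow_large"):
            ktuple_composition(seq, 8)
        assert len(ktuple_composition(seq, 8, allow_large=True)) == 4**8

    @pytest.mark.parametrize(
        "seq,nonzero",
        [
            ("AAAC", {"AA": 2 / 3, "AC": 1 / 3}),
            ("ACGT", {"AC": 1 / 3, "CG": 1 / 3, "GT": 1 / 3}),
        ],
    )
    def test_dnc_examples(self, seq, nonzero):
        fv = dnc(seq)
        for name, value in zip(fv.names, fv.values):
            assert value == pytest.approx(nonzero.get(name, 0.0))

    @given(seq=st.text(alphabet="ACGT", min_size=2, max_size=50))
    @settings(max_examples=50, derandomize=True)
    def test_dnc_sums_to_one(self, seq):
        assert dnc(seq).values.sum() == pytest.approx(1.0, abs=1e-12)


class TestThetaCorrelation:
    def test_identical_rows_zero(self):
        assert theta_correlation("AA", "AA") == 0.0
        # AA and TT share identical standardized property rows
        assert theta_correlation("AA", "TT") == 0.0

    def test_worked_value(self):
        assert theta_correlation("AA", "AC") == pytest.approx(1.200167, abs=1e-6)

    def test_matches_brute_force_everywhere(self):
        for d1, d2 in itertools.product(DI, DI):
            assert theta_correlation(d1, d2) == pytest.approx(bf_theta(d1, d2))

    def test_symmetric_and_nonnegative(self):
        for d1, d2 in itertools.product(DI, DI):
            v = theta_correlation(d1, d2)
            assert v >= 0.0
            assert v == pytest.approx(theta_correlation(d2, d1))

    def test_invariant_under_complementing_both_arguments(self):
        comp = str.maketrans("ACGT", "TGCA")
        for d1, d2 in itertools.product(DI, DI):
            rc1 = d1.translate(comp)[::-1]
            rc2 = d2.translate(comp)[::-1]
            assert theta_correlation(d1, d2) == pytest.approx(
                theta_correlation(rc1, rc2)
            )

    def test_unknown_dinucleotide_rejected(self):
        with pytest.raises(KeyError):
            theta_correlation("AN", "AC")


class TestTierFactors:
    def test_homopolymer_all_zero(self):
        assert tier_factors("A" * 20, 5) == pytest.approx(np.zeros(5))

    def test_worked_value(self):
        assert tier_factors("AAAC", 1)[0] == pytest.approx(0.600083, abs=1e-6)

    def test_lambda_too_large_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            tier_factors("ACGT", 3)

    @given(seq=sequences, lam=st.integers(1, 8))
    @settings(max_examples=60, derandomize=True)
    def test_matches_brute_force(self, seq, lam):
        assert tier_factors(seq, lam) == pytest.approx(
            bf_tier_factors(seq, lam), abs=1e-12
        )


class TestPseDNC:
    def test_worked_example(self):
        fv = psednc("AAAC", EncoderParams(lam=1, weight=0.5))
        assert fv.values[0] == pytest.approx(0.51280, abs=1e-5)   # AA
        assert fv.values[1] == pytest.approx(0.25640, abs=1e-5)   # AC
        assert fv.values[16] == pytest.approx(0.23079, abs=1e-5)  # theta tier
        assert fv.values[2:16].sum() == 0.0

    def test_zero_weight_reduces_to_padded_dnc(self):
        fv = psednc("ACGTTGCA", EncoderParams(lam=3, weight=0.0))
        assert fv.values[:16] == pytest.approx(dnc("ACGTTGCA").values)
        assert fv.values[16:] == pytest.approx(np.zeros(3))

    @given(
        seq=sequences,
        lam=st.integers(1, 8),
        w=st.sampled_from([0.0, 0.3, 0.5, 1.0]),
    )
    @settings(max_examples=60, derandomize=True)
    def test_matches_brute_force_and_sums_to_one(self, seq, lam, w):
        fv = psednc(seq, EncoderParams(lam=lam, weight=w))
        assert fv.values == pytest.approx(bf_psednc(seq, lam, w), abs=1e-10)
        assert fv.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert (fv.values >= 0).all()

    def test_increasing_weight_shrinks_composition_components(self):
        seq = "ACGTTGCAACGTTGCAACGT"
        lo = psednc(seq, EncoderParams(lam=4, weight=0.2)).values
        hi = psednc(seq, EncoderParams(lam=4, weight=0.8)).values
        comp = dnc(seq).values
        nonzero = comp > 0
        assert (hi[:16][nonzero] < lo[:16][nonzero]).all()

    def test_parameter_bounds_enforced_and_overridable(self):
        with pytest.raises(ValueError, match="lambda"):
            EncoderParams(lam=11, weight=0.3)
        with pytest.raises(ValueError, match="weight"):
            EncoderParams(lam=2, weight=1.5)
        params = EncoderParams(lam=11, weight=1.5, enforce_bounds=False)
        assert params.lam == 11

    def test_requires_standardized_table(self):
        with pytest.raises(ValueError, match="standardized"):
            EncoderParams(lam=2, weight=0.3, table=builtin_table("original"))


class TestEncodeDataset:
    def _dataset(self, n_pos=3, n_neg=2, length=40, seed=0):
        rng = np.random.default_rng(seed)
        seqs = []
        for i in range(n_pos + n_neg):
            label = Label.TRUE_SITE if i < n_pos else Label.FALSE_SITE
            residues = "".join(rng.choice(list("ACGT"), size=length))
            seqs.append(SpliceSequence(f"s{i}", residues, "donor", label))
        return LabeledDataset(seqs, "donor")

    @pytest.mark.parametrize("lam,width", [(4, 20), (2, 18), (10, 26)])
    def test_psednc_matrix_width(self, lam, width):
        fm = encode_dataset(self._dataset(), EncoderParams(lam=lam, weight=0.3))
        assert fm.X.shape == (5, width)

    def test_labels_mapped_to_signs(self):
        fm = encode_dataset(self._dataset(), EncoderParams(lam=2, weight=0.3))
        assert list(fm.y) == [1, 1, 1, -1, -1]

    def test_dnc_kind_width(self):
        fm = encode_dataset(self._dataset(), kind="dnc")
        assert fm.X.shape[1] == 16

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            encode_dataset(LabeledDataset([], "donor"), EncoderParams())

    def test_unlabeled_record_rejected(self):
        ds = LabeledDataset(
            [SpliceSequence("u", "ACGT" * 10, "donor", Label.UNLABELED)], "donor"
        )
        with pytest.raises(ValueError, match="unlabeled"):
            encode_dataset(ds, EncoderParams())

    def test_failure_names_offending_record(self):
        ds = LabeledDataset(
            [SpliceSequence("tiny", "ACGTA", "donor", Label.TRUE_SITE)], "donor"
        )
        with pytest.raises(ValueError, match="tiny"):
            encode_dataset(ds, EncoderParams(lam=8, weight=0.3))

    def test_tsv_and_libsvm_export(self, tmp_path):
        import pandas as pd

        fm = encode_dataset(self._dataset(), EncoderParams(lam=2, weight=0.3))
        tsv = tmp_path / "f.tsv"
        fm.to_tsv(tsv)
        df = pd.read_csv(tsv, sep="\t")
        assert list(df.columns[:2]) == ["id", "label"]
        assert df.shape == (5, 2 + 18)
        libsvm = tmp_path / "f.libsvm"
        fm.to_libsvm(libsvm)
        lines = libsvm.read_text().splitlines()
        assert len(lines) == 5
        assert lines[0].split()[0] in {"1", "-1"}
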