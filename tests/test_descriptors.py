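import numpy as np
import pytest

from oligostate.descriptors import (
    CLASS_WIDTHS,
    DescriptorConfig,
    class_feature_names,
    compute_aac,
    compute_apseaac,
    compute_class,
    compute_ctd,
    compute_ctriad,
    compute_dpc,
    compute_pseaac,
    compute_qso,
    compute_selected,
    compute_tpc,
)
from oligostate.descriptors.autocorrelation import autocorrelation_profile
from oligostate.descriptors.qso import coupling_numbers
from oligostate.scales import CTD_PROPERTIES
from oligostate.sequence_io import ALPHABET, ProteinRecord

from oracles import ORACLES

R = lambda seq, rid="x": ProteinRecord(id=rid, sequence=seq)


# ---------------------------------------------------------------- widths
@pytest.mark.parametrize("class_name,width", list(CLASS_WIDTHS.items()))
def test_class_width_matches_canonical_count(class_name, width, oracle_records):
    table = compute_class(oracle_records[:2], class_name)
    assert table.shape == (2, width)
    assert len(set(table.columns)) == width  # unique, deterministic names
    assert list(table.columns) == list(class_feature_names(class_name))


# ------------------------------------------------------------ composition
class TestComposition:
    def test_aac_homopolymer(self):
        vec = compute_aac(R("AAA"))
        assert vec[0] == 1.0 and vec[1:].sum() == 0.0

    def test_aac_uniform(self):
        assert np.allclose(compute_aac(R(ALPHABET)), 0.05)

    def test_aac_hand_example(self):
        vec = dict(zip(ALPHABET, compute_aac(R("MKV"))))
        assert vec["M"] == vec["K"] == vec["V"] == pytest.approx(1 / 3)

    def test_dpc_overlapping_windows(self):
        names = [f"DPC.{a}{b}" for a in ALPHABET for b in ALPHABET]
        vec = dict(zip(names, compute_dpc(R("ACAC"))))
        assert vec["DPC.AC"] == pytest.approx(2 / 3)
        assert vec["DPC.CA"] == pytest.approx(1 / 3)
        assert dict(zip(names, compute_dpc(R("AAA"))))["DPC.AA"] == 1.0
        assert dict(zip(names, compute_dpc(R("AC"))))["DPC.AC"] == 1.0

    def test_tpc_window_enumeration(self):
        tpc = compute_tpc(R("AAAA"))
        assert tpc[0] == 1.0 and tpc.sum() == 1.0
        assert compute_tpc(R("ACD")).sum() == 1.0

    def test_too_short_sequences_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            compute_dpc(R("A"))
        with pytest.raises(ValueError, match="too short"):
            compute_tpc(R("AC"))

    @pytest.mark.parametrize("fn", [compute_aac, compute_dpc, compute_tpc])
    def test_blocks_sum_to_one(self, fn, oracle_records):
        for rec in oracle_records[:5]:
            assert fn(rec).sum() == pytest.approx(1.0, abs=1e-9)


# -------------------------------------------------------- autocorrelation
class TestAutocorrelation:
    """Hand evaluations on the toy profile P=(1,2,3) at lag d=1."""

    def test_moreau_broto_toy(self):
        p = np.array([1.0, 2.0, 3.0])
        # unnormalized sum 1*2 + 2*3 = 8; divided by (N-d)=2 -> 4
        assert autocorrelation_profile(p, "moreau_broto", 1)[0] == pytest.approx(4.0)

    def test_moran_toy(self):
        p = np.array([1.0, 2.0, 3.0])
        assert autocorrelation_profile(p, "moran", 1)[0] == pytest.approx(0.0)

    def test_geary_toy(self):
        p = np.array([1.0, 2.0, 3.0])
        assert autocorrelation_profile(p, "geary", 1)[0] == pytest.approx(0.5)

    def test_zero_variance_profile_gives_zero(self):
        p = np.ones(40)
        assert np.all(autocorrelation_profile(p, "moran", 5) == 0.0)
        assert np.all(autocorrelation_profile(p, "geary", 5) == 0.0)

    def test_lag_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            autocorrelation_profile(np.arange(5.0), "moran", 5)


# -------------------------------------------------------------------- ctd
class TestCTD:
    def test_single_group_composition(self):
        # "RKEDQN" residues are all group 1 of the hydrophobicity property
        vec = dict(zip(class_feature_names("ctd"), compute_ctd(R("RKEDQN"))))
        assert vec["CTD.hydrophobicity.comp.g1"] == 1.0
        assert vec["CTD.hydrophobicity.comp.g2"] == 0.0
        assert vec["CTD.hydrophobicity.trans.g12"] == 0.0

    def test_transition_1212(self):
        # hydrophobicity encoding of "RGRG" is 1,2,1,2
        vec = dict(zip(class_feature_names("ctd"), compute_ctd(R("RGRG"))))
        assert vec["CTD.hydrophobicity.trans.g12"] == pytest.approx(1.0)

    def test_distribution_homopolymer(self):
        # 10 residues all in group 1: occurrence positions 1,3,5,8,10 -> percents
        vec = dict(zip(class_feature_names("ctd"), compute_ctd(R("R" * 10))))
        got = [vec[f"CTD.hydrophobicity.dist.g1.{q}"] for q in ("first", "p25", "p50", "p75", "p100")]
        assert got == pytest.approx([10.0, 30.0, 50.0, 80.0, 100.0])

    def test_absent_group_contributes_zeros(self):
        vec = dict(zip(class_feature_names("ctd"), compute_ctd(R("RK"))))
        assert all(vec[f"CTD.hydrophobicity.dist.g3.{q}"] == 0.0 for q in ("first", "p100"))

    def test_composition_block_sums_to_one_per_property(self, oracle_records):
        names = class_feature_names("ctd")
        vec = dict(zip(names, compute_ctd(oracle_records[0])))
        for prop in CTD_PROPERTIES:
            total = sum(vec[f"CTD.{prop}.comp.g{r}"] for r in (1, 2, 3))
            assert total == pytest.approx(1.0, abs=1e-9)


# ----------------------------------------------------------------- ctriad
class TestCTriad:
    def test_single_class_triads(self):
        vec = compute_ctriad(R("AAA"))
        assert vec[0] == 1.0 and vec.sum() == 1.0  # only triad (1,1,1)

    def test_class_equivalence(self):
        # A, G, V all map to class 1, so "AGV" equals "AAA"
        assert np.array_equal(compute_ctriad(R("AGV")), compute_ctriad(R("AAA")))


# -------------------------------------------------------------------- qso
class TestQSO:
    def test_toy_coupling_numbers(self):
        dist = np.zeros((20, 20))
        a, c = ALPHABET.index("A"), ALPHABET.index("C")
        dist[a, c] = dist[c, a] = 1.0
        codes = np.array([a, c, a])
        taus = coupling_numbers(codes, dist, 2)
        assert taus[0] == pytest.approx(2.0)  # 1^2 + 1^2
        assert taus[1] == pytest.approx(0.0)

    def test_lag_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            compute_qso(R("ACDEFGHIKL"), lag=30)


# ----------------------------------------------------------------- pseaac
class TestPseAAC:
    def test_vectors_sum_to_one(self, oracle_records):
        for rec in oracle_records[:5]:
            assert compute_pseaac(rec).sum() == pytest.approx(1.0, abs=1e-9)
            assert compute_apseaac(rec).sum() == pytest.approx(1.0, abs=1e-9)

    def test_homopolymer_brute_force(self):
        # all theta terms vanish on a homopolymer, so tau = 0 and the vector
        # collapses to the plain composition
        vec = compute_pseaac(R("A" * 40))
        assert vec[0] == pytest.approx(1.0)
        assert np.allclose(vec[1:], 0.0)

    def test_homopolymer_apseaac_constant_taus(self):
        # H1/H2 products are the same constant at every lag on a homopolymer
        vec = compute_apseaac(R("A" * 40))
        h1_taus = vec[20::2]
        assert np.allclose(h1_taus, h1_taus[0])

    def test_lambda_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            compute_pseaac(R("ACDEFGHIKL"), lam=30)


# ----------------------------------------------- naive-loop oracle checks
@pytest.mark.parametrize("class_name", list(ORACLES))
def test_descriptor_family_matches_naive_oracle(class_name, oracle_records):
    """Every family agrees with an independent loop implementation to 1e-9."""
    table = compute_class(oracle_records, class_name)
    for rec in oracle_records:
        expected = np.array(ORACLES[class_name](rec.sequence))
        np.testing.assert_allclose(
            table.loc[rec.id].to_numpy(), expected, atol=1e-9, rtol=0,
            err_msg=f"{class_name} mismatch on {rec.id}",
        )


# -------------------------------------------------------- selected-feature
class TestComputeSelected:
    def test_hand_example(self):
        table = compute_selected([R("RMYLI")], ["RMY", "LI"])
        assert table.loc["x", "TPC.RMY"] == pytest.approx(1 / 3)
        assert table.loc["x", "DPC.LI"] == pytest.approx(1 / 4)

    def test_equivalent_to_full_table_projection(self, oracle_records):
        recs = oracle_records[:20]
        full = compute_class(recs, "aac_dpc_tpc")
        rng = np.random.default_rng(5)
        names = list(rng.choice(full.columns, size=15, replace=False))
        sel = compute_selected(recs, names)
        for name in names:
            np.testing.assert_allclose(sel[name].to_numpy(), full[name].to_numpy(), atol=1e-12)

    def test_non_composition_features_supported(self, oracle_records):
        recs = oracle_records[:3]
        name = "CTD.hydrophobicity.comp.g1"
        sel = compute_selected(recs, [name])
        full = compute_class(recs, "ctd")
        np.testing.assert_allclose(sel[name].to_numpy(), full[name].to_numpy())

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            compute_selected([R("RMYLI")], ["ZZZ"])


def test_descriptors_invariant_to_id_and_wrapping(oracle_records):
    rec = oracle_records[0]
    renamed = ProteinRecord(id="other", sequence=rec.sequence)
    a = compute_class([rec], "qso").to_numpy()
    b = compute_class([renamed], "qso").to_numpy()
    np.testing.assert_array_equal(a, b)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        DescriptorConfig(lag=0)
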