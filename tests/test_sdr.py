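import math

import numpy as np
import pytest

from kinspec import KinaseSpecificityModel
from kinspec.alphabets import GAP, N_SUBSTRATE, SUBSTRATE_ALPHABET
from kinspec.io_formats import AlignedDomainSet
from kinspec.matrices import ConsensusSequence, ProfileMatrix, build_consensus, build_profile
from kinspec.sdr import (
    JointDistribution,
    ResidueInteractionMatrix,
    SDRMap,
    charge_dependency,
    column_distributions_profile_based,
    combined_dependency,
    consensus_codes,
    default_interaction_matrix,
    expected_interaction,
    find_sdrs,
    mutual_information,
)

from conftest import random_profile


def brute_force_mi(joint: np.ndarray) -> float:
    """Independent double-loop MI oracle (bits)."""
    p1 = joint.sum(axis=1)
    p2 = joint.sum(axis=0)
    total = 0.0
    for x in range(joint.shape[0]):
        for y in range(joint.shape[1]):
            if joint[x, y] > 0:
                total += joint[x, y] * math.log2(joint[x, y] / (p1[x] * p2[y]))
    return total


def random_joint(rng, shape=(4, 4)) -> np.ndarray:
    j = rng.random(shape)
    return j / j.sum()


class TestInteractionMatrix:
    @pytest.mark.parametrize(
        "substrate,domain,score",
        [
            ("R", "E", +2.0),  # opposite charges attract
            ("E", "R", +2.0),
            ("E", "E", -2.0),  # like charges repel
            ("K", "R", -2.0),
            ("H", "D", +1.0),  # weakly positive histidine
            ("H", "K", -1.0),
            ("H", "H", -1.0),
            ("L", "V", +2.0),  # hydrophobics attract
            ("F", "K", -1.0),  # hydrophobic vs charged
            ("E", "L", -1.0),
            ("S", "T", +0.5),  # hydroxyl residues weakly bind
            ("S", "A", 0.0),
            ("G", "E", +0.5),  # substrate-side glycine favored
            ("P", "E", 0.0),
            ("A", "G", 0.0),  # domain-side glycine carries no bonus
            ("x", "E", 0.0),
            ("R", GAP, 0.0),
        ],
    )
    def test_default_entries(self, substrate, domain, score):
        R = default_interaction_matrix()
        assert R.score(substrate, domain) == score

    def test_symmetric_except_substrate_only_rows(self):
        R = default_interaction_matrix().values[:20, :20]
        from kinspec.alphabets import AMINO_ACIDS

        g = AMINO_ACIDS.index("G")
        p = AMINO_ACIDS.index("P")
        mask = np.ones((20, 20), dtype=bool)
        mask[g, :] = mask[:, g] = mask[p, :] = mask[:, p] = False
        np.testing.assert_array_equal(R[mask], R.T[mask])

    def test_gap_column_and_x_row_zero(self):
        R = default_interaction_matrix().values
        assert (R[:, -1] == 0).all()
        assert (R[-1, :] == 0).all()

    def test_tsv_round_trip(self, tmp_path):
        R = default_interaction_matrix()
        path = tmp_path / "R.tsv"
        R.to_tsv(path)
        back = ResidueInteractionMatrix.from_tsv(path)
        np.testing.assert_array_equal(back.values, R.values)


class TestMutualInformation:
    def test_constant_variable_gives_zero(self):
        joint = np.zeros((3, 3))
        joint[0] = [0.2, 0.3, 0.5]  # X constant, Y varies
        assert mutual_information(joint) == 0.0

    def test_perfect_two_symbol_correspondence_is_one_bit(self):
        joint = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert mutual_information(joint) == pytest.approx(1.0)

    def test_brute_force_oracle_random_joints(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            joint = random_joint(rng)
            assert mutual_information(joint) == pytest.approx(brute_force_mi(joint))

    def test_non_negative_and_zero_on_factorized(self):
        rng = np.random.default_rng(18)
        for _ in range(25):
            joint = random_joint(rng)
            assert mutual_information(joint) >= 0.0
            p1 = joint.sum(axis=1)
            p2 = joint.sum(axis=0)
            assert mutual_information(np.outer(p1, p2)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_under_transpose(self):
        rng = np.random.default_rng(19)
        joint = random_joint(rng, (5, 3))
        assert mutual_information(joint) == pytest.approx(mutual_information(joint.T))


class TestChargeDependency:
    def test_printed_entry_means(self):
        R = default_interaction_matrix()
        # domain E with consensus R then K: both +2
        assert charge_dependency(["E", "E"], ["R", "K"], R) == pytest.approx(2.0)
        # attract (+2) and repel (-2) average out
        assert charge_dependency(["E", "E"], ["R", "E"], R) == pytest.approx(0.0)

    def test_all_x_consensus_contributes_zero(self):
        R = default_interaction_matrix()
        assert charge_dependency(["E", "K", "L"], ["x", "x", "x"], R) == 0.0

    def test_lowercase_consensus_folds_to_identity(self):
        R = default_interaction_matrix()
        assert charge_dependency(["E"], ["r"], R) == charge_dependency(["E"], ["R"], R)

    def test_permutation_invariance_and_linearity(self):
        R = default_interaction_matrix()
        dom, sub = list("EKLRD"), list("RKIDE")
        base = charge_dependency(dom, sub, R)
        assert charge_dependency(dom[::-1], sub[::-1], R) == pytest.approx(base)
        scaled = ResidueInteractionMatrix(3.0 * R.values)
        assert charge_dependency(dom, sub, scaled) == pytest.approx(3.0 * base)

    def test_errors(self):
        R = default_interaction_matrix()
        with pytest.raises(ValueError):
            charge_dependency([], [], R)
        with pytest.raises(ValueError):
            charge_dependency(["E"], ["R", "K"], R)

    def test_expected_interaction_matches_empirical_mean(self):
        # the joint-expectation form reduces to the mean over kinases
        R = default_interaction_matrix()
        dom, sub = list("EEKKLF"), list("RKEEID")
        from kinspec.alphabets import DOMAIN_INDEX, SUBSTRATE_INDEX

        joint = np.zeros((21, 21))
        for x, y in zip(dom, sub):
            joint[DOMAIN_INDEX[x], SUBSTRATE_INDEX[y]] += 1 / len(dom)
        assert expected_interaction(joint, R) == pytest.approx(
            charge_dependency(dom, sub, R)
        )


class TestCombinedDependency:
    def test_zero_factor_cases(self):
        # conserved column: I = 0 kills any charge score
        assert combined_dependency(0.0, 2.0) == 0.0
        assert combined_dependency(1.0, 0.0) == 0.0

    def test_product_oracle(self):
        assert combined_dependency(0.5, 2.0) == pytest.approx(0.5 * 2.0)
        assert combined_dependency(0.3, -1.5) == pytest.approx(-0.45)

    def test_sum_mode_and_errors(self):
        assert combined_dependency(0.5, 2.0, mode="sum") == pytest.approx(2.5)
        with pytest.raises(ValueError):
            combined_dependency(-0.1, 1.0)
        with pytest.raises(ValueError):
            combined_dependency(0.1, 1.0, mode="median")


class TestProfileBasedDistributions:
    def _two_kinase_setup(self):
        rng = np.random.default_rng(23)
        domains = AlignedDomainSet({"k1": "EA", "k2": "KA"})
        profiles = {
            "k1": ProfileMatrix("k1", random_profile(rng)),
            "k2": ProfileMatrix("k2", random_profile(rng)),
        }
        return domains, profiles

    def test_degenerate_marginal_point_mass(self):
        rng = np.random.default_rng(24)
        domains = AlignedDomainSet({"k1": "EA", "k2": "EC"})
        profiles = {
            "k1": ProfileMatrix("k1", random_profile(rng)),
            "k2": ProfileMatrix("k2", random_profile(rng)),
        }
        p1, p2, joint = column_distributions_profile_based(domains, profiles, 0, -3)
        from kinspec.alphabets import DOMAIN_INDEX

        e = DOMAIN_INDEX["E"]
        assert p1.probs[e] == pytest.approx(1.0)
        np.testing.assert_allclose(joint.probs[e], p2.probs)

    def test_two_kinase_hand_oracle(self):
        domains, profiles = self._two_kinase_setup()
        offset = +2
        p1, p2, joint = column_distributions_profile_based(domains, profiles, 0, offset)
        from kinspec.alphabets import DOMAIN_INDEX, offset_to_col

        j = offset_to_col(offset)
        q1 = profiles["k1"].probs[:, j]
        q2 = profiles["k2"].probs[:, j]
        np.testing.assert_allclose(joint.probs[DOMAIN_INDEX["E"]], q1 / 2)
        np.testing.assert_allclose(joint.probs[DOMAIN_INDEX["K"]], q2 / 2)
        np.testing.assert_allclose(p2.probs, (q1 + q2) / 2)

    def test_marginalization_identity(self):
        domains, profiles = self._two_kinase_setup()
        p1, p2, joint = column_distributions_profile_based(domains, profiles, 1, 0)
        np.testing.assert_allclose(joint.probs.sum(axis=1), p1.probs, atol=1e-12)
        np.testing.assert_allclose(joint.probs.sum(axis=0), p2.probs, atol=1e-12)


class TestFindSdrs:
    def test_m_validation(self, small_family):
        info = {
            k: ProfileMatrix(k, p.probs) for k, p in small_family.truth_profiles.items()
        }
        with pytest.raises(ValueError):
            find_sdrs(small_family.domains, info, m=0)

    def test_fully_conserved_alignment_is_uninformative(self):
        domains = AlignedDomainSet({f"k{i}": "AAAA" for i in range(6)})
        cons = {f"k{i}": ConsensusSequence(f"k{i}", "RRRRRRRSRRRRRRR") for i in range(6)}
        sdr_map = find_sdrs(domains, cons)
        assert all(sdr_map.is_uninformative(o) for o in sdr_map.offsets)

    def test_at_most_m_columns_per_offset(self, small_family):
        model = KinaseSpecificityModel(
            small_family.records, small_family.domains, variant="profile", m=3
        )
        sdr_map = model.fit().sdr_map_
        assert all(len(sels) <= 3 for sels in sdr_map.offsets.values())

    def test_planted_column_ranks_first(self, small_family):
        results = KinaseSpecificityModel(
            small_family.records, small_family.domains, variant="profile"
        ).fit()
        planted = small_family.model.planted[-3].column
        assert results.sdr_map_.selections(-3)[0].column == planted

    def test_consensus_variant_also_recovers(self, small_family):
        results = KinaseSpecificityModel(
            small_family.records, small_family.domains, variant="consensus"
        ).fit()
        planted = small_family.model.planted[-3].column
        assert results.sdr_map_.selections(-3)[0].column == planted

    def test_weights_normalized_and_positive(self, small_family):
        results = KinaseSpecificityModel(
            small_family.records, small_family.domains, variant="profile"
        ).fit()
        for sels in results.sdr_map_.offsets.values():
            if sels:
                assert all(s.weight > 0 and s.combined > 0 for s in sels)
                assert sum(s.weight for s in sels) == pytest.approx(1.0)

    def test_deterministic_output(self, small_family):
        info = {
            k: ProfileMatrix(k, p.probs) for k, p in small_family.truth_profiles.items()
        }
        a = find_sdrs(small_family.domains, info)
        b = find_sdrs(small_family.domains, info)
        assert a.to_json() == b.to_json()

    def test_json_round_trip(self, small_family, tmp_path):
        info = {
            k: ProfileMatrix(k, p.probs) for k, p in small_family.truth_profiles.items()
        }
        sdr_map = find_sdrs(small_family.domains, info)
        path = tmp_path / "sdr.json"
        sdr_map.to_json(path)
        back = SDRMap.from_json(path)
        assert back.to_json() == sdr_map.to_json()

    def test_mi_base_change_preserves_ranking(self, small_family):
        # scaling all MI values by a constant (change of log base) cannot
        # change the selected columns or their order
        info = {
            k: ProfileMatrix(k, p.probs) for k, p in small_family.truth_profiles.items()
        }
        sdr_map = find_sdrs(small_family.domains, info)
        for sels in sdr_map.offsets.values():
            scaled = sorted(
                sels, key=lambda s: (-s.mi * math.log(2) * s.charge, s.column)
            )
            assert [s.column for s in scaled] == [s.column for s in sels]


def test_consensus_codes_fold_case():
    cons = ConsensusSequence("k", "RrxxxxxSxxxxxxx")
    codes = consensus_codes(cons)
    assert codes[0] == codes[1] == SUBSTRATE_ALPHABET.index("R")
    assert codes[2] == SUBSTRATE_ALPHABET.index("x")
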