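"""EGF-like toxin mining, mature derivation, MW/pI, scaffold and naming."""

import numpy as np
import pytest

from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint as BioIsoelectricPoint

from myrmitox.egf import (
    adjust_signal,
    assign_names,
    classify_egf_type,
    cysteine_scaffold,
    derive_mature,
    isoelectric_point,
    mine_egf,
    molecular_weight,
    net_charge,
)
from myrmitox.sequence import SequenceRecord, find_orfs
from myrmitox.simulate import generate_egf_precursor

from oracles import pi_grid_search


class TestGenerateEgfPrecursor:
    def test_precursor_length_is_signal_plus_mature(self):
        protein, _ = generate_egf_precursor(30, 49, (4, 3, 7, 1, 10), seed=0)
        assert len(protein) == 79

    def test_exactly_six_cysteines_at_spacing(self):
        protein, _ = generate_egf_precursor(30, 49, (4, 3, 7, 1, 10), seed=1)
        signal, mature = protein[:30], protein[30:]
        assert "C" not in signal
        positions, spacing, canonical = cysteine_scaffold(mature)
        assert canonical and spacing == (4, 3, 7, 1, 10)

    def test_nucleotide_translates_to_protein(self):
        from myrmitox.sequence import translate

        for seed in range(100):
            protein, nt = generate_egf_precursor(30, 50, (3, 4, 5, 6, 7), seed=seed)
            # independent codon-table oracle
            from Bio.Seq import Seq

            assert str(Seq(nt).translate()) == protein
            assert translate(nt) == protein

    def test_inconsistent_spacing_rejected(self):
        with pytest.raises(ValueError):
            generate_egf_precursor(30, 20, (4, 3, 7, 1, 10), seed=0)


class TestMining:
    def test_seed_matches_itself_at_full_coverage(self):
        protein, nt = generate_egf_precursor(30, 49, (4, 3, 7, 1, 10), seed=3)
        rec = SequenceRecord("tx", "TAA" + nt + "TAA")
        orfs = find_orfs(rec, min_aa=10)
        seeds = [SequenceRecord("seed1", protein, alphabet="aa")]
        mined = mine_egf(orfs, seeds)
        assert len(mined) == 1
        assert mined[0].precursor_seq == protein

    def test_partial_coverage_dropped(self):
        protein, _ = generate_egf_precursor(30, 49, (4, 3, 7, 1, 10), seed=4)
        truncated, nt_trunc = protein[: int(len(protein) * 0.95)], None
        from myrmitox.simulate import encode_protein

        rng = np.random.default_rng(0)
        rec = SequenceRecord("tx", "TAA" + encode_protein(truncated, rng) + "TAA")
        orfs = find_orfs(rec, min_aa=10)
        mined = mine_egf(orfs, [SequenceRecord("seed1", protein, alphabet="aa")])
        assert mined == []

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            mine_egf([], [])


class TestSignalAndMature:
    def test_prediction_adjusted_to_reference(self):
        assert adjust_signal(28, 30, 79) == 30

    def test_prediction_equal_to_reference_unchanged(self):
        assert adjust_signal(30, 30, 79) == 30

    def test_no_reference_keeps_prediction(self):
        assert adjust_signal(28, None, 79) == 28

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            adjust_signal(28, 80, 79)

    @pytest.mark.parametrize(
        "precursor_len,signal,mature", [(79, 30, 49), (86, 30, 56), (76, 30, 46), (81, 30, 51)]
    )
    def test_mature_lengths(self, precursor_len, signal, mature):
        seq = "A" * precursor_len
        assert len(derive_mature(seq, signal)) == mature

    def test_signal_zero_is_identity(self):
        assert derive_mature("ACDEFGHIKLMN", 0) == "ACDEFGHIKLMN"

    def test_signal_out_of_range(self):
        with pytest.raises(ValueError):
            derive_mature("ACDE", 4)


class TestMolecularWeight:
    def test_glycine(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_diglycine(self):
        assert molecular_weight("GG") == pytest.approx(132.12, abs=0.01)

    def test_monotone_in_length(self):
        base = "ACDEFGHIK"
        for extra in "ACDEFGHIKLMNPQRSTVWY":
            assert molecular_weight(base + extra) > molecular_weight(base)

    def test_matches_biopython_average_masses(self):
        rng = np.random.default_rng(31)
        from Bio.SeqUtils import molecular_weight as bio_mw

        for _ in range(20):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=30))
            assert molecular_weight(seq) == pytest.approx(
                bio_mw(seq, seq_type="protein", monoisotopic=False), abs=0.5
            )

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            molecular_weight("ACDEZ1")


class TestIsoelectricPoint:
    def test_matches_grid_search(self):
        rng = np.random.default_rng(33)
        seqs = ["GGG", "DDDD", "KKKK", "ACDEFGHIKLMNPQRSTVWY"]
        seqs += [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=25)) for _ in range(6)
        ]
        for seq in seqs:
            assert isoelectric_point(seq) == pytest.approx(
                pi_grid_search(net_charge, seq), abs=2e-3
            )

    def test_charge_sign_extremes(self):
        assert isoelectric_point("DDDD") < 4.5
        assert isoelectric_point("KKKK") > 9.0

    def test_acidic_residue_never_raises_pi(self):
        # inserted internally so the terminal pKa overrides stay fixed
        rng = np.random.default_rng(34)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=20))
            with_d = seq[:10] + "D" + seq[10:]
            with_k = seq[:10] + "K" + seq[10:]
            assert isoelectric_point(with_d) <= isoelectric_point(seq) + 1e-6
            assert isoelectric_point(with_k) >= isoelectric_point(seq) - 1e-6

    def test_cross_check_against_independent_implementation(self):
        rng = np.random.default_rng(35)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
            assert isoelectric_point(seq) == pytest.approx(
                BioIsoelectricPoint(seq).pi(), abs=0.05
            )


class TestScaffold:
    def test_positions_to_spacing(self):
        mature = list("X" * 40)
        for pos in (5, 10, 14, 22, 24, 35):
            mature[pos - 1] = "C"
        mature = "".join(mature).replace("X", "A")
        positions, spacing, canonical = cysteine_scaffold(mature)
        assert positions == (5, 10, 14, 22, 24, 35)
        assert spacing == (4, 3, 7, 1, 10)
        assert canonical

    def test_five_cysteines_not_canonical(self):
        _, _, canonical = cysteine_scaffold("CACACACAC"[:9])
        assert not canonical

    def test_generator_scaffolds_recovered(self):
        for seed in range(100):
            spacing = tuple(int(x) for x in np.random.default_rng(seed).integers(0, 8, 5))
            mature_len = 6 + sum(spacing) + 10
            protein, _ = generate_egf_precursor(30, mature_len, spacing, seed=seed)
            _, got, canonical = cysteine_scaffold(protein[30:])
            assert canonical and got == spacing


class TestNaming:
    def test_first_and_fifth_names(self):
        matures = [f"SEQ{i}" + "A" * 10 for i in range(5)]
        names = assign_names(matures, "Mrub")
        assert names[matures[0]] == "U-MYRTX-Mrub1a"
        names = assign_names(matures, "Mrug")
        assert names[matures[4]] == "U-MYRTX-Mrug1e"

    def test_identical_matures_share_one_name(self):
        names = assign_names(["AAAA", "BBBB", "AAAA"], "Mrub")
        assert len(names) == 2
        assert names["BBBB"] == "U-MYRTX-Mrub1b"

    def test_injective_and_stable(self):
        matures = [f"M{i}" + "W" * 8 for i in range(26)]
        names1 = assign_names(matures, "Mrub")
        names2 = assign_names(matures, "Mrub")
        assert names1 == names2
        assert len(set(names1.values())) == len(matures)

    def test_overflow(self):
        with pytest.raises(ValueError):
            assign_names([f"M{i:02d}" + "W" * 8 for i in range(27)], "Mrub")


class TestClassification:
    def _panel(self, entries):
        return [
            {"id": pid, "seq": seq, "type": typ, "verified": ver}
            for pid, seq, typ, ver in entries
        ]

    def test_self_match(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEF"
        panel = self._panel([("p1", seq, "Vertebrate TGF-like", True)])
        pid, sim, label = classify_egf_type(seq, panel)
        assert pid == "p1" and sim == pytest.approx(100.0)
        assert label == "Vertebrate TGF-like"

    def test_verified_preferred_over_closer_unverified(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEF"
        near_decoy = seq[:-1] + "W"  # nearly identical but unverified
        verified_rel = seq[:20] + "WWWWW"
        panel = self._panel(
            [
                ("decoy", near_decoy, "predicted only", False),
                ("hormone", verified_rel, "Vertebrate epiregulin-like", True),
            ]
        )
        pid, _, label = classify_egf_type(seq, panel)
        assert pid == "hormone" and label == "Vertebrate epiregulin-like"

    def test_length_window_excludes_short_entries(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"  # 30 residues
        short = seq[:10]  # identical prefix, 10 residues: outside ±50%
        panel = self._panel([("short", short, "Vertebrate TGF-like", True)])
        pid, _, label = classify_egf_type(seq, panel)
        assert pid is None and label == "unclassified"

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            classify_egf_type("ACDEF", [])
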