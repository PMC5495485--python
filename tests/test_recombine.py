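import numpy as np
import pytest

from thermoinv.seqio import Interval, reverse_complement
from thermoinv.recombine import (
    AttSite,
    GeometryError,
    IncompatibleSitesError,
    Molecule,
    digest,
    homologous_recombine,
    molecule_from_dict,
    molecule_to_dict,
    pcr_predict,
    site_recombine,
)
from thermoinv.simulate import build_construct_map


def _random_mol(n, seed, circular=True, mid="m"):
    rng = np.random.default_rng(seed)
    return Molecule(mid, "".join(rng.choice(list("ACGT"), size=n)), circular=circular)


def _site(name, start, length, strand="+"):
    return AttSite(name, Interval(start, start + length), Interval(start, start + length), strand)


class TestExcision:
    def test_pmc479_releases_849bp_circle(self):
        mol = build_construct_map("pMC479_like", seed=1)
        res = site_recombine(
            mol, mol.site_by_name("attB_long"), site_b=mol.site_by_name("attB_short")
        )
        assert res.reaction == "excision"
        sizes = sorted(len(p) for p in res.products)
        assert sizes == [849, len(mol) - 849]
        circle = [p for p in res.products if len(p) == 849][0]
        assert circle.circular
        # the excised circle carries the long (87 bp) hybrid site
        assert len(circle.sites) == 1 and len(circle.sites[0].location) == 87

    def test_pmc479_digest_pattern(self):
        mol = build_construct_map("pMC479_like", seed=1)
        assert digest(mol, "CATATG").fragments == (3207, 1366)
        res = site_recombine(
            mol, mol.site_by_name("attB_long"), site_b=mol.site_by_name("attB_short")
        )
        circle = [p for p in res.products if len(p) == 849][0]
        backbone = [p for p in res.products if len(p) != 849][0]
        assert digest(circle, "CATATG").status == "uncut"
        assert digest(backbone, "CATATG").fragments == (2358, 1366)

    def test_linear_deletion(self):
        mol = _random_mol(2_000, 2, circular=False)
        seq = list(mol.seq)
        seq[100:140] = list(mol.seq[500:540])  # duplicate a 40 bp site
        mol = Molecule("lin", "".join(seq), circular=False)
        res = site_recombine(mol, _site("a", 100, 40), site_b=_site("b", 500, 40))
        kinds = sorted((p.circular, len(p)) for p in res.products)
        assert kinds == [(False, 1_600), (True, 400)]


class TestIntegration:
    def test_two_circles_become_one(self):
        a = _random_mol(3_000, 3, mid="A")
        b = _random_mol(2_000, 4, mid="B")
        shared = a.seq[500:620]
        b = Molecule("B", b.seq[:300] + shared + b.seq[420:], circular=True)
        res = site_recombine(a, _site("attP", 500, 120), b, _site("attB", 300, 120))
        assert res.reaction == "integration"
        assert len(res.products) == 1 and len(res.products[0]) == 5_000
        # hybrid attL/attR nomenclature
        assert {s.name for s in res.products[0].sites} >= {"attL", "attR"}
        # junction arithmetic: product is A and B each opened at its crossover
        pa, pb = 560, 360
        expected = a.seq[pa:] + a.seq[:pa] + b.seq[pb:] + b.seq[:pb]
        assert res.products[0].seq == expected

    def test_repeated_integration_multimer_ladder(self):
        a = _random_mol(2_500, 5, mid="mono")
        site = _site("attB", 700, 100)
        shared = a.seq[700:800]
        product = a
        for n in range(2, 5):
            cands = [s for s in product.sites if len(s.core) == 100]
            psite = cands[0] if cands else site
            res = site_recombine(product, psite, a, site)
            product = res.products[0]
            assert len(product) == n * 2_500

    def test_incompatible_cores_rejected(self):
        a = _random_mol(1_000, 6, mid="A")
        b = _random_mol(1_000, 7, mid="B")
        with pytest.raises(IncompatibleSitesError):
            site_recombine(a, _site("leu", 100, 43), b, _site("thr", 100, 43))


class TestInversion:
    def test_sequence_level_oracle_and_involution(self):
        mol = _random_mol(4_000, 8)
        core = mol.seq[300:400]
        seq = mol.seq[:1500] + reverse_complement(core) + mol.seq[1600:]
        mol = Molecule("inv", seq, circular=True)
        sa = _site("a", 300, 100, "+")
        sb = _site("b", 1500, 100, "-")
        res = site_recombine(mol, sa, site_b=sb)
        assert res.reaction == "inversion"
        prod = res.products[0]
        pa, pb = 350, 1550  # complementary crossover offsets (100 // 2)
        assert prod.seq == seq[:pa] + reverse_complement(seq[pa:pb]) + seq[pb:]
        again = site_recombine(prod, prod.sites[0], site_b=prod.sites[1])
        assert again.products[0].seq == seq

    def test_pmc477_digest_change(self):
        mol = build_construct_map("pMC477_like", seed=2)
        assert digest(mol, "CATATG").fragments == (2796, 1777)
        res = site_recombine(
            mol, mol.site_by_name("attB_long"), site_b=mol.site_by_name("attB_short")
        )
        assert digest(res.products[0], "CATATG").fragments == (2358, 2215)

    def test_direct_sites_requested_as_inversion(self):
        mol = build_construct_map("pMC479_like", seed=3)
        with pytest.raises(GeometryError):
            site_recombine(
                mol,
                mol.site_by_name("attB_long"),
                site_b=mol.site_by_name("attB_short"),
                reaction="inversion",
            )


class TestConservation:
    def test_nucleotides_conserved_across_random_reactions(self, rng):
        for trial in range(10):
            a = _random_mol(int(rng.integers(1_000, 3_000)), 100 + trial, mid="A")
            b = _random_mol(int(rng.integers(1_000, 3_000)), 200 + trial, mid="B")
            L = int(rng.integers(50, 200))
            start_a = int(rng.integers(0, len(a) - L))
            start_b = int(rng.integers(0, len(b) - L))
            shared = a.seq[start_a : start_a + L]
            b = Molecule("B", b.seq[:start_b] + shared + b.seq[start_b + L :], circular=True)
            res = site_recombine(
                a, _site("x", start_a, L), b, _site("y", start_b, L)
            )
            assert sum(len(p) for p in res.products) == len(a) + len(b)

    def test_excision_then_integration_is_identity_on_length(self):
        mol = build_construct_map("pMC479_like", seed=4)
        exc = site_recombine(
            mol, mol.site_by_name("attB_long"), site_b=mol.site_by_name("attB_short")
        )
        backbone, circle = exc.products
        re_int = site_recombine(
            backbone, backbone.sites[0], circle, circle.sites[0]
        )
        assert len(re_int.products) == 1
        assert len(re_int.products[0]) == len(mol)
        assert digest(re_int.products[0], "CATATG").fragments == (3207, 1366)


class TestHomologousRecombine:
    def test_identical_circles_dimerize(self):
        a = _random_mol(2_686, 9, mid="pBR")
        results = homologous_recombine(a, a, min_core=100)
        assert any(
            len(r.products) == 1 and len(r.products[0]) == 2 * len(a) for r in results
        )

    def test_threshold_boundary(self):
        base = _random_mol(3_000, 10)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for L, expect in ((99, 0), (100, 1)):
            core = base.seq[100 : 100 + L]
            seq = list(base.seq[:1500] + reverse_complement(core) + base.seq[1500 + L :])
            # forbid chance extension of the planted inverted segment
            a0, a1, b0 = 100, 100 + L, 1500
            if seq[b0 + L] == comp[seq[a0 - 1]]:
                seq[b0 + L] = seq[a0 - 1]
            if seq[b0 - 1] == comp[seq[a1]]:
                seq[b0 - 1] = seq[a1]
            mol = Molecule("m", "".join(seq), circular=False)
            res = homologous_recombine(mol, min_core=100)
            assert len(res) == expect
            if expect:
                assert res[0].reaction == "homologous_inversion"
                assert res[0].core_len == 100

    def test_single_120bp_shared_segment_product_verified(self):
        a = _random_mol(2_000, 11, mid="A")
        b0 = _random_mol(1_500, 12, mid="B")
        shared = a.seq[600:720]
        b = Molecule("B", b0.seq[:400] + shared + b0.seq[520:], circular=True)
        results = homologous_recombine(a, b, min_core=100)
        assert len(results) == 1
        res = results[0]
        assert res.core_len == 120 and res.reaction == "homologous_integration"
        pa, pb = 660, 460
        assert res.products[0].seq == a.seq[pa:] + a.seq[:pa] + b.seq[pb:] + b.seq[:pb]

    def test_min_core_one_on_identical_molecules_matches_site_behaviour(self):
        a = _random_mol(400, 13, mid="A")
        res = homologous_recombine(a, a, min_core=1)
        full = [r for r in res if r.core_len == 400]
        assert full and len(full[0].products[0]) == 800


class TestDigest:
    def test_circular_two_sites(self):
        mol = build_construct_map("pMC479_like", seed=5)
        d = digest(mol, "CATATG")
        assert sum(d.fragments) == len(mol) and len(d.fragments) == 2

    def test_linear_one_site(self):
        seq = "A" * 400 + "GGTCTC" + "A" * 594
        d = digest(Molecule("lin", seq, circular=False), "GGTCTC")
        assert sorted(d.fragments) == [400, 600]

    def test_uncut_circle(self):
        assert digest(_random_mol(300, 14), "GGTACCGG").status == "uncut"

    def test_both_strands_scanned(self):
        # non-palindromic recognition present only as reverse complement
        seq = "A" * 200 + reverse_complement("GGTCTC") + "A" * 294
        d = digest(Molecule("m", seq, circular=False), "GGTCTC")
        assert sorted(d.fragments) == [200, 300]

    def test_recognition_length_guard(self):
        with pytest.raises(ValueError):
            digest(_random_mol(100, 15), "ACG")


class TestPcrPredict:
    def test_convergent_primers_on_linear_template(self):
        mol = _random_mol(2_000, 16, circular=False)
        fwd = mol.seq[500:520]
        rev = reverse_complement(mol.seq[780:800])
        amps = pcr_predict(mol, fwd, rev)
        assert [a.length for a in amps] == [300]

    def test_outward_primers_require_circularization(self):
        mol = build_construct_map("TKV4_like", seed=17)
        fwd, rev = mol.primers["fwd"], mol.primers["rev"]
        assert pcr_predict(mol, fwd, rev, max_len=6_000) == []
        exc = site_recombine(mol, mol.site_by_name("attL"), site_b=mol.site_by_name("attR"))
        circle = [p for p in exc.products if p.circular][0]
        amps = pcr_predict(circle, fwd, rev, max_len=6_000)
        assert [a.length for a in amps] == [1_710]

    def test_primer_length_guard(self):
        with pytest.raises(ValueError):
            pcr_predict(_random_mol(100, 18), "ACGTACGT", "ACGTACGTACGTACG")


class TestMoleculeJson:
    def test_roundtrip(self):
        mol = build_construct_map("pMC477_like", seed=19)
        back = molecule_from_dict(molecule_to_dict(mol))
        assert back.seq == mol.seq and back.circular == mol.circular
        assert [s.name for s in back.sites] == [s.name for s in mol.sites]
        assert digest(back, "CATATG").fragments == digest(mol, "CATATG").fragments
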