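"""ORF finder and the Env/Gag motif grammar against brute-force oracles."""

import re

import numpy as np
import pytest

from erv_atlas import proteins, simulate

AA = proteins.AA20


def random_protein(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, size=n))


def oracle_orfs(seq, min_len_aa):
    """Naive per-frame regex ORF scan, forward strand only."""
    out = []
    stops = "TAA|TAG|TGA"
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        i = 0
        while i < len(codons):
            if codons[i] == "ATG":
                j = i
                while j < len(codons) and codons[j] not in ("TAA", "TAG", "TGA"):
                    j += 1
                length = j - i
                if length >= min_len_aa:
                    end = frame + 3 * (j + 1) if j < len(codons) else frame + 3 * j
                    out.append((frame + 3 * i, min(end, len(seq))))
                i = j + 1
            else:
                i += 1
    return sorted(out)


class TestFindOrfs:
    def test_minimal_orf(self):
        hits = proteins.find_orfs("ATGAAATAA", min_len_aa=1, both_strands=False)
        assert len(hits) == 1
        assert hits[0].protein == "MK"
        assert (hits[0].start, hits[0].end) == (0, 9)

    def test_no_start_codon_no_orfs(self):
        seq = "CCCCCCCCCCCCCCCCCC"
        assert proteins.find_orfs(seq, min_len_aa=1, both_strands=False) == []

    def test_matches_naive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(4)
        for i in range(10):
            seq = simulate.generate_background(10_000, 0.5, int(rng.integers(2**31)))
            got = sorted(
                (h.start, h.end)
                for h in proteins.find_orfs(seq, min_len_aa=30, both_strands=False)
            )
            assert got == oracle_orfs(seq, 30)

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError):
            proteins.find_orfs("AT", min_len_aa=1)

    def test_reverse_strand_coordinates(self):
        from Bio.Seq import Seq

        fwd = "ATGAAAAAATAA"
        seq = str(Seq(fwd).reverse_complement())
        hits = proteins.find_orfs(seq, min_len_aa=1)
        minus = [h for h in hits if h.strand == "-"]
        assert minus
        h = minus[0]
        assert str(Seq(seq[h.start : h.end]).reverse_complement()) == fwd


class TestSimpleMotifs:
    def test_furin_consensus(self):
        assert proteins.scan_simple_motifs("AARSKRGG")["furin"] == [2]

    def test_cxxc(self):
        assert proteins.scan_simple_motifs("CAAC")["cxxc"] == [0]
        assert proteins.scan_simple_motifs("CAAAC")["cxxc"] == []

    def test_cx6cc(self):
        hits = proteins.scan_simple_motifs("CAAAAAACC")
        assert hits["cx6cc"] == [0]
        assert hits["cx5cc"] == [] and hits["cx7cc"] == []

    def test_x_never_matches(self):
        assert proteins.scan_simple_motifs("RXKR")["furin"] == []
        assert proteins.scan_simple_motifs("CXXC")["cxxc"] == []

    def test_overlapping_matches_reported(self):
        # two overlapping furin sites
        hits = proteins.scan_simple_motifs("RKRKRR")["furin"]
        assert len(hits) >= 2

    def test_equals_positionwise_oracle(self):
        rng = np.random.default_rng(12)
        checks = {
            "furin": lambda s, i: s[i] in "RK" and s[i + 2] in "RK" and s[i + 3] == "R"
            and s[i + 1] in AA,
            "cxxc": lambda s, i: s[i] == "C" and s[i + 3] == "C"
            and all(c in AA for c in s[i + 1 : i + 3]),
            "cx6cc": lambda s, i: s[i] == "C" and s[i + 7 : i + 9] == "CC"
            and all(c in AA for c in s[i + 1 : i + 7]),
        }
        width = {"furin": 4, "cxxc": 4, "cx6cc": 9}
        for _ in range(300):
            prot = random_protein(rng, 120)
            hits = proteins.scan_simple_motifs(prot)
            for name, check in checks.items():
                expect = [
                    i for i in range(len(prot) - width[name] + 1) if check(prot, i)
                ]
                assert hits[name] == expect, name


class TestIsd:
    PROFILE = proteins.DEFAULT_ISD_PROFILES[0]  # Q at position 14

    def test_reference_window_with_q14_is_suppressive(self):
        rng = np.random.default_rng(1)
        prot = random_protein(rng, 30) + self.PROFILE + random_protein(rng, 30)
        hit = proteins.locate_isd(prot)
        assert hit.start == 30
        assert hit.residue14 == "Q"
        assert hit.suppressive is True

    def test_k14_window_not_suppressive(self):
        window = self.PROFILE[:13] + "K" + self.PROFILE[14:]
        rng = np.random.default_rng(2)
        prot = random_protein(rng, 20) + window + random_protein(rng, 20)
        hit = proteins.locate_isd(prot)
        assert hit.suppressive is False

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        core = random_protein(rng, 10) + self.PROFILE + random_protein(rng, 10)
        h0 = proteins.locate_isd(core)
        h7 = proteins.locate_isd(random_protein(rng, 7) + core)
        assert h7.start == h0.start + 7
        assert h7.window == h0.window

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            prot = random_protein(rng, int(rng.integers(17, 61)))
            hit = proteins.locate_isd(prot)
            scores = [
                max(
                    sum(a == b for a, b in zip(prot[i : i + 17], prof))
                    for prof in proteins.DEFAULT_ISD_PROFILES
                )
                for i in range(len(prot) - 16)
            ]
            assert hit.score == max(scores)
            assert hit.start == scores.index(max(scores))

    def test_short_protein_raises(self):
        with pytest.raises(ValueError):
            proteins.locate_isd("MKV")


class TestTm:
    def test_hydrophobic_stretch_found(self):
        prot = "D" * 20 + "A" * 30 + "D" * 20
        segs = proteins.predict_tm(prot)
        assert len(segs) == 1
        s, e = segs[0]
        assert s >= 15 and e <= 55

    def test_all_polar_protein_has_none(self):
        assert proteins.predict_tm("D" * 60) == []

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            prot = random_protein(rng, 200)
            hi = proteins.predict_tm(prot, threshold=2.0)
            lo = proteins.predict_tm(prot, threshold=1.2)
            covered_lo = set()
            for s, e in lo:
                covered_lo.update(range(s, e))
            for s, e in hi:
                assert set(range(s, e)) <= covered_lo

    def test_short_protein_raises(self):
        with pytest.raises(ValueError):
            proteins.predict_tm("MKV")


class TestAnnotateEnv:
    def _env_protein(self, seed=17):
        """Synthetic Env with furin < ISD < C-X6-CC < TM."""
        rng = np.random.default_rng(seed)
        return (
            random_protein(rng, 40)
            + "RSKR"
            + random_protein(rng, 30)
            + proteins.DEFAULT_ISD_PROFILES[0]
            + random_protein(rng, 10)
            + "CGFEGTACC"
            + random_protein(rng, 20)
            + "AILIIVILVIGLLFILAIVGGIVLL"
            + random_protein(rng, 5)
        )

    def test_canonical_architecture_valid(self):
        ann = proteins.annotate_env(self._env_protein())
        assert ann.furin_site is not None
        assert ann.isd is not None and ann.isd.suppressive is True
        assert any(n == 6 for n, _ in ann.cx_n_cc)
        assert ann.tm_segment is not None
        assert ann.architecture_valid

    def test_tm_before_furin_invalid(self):
        rng = np.random.default_rng(5)
        prot = (
            "AILIIVILVIGLLFILAIVGGIVLL"
            + random_protein(rng, 30)
            + "RSKR"
            + random_protein(rng, 30)
        )
        ann = proteins.annotate_env(prot, isd_min_score=18)  # disable ISD
        assert ann.furin_site is not None and ann.tm_segment is not None
        assert not ann.architecture_valid

    def test_featureless_protein_vacuously_valid(self):
        ann = proteins.annotate_env("DEDEDEDEDEDEDEDE", isd_min_score=18)
        assert ann.architecture_valid
        assert ann.notes == "no features"

    def test_simulator_payload_recovered_at_planted_coordinates(self):
        from Bio.Seq import Seq

        spec = simulate.ElementSpec(
            motif_payload=("furin", "isd_k", "cxxc", "cx6cc", "tm")
        )
        seq, rec = simulate.synthesize_element(spec, seed=23)
        a, b = rec.genes["env"]
        prot = str(Seq(seq[a:b]).translate()).rstrip("*")
        hits = proteins.scan_simple_motifs(prot)
        planted = dict()
        for m, (s, e) in rec.planted_motif_coords:
            planted[m] = s + 1  # +1: protein coord 0 is the residue after Met
        assert planted["furin"] in hits["furin"]
        assert planted["cxxc"] in hits["cxxc"]
        assert planted["cx6cc"] in hits["cx6cc"]
        isd = proteins.locate_isd(prot)
        assert isd.start == planted["isd_k"]
        assert isd.suppressive is False
        tms = proteins.predict_tm(prot)
        assert any(s <= planted["tm"] < e for s, e in tms)
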