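"""MSA handling, domain projection, homolog-set filters, dispersion
statistics and BLOSUM62 similarity scores."""

import numpy as np
import pytest

from idrpipe import homologs as hm
from idrpipe.ensembles import afrc_reference


@pytest.fixture(scope="module")
def blosum():
    return hm.load_blosum62()


class TestReadMSA:
    def test_fasta_alignment(self, tmp_path):
        p = tmp_path / "a.afa"
        p.write_text(">s1\nMKV-LYQRST\n>s2\nMKVALYQRST\n>s3\nMKV-LY-RST\n")
        msa = hm.read_msa(p)
        assert (msa.n_rows, msa.n_cols) == (3, 10)

    def test_ragged_rejected(self, tmp_path):
        p = tmp_path / "a.afa"
        p.write_text(">s1\nMKVLYQRSTA\n>s2\nMKVLYQRST\n")
        with pytest.raises(ValueError, match="ragged|length"):
            hm.read_msa(p)

    def test_clustal_equals_fasta(self, tmp_path):
        fa = tmp_path / "a.afa"
        fa.write_text(">s1\nMKV-LY\n>s2\nMKVALY\n")
        cl = tmp_path / "a.aln"
        cl.write_text("CLUSTAL W multiple sequence alignment\n\n"
                      "s1   MKV-LY\ns2   MKVALY\n")
        a, b = hm.read_msa(fa), hm.read_msa(cl)
        assert a.rows == b.rows and a.ids == b.ids

    def test_empty_rejected(self, tmp_path):
        p = tmp_path / "a.afa"
        p.write_text("")
        with pytest.raises(Exception):
            hm.read_msa(p)


class TestProjection:
    DOMAINS = [(1, 4, "folded"), (5, 10, "idr")]

    def test_gapless_identical_inherits_verbatim(self):
        row = "MKVALYQRST"
        msa = hm.MSA(["ref", "h1", "h2"], [row, row, row])
        proj = hm.project_reference_idrs(msa, "ref", self.DOMAINS)
        for rid in msa.ids:
            assert proj[rid] == [(1, 4, "folded"), (5, 10, "idr")]

    def test_insertion_extends_member_idr(self):
        # member has a 5-residue insertion inside the IDR span
        msa = hm.MSA(["ref", "h1"],
                     ["MKVALYQ-----RST", "MKVALYQGGGGGRST"])
        proj = hm.project_reference_idrs(msa, "ref", self.DOMAINS)
        ref_idr = proj["ref"][1]
        h1_idr = proj["h1"][1]
        assert (ref_idr[1] - ref_idr[0]) + 5 == h1_idr[1] - h1_idr[0]

    def test_fully_gapped_member_empty_idr(self):
        msa = hm.MSA(["ref", "h1"], ["MKVALYQRST", "MKVA------"])
        proj = hm.project_reference_idrs(msa, "ref", self.DOMAINS)
        start, end, kind = proj["h1"][1]
        assert kind == "idr" and end < start   # empty interval

    def test_projection_conserves_residues(self):
        msa = hm.MSA(["ref", "h1", "h2"],
                     ["MKV-ALYQRS-T", "MKVPALY--SQT", "M-VPAL-QRSQT"])
        doms = [(1, 3, "folded"), (4, 8, "idr"), (9, 10, "folded")]
        proj = hm.project_reference_idrs(msa, "ref", doms)
        for rid in msa.ids:
            full = msa.ungapped(rid)
            rebuilt = "".join(full[s - 1:e] for s, e, _ in proj[rid] if e >= s)
            assert rebuilt == full

    def test_absent_reference_rejected(self):
        msa = hm.MSA(["a", "b"], ["MKVALYQRST", "MKVALYQRST"])
        with pytest.raises(ValueError, match="absent"):
            hm.project_reference_idrs(msa, "ref", self.DOMAINS)

    def test_overlapping_domains_rejected(self):
        msa = hm.MSA(["ref"], ["MKVALYQRST"])
        with pytest.raises(ValueError, match="overlap"):
            hm.project_reference_idrs(msa, "ref", [(1, 5, "folded"), (4, 10, "idr")])


def _mkset(lengths, ref_len=50, set_id="s"):
    members = [("ref", "G" * ref_len)]
    members += [(f"h{i}", "G" * L) for i, L in enumerate(lengths)]
    return hm.HomologIDRSet(set_id, "ref", members)


class TestFilters:
    def test_ten_members_dropped_strictly(self):
        hs = _mkset([50] * 9)   # 10 total with reference
        kept, log = hm.filter_homolog_sets([hs])
        assert kept == [] and "dropped" in log[0][1]

    def test_eleven_members_kept(self):
        hs = _mkset([50] * 10)
        kept, _ = hm.filter_homolog_sets([hs])
        assert len(kept) == 1

    def test_short_reference_drops_whole_set(self):
        hs = _mkset([50] * 12, ref_len=39)
        kept, log = hm.filter_homolog_sets([hs])
        assert kept == [] and "reference IDR 39" in log[0][2]

    def test_short_member_dropped_set_retained(self):
        hs = _mkset([50] * 10 + [14])
        kept, _ = hm.filter_homolog_sets([hs])
        assert len(kept) == 1
        assert len(kept[0].members) == 11
        assert all(len(s) >= 15 for _, s in kept[0].members)


class TestConservationStats:
    def test_identical_members_zero_dispersion(self):
        hs = _mkset([50] * 11)
        st = hm.conservation_stats(hs, lambda s: afrc_reference(s)[1])
        assert st.sd_length == 0.0
        assert st.sd_re == pytest.approx(0.0, abs=1e-12)

    def test_two_point_length_sd(self):
        hs = hm.HomologIDRSet("s", "ref", [("ref", "G" * 100), ("h", "G" * 102)])
        st = hm.conservation_stats(hs, lambda s: 1.0)
        assert st.sd_length == pytest.approx(np.sqrt(2.0))

    def test_constant_estimator_zero_re_sd(self):
        hs = _mkset([40, 60, 80, 120, 200])
        st = hm.conservation_stats(hs, lambda s: 33.0)
        assert st.sd_re == 0.0 and st.sd_length > 0

    def test_buffering_contrast(self):
        """Equal length dispersion, but a length-buffered estimator (Re
        independent of length) must show lower Re dispersion than a
        Gaussian-null estimator."""
        lengths = [60, 80, 100, 120, 140, 160, 180, 200, 220, 240]
        hs = _mkset(lengths, ref_len=100)
        null_est = lambda s: afrc_reference(s)[1]
        buffered_est = lambda s: afrc_reference(100)[1]
        sd_null = hm.conservation_stats(hs, null_est).sd_re
        sd_buf = hm.conservation_stats(hs, buffered_est).sd_re
        assert sd_buf < sd_null
        assert hm.conservation_stats(hs, null_est).null_sd_re == pytest.approx(sd_null)

    def test_single_member_rejected(self):
        hs = hm.HomologIDRSet("s", "ref", [("ref", "G" * 50)])
        with pytest.raises(ValueError):
            hm.conservation_stats(hs, lambda s: 1.0)


class TestSimilarity:
    def test_single_column_pair(self, blosum):
        msa = hm.MSA(["a", "b"], ["A", "A"])
        sop, star = hm.msa_similarity(msa, blosum)
        # total S(A,A) = 4, normalized by 2 rows x 1 column
        assert sop == pytest.approx(4.0 / 2.0)

    def test_identical_rows_star_total(self, blosum):
        rows = ["MKY"] * 4
        msa = hm.MSA([f"s{i}" for i in range(4)], rows)
        _, star = hm.msa_similarity(msa, blosum)
        diag = sum(blosum[(c, c)] for c in "MKY")
        assert star == pytest.approx(4 * diag / (4 * 3))

    def test_matches_brute_force_oracle(self, blosum):
        rng = np.random.default_rng(6)
        aa = "ACDEFGHIKLMNPQRSTVWY-"
        for _ in range(5):
            rows = ["".join(rng.choice(list(aa), size=6)) for _ in range(4)]
            try:
                msa = hm.MSA(["a", "b", "c", "d"], rows)
            except ValueError:
                continue
            sop, star = hm.msa_similarity(msa, blosum)

            def score(x, y):
                if "-" in (x, y):
                    return 0.0
                return blosum[(x, y)] if (x, y) in blosum else blosum[(y, x)]

            sop_ref = star_ref = 0.0
            for c in range(6):
                col = [r[c] for r in rows]
                for i in range(4):
                    for j in range(i + 1, 4):
                        sop_ref += score(col[i], col[j])
                res = [ch for ch in col if ch != "-"]
                if res:
                    top = max(res.count(ch) for ch in set(res))
                    cons = min(ch for ch in set(res) if res.count(ch) == top)
                    star_ref += sum(score(cons, ch) for ch in col)
            assert sop == pytest.approx(sop_ref / 24)
            assert star == pytest.approx(star_ref / 24)

    def test_row_order_invariance(self, blosum):
        rows = ["MKVLY", "MRVLF", "MKVIW"]
        a = hm.msa_similarity(hm.MSA(["1", "2", "3"], rows), blosum)
        b = hm.msa_similarity(hm.MSA(["3", "1", "2"], [rows[2], rows[0], rows[1]]), blosum)
        assert a == pytest.approx(b)

    def test_degradation_monotonicity(self, blosum):
        """Progressively mutating one row of an identical-row MSA strictly
        lowers both normalized scores (BLOSUM62 diagonal dominance)."""
        rng = np.random.default_rng(7)
        base = "MKVLYQRSTADE"
        rows = [base] * 4
        prev = hm.msa_similarity(hm.MSA(list("abcd"), rows), blosum)
        mutated = list(base)
        positions = rng.permutation(len(base))[:6]
        for pos in positions:
            choices = [c for c in "ACDEFGHIKLMNPQRSTVWY" if c != mutated[pos]]
            mutated[pos] = choices[rng.integers(len(choices))]
            rows = [base, base, base, "".join(mutated)]
            cur = hm.msa_similarity(hm.MSA(list("abcd"), rows), blosum)
            assert cur[0] < prev[0] and cur[1] < prev[1]
            prev = cur

    def test_single_row_rejected(self, blosum):
        with pytest.raises(ValueError):
            hm.msa_similarity(hm.MSA(["a"], ["MKV"]), blosum)


def test_extract_sets_from_msa():
    msa = hm.MSA(["ref", "h1", "h2"],
                 ["MKV-ALYQRS-T", "MKVPALY--SQT", "M-VPAL-QRSQT"])
    doms = [(1, 3, "folded"), (4, 8, "idr"), (9, 10, "folded")]
    sets = hm.extract_homolog_idr_sets(msa, "ref", doms)
    assert len(sets) == 1
    ids = sets[0].member_ids()
    assert "ref" in ids and len(ids) == 3
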