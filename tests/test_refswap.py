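"""Tailored reference construction and dual-alignment count combination."""

import numpy as np
import pandas as pd
import pytest
from pyfaidx import Fasta

from lowcov import (
    VariantSite,
    alignment_bias_summary,
    build_tailored_reference,
    combine_counts,
)


def _write_fasta(path, seq, name="chr1"):
    with open(path, "w") as fh:
        fh.write(f">{name}\n{seq}\n")
    return str(path)


class TestBuildTailoredReference:
    def test_single_substitution(self, tmp_path):
        src = _write_fasta(tmp_path / "g.fa", "AAAAAAAAAA")
        out = build_tailored_reference(src, [VariantSite("chr1", 5, "A", "G")],
                                       tmp_path / "t.fa")
        with Fasta(out, as_raw=True) as fa:
            assert str(fa["chr1"][:]) == "AAAAGAAAAA"

    def test_empty_site_list_preserves_sequence(self, tmp_path):
        src = _write_fasta(tmp_path / "g.fa", "ACGTACGTACGT")
        out = build_tailored_reference(src, [], tmp_path / "t.fa")
        with Fasta(out, as_raw=True) as fa:
            assert str(fa["chr1"][:]) == "ACGTACGTACGT"

    def test_involution_restores_original_bytes(self, tmp_path):
        seq = "ACGTAAGGTTCCACGTAAGGTTCC"
        src = _write_fasta(tmp_path / "g.fa", seq)
        sites = [VariantSite("chr1", 3, "G", "C"), VariantSite("chr1", 10, "T", "A")]
        mid = build_tailored_reference(src, sites, tmp_path / "mid.fa")
        swapped = [VariantSite(s.contig, s.pos, s.alt, s.ref) for s in sites]
        back = build_tailored_reference(mid, swapped, tmp_path / "back.fa")
        assert open(back, "rb").read() == open(src, "rb").read()

    def test_genome_mismatch_reported_with_coordinates(self, tmp_path):
        src = _write_fasta(tmp_path / "g.fa", "AAAAAAAAAA")
        with pytest.raises(ValueError, match="chr1:5"):
            build_tailored_reference(src, [VariantSite("chr1", 5, "C", "G")],
                                     tmp_path / "t.fa")

    def test_duplicate_sites_rejected(self, tmp_path):
        src = _write_fasta(tmp_path / "g.fa", "AAAAAAAAAA")
        sites = [VariantSite("chr1", 5, "A", "G"), VariantSite("chr1", 5, "A", "C")]
        with pytest.raises(ValueError, match="duplicate"):
            build_tailored_reference(src, sites, tmp_path / "t.fa")


def _counts(rows):
    return pd.DataFrame(rows, columns=["sample", "contig", "pos", "nRef", "nAlt"])


class TestCombineCounts:
    def test_mode_selection_rule(self):
        ref_aln = _counts([("S0", "chr1", 100, 5, 2)])
        alt_aln = _counts([("S0", "chr1", 100, 4, 3)])
        cis = combine_counts(ref_aln, alt_aln, "CIS")
        assert (int(cis.loc[0, "nRef"]), int(cis.loc[0, "nAlt"])) == (5, 3)
        trans = combine_counts(ref_aln, alt_aln, "TRANS")
        assert (int(trans.loc[0, "nRef"]), int(trans.loc[0, "nAlt"])) == (4, 2)

    def test_ref_and_alt_pass_through(self):
        ref_aln = _counts([("S0", "chr1", 100, 5, 2)])
        alt_aln = _counts([("S0", "chr1", 100, 4, 3)])
        pd.testing.assert_frame_equal(combine_counts(ref_aln, alt_aln, "REF"), ref_aln)
        pd.testing.assert_frame_equal(combine_counts(ref_aln, alt_aln, "ALT"), alt_aln)

    def test_identical_tables_make_all_modes_agree(self):
        tab = _counts([("S0", "chr1", 100, 3, 1), ("S0", "chr1", 200, 0, 2)])
        for mode in ("REF", "ALT", "CIS", "TRANS"):
            out = combine_counts(tab, tab.copy(), mode)
            np.testing.assert_array_equal(out["nRef"].to_numpy(), tab["nRef"].to_numpy())
            np.testing.assert_array_equal(out["nAlt"].to_numpy(), tab["nAlt"].to_numpy())

    def test_cis_trans_complementary_depth(self):
        rng = np.random.default_rng(9)
        rows_ref = [("S0", "chr1", 100 * (i + 1), int(a), int(b))
                    for i, (a, b) in enumerate(rng.integers(0, 6, size=(50, 2)))]
        rows_alt = [("S0", "chr1", 100 * (i + 1), int(a), int(b))
                    for i, (a, b) in enumerate(rng.integers(0, 6, size=(50, 2)))]
        ref_aln, alt_aln = _counts(rows_ref), _counts(rows_alt)
        cis = combine_counts(ref_aln, alt_aln, "CIS")
        trans = combine_counts(ref_aln, alt_aln, "TRANS")
        lhs = (cis["nRef"] + cis["nAlt"] + trans["nRef"] + trans["nAlt"]).to_numpy()
        rhs = (ref_aln["nRef"] + ref_aln["nAlt"] + alt_aln["nRef"] + alt_aln["nAlt"]).to_numpy()
        np.testing.assert_array_equal(lhs, rhs)

    def test_key_mismatch_reported(self):
        ref_aln = _counts([("S0", "chr1", 100, 5, 2)])
        alt_aln = _counts([("S0", "chr1", 999, 4, 3)])
        with pytest.raises(ValueError, match="keyed identically"):
            combine_counts(ref_aln, alt_aln, "CIS")


class TestAlignmentBiasSummary:
    def test_identical_tables_have_zero_difference(self):
        tab = _counts([("S0", "chr1", 100 * (i + 1), i % 4, (i + 1) % 3) for i in range(40)])
        report = alignment_bias_summary(tab, tab.copy())
        assert (report["difference_percent"].abs() < 1e-12).all()

    def test_published_reference_allele_difference(self):
        # overall mean 1.483 under the favourable genome vs 1.463 under the
        # unfavourable one corresponds to a 1.3% not-aligned difference
        n = 1000
        nref_fav = np.zeros(n, dtype=int)
        nref_fav[:483] = 2
        nref_fav[483:] = 1  # mean 1.483
        nref_unfav = np.zeros(n, dtype=int)
        nref_unfav[:463] = 2
        nref_unfav[463:] = 1  # mean 1.463
        ref_aln = _counts([("S0", "chr1", 100 * (i + 1), int(nref_fav[i]), 0) for i in range(n)])
        alt_aln = _counts([("S0", "chr1", 100 * (i + 1), int(nref_unfav[i]), 0) for i in range(n)])
        report = alignment_bias_summary(ref_aln, alt_aln)
        row = report[(report["allele"] == "reference") & (report["stratum"] == "overall")]
        assert float(row["mean_favourable"].iloc[0]) == pytest.approx(1.483)
        assert round(float(row["difference_percent"].iloc[0]), 1) == 1.3

    def test_binomial_thinning_recovers_loss_rate(self):
        rng = np.random.default_rng(11)
        n = 4000
        fav = rng.poisson(2.0, size=n)
        unfav = rng.binomial(fav, 0.95)  # each read lost with probability 5%
        ref_aln = _counts([("S0", "chr1", 100 * (i + 1), int(fav[i]), 0) for i in range(n)])
        alt_aln = _counts([("S0", "chr1", 100 * (i + 1), int(unfav[i]), 0) for i in range(n)])
        report = alignment_bias_summary(ref_aln, alt_aln)
        row = report[(report["allele"] == "reference") & (report["stratum"] == "overall")]
        diff = float(row["difference_percent"].iloc[0])
        sd = 100 * np.sqrt(0.05 * 0.95 * fav.sum()) / fav.sum()
        assert abs(diff - 5.0) < 3 * sd

    def test_truth_stratification(self):
        truth = pd.DataFrame(
            {"sample": ["S0"] * 2, "contig": ["chr1"] * 2, "pos": [100, 200],
             "dosage": [0, 2]}
        )
        ref_aln = _counts([("S0", "chr1", 100, 3, 0), ("S0", "chr1", 200, 0, 2)])
        alt_aln = _counts([("S0", "chr1", 100, 2, 0), ("S0", "chr1", 200, 0, 3)])
        report = alignment_bias_summary(ref_aln, alt_aln, truth)
        assert set(report["stratum"]) == {"overall", "true=0", "true=1", "true=2"}

    def test_empty_intersection_rejected(self):
        ref_aln = _counts([("S0", "chr1", 100, 1, 0)])
        alt_aln = _counts([("S1", "chr2", 200, 1, 0)])
        with pytest.raises(ValueError):
            alignment_bias_summary(ref_aln, alt_aln)
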