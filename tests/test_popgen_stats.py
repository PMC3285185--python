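"""Per-locus and cross-locus summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetfit.popgen_stats import (
    LocusAlignment,
    load_locus_fasta,
    locus_stats,
    multilocus_summary,
    nucleotide_diversity,
    phi_st,
    read_table1,
    segregating_sites,
    tajimas_d,
    write_locus_fasta,
)
from hetfit.synthetic_data import table1_fixture

from conftest import brute_force_pi


def random_alignment(rng, n=6, L=40, pops=("popA", "popB"), gap_prob=0.05):
    bases = np.array(list("ACGT"))
    anc = bases[rng.integers(4, size=L)]
    seqs = []
    for _ in range(n):
        s = anc.copy()
        nmut = rng.integers(0, L // 4)
        cols = rng.choice(L, size=nmut, replace=False)
        s[cols] = bases[rng.integers(4, size=nmut)]
        gaps = rng.random(L) < gap_prob
        s[gaps] = "-"
        seqs.append("".join(s))
    labels = [pops[i % len(pops)] for i in range(n)]
    return LocusAlignment("rand", seqs, labels)


class TestAlignmentIO:
    def test_fasta_round_trip_byte_exact(self, toy_alignment, tmp_path):
        path = tmp_path / "toy.fasta"
        write_locus_fasta(toy_alignment, path)
        pop_map = {
            f"toy_{i}_{p}": p for i, p in enumerate(toy_alignment.pop_labels)
        }
        back = load_locus_fasta(path, pop_map, locus_id="toy")
        assert back.sequences == toy_alignment.sequences
        assert back.pop_labels == toy_alignment.pop_labels

    def test_missing_label_names_the_record(self, toy_alignment, tmp_path):
        path = tmp_path / "toy.fasta"
        write_locus_fasta(toy_alignment, path)
        with pytest.raises(KeyError, match="toy_0_popA"):
            load_locus_fasta(path, {"other": "popA"})

    def test_empty_fasta_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            load_locus_fasta(path, {})

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            LocusAlignment("x", ["AAA", "AA"], ["popA", "popB"])


class TestNucleotideDiversity:
    def test_identical_sequences_zero(self):
        aln = LocusAlignment("x", ["ACGT" * 5] * 10, ["popA"] * 10)
        pi, n_sites = nucleotide_diversity(aln)
        assert pi == 0.0
        assert n_sites == 20

    def test_single_difference_per_site(self):
        a = "A" * 100
        b = "A" * 99 + "T"
        pi, _ = nucleotide_diversity(LocusAlignment("x", [a, b], ["popA", "popB"]))
        assert pi == pytest.approx(0.01)

    def test_toy_alignment_value(self, toy_alignment):
        # 10 pairwise diffs / 6 pairs / 3 sites
        pi, n_sites = nucleotide_diversity(toy_alignment)
        assert n_sites == 3
        assert pi == pytest.approx(10 / 6 / 3)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            aln = random_alignment(rng)
            try:
                pi, _ = nucleotide_diversity(aln)
            except ValueError:
                continue  # all columns gapped
            assert pi == pytest.approx(brute_force_pi(aln.sequences), abs=0)

    def test_all_gap_column_changes_nothing(self, toy_alignment):
        pi0, _ = nucleotide_diversity(toy_alignment)
        gapped = LocusAlignment(
            "x",
            [s + "-" for s in toy_alignment.sequences],
            toy_alignment.pop_labels,
        )
        pi1, n_sites = nucleotide_diversity(gapped)
        assert pi1 == pi0
        assert n_sites == 3
        assert segregating_sites(gapped) == segregating_sites(toy_alignment)

    def test_zero_usable_columns_error(self):
        aln = LocusAlignment("x", ["A-", "-A"], ["popA", "popB"])
        with pytest.raises(ValueError, match="usable"):
            nucleotide_diversity(aln)


class TestTajimasD:
    def test_monomorphic_undefined(self):
        aln = LocusAlignment("x", ["ACGT"] * 5, ["popA"] * 5)
        assert tajimas_d(aln) is None

    def test_small_sample_undefined(self):
        aln = LocusAlignment("x", ["AAA", "AAT", "ATT"], ["popA"] * 3)
        assert tajimas_d(aln) is None

    def test_toy_alignment_frozen_oracle(self, toy_alignment):
        # direct evaluation of the 1989 formulas by hand:
        # pi_hat = 5/3, theta_W = 3/a1, a1 = 11/6
        assert tajimas_d(toy_alignment) == pytest.approx(0.1676557950339493)

    def test_per_population_subset(self, toy_alignment):
        # each population has n = 2 < 4
        assert tajimas_d(toy_alignment, pop="popA") is None


class TestPhiSt:
    def test_fixed_haplotypes_fully_partitioned(self):
        aln = LocusAlignment(
            "x", ["AAAA"] * 3 + ["TTTT"] * 3, ["popA"] * 3 + ["popB"] * 3
        )
        phi, p = phi_st(aln, n_permutations=99, rng=np.random.default_rng(0))
        assert phi == pytest.approx(1.0)
        assert p <= 0.2

    def test_identical_composition_near_zero(self, rng):
        # both populations hold exactly the same pair of haplotypes
        aln = LocusAlignment(
            "x",
            ["AAAA", "AATT", "AAAA", "AATT"],
            ["popA", "popA", "popB", "popB"],
        )
        phi, p = phi_st(aln, n_permutations=199, rng=rng)
        assert abs(phi) < 0.05 or phi < 0  # no among-population variance
        assert p > 0.05

    def test_two_plus_two_amova_oracle(self, two_pop_alignment, rng):
        # hand-computed variance components: SSD_T = 2, SSD_W = 1 -> 1/3
        phi, _ = phi_st(two_pop_alignment, n_permutations=0)
        assert phi == pytest.approx(1 / 3)

    def test_small_population_rejected(self):
        aln = LocusAlignment("x", ["AA", "AT", "TT"], ["popA", "popA", "popB"])
        with pytest.raises(ValueError, match="<2"):
            phi_st(aln)

    def test_negative_values_retained(self, rng):
        # within-population diversity exceeding between: Phi_st may go
        # negative and must not be clamped
        seen_negative = False
        for _ in range(30):
            aln = random_alignment(rng, n=8, L=30, gap_prob=0.0)
            try:
                phi, _ = phi_st(aln, n_permutations=0)
            except ValueError:
                continue
            if phi < 0:
                seen_negative = True
        assert seen_negative

    def test_permutation_p_roughly_uniform_under_null(self, rng):
        ps = []
        for _ in range(40):
            aln = random_alignment(rng, n=8, L=50, gap_prob=0.0)
            try:
                _, p = phi_st(aln, n_permutations=49, rng=rng)
            except ValueError:
                continue
            ps.append(p)
        assert 0.3 < np.mean(ps) < 0.75


class TestLocusStats:
    def test_monomorphic_bundle(self):
        aln = LocusAlignment("x", ["ACGT"] * 8, ["popA"] * 4 + ["popB"] * 4)
        st_ = locus_stats(aln)
        assert st_.pi == 0.0
        assert st_.S == 0
        assert st_.tajd_mean is None

    def test_consistency_with_components(self, toy_alignment):
        st_ = locus_stats(toy_alignment)
        assert st_.pi == pytest.approx(nucleotide_diversity(toy_alignment)[0])
        assert st_.S == 3
        assert st_.tajd_total == pytest.approx(tajimas_d(toy_alignment))

    def test_sequence_order_invariance(self, rng):
        aln = random_alignment(rng, n=8, L=60)
        order = rng.permutation(8)
        shuffled = LocusAlignment(
            aln.locus_id,
            [aln.sequences[i] for i in order],
            [aln.pop_labels[i] for i in order],
        )
        a, b = locus_stats(aln), locus_stats(shuffled)
        assert a.pi == pytest.approx(b.pi)
        assert a.S == b.S
        assert a.phi_st == pytest.approx(b.phi_st)
        for pop in a.tajd_per_pop:
            if a.tajd_per_pop[pop] is None:
                assert b.tajd_per_pop[pop] is None
            else:
                assert a.tajd_per_pop[pop] == pytest.approx(b.tajd_per_pop[pop])

    def test_s_zero_iff_pi_zero(self, rng):
        for _ in range(20):
            aln = random_alignment(rng, n=6, L=30)
            try:
                st_ = locus_stats(aln)
            except ValueError:
                continue
            assert (st_.S == 0) == (st_.pi == 0.0)


class TestMultilocusSummary:
    def test_empirical_table_aggregates(self):
        s = multilocus_summary(table1_fixture())
        assert s["pi"]["mean"] == pytest.approx(0.010, abs=5e-4)
        assert s["pi"]["sd"] == pytest.approx(0.010, abs=5e-4)
        assert s["pi"]["min"] == pytest.approx(0.0004)
        assert s["phi_st"]["mean"] == pytest.approx(0.065, abs=5e-4)
        assert s["phi_st"]["sd"] == pytest.approx(0.075, abs=1e-3)
        assert s["tajd"]["mean"] == pytest.approx(-0.37, abs=5e-3)
        assert s["tajd"]["sd"] == pytest.approx(0.80, abs=5e-3)

    def test_constant_vector(self):
        df = pd.DataFrame(
            {"locus": list("abc"), "pi": [0.01] * 3, "phi_st": [0.1] * 3, "tajd": [0.5] * 3}
        )
        s = multilocus_summary(df)
        assert s["pi"]["sd"] == 0.0
        assert s["pi"]["cv"] == 0.0

    def test_undefined_entries_excluded_and_counted(self):
        df = pd.DataFrame(
            {
                "locus": list("abcd"),
                "pi": [0.01, 0.02, 0.03, 0.04],
                "phi_st": [0.1, 0.2, 0.1, 0.2],
                "tajd": [0.5, np.nan, -0.5, np.nan],
            }
        )
        s = multilocus_summary(df)
        assert s["tajd"]["n_loci"] == 2
        assert s["tajd"]["n_undefined"] == 2

    def test_all_undefined_statistic_errors(self):
        df = pd.DataFrame(
            {"locus": list("ab"), "pi": [0.01, 0.02], "phi_st": [0.1, 0.2], "tajd": [np.nan] * 2}
        )
        with pytest.raises(ValueError, match="tajd"):
            multilocus_summary(df)


class TestTableIO:
    def test_read_table_requires_columns(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("locus\tpi\na\t0.1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_table1(path)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_pi_brute_force_property(seed):
    """pi from allele-count shortcut equals the O(n^2 L) oracle exactly."""
    rng = np.random.default_rng(seed)
    aln = random_alignment(rng, n=5, L=30)
    try:
        pi, _ = nucleotide_diversity(aln)
    except ValueError:
        return
    assert pi == pytest.approx(brute_force_pi(aln.sequences), abs=1e-12)
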