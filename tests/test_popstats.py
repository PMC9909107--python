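"""Diversity estimators against brute-force oracles, plus window/region
additivity and polarization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gadpopgen import popstats
from gadpopgen.popstats import (
    AlignmentSummary,
    classify_polymorphisms,
    count_sites_neigojobori,
    pi,
    polarize,
    region_stats,
    sliding_window,
    watterson_theta,
)
from gadpopgen.seqio import CodingAlignment, RegionSpec, SequenceRecord

from conftest import random_coding_alignment


def brute_force_pi_all(aln):
    """Double loop over pairs and sites, raw per-site diversity."""
    recs = aln.ingroup
    n = len(recs)
    total = 0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            npairs += 1
            total += sum(a != b for a, b in zip(recs[i].seq, recs[j].seq))
    return total / npairs / aln.length


class TestPi:
    def test_two_sequences_two_of_hundred(self):
        base = "AAAGGGTTT" * 11 + "AAA"  # 34 codons = 102 nt; use 100-site view
        a = SequenceRecord("a", base, "nt")
        b_seq = base[:3] + "C" + base[4:50] + "C" + base[51:]
        b = SequenceRecord("b", b_seq, "nt")
        aln = CodingAlignment(records=(a, b), populations={"a": "p", "b": "p"})
        assert pi(aln, "all", jc=False) == pytest.approx(2 / 102)

    def test_identical_sequences_zero(self):
        a = SequenceRecord("a", "ATGAAA", "nt")
        b = SequenceRecord("b", "ATGAAA", "nt")
        aln = CodingAlignment(records=(a, b), populations={"a": "p", "b": "p"})
        assert pi(aln, "all", jc=False) == 0.0

    def test_matches_brute_force_on_random_alignments(self, rng):
        for _ in range(25):
            aln = random_coding_alignment(
                rng,
                n=int(rng.integers(2, 9)),
                n_codons=int(rng.integers(10, 80)),
            )
            assert pi(aln, "all", jc=False) == pytest.approx(
                brute_force_pi_all(aln), abs=1e-12
            )

    def test_syn_plus_nonsyn_diffs_equal_total(self, rng):
        for _ in range(10):
            aln = random_coding_alignment(rng, n=6, n_codons=40)
            s = AlignmentSummary(aln)
            assert s.diffs_in("syn") + s.diffs_in("nonsyn") == pytest.approx(
                s.diffs_in("all")
            )

    def test_jc_correction_increases_pi(self, rng):
        aln = random_coding_alignment(rng, n=6, n_codons=60, mutation_rate=0.05)
        raw = pi(aln, "all", jc=False)
        corrected = pi(aln, "all", jc=True)
        assert corrected > raw > 0


class TestWatterson:
    def test_n2_pair(self):
        assert watterson_theta(3, 2, 100) == pytest.approx(0.03)

    def test_zero_sites(self):
        assert watterson_theta(0, 10, 100) == 0.0

    def test_n10(self):
        a1 = sum(1 / i for i in range(1, 10))
        assert watterson_theta(12, 10, 1000) == pytest.approx(12 / (a1 * 1000))


class TestSiteCounts:
    def test_conservation_on_random_alignments(self, rng):
        for _ in range(5):
            aln = random_coding_alignment(rng, n=5, n_codons=30)
            counts = count_sites_neigojobori(aln)
            assert counts.L_syn + counts.L_nonsyn == pytest.approx(
                3.0 * aln.n_codons, abs=1e-6
            )

    def test_internal_stop_is_error(self):
        recs = (
            SequenceRecord("a", "ATGTAAAAA", "nt"),
            SequenceRecord("b", "ATGCAAAAA", "nt"),
        )
        aln = CodingAlignment(records=recs, populations={"a": "p", "b": "p"})
        with pytest.raises(popstats.InternalStopError, match="'a'"):
            count_sites_neigojobori(aln)

    def test_additive_over_codon_partition(self, rng):
        aln = random_coding_alignment(rng, n=5, n_codons=40)
        whole = count_sites_neigojobori(aln)
        left = count_sites_neigojobori(aln.subset_codons(list(range(20))))
        right = count_sites_neigojobori(aln.subset_codons(list(range(20, 40))))
        assert left.L_syn + right.L_syn == pytest.approx(whole.L_syn)


class TestClassifyPolymorphisms:
    def test_phe_synonymous_singleton(self):
        rows = ["TTT"] * 4 + ["TTC"]
        recs = tuple(
            SequenceRecord(f"s{i}", s, "nt") for i, s in enumerate(rows)
        )
        aln = CodingAlignment(
            records=recs, populations={r.id: "p" for r in recs}
        )
        table = classify_polymorphisms(aln)
        assert table.S == 1
        site = table.sites[0]
        assert site.site_class == "synonymous"
        assert site.singleton
        assert not site.parsimony_informative

    def test_phe_leu_nonsynonymous(self):
        rows = ["TTT", "TTT", "TTA", "TTA"]
        recs = tuple(
            SequenceRecord(f"s{i}", s, "nt") for i, s in enumerate(rows)
        )
        aln = CodingAlignment(
            records=recs, populations={r.id: "p" for r in recs}
        )
        table = classify_polymorphisms(aln)
        assert table.sites[0].site_class == "nonsynonymous"
        assert table.sites[0].parsimony_informative

    def test_eta_exceeds_s_at_triallelic_site(self):
        rows = ["GGA", "GGA", "GGC", "GGT"]
        recs = tuple(
            SequenceRecord(f"s{i}", s, "nt") for i, s in enumerate(rows)
        )
        aln = CodingAlignment(
            records=recs, populations={r.id: "p" for r in recs}
        )
        table = classify_polymorphisms(aln)
        assert table.S == 1
        assert table.eta == 2

    def test_eta_ge_s_property(self, rng):
        for _ in range(10):
            aln = random_coding_alignment(rng, n=8, n_codons=40, mutation_rate=0.04)
            t = classify_polymorphisms(aln)
            assert t.eta >= t.S

    def test_outgroup_excluded_from_counts(self, rng):
        aln = random_coding_alignment(rng, n=6, n_codons=40, outgroup=True)
        with_og = classify_polymorphisms(aln)
        no_og = classify_polymorphisms(
            CodingAlignment(
                records=aln.ingroup,
                populations={r.id: "p" for r in aln.ingroup},
            )
        )
        assert with_og.S == no_og.S
        assert with_og.eta == no_og.eta


class TestPolarize:
    def test_singleton_derived(self):
        rows = ["AAA", "AAA", "AAA", "TAA"[0] + "AA"]
        recs = [SequenceRecord(f"s{i}", s, "nt") for i, s in enumerate(rows)]
        recs.append(SequenceRecord("og", "AAA", "nt"))
        aln = CodingAlignment(
            records=tuple(recs),
            populations={f"s{i}": "p" for i in range(4)},
            outgroup_id="og",
        )
        sfs = polarize(aln)
        assert sfs.xi[1] == 1
        assert sfs.n_polarized == 1

    def test_outgroup_third_allele_excluded(self):
        rows = ["AAA", "AAA", "TAA", "TAA"]
        recs = [SequenceRecord(f"s{i}", s, "nt") for i, s in enumerate(rows)]
        recs.append(SequenceRecord("og", "CAA", "nt"))
        aln = CodingAlignment(
            records=tuple(recs),
            populations={f"s{i}": "p" for i in range(4)},
            outgroup_id="og",
        )
        sfs = polarize(aln)
        assert sfs.n_polarized == 0
        assert sfs.excluded_sites["outgroup_third_allele"] == 1

    def test_total_matches_brute_force_scan(self, rng):
        for _ in range(5):
            aln = random_coding_alignment(
                rng, n=6, n_codons=50, mutation_rate=0.03, outgroup=True
            )
            sfs = polarize(aln)
            # independent scan
            ingroup = aln.ingroup
            og = aln.outgroup
            count = 0
            for col in range(aln.length):
                alleles = {r.seq[col] for r in ingroup}
                if len(alleles) == 2 and og.seq[col] in alleles:
                    count += 1
            assert sfs.n_polarized == count

    def test_missing_outgroup_is_error(self, small_alignment):
        with pytest.raises(ValueError, match="outgroup"):
            polarize(small_alignment, "nope")


class TestSlidingWindow:
    def test_full_length_window_equals_global(self, rng):
        aln = random_coding_alignment(rng, n=6, n_codons=30)
        summary = AlignmentSummary(aln)
        df = sliding_window(aln, window_bp=aln.length, step_bp=1,
                            stats=("pi_nonsyn", "pi_all"))
        assert df.shape[0] == 1
        assert df["pi_nonsyn"][0] == pytest.approx(summary.pi_raw("nonsyn"))
        assert df["pi_all"][0] == pytest.approx(summary.pi_raw("all"))

    def test_variation_localized(self):
        rows = ["AAA" * 20, "AAA" * 10 + "AAC" + "AAA" * 9]
        recs = tuple(
            SequenceRecord(f"s{i}", s, "nt") for i, s in enumerate(rows)
        )
        aln = CodingAlignment(
            records=recs, populations={r.id: "p" for r in recs}
        )
        df = sliding_window(aln, window_bp=10, step_bp=1, stats=("pi_all",))
        var_site = 32  # 0-based position of the C
        for _, row in df.iterrows():
            lo, hi = row["start_1based"] - 1, row["end_1based"]
            inside = lo <= var_site < hi
            assert (row["pi_all"] > 0) == inside

    def test_monomorphic_zero_pi_undefined_d(self):
        recs = tuple(
            SequenceRecord(f"s{i}", "ATGAAAGGG", "nt") for i in range(5)
        )
        aln = CodingAlignment(
            records=recs, populations={r.id: "p" for r in recs}
        )
        df = sliding_window(aln, window_bp=6, step_bp=3,
                            stats=("pi_all", "tajima_d"))
        assert (df["pi_all"] == 0).all()
        assert df["tajima_d"].isna().all()

    def test_bad_window_rejected(self, small_alignment):
        with pytest.raises(ValueError):
            sliding_window(small_alignment, window_bp=0)


class TestRegionStats:
    def test_whole_gene_region_equals_global(self, rng):
        aln = random_coding_alignment(rng, n=6, n_codons=30)
        summary = AlignmentSummary(aln)
        df = region_stats(aln, [RegionSpec("whole", 0, 30)],
                          site_classes=("all",))
        assert df["pi"][0] == pytest.approx(summary.pi_raw("all"))
        assert df["S"][0] == summary.table.S

    def test_disjoint_regions_site_counts_sum(self, rng):
        aln = random_coding_alignment(rng, n=6, n_codons=30)
        df = region_stats(
            aln,
            [RegionSpec("left", 0, 15), RegionSpec("right", 15, 30)],
            site_classes=("all",),
        )
        assert df["L"].sum() == pytest.approx(aln.length)
        assert df["S"].sum() == AlignmentSummary(aln).table.S

    def test_out_of_bounds_rejected(self, small_alignment):
        with pytest.raises(ValueError, match="outside"):
            region_stats(small_alignment, [RegionSpec("bad", 0, 10_000)])

    def test_elevated_region_recovered(self, rng):
        """A region seeded with extra nonsynonymous variation shows the
        higher pi_N."""
        from gadpopgen.codons import codon_map

        cmap = codon_map(11)
        base = random_coding_alignment(rng, n=8, n_codons=40, mutation_rate=0.0)
        rows = [list(r.seq) for r in base.records]
        # inject nonsynonymous variants only in codons 0..19
        injected = 0
        for codon_idx in range(20):
            if injected >= 12:
                break
            pos = codon_idx * 3
            for r in range(0, 8, 3):
                codon = "".join(rows[r][pos : pos + 3])
                for nt in "ACGT":
                    alt = nt + codon[1:]
                    if alt != codon and cmap[alt] not in ("*", cmap[codon]):
                        rows[r][pos] = nt
                        injected += 1
                        break
                break
        recs = tuple(
            SequenceRecord(f"s{k}", "".join(rows[k]), "nt") for k in range(8)
        )
        aln = CodingAlignment(
            records=recs, populations={r.id: "p" for r in recs}
        )
        df = region_stats(
            aln,
            [RegionSpec("hot", 0, 20), RegionSpec("cold", 20, 40)],
            site_classes=("nonsyn",),
        )
        hot = df[df.region == "hot"]["pi"].iloc[0]
        cold = df[df.region == "cold"]["pi"].iloc[0]
        assert hot > cold


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_site_decomposition_additivity(seed):
    """Per-pair class difference totals equal the per-site attributions."""
    rng = np.random.default_rng(seed)
    aln = random_coding_alignment(rng, n=5, n_codons=25, mutation_rate=0.04)
    s = AlignmentSummary(aln)
    for cls in ("all", "syn", "nonsyn"):
        assert s.pair_diffs(cls).sum() == pytest.approx(s.diffs_in(cls))
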