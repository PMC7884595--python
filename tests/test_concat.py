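"""Subset enumeration, concatenation, alignment statistics, NEXUS emission,
and posterior rate summarization."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evomap.concat_opt import (OrthologSet, SpeciesSubset, alignment_stats,
                               build_concatenation, enumerate_subsets,
                               rank_subsets, read_nexus_matrix,
                               read_ortholog_sets, summarize_rate_posteriors,
                               write_partitioned_nexus, ConcatenatedAlignment)
from evomap.structures import SprinzlMap, StructuralAlignment
from evomap.synth import SynthConfig, simulate_ortholog_sets
from tests.conftest import make_alignment, make_gene


class TestEnumerateSubsets:
    @pytest.mark.parametrize("n,k,expected", [
        (11, 7, 562),
        (3, 2, 4),
        (5, 5, 1),
    ])
    def test_counts(self, n, k, expected):
        roster = [f"s{i}" for i in range(n)]
        assert len(enumerate_subsets(roster, k)) == expected

    @given(n=st.integers(1, 12), k=st.integers(1, 12))
    @settings(max_examples=40, deadline=None)
    def test_closed_form_count(self, n, k):
        if k > n:
            return
        roster = [f"s{i}" for i in range(n)]
        expected = sum(math.comb(n, j) for j in range(k, n + 1))
        assert len(enumerate_subsets(roster, k)) == expected

    def test_deterministic_order_and_masks(self):
        subsets = enumerate_subsets(["a", "b", "c"], 2)
        assert [s.mask for s in subsets] == ["111", "110", "101", "011"]

    def test_invalid_min_size(self):
        with pytest.raises(ValueError):
            enumerate_subsets(["a"], 0)


def _toy_world(n_species=4, n_sets=5, width=6, seed=0):
    """Tiny ortholog world with full-coverage sequences, no gaps."""
    rng = np.random.default_rng(seed)
    roster = [f"sp{i}" for i in range(n_species)]
    sprinzl = SprinzlMap(tuple(str(i) for i in range(1, width + 1)))
    genes, sets = [], []
    for s in range(n_sets):
        coverage = roster if s % 2 == 0 else roster[: n_species - 1]
        members = {}
        for sp in coverage:
            gid = f"os{s}_{sp}"
            seq = "".join(rng.choice(list("ACGU"), width))
            genes.append(make_gene(gid, "K", seq, width=width))
            members[sp] = gid
        sets.append(OrthologSet(f"os{s}", members))
    aln = StructuralAlignment(genes, width=width, sprinzl=sprinzl)
    return roster, sets, aln


class TestBuildConcatenation:
    def test_superset_sets_included_and_rows_restricted(self):
        roster, sets, aln = _toy_world()
        subset = SpeciesSubset.from_species(roster, roster[:3])
        conc = build_concatenation(sets, aln, subset)
        assert len(conc.rows) == 3
        assert len(conc.blocks) == 5          # every set covers sp0..sp2
        assert conc.length == 5 * 6

    def test_set_missing_a_subset_species_excluded(self):
        roster, sets, aln = _toy_world()
        subset = SpeciesSubset.from_species(roster, roster)   # all 4 species
        conc = build_concatenation(sets, aln, subset)
        assert conc.blocks == ("os0", "os2", "os4")

    def test_block_count_equals_bruteforce_superset_count(self, rng):
        cfg = SynthConfig(seed=6, n_ortholog_sets=10)
        sets, aln = simulate_ortholog_sets(cfg)
        roster = cfg.roster
        subset = SpeciesSubset.from_species(roster, roster[:7])
        conc = build_concatenation(sets, aln, subset)
        oracle = sum(1 for s in sets
                     if set(roster[:7]) <= set(s.members) and not s.flagged)
        assert len(conc.blocks) == oracle

    def test_flagged_sets_excluded(self):
        roster, sets, aln = _toy_world()
        sets[0].anticodon_shift = True
        subset = SpeciesSubset.from_species(roster, roster[:2])
        conc = build_concatenation(sets, aln, subset)
        assert "os0" not in conc.blocks

    def test_no_qualifying_sets_gives_empty_alignment(self):
        roster, sets, aln = _toy_world()
        stranger = SpeciesSubset(tuple(roster) + ("spX",), "00001")
        conc = build_concatenation(sets, aln, stranger)
        assert conc.length == 0 and conc.blocks == ()


def _conc_from_rows(rows):
    width = len(next(iter(rows.values())))
    sprinzl_labels = tuple(str(i) for i in range(1, width + 1))
    roster = tuple(rows)
    return ConcatenatedAlignment(
        subset=SpeciesSubset(roster, "1" * len(roster)),
        rows=rows, blocks=("b1",), site_partition=sprinzl_labels)


class TestAlignmentStats:
    def test_column_classification(self):
        conc = _conc_from_rows({"s1": "AAC", "s2": "AAC",
                                "s3": "CAA", "s4": "CCA"})
        st_ = alignment_stats(conc)
        # col1 A,A,C,C: variable + PI; col2 A,A,A,C: variable only;
        # col3 C,C,A,A: variable + PI
        assert st_.variable_sites == 3
        assert st_.pi_sites == 2
        assert st_.gapfree_sites == 3

    def test_identical_rows(self):
        conc = _conc_from_rows({"s1": "ACGU", "s2": "ACGU"})
        st_ = alignment_stats(conc)
        assert st_.variable_sites == 0
        assert st_.mean_pairwise_diff == 0.0

    def test_gap_column_excluded(self):
        conc = _conc_from_rows({"s1": "A-C", "s2": "AGC"})
        assert alignment_stats(conc).gapfree_sites == 2

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            alignment_stats(_conc_from_rows({"s1": "ACGU"}))

    def test_matches_bruteforce_on_random_alignments(self, rng):
        for _ in range(25):
            n_rows = int(rng.integers(2, 9))
            n_cols = int(rng.integers(2, 201))
            mat = rng.choice(list("ACGU-"), size=(n_rows, n_cols),
                             p=[0.23, 0.23, 0.23, 0.23, 0.08])
            rows = {f"s{i}": "".join(mat[i]) for i in range(n_rows)}
            st_ = alignment_stats(_conc_from_rows(rows))
            # brute force
            gf = [j for j in range(n_cols)
                  if all(rows[f"s{i}"][j] != "-" for i in range(n_rows))]
            var = pi = 0
            for j in gf:
                col = [rows[f"s{i}"][j] for i in range(n_rows)]
                counts = {c: col.count(c) for c in set(col)}
                if len(counts) >= 2:
                    var += 1
                    if sum(1 for v in counts.values() if v >= 2) >= 2:
                        pi += 1
            diffs = []
            for a, b in itertools.combinations(range(n_rows), 2):
                if gf:
                    diffs.append(sum(rows[f"s{a}"][j] != rows[f"s{b}"][j]
                                     for j in gf) / len(gf))
                else:
                    diffs.append(0.0)
            assert st_.gapfree_sites == len(gf)
            assert st_.variable_sites == var
            assert st_.pi_sites == pi
            assert st_.mean_pairwise_diff == pytest.approx(np.mean(diffs))

    def test_fewer_sets_never_lengthen_gapfree(self):
        roster, sets, aln = _toy_world(seed=3)
        subset = SpeciesSubset.from_species(roster, roster[:3])
        full = alignment_stats(build_concatenation(sets, aln, subset))
        fewer = alignment_stats(build_concatenation(sets[:3], aln, subset))
        assert fewer.gapfree_sites <= full.gapfree_sites


class TestRankSubsets:
    def test_single_subset_ranks_first(self):
        roster, sets, aln = _toy_world()
        subset = SpeciesSubset.from_species(roster, roster[:2])
        stats = {subset.mask: alignment_stats(
            build_concatenation(sets, aln, subset))}
        frame = rank_subsets(stats)
        assert frame.loc[0, "rank"] == 1

    def test_longer_gapfree_ranks_first(self):
        from evomap.concat_opt import AlignmentStats
        a = AlignmentStats(3, 300, 290, 40, 12, 0.1)
        b = AlignmentStats(3, 300, 250, 40, 12, 0.1)
        frame = rank_subsets({"110": a, "101": b})
        assert frame.loc[0, "subset"] == "110"

    def test_designed_dominating_subset_ranks_first(self):
        cfg = SynthConfig(seed=17, n_ortholog_sets=80)
        sets, aln = simulate_ortholog_sets(cfg)
        stats = {}
        for ss in enumerate_subsets(cfg.roster, 7):
            conc = build_concatenation(sets, aln, ss)
            if conc.blocks and len(conc.rows) >= 2:
                stats[ss.mask] = alignment_stats(conc)
        frame = rank_subsets(stats)
        # presence probabilities are graded so the subset excluding the four
        # poorly covered species (sp08..sp11) concatenates the most sets
        assert frame.loc[0, "subset"] == "11111110000"

    def test_low_coverage_species_exclusion_gains_sets(self):
        cfg = SynthConfig(seed=17, n_ortholog_sets=80)
        sets, aln = simulate_ortholog_sets(cfg)
        with_low = SpeciesSubset.from_species(cfg.roster,
                                              cfg.roster[:6] + (cfg.roster[-1],))
        without_low = SpeciesSubset.from_species(cfg.roster, cfg.roster[:7])
        n_with = len(build_concatenation(sets, aln, with_low).blocks)
        n_without = len(build_concatenation(sets, aln, without_low).blocks)
        assert n_without > n_with


class TestNexus:
    def _conc(self, model_width=74, n_blocks=2, seed=0):
        rng = np.random.default_rng(seed)
        sprinzl = SprinzlMap()
        rows = {f"sp{i}": "".join(rng.choice(list("ACGU"),
                                             model_width * n_blocks))
                for i in range(4)}
        return ConcatenatedAlignment(
            subset=SpeciesSubset(tuple(rows), "1111"),
            rows=rows, blocks=tuple(f"os{i}" for i in range(n_blocks)),
            site_partition=sprinzl.labels * n_blocks)

    def test_structural_scheme_has_nine_charsets_covering_once(self):
        conc = self._conc()
        doc = write_partitioned_nexus(conc, scheme="structural")
        charsets = [l for l in doc.splitlines()
                    if l.strip().startswith("charset")]
        assert len(charsets) == 9
        covered = []
        for line in charsets:
            spec = line.split("=")[1].strip().rstrip(";")
            for token in spec.split():
                if "-" in token:
                    a, b = token.split("-")
                    covered.extend(range(int(a), int(b) + 1))
                else:
                    covered.append(int(token))
        assert sorted(covered) == list(range(1, conc.length + 1))

    def test_per_site_scheme_one_charset_per_coordinate(self):
        conc = self._conc()
        doc = write_partitioned_nexus(conc, scheme="per_site")
        n = sum(1 for l in doc.splitlines()
                if l.strip().startswith("charset"))
        assert n == 74

    def test_ratemult_scaled_and_mcmc_defaults(self):
        doc = write_partitioned_nexus(self._conc())
        assert "ratemult = scaled" in doc
        assert "ngen=4000000" in doc
        assert "nruns=2" in doc
        assert "samplefreq=500" in doc

    def test_doublet_model_pairs_stems(self):
        doc = write_partitioned_nexus(self._conc(), model="doublet_gtr_i")
        assert "nucmodel=doublet" in doc
        assert "pairs " in doc

    def test_matrix_roundtrip(self):
        conc = self._conc(seed=4)
        doc = write_partitioned_nexus(conc)
        assert read_nexus_matrix(doc) == conc.rows

    def test_fixed_tree_disables_topology_moves(self):
        doc = write_partitioned_nexus(self._conc(), tree="(sp0,(sp1,sp2));")
        assert "usertree" in doc
        assert "$prob=0" in doc

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            write_partitioned_nexus(self._conc(), model="jc")


def _write_p_file(path, values, header="m{1}"):
    values = np.asarray(values)
    if values.ndim == 1:
        values = values[:, None]
    lines = ["[ID: 0001]", "Gen\tLnL\t" + header]
    for i, v in enumerate(values):
        lines.append("\t".join([str(i * 500), "-100.0"]
                               + [f"{x:.6f}" for x in np.atleast_1d(v)]))
    path.write_text("\n".join(lines) + "\n")


class TestRatePosteriors:
    def test_constant_samples(self, tmp_path):
        p = tmp_path / "run1.p"
        _write_p_file(p, np.full(100, 2.5))
        summ = summarize_rate_posteriors([p], burnin_frac=0.25)
        s = summ["m{1}"]
        assert s["median"] == pytest.approx(2.5)
        assert s["ci95_high"] - s["ci95_low"] == pytest.approx(0.0)

    def test_uniform_quantiles_recovered(self, tmp_path, rng):
        n = 10_000
        vals = rng.random(int(n / 0.75))      # so 10k survive 25% burn-in
        p = tmp_path / "run1.p"
        _write_p_file(p, vals)
        summ = summarize_rate_posteriors([p], burnin_frac=0.25)
        s = summ["m{1}"]
        assert summ.n_samples == pytest.approx(10_000, abs=1)
        assert s["ci95_low"] == pytest.approx(0.025, abs=0.01)
        assert s["ci95_high"] == pytest.approx(0.975, abs=0.01)
        assert s["median"] == pytest.approx(0.5, abs=0.02)

    def test_burnin_arithmetic(self, tmp_path, rng):
        p = tmp_path / "run1.p"
        _write_p_file(p, rng.random(8000))
        summ = summarize_rate_posteriors([p], burnin_frac=0.25)
        assert summ.n_samples == 6000

    def test_runs_pooled(self, tmp_path, rng):
        p1, p2 = tmp_path / "r1.p", tmp_path / "r2.p"
        _write_p_file(p1, rng.random(400))
        _write_p_file(p2, rng.random(400))
        summ = summarize_rate_posteriors([p1, p2], burnin_frac=0.25)
        assert summ.n_samples == 600

    def test_header_mismatch_rejected(self, tmp_path, rng):
        p1, p2 = tmp_path / "r1.p", tmp_path / "r2.p"
        _write_p_file(p1, rng.random(10), header="m{1}")
        _write_p_file(p2, rng.random(10), header="m{2}")
        with pytest.raises(ValueError, match="headers"):
            summarize_rate_posteriors([p1, p2])

    def test_partition_naming(self, tmp_path, rng):
        p = tmp_path / "r1.p"
        _write_p_file(p, rng.random((50, 2)), header="m{1}\tm{2}")
        summ = summarize_rate_posteriors(
            [p], partition_names={"m{1}": "D-loop", "m{2}": "T-loop"})
        assert set(summ.partitions) == {"D-loop", "T-loop"}


class TestOrthologSetIO:
    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "sets.tsv"
        p.write_text(
            "set_id\tspecies\tgene_id\tclass\tflags\n"
            "os1\tspA\tg1\tK\t\n"
            "os1\tspB\tg2\tK\t\n"
            "os2\tspA\tg3\tN\tanticodon_shift\n")
        sets = read_ortholog_sets(p)
        assert len(sets) == 2
        assert sets[0].members == {"spA": "g1", "spB": "g2"}
        assert sets[1].anticodon_shift and sets[1].flagged

    def test_duplicate_species_rejected(self, tmp_path):
        p = tmp_path / "sets.tsv"
        p.write_text("set_id\tspecies\tgene_id\tclass\tflags\n"
                     "os1\tspA\tg1\tK\t\nos1\tspA\tg2\tK\t\n")
        with pytest.raises(ValueError):
            read_ortholog_sets(p)
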