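"""Genotype caller: enumeration, realignment, padding, separation, calling."""

import numpy as np
import pytest

from qtronset import ALLELES, CallerConfig, LowDepthError, RepeatLocus
from qtronset.align import find_min_error_path
from qtronset.caller import (
    LocusRead,
    apply_signature,
    build_padded_alignment,
    call_cohort,
    call_genotype,
    cross_sample_correct,
    enumerate_candidates,
    mate_pair_correct,
    realign_and_select,
    separate_alleles,
)
from qtronset.simulate import ReadSimConfig, simulate_reads


def _ref_paths(reads, locus, cfg):
    win = locus.reference_window()
    out = []
    for r in reads:
        p = find_min_error_path(
            r.seq, win, cfg.max_gaps, seed_len=cfg.seed_len,
            two_gap_trigger=cfg.two_gap_trigger,
            max_gap_penalty=cfg.max_gap_penalty,
        )
        if p is not None and p.M <= cfg.m_max:
            out.append((r, p))
    return out


class TestEnumerateCandidates:
    def test_perfect_reads_give_reference_only(self, locus, caller_config, make_reads):
        paths = _ref_paths(make_reads("A1", "A1"), locus, caller_config)
        cands = enumerate_candidates(paths, locus, caller_config)
        assert len(cands) == 1 and cands[0].signature == ()

    def test_single_deletion_signature(self, locus, caller_config, make_reads):
        paths = _ref_paths(make_reads("A1", "A2"), locus, caller_config)
        cands = enumerate_candidates(paths, locus, caller_config)
        sigs = {c.signature for c in cands}
        assert ((locus.tract_start + 96, -18, None),) in sigs

    def test_two_signatures_give_four_combinations(self, locus, caller_config):
        """Signatures {-18, +12} at distinct positions combine freely."""
        win = locus.reference_window()
        sig_del = ((200, -18, None),)
        sig_ins = ((400, 12, "CAGGCCCAGGCC"),)
        cands = enumerate_candidates(
            [], locus, caller_config, extra_signatures=(sig_del, sig_ins)
        )
        assert len(cands) == 4  # reference, each single, both
        lengths = sorted(len(c.sequence) for c in cands)
        assert lengths == [len(win) - 18, len(win) - 6, len(win), len(win) + 12]

    def test_overlapping_events_not_combined(self, locus, caller_config):
        cands = enumerate_candidates(
            [], locus, caller_config,
            extra_signatures=(((200, -18, None),), ((205, -6, None),)),
        )
        assert len(cands) == 3  # no joint haplotype for overlapping deletions


class TestApplySignature:
    def test_deletion_then_insertion(self):
        win = "AAAACCCCGGGGTTTT"
        assert apply_signature(win, ((4, -4, None),)) == "AAAAGGGGTTTT"
        assert apply_signature(win, ((4, 2, "NN"),)) == "AAAANNCCCCGGGGTTTT"
        assert (
            apply_signature(win, ((4, -4, None), (12, 2, "NN")))
            == "AAAAGGGGNNTTTT"
        )


class TestRealignAndSelect:
    def test_true_haplotype_preferred(self, locus, caller_config, make_reads):
        reads = make_reads("A1", "A2")
        paths = _ref_paths(reads, locus, caller_config)
        cands = enumerate_candidates(paths, locus, caller_config)
        asg = realign_and_select(
            [r for r, _ in paths], cands, locus, caller_config,
            reference_paths={(r.name, r.mate): p for r, p in paths},
        )
        h1 = next(i for i, c in enumerate(cands) if c.signature)
        spanning = [a for a in asg if a.candidate == h1]
        assert len(spanning) >= caller_config.min_support
        assert all(a.path.M == 0 for a in spanning)

    def test_pure_repeat_read_is_ambiguous(self, locus, caller_config):
        # a read lying wholly inside the pure-STR run cannot distinguish the
        # reference from a run-expansion haplotype: it ties and stays
        # uninformative for length
        run_start = locus.tract_start + 96
        reads = [LocusRead("amb", "CAGGCC" * 6, 1)]
        paths = _ref_paths(reads, locus, caller_config)
        assert paths
        cands = enumerate_candidates(
            paths, locus, caller_config,
            extra_signatures=(((run_start, 12, "CAGGCC" * 2),),),
        )
        asg = realign_and_select([r for r, _ in paths], cands, locus, caller_config)
        assert len(asg[0].ties) > 1
        assert asg[0].path.M == 0


class TestMatePairCorrection:
    def _mk(self, name, mate, cand, ties, path):
        from qtronset.caller import ReadAssignment

        return ReadAssignment(
            LocusRead(name, "A" * 20, mate), cand, path, ties, True,
            tie_paths={t: path for t in ties},
        )

    @pytest.fixture()
    def path(self, locus):
        win = locus.reference_window()
        return find_min_error_path(win[:40], win)

    def test_tie_resolved_by_informative_mate(self, path):
        a = self._mk("p", 1, 1, (1,), path)
        b = self._mk("p", 2, 0, (0, 1), path)
        mate_pair_correct([a, b])
        assert b.candidate == 1 and b.resolved_by_mate

    def test_concordant_pair_unchanged(self, path):
        a = self._mk("p", 1, 1, (1,), path)
        b = self._mk("p", 2, 1, (1,), path)
        mate_pair_correct([a, b])
        assert not a.conflict and not b.conflict

    def test_discordant_informative_pair_flagged(self, path):
        a = self._mk("p", 1, 0, (0,), path)
        b = self._mk("p", 2, 1, (1,), path)
        mate_pair_correct([a, b])
        assert a.conflict and b.conflict


class TestPaddedAlignment:
    def _padded(self, locus, cfg, reads):
        paths = _ref_paths(reads, locus, cfg)
        cands = enumerate_candidates(paths, locus, cfg)
        asg = realign_and_select(
            [r for r, _ in paths], cands, locus, cfg,
            reference_paths={(r.name, r.mate): p for r, p in paths},
        )
        asg = mate_pair_correct(asg)
        return build_padded_alignment(asg, cands, locus), cands

    def test_no_indels_no_asterisk_columns(self, locus, caller_config, make_reads):
        padded, _ = self._padded(locus, caller_config, make_reads("A1", "A1"))
        assert "*" not in padded.expanded_reference

    def test_depadding_reproduces_reads(self, locus, caller_config, make_reads):
        reads = make_reads("A1", "A2")
        padded, _ = self._padded(locus, caller_config, reads)
        by_key = {(r.name, r.mate): r.seq for r in reads}
        assert padded.rows, "no rows built"
        for i, (name, row) in enumerate(padded.rows):
            a = padded.row_assignments[i]
            assert padded.depad_row(i) == by_key[(a.read.name, a.read.mate)]

    def test_deletion_columns_carry_asterisks(self, locus, caller_config, make_reads):
        padded, cands = self._padded(locus, caller_config, make_reads("A1", "A2"))
        del_cols = range(
            locus.tract_start + 96, locus.tract_start + 96 + 18
        )
        star_rows = [
            row for _, row in padded.rows
            if all(row[c] == "*" for c in del_cols)
            and row[locus.tract_start + 95] in "ACGT"
        ]
        assert len(star_rows) >= caller_config.min_support

    def test_insertion_allele_expands_reference(self, locus, caller_config, make_reads):
        padded, _ = self._padded(locus, caller_config, make_reads("A1", "A4"))
        assert padded.expanded_reference.count("*") == 12


class TestSeparation:
    def test_single_stray_read_keeps_hom_call(self, locus, caller_config, make_reads):
        reads = make_reads("A1", "A1")
        # one stray read carrying a fake SNV
        pos = locus.tract_start + 30
        win = locus.reference_window()
        stray_seq = win[pos - 30 : pos] + "T" + win[pos + 1 : pos + 45]
        reads = reads + [LocusRead("stray", stray_seq, 1)]
        g = call_genotype(locus, reads, caller_config)
        assert g.zygosity == "hom" and g.allele_a.matched_spec == "A1"


class TestCallGenotype:
    @pytest.mark.parametrize(
        "pair",
        [("A1", "A1"), ("A1", "A2"), ("A2", "A4"), ("A5", "A8"), ("A1", "A6")],
    )
    def test_exact_recovery(self, locus, caller_config, make_reads, pair):
        g = call_genotype(locus, make_reads(*pair), caller_config)
        want_qtr = tuple(sorted(ALLELES[p].qtr_units for p in pair))
        want_str = tuple(
            s for _, s in sorted(
                (ALLELES[p].qtr_units, ALLELES[p].str_units) for p in pair
            )
        )
        assert (g.n_min, g.n_max) == want_qtr
        assert (g.allele_a.str_units, g.allele_b.str_units) == want_str
        assert g.zygosity == ("hom" if pair[0] == pair[1] else "het")

    def test_statistic_identities(self, locus, caller_config, make_reads):
        g = call_genotype(locus, make_reads("A2", "A4"), caller_config)
        assert g.n_sum == g.n_min + g.n_max
        assert g.n_diff == g.n_max - g.n_min
        assert g.n_min <= g.n_max
        assert g.allele_a.qtr_units == len(g.allele_a.sequence) // 6

    def test_low_coverage_uncallable(self, locus, caller_config, haplotypes):
        reads, _ = simulate_reads(
            haplotypes["A1"], haplotypes["A1"], ReadSimConfig(coverage=2, seed=3)
        )
        with pytest.raises(LowDepthError):
            call_genotype(locus, reads, caller_config)


class TestErrorRobustness:
    def test_recovery_with_sequencing_errors(self, locus, caller_config, haplotypes):
        """At a 0.2% per-base substitution rate and 30x coverage the vast
        majority of genotypes are still recovered exactly (replicates
        scaled to keep the suite fast; the recovery rate target is 95%)."""
        rng = np.random.default_rng(77)
        freqs = np.array([0.9131, 0.0410, 0.0230, 0.0197, 0.0008, 0.0008, 0.0008, 0.0008])
        freqs /= freqs.sum()
        names = sorted(ALLELES)
        n_reps, exact = 60, 0
        for _ in range(n_reps):
            a, b = np.random.default_rng(rng.integers(2**31)).choice(
                names, size=2, p=freqs
            )
            reads, _ = simulate_reads(
                haplotypes[a], haplotypes[b],
                ReadSimConfig(error_rate=0.002), rng=rng,
            )
            try:
                g = call_genotype(locus, reads, caller_config)
            except Exception:
                continue
            want = tuple(sorted((ALLELES[a].qtr_units, ALLELES[b].qtr_units)))
            exact += (g.n_min, g.n_max) == want
        assert exact / n_reps >= 0.90


class TestCrossSample:
    def test_single_sample_identity(self, locus, caller_config, make_reads):
        reads = {"s1": make_reads("A1", "A2")}
        first = {"s1": call_genotype(locus, reads["s1"], caller_config)}
        out = cross_sample_correct(locus, reads, first, caller_config)
        assert out["s1"] == first["s1"]

    def test_cohort_calling_two_samples(self, locus, caller_config, make_reads):
        reads = {
            "s1": make_reads("A1", "A3", seed=11),
            "s2": make_reads("A3", "A3", seed=12),
        }
        out = call_cohort(locus, reads, caller_config)
        assert out["s1"].n_sum == 74 and out["s2"].n_sum == 72

    def test_all_hom_ref_identity(self, locus, caller_config, make_reads):
        reads = {
            "s1": make_reads("A1", "A1", seed=21),
            "s2": make_reads("A1", "A1", seed=22),
        }
        out = call_cohort(locus, reads, caller_config)
        for g in out.values():
            assert g.zygosity == "hom" and g.n_sum == 76
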