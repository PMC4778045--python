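"""Quality trimming, codon extraction, frequency tables and enrichment."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropscreen import (
    ExtractionSyntax,
    enrichment,
    enrichment_significance,
    extract_codons,
    tabulate,
    trim_read,
)
from dropscreen.analysis import syntax_for_design, trim_batch


def oracle_trim_position(quals, cutoff):
    """Independent running-sum oracle: keep-length p minimizing the
    3'-partial sum S(p) = sum_{i>=p}(q_i - cutoff); least trimming on ties."""
    n = len(quals)
    best_p, best_s = n, 0
    for p in range(n, -1, -1):
        s = sum(q - cutoff for q in quals[p:])
        if s < best_s:
            best_s, best_p = s, p
    return best_p


class TestTrimming:
    def test_high_quality_read_unchanged(self):
        seq = "ACGT" * 14
        q = [30] * 56
        t_seq, t_q = trim_read(seq, q)
        assert t_seq == seq and len(t_q) == 56

    def test_low_quality_tail_removed(self):
        # 50 bases at Q35 then 6 at Q2: running sum cuts exactly at 50
        seq = "A" * 56
        q = [35] * 50 + [2] * 6
        t_seq, _ = trim_read(seq, q)
        assert len(t_seq) == 50

    def test_adapter_removed_before_quality_trim(self):
        adapter = "AGATCGGAAGAGC"
        insert = "ACGTACGTACGTACGT"
        seq = insert + adapter
        q = [35] * len(seq)
        t_seq, _ = trim_read(seq, q, adapter=adapter)
        assert t_seq == insert

    def test_partial_adapter_prefix_at_3prime_removed(self):
        adapter = "AGATCGGAAGAGC"
        insert = "ACGTACGTACGTACGT"
        seq = insert + adapter[:5]
        t_seq, _ = trim_read(seq, [35] * len(seq), adapter=adapter)
        assert t_seq == insert

    def test_never_lengthens_and_idempotent(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 80))
            seq = "".join(rng.choice(list("ACGT"), n))
            q = rng.integers(2, 41, n)
            t1, q1 = trim_read(seq, q)
            assert len(t1) <= n
            t2, _ = trim_read(t1, q1)
            assert t2 == t1

    def test_matches_brute_force_oracle_on_random_fixtures(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 70))
            q = rng.integers(2, 41, n).tolist()
            seq = "A" * n
            t_seq, _ = trim_read(seq, q)
            assert len(t_seq) == oracle_trim_position(q, 20)

    @given(st.lists(st.integers(min_value=2, max_value=41), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=200)
    def test_oracle_equivalence_property(self, quals):
        t_seq, _ = trim_read("A" * len(quals), quals)
        assert len(t_seq) == oracle_trim_position(quals, 20)

    def test_batch_trim_equals_scalar(self, rng):
        qmat = rng.integers(2, 41, size=(200, 56))
        cuts = trim_batch(qmat)
        for row, cut in zip(qmat, cuts):
            t_seq, _ = trim_read("A" * 56, row)
            assert len(t_seq) == cut


@pytest.fixture(scope="module")
def syntax(design):
    return syntax_for_design(design)


def _perfect_read(design, genotype):
    from dropscreen import build_template
    from dropscreen.reads import read_window_offset

    offset = read_window_offset(design)
    return build_template(design, genotype)[offset : offset + 56]


class TestExtraction:
    def test_error_free_read_yields_genotype_and_peptide(self, design, syntax):
        read = _perfect_read(design, ("TTT", "TGG", "TTG"))
        codons, reason = extract_codons(read, syntax)
        assert reason is None
        assert codons == ("TTT", "TGG", "TTG")
        from dropscreen import translate_codon

        assert "".join(translate_codon(c) for c in codons) == "FWL"

    def test_single_anchor_mismatch_tolerated(self, design, syntax):
        read = list(_perfect_read(design, ("TTT", "TGG", "TTG")))
        read[2] = "A" if read[2] != "A" else "C"  # inside the first anchor
        codons, reason = extract_codons("".join(read), syntax)
        assert reason is None
        assert codons == ("TTT", "TGG", "TTG")

    def test_two_mismatches_in_one_anchor_rejected(self, design, syntax):
        read = list(_perfect_read(design, ("TTT", "TGG", "TTG")))
        for i in (2, 4):  # both inside the first 16-nt anchor
            read[i] = "A" if read[i] != "A" else "C"
        codons, reason = extract_codons("".join(read), syntax)
        assert codons is None and reason == "anchor_mismatch"

    def test_truncated_read_rejected(self, design, syntax):
        read = _perfect_read(design, ("TTT", "TGG", "TTG"))
        last_slot_end = syntax.slot_offset(syntax.n_slots - 1) + 3
        codons, reason = extract_codons(read[: last_slot_end - 2], syntax)
        assert codons is None and reason == "truncated"

    def test_empty_read_rejected(self, syntax):
        codons, reason = extract_codons("", syntax)
        assert codons is None and reason == "empty"

    def test_ambiguous_placement_rejected(self):
        # repeated anchor admits two alignments of the layout
        syntax = ExtractionSyntax(("AC", "AC"), max_mismatches_per_anchor=0)
        codons, reason = extract_codons("ACGGGACGGGAC", syntax)
        assert codons is None and reason == "ambiguous"

    def test_batch_extraction_equals_scalar_scan(self, design, syntax, rng):
        # random perturbations: substitutions, truncations, empties
        from dropscreen.analysis import extract_batch

        base = _perfect_read(design, ("TTT", "TGG", "TTG"))
        reads = []
        for _ in range(300):
            r = list(base)
            for _ in range(int(rng.integers(0, 4))):
                i = int(rng.integers(len(r)))
                r[i] = "ACGT"[int(rng.integers(4))]
            cut = int(rng.integers(0, len(r) + 1)) if rng.random() < 0.3 else len(r)
            reads.append("".join(r[:cut]))
        batch_codons, batch_reasons = extract_batch(reads, syntax)
        for read, bc, br in zip(reads, batch_codons, batch_reasons):
            sc, sr = extract_codons(read, syntax)
            assert (bc, br) == (sc, sr)

    def test_round_trip_through_template(self, design, syntax, library):
        for v in library[::1111]:
            for g in v.genotypes:
                codons, reason = extract_codons(_perfect_read(design, g), syntax)
                assert reason is None and codons == g


class TestTabulate:
    def test_singleton(self):
        t = tabulate([("TTT", "TGG", "TTG")], "bright")
        assert t.per_peptide == {"FWL": 1.0}
        assert t.genotype_diversity == {"FWL": 1}

    def test_genotype_diversity_counts_synonyms(self):
        tuples = [("TTT", "TGG", "TTG"), ("TTT", "TGG", "CTG"), ("TTT", "TGG", "CTT")]
        t = tabulate(tuples * 4, "bright")
        assert t.per_peptide == {"FWL": 1.0}
        assert t.genotype_diversity["FWL"] == 3

    def test_stop_tuples_counted_and_excluded(self):
        tuples = [("TTT", "TGG", "TTG"), ("TAG", "TGG", "TTG")]
        t = tabulate(tuples, "input")
        assert t.n_stop == 1
        assert t.per_peptide == {"FWL": 1.0}

    def test_marginals_normalized_and_consistent(self):
        tuples = [
            ("TTT", "TGG", "TTG"),
            ("TTT", "AGT", "TTG"),
            ("CAT", "TGG", "TTG"),
            ("TTT", "TGG", "CTG"),
        ]
        t = tabulate(tuples, "input")
        for marg in t.per_position:
            assert sum(marg.values()) == pytest.approx(1.0)
        # position-1 marginal equals the joint summed over other positions
        f_from_joint = sum(
            f for pep, f in t.per_peptide.items() if pep[0] == "F"
        )
        assert t.per_position[0]["F"] == pytest.approx(f_from_joint)


def _table_from_freqs(freqs, pool, depth=100_000):
    tuples = []
    by_pep = {"FWL": ("TTT", "TGG", "TTG"), "AAA": ("GCT", "GCT", "GCT"),
              "CCC": ("TGT", "TGT", "TGT")}
    for pep, f in freqs.items():
        tuples.extend([by_pep[pep]] * round(f * depth))
    return tabulate(tuples, pool)


class TestEnrichment:
    def test_printed_pool_frequencies_give_488_fold(self):
        # bright 21% vs input 0.043% -> 488-fold for the FWL binder
        bright = _table_from_freqs({"FWL": 0.21, "AAA": 0.79}, "bright")
        input_ = _table_from_freqs({"FWL": 0.00043, "AAA": 0.99957}, "input")
        table = enrichment(bright, input_)
        assert round(table.fold("FWL")) == 488

    def test_identical_pools_fold_one(self):
        a = _table_from_freqs({"FWL": 0.3, "AAA": 0.7}, "bright")
        b = _table_from_freqs({"FWL": 0.3, "AAA": 0.7}, "input")
        table = enrichment(a, b)
        assert np.allclose(table.table["fold"], 1.0)

    def test_dark_pool_fold_1_8_not_significant(self):
        # dark 0.079% vs input 0.043%: fold 1.8 at one decimal
        dark = _table_from_freqs({"FWL": 0.00079, "AAA": 0.99921}, "dark")
        input_ = _table_from_freqs({"FWL": 0.00043, "AAA": 0.99957}, "input")
        table = enrichment(dark, input_)
        assert round(table.fold("FWL"), 1) == 1.8
        # at a shallow dark-pool depth the bootstrap ratio CI straddles 1
        shallow = _table_from_freqs({"FWL": 0.00079, "AAA": 0.99921}, "dark", 10_000)
        sig = enrichment_significance(
            shallow.count("FWL"), shallow.n_reads_used,
            input_.count("FWL"), input_.n_reads_used, seed=0,
        )
        assert not sig["enriched"]

    def test_absent_from_input_flagged_not_divided(self):
        bright = _table_from_freqs({"FWL": 0.5, "AAA": 0.5}, "bright")
        input_ = _table_from_freqs({"AAA": 1.0}, "input")
        table = enrichment(bright, input_)
        row = table.table.set_index("peptide").loc["FWL"]
        assert row["flagged_no_input"]
        assert math.isnan(row["fold"])

    def test_ranked_descending(self):
        bright = _table_from_freqs({"FWL": 0.6, "AAA": 0.3, "CCC": 0.1}, "bright")
        input_ = _table_from_freqs({"FWL": 0.1, "AAA": 0.3, "CCC": 0.6}, "input")
        table = enrichment(bright, input_).table
        folds = table["fold"].dropna().to_numpy()
        assert np.all(np.diff(folds) <= 0)
        assert table.iloc[0]["peptide"] == "FWL"


class TestSignificance:
    def test_strong_enrichment_ci_excludes_one(self):
        sig = enrichment_significance(2100, 10_000, 43, 100_000, seed=1)
        assert sig["enriched"] and sig["ci_low"] > 1
        # normal-approximation oracle for the log frequency ratio
        p1, p2 = 2100 / 10_000, 43 / 100_000
        se = math.sqrt((1 - p1) / 2100 + (1 - p2) / 43)
        log_lo = math.log(p1 / p2) - 1.96 * se
        log_hi = math.log(p1 / p2) + 1.96 * se
        assert math.log(sig["ci_low"]) == pytest.approx(log_lo, abs=3 * se / math.sqrt(43))
        assert math.log(sig["ci_high"]) == pytest.approx(log_hi, abs=3 * se / math.sqrt(43))

    def test_symmetric_null_ci_contains_one(self):
        sig = enrichment_significance(50, 10_000, 50, 10_000, seed=2)
        assert not sig["enriched"]
        assert sig["ci_low"] < 1 < sig["ci_high"]

    def test_zero_reference_count_undefined(self):
        sig = enrichment_significance(10, 1000, 0, 1000, seed=3)
        assert sig["undefined"] and not sig["enriched"]
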