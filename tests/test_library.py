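"""Fusion enumeration, junction windows, scoring, selection, dedup."""

import pytest

from hipscreen.library import (
    ConstantPredictor,
    LibraryConfig,
    SurrogatePwmPredictor,
    TablePredictor,
    build_library,
    deduplicate,
    enumerate_fusions,
    junction_windows,
    load_predictor_table,
    score_candidates,
    select_top_fraction,
)
from hipscreen.proinsulin import ProinsulinSequence, fragment_kmers


class TestEnumerateFusions:
    def test_small_counts(self, proinsulin):
        frags = fragment_kmers(proinsulin, k=12)[:3]
        assert len(enumerate_fusions(frags, allow_self=False)) == 6
        assert len(enumerate_fusions(frags, allow_self=True)) == 9

    def test_full_counts(self, proinsulin):
        frags = fragment_kmers(proinsulin, k=12)
        assert len(frags) == 75
        assert len(enumerate_fusions(frags, allow_self=False)) == 75 * 74
        assert len(enumerate_fusions(frags, allow_self=True)) == 75 * 75

    def test_deterministic_order(self, proinsulin):
        frags = fragment_kmers(proinsulin, k=12)[:5]
        a = enumerate_fusions(frags)
        b = enumerate_fusions(list(reversed(frags)))
        assert [(f.left.span.as_tuple(), f.right.span.as_tuple()) for f in a] == [
            (f.left.span.as_tuple(), f.right.span.as_tuple()) for f in b
        ]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            enumerate_fusions([])


class TestJunctionWindows:
    def test_24mer_yields_11_candidates(self, proinsulin):
        frags = fragment_kmers(proinsulin, k=12)
        fusion = enumerate_fusions(frags[:2])[0]
        cands = junction_windows(fusion, w=12)
        assert len(cands) == 11
        assert [c.offset for c in cands] == list(range(1, 12))

    def test_end_window_contributions(self, proinsulin):
        frags = fragment_kmers(proinsulin, k=12)
        fusion = enumerate_fusions(frags[:2])[0]
        last = junction_windows(fusion, w=12)[-1]
        assert (last.left_len, last.right_len) == (1, 11)

    def test_total_candidates_before_dedup(self, proinsulin):
        frags = fragment_kmers(proinsulin, k=12)
        fusions = enumerate_fusions(frags, allow_self=False)
        total = sum(len(junction_windows(f, w=12)) for f in fusions[:50])
        assert total == 50 * 11  # every 24-mer contributes 11
        assert len(fusions) * 11 == 61050

    def test_oversized_window_rejected(self, proinsulin):
        frags = fragment_kmers(proinsulin, k=12)
        fusion = enumerate_fusions(frags[:2])[0]
        with pytest.raises(ValueError):
            junction_windows(fusion, w=25)


class TestPredictors:
    def test_surrogate_deterministic_and_anchor_preference(self):
        pred = SurrogatePwmPredictor()
        assert pred.score("GQVELGGGE") == pred.score("GQVELGGGE")
        # acidic P9 anchor scores stronger (lower) than alanine
        assert pred.score("GQVELGGGE") < pred.score("GQVELGGGA")

    def test_table_lookup_and_missing(self):
        pred = TablePredictor({"AAAA": 5.0})
        assert pred.score("AAAA") == 5.0
        with pytest.raises(KeyError):
            pred.score_many(["AAAA", "CCCC"])

    def test_table_loader_requires_direction(self, tmp_path):
        good = tmp_path / "good.csv"
        good.write_text("# rank: ascending\nsequence,rank\nAAAA,5.0\n")
        assert load_predictor_table(good).score("AAAA") == 5.0
        bad = tmp_path / "bad.csv"
        bad.write_text("sequence,rank\nAAAA,5.0\n")
        with pytest.raises(ValueError, match="ascending"):
            load_predictor_table(bad)


def _scored_toy_candidates(proinsulin, n_frags=4):
    frags = fragment_kmers(proinsulin, k=12)[:n_frags]
    cands = [c for f in enumerate_fusions(frags) for c in junction_windows(f, w=12)]
    return cands


class TestSelection:
    def test_floor_rule(self, proinsulin):
        cands = score_candidates(_scored_toy_candidates(proinsulin), SurrogatePwmPredictor())
        n = len(cands)
        kept = select_top_fraction(cands, q=0.21)
        assert len(kept) == int(0.21 * n)

    def test_q_one_keeps_all(self, proinsulin):
        cands = score_candidates(_scored_toy_candidates(proinsulin), SurrogatePwmPredictor())
        assert len(select_top_fraction(cands, q=1.0)) == len(cands)

    def test_tie_break_is_lexicographic(self, proinsulin):
        cands = score_candidates(
            _scored_toy_candidates(proinsulin)[:10], ConstantPredictor()
        )
        kept = select_top_fraction(cands, q=0.5)
        expected = sorted({c.sequence for c in cands} | set())
        brute = sorted(cands, key=lambda c: (c.sequence, c.sort_key()))[:5]
        assert [c.sequence for c in kept] == [c.sequence for c in brute]

    def test_invalid_q_and_unscored(self, proinsulin):
        cands = _scored_toy_candidates(proinsulin)
        with pytest.raises(ValueError):
            select_top_fraction(score_candidates(cands, ConstantPredictor()), q=0.0)
        with pytest.raises(ValueError):
            select_top_fraction(cands, q=0.5)  # unscored

    def test_selection_monotone_in_q(self, proinsulin):
        cands = score_candidates(_scored_toy_candidates(proinsulin), SurrogatePwmPredictor())
        sizes = [len(deduplicate(select_top_fraction(cands, q=q))) for q in (0.1, 0.3, 0.6, 1.0)]
        assert sizes == sorted(sizes)


class TestDeduplicate:
    def test_merges_identical_sequences(self, proinsulin):
        cands = score_candidates(_scored_toy_candidates(proinsulin), ConstantPredictor())
        lib = deduplicate(cands)
        assert len(lib) == len({c.sequence for c in cands})
        assert sum(len(e.provenances) for e in lib.entries) == len(cands)
        assert lib.sequences() == sorted(lib.sequences())

    def test_idempotent(self, proinsulin):
        cands = score_candidates(_scored_toy_candidates(proinsulin), ConstantPredictor())
        lib = deduplicate(cands)
        again = deduplicate([p for e in lib.entries for p in e.provenances])
        assert again.sequences() == lib.sequences()


def brute_force_junction_wmers(residues: str, k: int, w: int) -> set[str]:
    """Independent enumeration of all distinct junction-spanning w-mers."""
    kmers = [(i, residues[i : i + k]) for i in range(len(residues) - k + 1)]
    out = set()
    for i, a in kmers:
        for j, b in kmers:
            if i == j:
                continue
            fusion = a + b
            for off in range(len(fusion) - w + 1):
                left_len = k - off
                if 1 <= left_len <= w - 1:
                    out.add(fusion[off : off + w])
    return out


class TestBuildLibrary:
    def test_toy_pipeline_matches_brute_force(self):
        toy = ProinsulinSequence(
            residues="FVNQHLCGSHLVEALYLVCG", regions=(("B_chain", 1, 20),)
        )
        lib = build_library(LibraryConfig(k=6, w=6, q=1.0), ConstantPredictor(), seq=toy)
        expected = brute_force_junction_wmers(toy.residues, k=6, w=6)
        assert set(lib.sequences()) == expected

    def test_every_member_spans_a_junction(self, proinsulin):
        toy = ProinsulinSequence(
            residues="FVNQHLCGSHLVEALYLVCG", regions=(("B_chain", 1, 20),)
        )
        lib = build_library(LibraryConfig(k=6, w=6, q=0.5), SurrogatePwmPredictor(), seq=toy)
        for e in lib.entries:
            for p in e.provenances:
                assert p.left_len >= 1 and p.right_len >= 1

    def test_stage_counts_reported(self, proinsulin):
        toy = ProinsulinSequence(residues="FVNQHLCGSHLV", regions=(("B_chain", 1, 12),))
        lib = build_library(LibraryConfig(k=4, w=4, q=1.0), ConstantPredictor(), seq=toy)
        rep = lib.build_report
        assert rep["fragments"] == 9
        assert rep["fusions"] == 9 * 8
        assert rep["junction_candidates"] == 9 * 8 * 3
        assert rep["library"] == len(lib)

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            build_library(LibraryConfig(q=0.0), ConstantPredictor())

    def test_paper_scale_stage_counts(self, paper_scale_library):
        assert len(paper_scale_library) == 4488
        assert paper_scale_library.build_report["candidates"] == 61050
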