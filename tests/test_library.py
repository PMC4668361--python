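"""Natural-diversity tallying and framework-library design filters."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from baddisplay.errors import IncompatibleChainError, LibraryParseError, MissingAnnotationError
from baddisplay.kabat import KABAT_HEAVY_REGIONS, KABAT_LIGHT_REGIONS, KabatPosition
from baddisplay.library import (
    BurialAnnotation,
    DesignConfig,
    LibraryVariant,
    VariantObservation,
    audit_design,
    design_library,
    read_library,
    tally_natural_diversity,
    write_library,
)
from baddisplay.numbering import NumberedSequence, assign_numbering


def _numbered(germline, seq, source_id):
    return assign_numbering(seq, germline, source_id=source_id)


def _mutate(seq, idx0, to):
    return seq[:idx0] + to + seq[idx0 + 1 :]


class TestTally:
    def test_pure_germline_repertoire_is_empty(self, kappa_germline):
        rep = [
            _numbered(kappa_germline, kappa_germline.sequence, f"s{i}")
            for i in range(5)
        ]
        assert tally_natural_diversity(rep, kappa_germline) == []

    def test_counts_match_direct_enumeration(self, kappa_germline):
        seq = kappa_germline.sequence
        rep = []
        for i in range(10):
            s = _mutate(seq, 3, "L") if i < 3 else seq  # M4L in 3 of 10
            rep.append(_numbered(kappa_germline, s, f"s{i}"))
        obs = tally_natural_diversity(rep, kappa_germline)
        assert len(obs) == 1
        o = obs[0]
        assert (str(o.pos), o.from_aa, o.to_aa, o.count) == ("4", "M", "L", 3)

    def test_two_alternatives_at_one_position(self, kappa_germline):
        seq = kappa_germline.sequence
        rep = [
            _numbered(kappa_germline, _mutate(seq, 3, "L"), "a"),
            _numbered(kappa_germline, _mutate(seq, 3, "L"), "b"),
            _numbered(kappa_germline, _mutate(seq, 3, "V"), "c"),
        ]
        obs = tally_natural_diversity(rep, kappa_germline)
        assert [(o.to_aa, o.count) for o in obs] == [("L", 2), ("V", 1)]

    def test_mixed_chain_classes_rejected(self, kappa_germline, heavy_germline):
        rep = [_numbered(heavy_germline, heavy_germline.sequence, "h")]
        with pytest.raises(IncompatibleChainError):
            tally_natural_diversity(rep, kappa_germline)


def _obs(number, from_aa, to_aa, count=1, chain="heavy"):
    return VariantObservation(
        chain=chain, pos=KabatPosition(number), from_aa=from_aa, to_aa=to_aa, count=count
    )


def _burial(number, rsa, chain="heavy"):
    return BurialAnnotation(chain=chain, pos=KabatPosition(number), rsa=rsa)


class TestDesignFilters:
    def test_cdr_observation_excluded(self):
        obs = [_obs(50, "V", "I")]  # CDR-H2
        out = design_library(obs, [_burial(50, 0.05)], KABAT_HEAVY_REGIONS)
        assert out == []

    def test_surface_exposed_excluded(self):
        obs = [_obs(6, "E", "Q")]
        out = design_library(obs, [_burial(6, 0.6)], KABAT_HEAVY_REGIONS)
        assert out == []

    def test_planted_truth_table(self):
        """8 buried-FR changes pass; CDR, surface, excluded and low-support fail."""
        buried_fr = [2, 4, 6, 18, 37, 48, 70, 80]
        obs = [_obs(n, "V", "I", count=2) for n in buried_fr]
        obs += [_obs(50, "V", "I", count=2), _obs(96, "D", "E", count=2)]  # CDR
        obs += [_obs(10, "G", "A", count=2)]  # surface
        obs += [_obs(43, "K", "R", count=1)]  # low support under min_count=2
        burial = [_burial(n, 0.1) for n in buried_fr + [50, 96, 43]]
        burial += [_burial(10, 0.8)]
        config = DesignConfig(min_count=2)
        out = design_library(obs, burial, KABAT_HEAVY_REGIONS, config)
        assert [v.pos.number for v in out] == buried_fr
        assert all(
            v.filter_log == ("framework", "buried", "not-excluded", "supported")
            for v in out
        )
        audit = audit_design(obs, burial, KABAT_HEAVY_REGIONS, config)
        assert audit["retained"].sum() == len(buried_fr)

    def test_excluded_positions(self):
        obs = [_obs(6, "E", "Q")]
        config = DesignConfig(excluded_positions=frozenset({KabatPosition(6)}))
        out = design_library(obs, [_burial(6, 0.05)], KABAT_HEAVY_REGIONS, config)
        assert out == []

    def test_missing_burial_strict_vs_permissive(self):
        obs = [_obs(6, "E", "Q")]
        assert design_library(obs, [], KABAT_HEAVY_REGIONS) == []
        with pytest.raises(MissingAnnotationError):
            design_library(obs, [], KABAT_HEAVY_REGIONS, DesignConfig(strict_burial=True))

    def test_variant_names(self):
        out = design_library(
            [_obs(6, "E", "Q"), _obs(48, "V", "I")],
            [_burial(6, 0.1), _burial(48, 0.1)],
            KABAT_HEAVY_REGIONS,
        )
        assert [v.name for v in out] == ["E6Q", "V48I"]


@given(
    rsa_pairs=st.lists(
        st.tuples(st.integers(min_value=1, max_value=94), st.floats(0, 1)),
        min_size=1,
        max_size=12,
        unique_by=lambda t: t[0],
    ),
    rsa_max_lo=st.floats(0.05, 0.4),
    rsa_max_hi=st.floats(0.45, 0.9),
)
def test_design_monotone_in_rsa_cutoff(rsa_pairs, rsa_max_lo, rsa_max_hi):
    """Raising rsa_max never removes a variant: output sets are nested."""
    obs = [_obs(n, "A", "G", count=1) for n, _ in rsa_pairs]
    burial = [_burial(n, r) for n, r in rsa_pairs]
    lo = design_library(obs, burial, KABAT_HEAVY_REGIONS, DesignConfig(rsa_max=rsa_max_lo))
    hi = design_library(obs, burial, KABAT_HEAVY_REGIONS, DesignConfig(rsa_max=rsa_max_hi))
    assert {v.name for v in lo} <= {v.name for v in hi}


class TestLibraryRoundTrip:
    def test_empty(self, tmp_path):
        path = tmp_path / "lib.tsv"
        write_library([], path)
        assert read_library(path) == []

    def test_campaign_scale_library_round_trips(self, tmp_path):
        """A 33-member library (5 light + 28 heavy) survives the round trip."""
        light = [
            LibraryVariant("light", KabatPosition(n), f, t, support=s)
            for n, f, t, s in [
                (4, "M", "L", 7),
                (9, "S", "A", 2),
                (12, "S", "A", 3),
                (15, "V", "L", 1),
                (18, "R", "K", 2),
            ]
        ]
        heavy_positions = [2, 5, 6, 7, 11, 12, 13, 16, 17, 18, 19, 20, 21, 23,
                           24, 25, 38, 40, 41, 42, 43, 44, 46, 48, 49, 69, 71, 78]
        froms = itertools.cycle("VLESAG")
        tos = itertools.cycle("ILMQTV")
        heavy = []
        for n in heavy_positions:
            f = next(froms)
            t = next(t2 for t2 in tos if t2 != f)
            heavy.append(LibraryVariant("heavy", KabatPosition(n), f, t, support=1))
        lib = light + heavy
        path = tmp_path / "lib.tsv"
        write_library(lib, path)
        back = read_library(path)
        assert back == lib
        assert sum(v.chain == "light" for v in back) == 5
        assert sum(v.chain == "heavy" for v in back) == 28

    def test_byte_identical_output(self, tmp_path):
        lib = [LibraryVariant("heavy", KabatPosition(6), "E", "Q", 4, ("framework",))]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_library(lib, p1)
        write_library(lib, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "chain\tkabat_position\tfrom_aa\tto_aa\tsupport\tname\tfilters_passed\n"
            "heavy\t6\tE\tQ\t4\tE6Q\t\n"
            "heavy\tnot_a_pos\tE\tQ\t1\tE6Q\t\n"
        )
        with pytest.raises(LibraryParseError, match="line 3"):
            read_library(path)
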