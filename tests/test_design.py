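"""Template library construction: variant series, validators, screens."""

from collections import Counter

import numpy as np
import pytest

from rnarray.design import (
    ConstraintError,
    ConstructionError,
    DesignTable,
    agilent_series,
    da_walk_series,
    make_control,
    make_template,
    primer_selectivity_screen,
    validate_crosslink_site,
    _distinct_rearrangements,
)
from rnarray.seqcore import (
    Chemistry,
    DEFAULT_PRIMER,
    PrimerSpec,
    RoleError,
    predicted_product,
    revcomp,
)

from conftest import BLUE, GREEN, RED, SHARED_3P_BLOCK


class TestMakeTemplate:
    def test_green_dt5_full_sequence(self):
        t = make_template(GREEN, 5)
        assert t.full_sequence == "TCAACCCAGGTCCAATTTCCTTCGCCGTGTCCCTATTTTT"
        assert t.length == 40

    def test_red_dt5_length(self):
        assert make_template(RED, 5).length == 45  # 25 + 15 + 5

    def test_platform_limit_boundary(self):
        ok = make_template("A" * 130, 5)  # 130 + 15 + 5 = 150
        assert ok.length == 150
        with pytest.raises(ConstraintError, match="151"):
            make_template("A" * 131, 5)
        # photolithography platform has no hard length cap
        make_template("A" * 131, 5, platform="photolithography")

    def test_ends_with_shared_block(self):
        assert make_template(GREEN, 5).full_sequence.endswith(SHARED_3P_BLOCK)


class TestMakeControl:
    def test_green_control_sequence(self):
        c = make_control(GREEN, 5)
        assert c.full_sequence == "GGAAATTGGACCTGGGTTGA" + "TTTTT"
        assert c.role == "control"

    def test_no_primer_complement_15mer(self):
        block = DEFAULT_PRIMER.complement_block()
        c = make_control(GREEN, 5)
        assert block not in c.full_sequence
        # planting the block in the control sequence is rejected at build time
        with pytest.raises(ConstraintError):
            make_control(revcomp(block, Chemistry.DNA, Chemistry.DNA), 5)


class TestCrosslinkSite:
    def test_default_primer_passes(self):
        for variable in (GREEN, RED, BLUE):
            report = validate_crosslink_site(make_template(variable, 5))
            assert report.passed
            assert report.duplex_len == 15

    def test_changed_5p_base_breaks_terminal_pair(self):
        mut = PrimerSpec.from_sequence("CAGGGACACGGCGAA", name="mut")  # 5' U -> C
        template = make_template(GREEN, 5, mut)
        report = validate_crosslink_site(template, mut)
        assert report.all_watson_crick  # duplex itself is still perfect
        assert not report.terminal_pair_is_ua_or_ta
        assert not report.passed

    def test_zero_linker_fails(self):
        report = validate_crosslink_site(make_template(GREEN, 0))
        assert not report.linker_first_base_is_t
        assert not report.passed

    def test_control_has_no_site(self):
        with pytest.raises(RoleError):
            validate_crosslink_site(make_control(GREEN, 5))


class TestSelectivityScreen:
    def test_planted_12mer_is_flagged(self):
        # TTCGCCGTGTCC is the complement of the primer's 3'-most 12 nt
        bad = make_template("AAAA" + "TTCGCCGTGTCC" + "AAAA", 5, probe_id="bad")
        hits = primer_selectivity_screen([bad])
        assert len(hits) == 1
        assert hits[0].stretch_len == 12
        assert hits[0].offset == 4

    def test_rgb_variable_regions_are_clean(self):
        lib = [make_template(v, 5, probe_id=v[:6]) for v in (RED, GREEN, BLUE)]
        assert primer_selectivity_screen(lib) == []

    def test_degenerate_threshold_flags_everything(self):
        lib = [make_template(v, 5, probe_id=v[:6]) for v in (RED, GREEN, BLUE)]
        assert len(primer_selectivity_screen(lib, min_flag_len=1)) == 3

    def test_brute_force_oracle_agreement(self):
        # independent oracle: enumerate every primer substring directly
        rng = np.random.default_rng(42)
        primer_dna = DEFAULT_PRIMER.sequence.replace("U", "T")
        for _ in range(25):
            var = "".join(rng.choice(list("ACGT"), size=30))
            t = make_template(var, 5, probe_id="r")
            best = 0
            for i in range(len(primer_dna)):
                for j in range(i + 1, len(primer_dna) + 1):
                    sub = primer_dna[i:j]
                    rc = revcomp(sub, Chemistry.DNA, Chemistry.DNA)
                    if rc in var or sub in var:
                        best = max(best, j - i)
            hits = primer_selectivity_screen([t], min_flag_len=4)
            found = hits[0].stretch_len if hits else 0
            assert found == (best if best >= 4 else 0)

    def test_empty_library(self):
        assert primer_selectivity_screen([]) == []


@pytest.fixture(scope="module")
def series():
    return agilent_series(GREEN, replicate_count=60, seed=1)


@pytest.fixture(scope="module")
def walk():
    return da_walk_series()


class TestAgilentSeries:
    def test_sixty_replicates_per_probe(self, series):
        layout = series.randomized_layout(seed=1)
        counts = Counter(layout.features.values())
        assert set(counts.values()) == {60}
        assert len(counts) == len(series)

    def test_linker_lengths(self, series):
        linkers = {t.linker_len for t in series}
        assert max(linkers) == 20
        assert {5, 10, 15, 20} <= linkers

    def test_platform_limit_respected(self, series):
        assert all(t.length <= 150 for t in series)

    def test_identical_terminal_bases_collapse(self):
        assert _distinct_rearrangements("TTT") == ["TTT"]
        assert len(_distinct_rearrangements("CTA")) == 6

    def test_reference_templates_pass_crosslink_check(self, series):
        for t in series:
            if t.probe_id.startswith(("tmpl_", "cperm")):
                assert validate_crosslink_site(t).passed

    def test_duplicate_ids_rejected(self):
        t = make_template(GREEN, 5, probe_id="dup")
        with pytest.raises(ConstructionError):
            DesignTable([t, t])


class TestDaWalkSeries:
    def test_variant_geometry(self, walk):
        templates = [t for t in walk if t.role == "transcribable"]
        assert len(templates) == 21
        for t in templates:
            assert len(t.variable) == 61
            assert Counter(t.variable) == {"A": 1, "T": 20, "G": 20, "C": 20}

    def test_twenty_after_dc_variants(self, walk):
        positions = sorted(t.ru_position for t in walk if t.role == "transcribable")
        assert positions == [1] + [3 * k + 1 for k in range(1, 21)]

    def test_position_annotation_matches_extension_oracle(self, walk):
        """Brute-force simulation of templated extension, base by base."""
        for t in walk:
            if t.role != "transcribable":
                continue
            rna = predicted_product(t, DEFAULT_PRIMER).segments[1].sequence
            # extension position p copies the template base p steps from the
            # block-proximal (3') end of the variable region
            assert rna.index("U") + 1 == t.ru_position

    def test_endpoint_variants(self, walk):
        by_pos = {t.ru_position: t for t in walk if t.role == "transcribable"}
        # surface-proximal variant: dA adjacent to the primer-complement block
        assert by_pos[1].variable.endswith("A")
        # distal variant: dA at the 5' end of the variable region
        assert by_pos[61].variable.startswith("A")

    def test_matched_controls(self, walk):
        controls = [t for t in walk if t.role == "control"]
        assert len(controls) == 21
        assert {c.ru_position for c in controls} == {
            t.ru_position for t in walk if t.role == "transcribable"
        }


def test_product_round_trip_recovers_variable():
    """revcomp(RNA product segment) recovers the variable region exactly."""
    rng = np.random.default_rng(7)
    for _ in range(1000):
        var = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
        t = make_template(var, 5, probe_id="rt")
        rna = predicted_product(t, DEFAULT_PRIMER).segments[1].sequence
        assert revcomp(rna, Chemistry.RNA, Chemistry.DNA) == var
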