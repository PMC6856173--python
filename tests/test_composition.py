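"""Composition parsing and N-glycan classification rules."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoculture.composition import (
    CompositionError,
    GlycanClassError,
    MonosaccharideCounts,
    PROTON_MASS,
    classify_n_glycan,
    count_antennae,
    format_composition,
    lacdinac_by_composition,
    match_oxonium,
    oxonium_mz,
    parse_composition,
    split_fucose,
)


@pytest.mark.parametrize(
    "text, aliases, expected",
    [
        ("HexNAc(4)Hex(5)Fuc(1)NeuAc(2)", False,
         MonosaccharideCounts(hexnac=4, hex=5, fuc=1, neuac=2)),
        ("HexNAc4Hex5Fuc1NeuAc2", False,
         MonosaccharideCounts(hexnac=4, hex=5, fuc=1, neuac=2)),
        # O-glycan vocabulary: Gal→Hex, GalNAc→HexNAc
        ("NeuAc2GalGalNAc", True,
         MonosaccharideCounts(hexnac=1, hex=1, neuac=2)),
        ("HexNAc", False, MonosaccharideCounts(hexnac=1)),
        # repeated tokens sum
        ("Hex(2)Hex(3)", False, MonosaccharideCounts(hex=5)),
        ("NeuGc(1)HexNAc(2)", False, MonosaccharideCounts(hexnac=2, neugc=1)),
    ],
)
def test_parse_composition(text, aliases, expected):
    assert parse_composition(text, aliases=aliases) == expected


@pytest.mark.parametrize(
    "text, aliases",
    [
        ("HexNAc4Xyl1", False),   # unknown residue
        ("HexNAc(0)", False),     # zero multiplicity
        ("HexNAc-1", False),      # malformed multiplicity
        ("", False),
        ("Gal2", False),          # alias without opt-in
    ],
)
def test_parse_rejects_malformed(text, aliases):
    with pytest.raises(CompositionError):
        parse_composition(text, aliases=aliases)


def test_parse_error_names_offending_token():
    with pytest.raises(CompositionError, match="Xyl1"):
        parse_composition("HexNAc4Xyl1")


@st.composite
def compositions(draw, min_total=1):
    counts = {
        k: draw(st.integers(min_value=0, max_value=9))
        for k in ("hexnac", "hex", "fuc", "neuac", "neugc")
    }
    if sum(counts.values()) < min_total:
        counts["hexnac"] += min_total
    return MonosaccharideCounts(**counts)


@settings(max_examples=1000, derandomize=True)
@given(c=compositions(), compact=st.booleans())
def test_format_parse_round_trip(c, compact):
    """format → parse reproduces the exact counts in both dialects."""
    assert parse_composition(format_composition(c, compact=compact)) == c


@pytest.mark.parametrize(
    "counts, antennae",
    [
        (MonosaccharideCounts(hexnac=4, hex=5, neuac=2), 2),
        (MonosaccharideCounts(hexnac=6, hex=7, fuc=1, neuac=4), 4),
        (MonosaccharideCounts(hexnac=2, hex=9), 0),  # high-mannose
    ],
)
def test_count_antennae(counts, antennae):
    assert count_antennae(counts) == antennae


def test_count_antennae_rejects_broken_core():
    with pytest.raises(GlycanClassError):
        count_antennae(MonosaccharideCounts(hexnac=1, hex=3))


@pytest.mark.parametrize("fuc, expected", [(0, (0, 0)), (1, (1, 0)), (3, (1, 2))])
def test_split_fucose_first_fucose_is_core(fuc, expected):
    assert split_fucose(MonosaccharideCounts(hexnac=4, hex=5, fuc=fuc)) == expected


@pytest.mark.parametrize(
    "counts, possible, unoccupied",
    [
        # 4 antennae, 2 non-core Hex → 2 bare HexNAc
        (MonosaccharideCounts(hexnac=6, hex=5, fuc=1), True, 2),
        # fully galactosylated biantennary
        (MonosaccharideCounts(hexnac=4, hex=5, neuac=2), False, 0),
        # agalactosylated biantennary: both antennal HexNAc bare
        (MonosaccharideCounts(hexnac=4, hex=3), True, 2),
    ],
)
def test_lacdinac_by_composition(counts, possible, unoccupied):
    assert lacdinac_by_composition(counts) == (possible, unoccupied)


def _lacdinac_oracle(c: MonosaccharideCounts) -> bool:
    """Exhaustive assignment oracle: place ALL non-core Hex onto LacNAc
    antennae (at most one Hex per antennal HexNAc) in every possible way and
    ask whether any assignment leaves >= 2 antennal HexNAc bare."""
    antennae = c.hexnac - 2
    non_core_hex = max(c.hex - 3, 0)
    feasible_bare = set()
    for placement in itertools.product((0, 1), repeat=antennae):
        if sum(placement) == non_core_hex:
            feasible_bare.add(placement.count(0))
    if not feasible_bare:  # cannot place all Hex → no bare pair inferable
        return False
    return max(feasible_bare) >= 2


def test_lacdinac_matches_exhaustive_oracle():
    """Closed-form rule equals the enumerate-all-assignments oracle over the
    whole hexnac <= 8, hex <= 10 composition grid."""
    for hexnac in range(2, 9):
        for hex_ in range(0, 11):
            c = MonosaccharideCounts(hexnac=hexnac, hex=hex_)
            assert lacdinac_by_composition(c)[0] == _lacdinac_oracle(c), c


@settings(max_examples=300, derandomize=True)
@given(c=compositions())
def test_classification_invariants(c):
    """Antenna count, fucose conservation and bare-HexNAc bounds hold for
    every valid N-glycan composition."""
    if c.hexnac < 2:
        with pytest.raises(GlycanClassError):
            classify_n_glycan(c)
        return
    g = classify_n_glycan(c)
    assert g.antennae + 2 == c.hexnac
    assert g.core_fucose + g.antenna_fucose == c.fuc
    assert 0 <= g.unoccupied_hexnac <= max(g.antennae, 0)
    if g.lacdinac_possible:
        assert g.unoccupied_hexnac >= 2
    assert g.neugc_present == (c.neugc > 0)


@pytest.mark.parametrize(
    "counts, family",
    [
        (MonosaccharideCounts(hexnac=2, hex=5), "high-mannose"),
        (MonosaccharideCounts(hexnac=2, hex=3), "paucimannose-or-core"),
        (MonosaccharideCounts(hexnac=5, hex=6, fuc=1, neuac=3), "hybrid-or-complex"),
    ],
)
def test_family_labels(counts, family):
    assert classify_n_glycan(counts).family == family


@pytest.mark.parametrize(
    "counts, mz",
    [
        (MonosaccharideCounts(hexnac=1), 204.086649),
        (MonosaccharideCounts(hexnac=2), 407.166022),  # LacdiNAc diagnostic
        (MonosaccharideCounts(hexnac=1, hex=1), 366.139473),
    ],
)
def test_oxonium_mz(counts, mz):
    assert oxonium_mz(counts) == pytest.approx(mz, abs=1e-5)


@settings(max_examples=200, derandomize=True)
@given(a=compositions(), b=compositions())
def test_oxonium_additivity(a, b):
    """m/z of a merged composition = sum of parts minus one extra proton."""
    merged = MonosaccharideCounts(
        hexnac=a.hexnac + b.hexnac, hex=a.hex + b.hex, fuc=a.fuc + b.fuc,
        neuac=a.neuac + b.neuac, neugc=a.neugc + b.neugc,
    )
    assert oxonium_mz(merged) == pytest.approx(
        oxonium_mz(a) + oxonium_mz(b) - PROTON_MASS, abs=1e-9
    )


def test_match_oxonium():
    target = 407.1658
    assert match_oxonium([(407.167, 1e4)], target, tolerance_ppm=10)
    assert not match_oxonium([(407.30, 1e4)], target, tolerance_ppm=10)
    assert not match_oxonium([], target)
    # zero-intensity peaks never match
    assert not match_oxonium([(407.1658, 0.0)], target)
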