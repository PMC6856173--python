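"""Per-site quantification and Table-style aggregation conventions."""

import random

import pytest

from glycoculture.composition import MonosaccharideCounts, parse_composition, split_fucose
from glycoculture.quant import (
    AntennaPercentages,
    GlycopeptideRecord,
    QuantError,
    SiteGlycoProfile,
    aggregate_report,
    antennarity_distribution,
    build_report,
    build_site_profile,
    group_records,
    site_fractions,
    site_mole_ratio,
    site_occupancy,
)

BI = parse_composition("HexNAc(4)Hex(5)NeuAc(2)")
BI_FUC = parse_composition("HexNAc(4)Hex(5)Fuc(1)NeuAc(1)")
TRI = parse_composition("HexNAc(5)Hex(6)Fuc(1)NeuAc(3)")
HM = parse_composition("HexNAc(2)Hex(9)")


def rec(site, comp, abundance, kind="N", mc=0):
    return GlycopeptideRecord(
        site=site, site_kind=kind, peptide=f"{site}_PEP", missed_cleavages=mc,
        composition=comp, abundance=abundance,
    )


class TestGrouping:
    def test_redundant_rows_merge_and_conserve_abundance(self):
        rows = [rec("Asn24", BI, 30.0, mc=0), rec("Asn24", BI, 10.0, mc=1)]
        grouped = group_records(rows)
        assert grouped == {("Asn24", BI): 40.0}

    def test_sites_never_merge(self):
        grouped = group_records([rec("Asn24", BI, 1.0), rec("Asn38", BI, 2.0)])
        assert set(grouped) == {("Asn24", BI), ("Asn38", BI)}

    def test_empty_input(self):
        assert group_records([]) == {}


class TestSiteMetrics:
    def test_fractions_normalize_with_unglycosylated_in_denominator(self):
        grouped = {("s", None): 10.0, ("s", BI): 60.0, ("s", BI_FUC): 30.0}
        fr = site_fractions(grouped, "s")
        assert fr == pytest.approx({None: 0.10, BI: 0.60, BI_FUC: 0.30})
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_site_errors(self):
        with pytest.raises(QuantError, match="dead"):
            site_fractions({("dead", BI): 0.0}, "dead")

    def test_occupancy(self):
        assert site_occupancy({None: 0.10, BI: 0.90}) == pytest.approx(90.0)
        assert site_occupancy({BI: 1.0}) == 100.0
        # the partially occupied O-site convention: 25.55% unglycosylated
        assert site_occupancy({None: 0.2555, BI: 0.7445}) == pytest.approx(74.45)

    def test_mole_ratio_weighted_sum(self):
        fr = {BI: 0.6, BI_FUC: 0.3, None: 0.1}
        assert site_mole_ratio(fr, lambda c: c.neuac) == pytest.approx(1.5)
        assert site_mole_ratio(fr, lambda c: c.fuc) == pytest.approx(0.3)
        assert site_mole_ratio({}, lambda c: c.neuac) == 0.0

    def test_core_fucose_upper_bound(self):
        fr = {BI_FUC: 0.5, TRI: 0.5}
        assert site_mole_ratio(fr, lambda c: split_fucose(c)[0]) == pytest.approx(1.0)


class TestAntennarity:
    def test_rescaled_to_multiantennary_pool(self):
        # bi 0.60 + tri 0.30, rest unglycosylated → 66.67 / 33.33
        fr = {BI: 0.60, TRI: 0.30, None: 0.10}
        a = antennarity_distribution(fr)
        assert a.bi == pytest.approx(200 / 3)
        assert a.tri == pytest.approx(100 / 3)
        assert a.tetra == 0.0

    def test_single_biantennary(self):
        a = antennarity_distribution({BI: 1.0})
        assert (a.bi, a.tri, a.tetra) == (100.0, 0.0, 0.0)

    def test_high_mannose_only_is_undefined(self):
        assert antennarity_distribution({HM: 1.0, None: 0.2}) is None


def profile(site, kind, occ, neuac, core_fuc=None, antenna=None):
    return SiteGlycoProfile(
        site=site, site_kind=kind, fractions={}, occupancy_pct=occ,
        mol_neuac=neuac, mol_total_fuc=0.0, mol_core_fuc=core_fuc,
        antenna_pct=antenna,
    )


class TestAggregation:
    """The published-table conventions: mole ratios sum over N sites,
    percentages average; the O site joins only occupancy and sialylation."""

    def make_profiles(self):
        ant = [
            AntennaPercentages(0.0, 86.85, 8.11, 5.04),
            AntennaPercentages(0.0, 68.14, 10.11, 21.75),
            AntennaPercentages(0.0, 64.06, 9.09, 26.85),
        ]
        return [
            profile("Asn24", "N", 100.00, 0.58, 0.9832, ant[0]),
            profile("Asn38", "N", 100.00, 1.70, 0.9965, ant[1]),
            profile("Asn83", "N", 99.96, 2.82, 0.9954, ant[2]),
            profile("Ser126", "O", 74.45, 1.45),
        ]

    def test_total_n_is_sum_of_site_mole_ratios(self):
        rep = aggregate_report(self.make_profiles())
        assert rep.total_n.mol_core_fuc == pytest.approx(2.9751, abs=1e-9)
        assert rep.total_n.mol_neuac == pytest.approx(5.10, abs=1e-9)

    def test_overall_sialylation_adds_o_site(self):
        rep = aggregate_report(self.make_profiles())
        assert rep.overall.mol_neuac == pytest.approx(6.55, abs=1e-9)

    def test_antenna_percentages_average_unweighted(self):
        rep = aggregate_report(self.make_profiles())
        assert rep.total_n.antenna_pct.bi == pytest.approx(73.02, abs=0.005)
        assert rep.total_n.antenna_pct.tri == pytest.approx(9.10, abs=0.005)
        assert rep.total_n.antenna_pct.tetra == pytest.approx(17.88, abs=0.005)

    def test_occupancy_averages(self):
        rep = aggregate_report(self.make_profiles())
        assert rep.total_n.occupancy_pct == pytest.approx(99.99, abs=0.005)
        assert rep.overall.occupancy_pct == pytest.approx(93.60, abs=0.005)

    def test_requires_an_n_site(self):
        with pytest.raises(QuantError):
            aggregate_report([profile("Ser126", "O", 74.45, 1.45)])


def _brute_force_report(rows):
    """First-principles recomputation with explicit sums, independent of the
    pipeline's grouping/normalization code path."""
    sites = {}
    for r in rows:
        sites.setdefault((r.site, r.site_kind), []).append(r)
    out = {}
    for (site, kind), rs in sites.items():
        total = sum(r.abundance for r in rs)
        comps = {}
        for r in rs:
            comps[r.composition] = comps.get(r.composition, 0.0) + r.abundance
        unglyc = comps.get(None, 0.0) / total
        neuac = sum(a / total * c.neuac for c, a in comps.items() if c is not None)
        out[site] = {"kind": kind, "occ": 100 * (1 - unglyc), "neuac": neuac}
    return out


def test_build_report_matches_brute_force_oracle():
    """End-to-end report equals an explicit-sums recomputation on randomized
    small tables (<=5 glycoforms/site)."""
    rng = random.Random(7)
    library = [None, BI, BI_FUC, TRI, HM]
    for _ in range(20):
        rows = []
        for site, kind in [("Asn24", "N"), ("Asn83", "N"), ("Ser126", "O")]:
            comps = [BI, BI_FUC] if kind == "O" else library
            for comp in comps:
                for mc in range(rng.randint(1, 3)):
                    rows.append(rec(site, comp, rng.uniform(0.1, 100.0), kind, mc))
        rng.shuffle(rows)
        report = build_report(rows)
        expected = _brute_force_report(rows)
        for p in report.profiles:
            assert p.occupancy_pct == pytest.approx(expected[p.site]["occ"], abs=1e-12)
            assert p.mol_neuac == pytest.approx(expected[p.site]["neuac"], abs=1e-12)


def test_permutation_invariance():
    rows = [
        rec("Asn24", BI, 5.0), rec("Asn24", None, 1.0), rec("Asn83", TRI, 3.0),
        rec("Ser126", BI, 2.0, kind="O"), rec("Asn83", BI_FUC, 4.0),
    ]
    base = build_report(rows)
    for seed in range(5):
        shuffled = rows[:]
        random.Random(seed).shuffle(shuffled)
        other = build_report(shuffled)
        assert other == base


def test_increasing_unglycosylated_abundance_lowers_site_metrics():
    """Occupancy and all mole ratios strictly decrease as the unglycosylated
    abundance grows."""
    def metrics(unglyc_abundance):
        rows = [rec("s", BI_FUC, 10.0), rec("s", None, unglyc_abundance)]
        p = build_site_profile(group_records(rows), "s", "N")
        return p.occupancy_pct, p.mol_neuac, p.mol_core_fuc, p.mol_total_fuc

    previous = metrics(0.0)
    for ab in (1.0, 5.0, 25.0):
        current = metrics(ab)
        assert all(c < p for c, p in zip(current, previous))
        previous = current


def test_single_site_single_glycoform_report():
    rows = [rec("Asn24", TRI, 42.0)]
    rep = build_report(rows)
    p = rep.profile("Asn24")
    assert p.occupancy_pct == 100.0
    assert p.mol_neuac == pytest.approx(TRI.neuac)
    assert p.mol_total_fuc == pytest.approx(TRI.fuc)


def test_o_site_only_table_fails_aggregation():
    with pytest.raises(QuantError):
        build_report([rec("Ser126", BI, 1.0, kind="O")])
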