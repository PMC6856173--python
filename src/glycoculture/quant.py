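"""Site-specific glycosylation quantification.

Turns a table of identified (glyco)peptide abundances — one row per
identification, redundant across missed cleavages and charge states — into
the per-site and aggregate metrics of a glycoprotein glycosylation report:

* per-site glycoform **relative abundances** (normalized within each site,
  the unglycosylated peptide included in the denominator);
* **site occupancy**: 100% minus the site-normalized unglycosylated
  fraction;
* **mole ratios** (mol NeuAc, mol core Fuc, mol total Fuc per mole of
  protein at the site): abundance-weighted sums of per-glycan counts;
* **antennarity distribution**: per-site percentages of bi-/tri-/
  tetra-antennary structures rescaled to sum to 100 (mono-antennary
  reported separately, unrescaled);
* aggregates: total-N mole ratios are *sums* over N sites, total-N
  antennarity and occupancy are *unweighted means*, and the overall
  sialylation adds the O-site mole ratios to the N total.

The conventions mirror standard site-specific glycoprofiling reports for
recombinant glycoproteins such as erythropoietin (three N sites, one
O site).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .composition import MonosaccharideCounts, count_antennae, split_fucose

__all__ = [
    "GlycopeptideRecord",
    "AntennaPercentages",
    "SiteGlycoProfile",
    "AggregateMetrics",
    "GlycoReport",
    "QuantError",
    "group_records",
    "site_fractions",
    "site_occupancy",
    "site_mole_ratio",
    "antennarity_distribution",
    "build_site_profile",
    "aggregate_report",
    "build_report",
]


class QuantError(ValueError):
    """Invalid input to a quantification stage."""


@dataclass(frozen=True)
class GlycopeptideRecord:
    """One identified (glyco)peptide row.

    ``composition is None`` marks the unglycosylated peptide spanning the
    site; its abundance enters the site denominator and drives occupancy.
    """

    site: str
    site_kind: str  # "N" or "O"
    peptide: str
    missed_cleavages: int
    composition: MonosaccharideCounts | None
    abundance: float

    def __post_init__(self) -> None:
        if not self.site:
            raise QuantError("site label must be non-empty")
        if self.site_kind not in ("N", "O"):
            raise QuantError(f"site kind must be 'N' or 'O', got {self.site_kind!r}")
        if self.missed_cleavages < 0:
            raise QuantError("missed_cleavages must be >= 0")
        if not (self.abundance >= 0):
            raise QuantError(f"abundance must be >= 0, got {self.abundance}")


@dataclass(frozen=True)
class AntennaPercentages:
    """Antennarity distribution at one N site.

    ``bi``/``tri``/``tetra`` are rescaled to sum to 100 over the
    multi-antennary pool; ``mono`` is the raw percentage of site abundance
    carried by mono-antennary structures, not part of the rescaling.
    """

    mono: float
    bi: float
    tri: float
    tetra: float


@dataclass(frozen=True)
class SiteGlycoProfile:
    """Per-site relative abundances and derived metrics."""

    site: str
    site_kind: str
    fractions: dict[MonosaccharideCounts | None, float]
    occupancy_pct: float
    mol_neuac: float
    mol_total_fuc: float
    mol_core_fuc: float | None = None  # N sites only
    antenna_pct: AntennaPercentages | None = None  # None = undefined


@dataclass(frozen=True)
class AggregateMetrics:
    """Aggregate block of a report (total-N or overall)."""

    occupancy_pct: float
    mol_neuac: float
    mol_core_fuc: float | None = None
    mol_total_fuc: float | None = None
    antenna_pct: AntennaPercentages | None = None


@dataclass(frozen=True)
class GlycoReport:
    """Per-site profiles plus total-N and overall aggregates."""

    profiles: tuple[SiteGlycoProfile, ...]
    total_n: AggregateMetrics
    overall: AggregateMetrics

    def profile(self, site: str) -> SiteGlycoProfile:
        for p in self.profiles:
            if p.site == site:
                return p
        raise KeyError(site)


GroupedAbundances = dict[tuple[str, MonosaccharideCounts | None], float]


def group_records(records: list[GlycopeptideRecord]) -> GroupedAbundances:
    """Sum abundances of redundant rows sharing (site, composition).

    Peptide sequence, missed cleavages and any charge-state redundancy are
    deliberately collapsed; total abundance is conserved.
    """
    grouped: GroupedAbundances = {}
    for rec in records:
        key = (rec.site, rec.composition)
        grouped[key] = grouped.get(key, 0.0) + rec.abundance
    return grouped


def site_fractions(
    grouped: GroupedAbundances, site: str
) -> dict[MonosaccharideCounts | None, float]:
    """Site-normalized relative abundances (sum to 1, unglycosylated
    included)."""
    entries = {comp: ab for (s, comp), ab in grouped.items() if s == site}
    total = sum(entries.values())
    if not entries or total <= 0:
        raise QuantError(f"site {site!r} has no abundance to normalize")
    return {comp: ab / total for comp, ab in entries.items()}


def site_occupancy(fractions: dict[MonosaccharideCounts | None, float]) -> float:
    """Occupancy %: 100 × (1 − unglycosylated fraction); 100 when no
    unglycosylated form was observed."""
    return 100.0 * (1.0 - fractions.get(None, 0.0))


def site_mole_ratio(
    fractions: dict[MonosaccharideCounts | None, float],
    count_of,
) -> float:
    """Abundance-weighted mean of a per-glycan count: moles per mole of
    protein at this site.  The unglycosylated form contributes zero."""
    return sum(
        frac * count_of(comp)
        for comp, frac in fractions.items()
        if comp is not None
    )


def antennarity_distribution(
    fractions: dict[MonosaccharideCounts | None, float],
) -> AntennaPercentages | None:
    """Per-class antennarity percentages at one N site.

    Bi/tri/tetra percentages are rescaled to sum to 100 over the
    multi-antennary pool; glycans with zero antennae (high-mannose,
    paucimannose) and the unglycosylated form are excluded from that pool.
    Returns ``None`` when the site carries no multi-antennary glycan
    (the distribution is undefined, not zero).
    """
    by_class = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
    for comp, frac in fractions.items():
        if comp is None:
            continue
        n = count_antennae(comp)
        if n in by_class:
            by_class[n] += frac
    pool = by_class[2] + by_class[3] + by_class[4]
    if pool <= 0:
        return None
    return AntennaPercentages(
        mono=100.0 * by_class[1],
        bi=100.0 * by_class[2] / pool,
        tri=100.0 * by_class[3] / pool,
        tetra=100.0 * by_class[4] / pool,
    )


def _neuac(c: MonosaccharideCounts) -> int:
    return c.neuac


def _total_fuc(c: MonosaccharideCounts) -> int:
    return c.fuc


def _core_fuc(c: MonosaccharideCounts) -> int:
    return split_fucose(c)[0]


def build_site_profile(
    grouped: GroupedAbundances, site: str, site_kind: str
) -> SiteGlycoProfile:
    """Compute all per-site metrics from grouped abundances."""
    fractions = site_fractions(grouped, site)
    profile = SiteGlycoProfile(
        site=site,
        site_kind=site_kind,
        fractions=fractions,
        occupancy_pct=site_occupancy(fractions),
        mol_neuac=site_mole_ratio(fractions, _neuac),
        mol_total_fuc=site_mole_ratio(fractions, _total_fuc),
        mol_core_fuc=site_mole_ratio(fractions, _core_fuc)
        if site_kind == "N"
        else None,
        antenna_pct=antennarity_distribution(fractions)
        if site_kind == "N"
        else None,
    )
    return profile


def _mean(values: list[float]) -> float:
    return sum(values) / len(values)


def aggregate_report(profiles: list[SiteGlycoProfile]) -> GlycoReport:
    """Aggregate per-site profiles into total-N and overall blocks.

    Total-N mole ratios are sums over the N sites; total-N antennarity and
    occupancy are unweighted means over them.  Overall sialylation is the
    N total plus the O-site mole ratios; overall occupancy is the
    unweighted mean over all sites.
    """
    n_sites = [p for p in profiles if p.site_kind == "N"]
    o_sites = [p for p in profiles if p.site_kind == "O"]
    if not n_sites:
        raise QuantError("at least one N-site profile is required")

    with_antennae = [p for p in n_sites if p.antenna_pct is not None]
    if with_antennae:
        antenna = AntennaPercentages(
            mono=_mean([p.antenna_pct.mono for p in with_antennae]),
            bi=_mean([p.antenna_pct.bi for p in with_antennae]),
            tri=_mean([p.antenna_pct.tri for p in with_antennae]),
            tetra=_mean([p.antenna_pct.tetra for p in with_antennae]),
        )
    else:
        antenna = None

    total_n = AggregateMetrics(
        occupancy_pct=_mean([p.occupancy_pct for p in n_sites]),
        mol_neuac=sum(p.mol_neuac for p in n_sites),
        mol_core_fuc=sum(p.mol_core_fuc for p in n_sites),
        mol_total_fuc=sum(p.mol_total_fuc for p in n_sites),
        antenna_pct=antenna,
    )
    overall = AggregateMetrics(
        occupancy_pct=_mean([p.occupancy_pct for p in profiles]),
        mol_neuac=total_n.mol_neuac + sum(p.mol_neuac for p in o_sites),
    )
    return GlycoReport(profiles=tuple(profiles), total_n=total_n, overall=overall)


def build_report(records: list[GlycopeptideRecord]) -> GlycoReport:
    """Full pipeline: group → per-site fractions → metrics → aggregates.

    Deterministic for a fixed input; row order never matters.
    """
    if not records:
        raise QuantError("empty record list")
    grouped = group_records(records)
    # stable site order: first appearance in the input
    kinds: dict[str, str] = {}
    for rec in records:
        prior = kinds.setdefault(rec.site, rec.site_kind)
        if prior != rec.site_kind:
            raise QuantError(
                f"site {rec.site!r} labeled both {prior!r} and {rec.site_kind!r}"
            )
    order = sorted(kinds)  # site-label order, independent of row order
    profiles = [build_site_profile(grouped, site, kinds[site]) for site in order]
    return aggregate_report(profiles)
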