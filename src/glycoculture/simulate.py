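"""Seeded synthetic-data generators with analytic ground truth.

Every pipeline stage in this package can be exercised without any external
dataset: the generators here produce inputs with the statistical structure
the real data have —

* a glycopeptide identification table for an EPO-like glycoprotein (three
  N sites, one O site) with per-site glycoform distributions, partial
  occupancy, missed-cleavage redundancy and multiplicative lognormal
  abundance noise;
* droplet assays with binomial positive counts from a Poisson occupancy
  model;
* fed-batch culture trajectories with exponential growth and titer
  proportional to cumulative IVCD.

Each generator returns (or can be paired with) its analytic ground truth,
computed by closed-form weighted sums that never call the pipeline under
test, so parameter-recovery tests have an independent reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import MonosaccharideCounts, parse_composition
from .quant import (
    AggregateMetrics,
    AntennaPercentages,
    GlycoReport,
    GlycopeptideRecord,
    SiteGlycoProfile,
)
from .bioprocess import CultureTimeSeries
from .ddpcr import DropletAssay

__all__ = [
    "SiteSimSpec",
    "GlycoSimConfig",
    "default_epo_config",
    "ground_truth_report",
    "simulate_glycopeptide_table",
    "simulate_droplet_assay",
    "simulate_culture",
]


@dataclass(frozen=True)
class SiteSimSpec:
    """True glycoform distribution at one site.

    ``glycoforms`` maps composition strings to fractional weights that sum
    to 1 over the glycosylated forms; ``occupancy`` is the true fraction of
    protein molecules glycosylated at the site.
    """

    site: str
    site_kind: str
    glycoforms: dict[str, float]
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.glycoforms.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"glycoform weights at {self.site} sum to {total}, expected 1"
            )
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass(frozen=True)
class GlycoSimConfig:
    """Configuration of one simulated glycopeptide identification table."""

    sites: tuple[SiteSimSpec, ...]
    redundant_features: int = 3  # missed-cleavage/charge redundancy per species
    abundance_scale: float = 1e6  # XIC area of one site's total signal
    noise_sigma: float = 0.1  # lognormal σ on each feature abundance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.redundant_features < 1:
            raise ValueError("redundant_features must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def default_epo_config(
    noise_sigma: float = 0.1,
    redundant_features: int = 3,
    seed: int = 0,
) -> GlycoSimConfig:
    """EPO-like default: sites Asn24/Asn38/Asn83 (N) and Ser126 (O).

    Occupancies follow published site-occupancy estimates for HEK-derived
    EPO (Asn24 and Asn38 fully occupied, Asn83 99.96%, Ser126 74.45%); the
    glycoform libraries are plausible sialylated, core-fucosylated complex
    N-glycans plus minor high-mannose/agalactosylated species, and mono-
    and disialylated core 1 O-glycans.
    """
    sites = (
        SiteSimSpec(
            site="Asn24",
            site_kind="N",
            occupancy=1.0,
            glycoforms={
                "HexNAc(4)Hex(5)Fuc(1)": 0.40,
                "HexNAc(4)Hex(5)Fuc(1)NeuAc(1)": 0.30,
                "HexNAc(4)Hex(5)Fuc(1)NeuAc(2)": 0.12,
                "HexNAc(5)Hex(6)Fuc(1)NeuAc(1)": 0.08,
                "HexNAc(6)Hex(7)Fuc(1)NeuAc(2)": 0.05,
                "HexNAc(4)Hex(3)": 0.03,
                "HexNAc(2)Hex(5)": 0.02,
            },
        ),
        SiteSimSpec(
            site="Asn38",
            site_kind="N",
            occupancy=1.0,
            glycoforms={
                "HexNAc(4)Hex(5)Fuc(1)NeuAc(2)": 0.45,
                "HexNAc(5)Hex(6)Fuc(1)NeuAc(2)": 0.15,
                "HexNAc(6)Hex(7)Fuc(1)NeuAc(3)": 0.25,
                "HexNAc(4)Hex(5)Fuc(1)NeuAc(1)": 0.10,
                "HexNAc(6)Hex(5)Fuc(2)": 0.05,
            },
        ),
        SiteSimSpec(
            site="Asn83",
            site_kind="N",
            occupancy=0.9996,
            glycoforms={
                "HexNAc(4)Hex(5)Fuc(1)NeuAc(2)": 0.40,
                "HexNAc(6)Hex(7)Fuc(1)NeuAc(4)": 0.30,
                "HexNAc(5)Hex(6)Fuc(1)NeuAc(3)": 0.10,
                "HexNAc(6)Hex(7)Fuc(2)NeuAc(3)": 0.15,
                "HexNAc(3)Hex(4)Fuc(1)NeuAc(1)": 0.05,
            },
        ),
        SiteSimSpec(
            site="Ser126",
            site_kind="O",
            occupancy=0.7445,
            glycoforms={
                "HexNAc(1)Hex(1)NeuAc(2)": 0.70,
                "HexNAc(1)Hex(1)NeuAc(1)": 0.30,
            },
        ),
    )
    return GlycoSimConfig(
        sites=sites,
        redundant_features=redundant_features,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _mean(values: list[float]) -> float:
    return sum(values) / len(values)


def ground_truth_report(config: GlycoSimConfig) -> GlycoReport:
    """The exact report implied by the configured weights and occupancies.

    Computed by closed-form weighted sums directly from the configuration —
    independent of the grouping/normalization pipeline — so it can serve as
    the reference in recovery tests.
    """
    profiles: list[SiteGlycoProfile] = []
    for spec in sorted(config.sites, key=lambda s: s.site):
        parsed = {
            parse_composition(comp, aliases=True): w
            for comp, w in spec.glycoforms.items()
        }
        fractions: dict[MonosaccharideCounts | None, float] = {
            comp: spec.occupancy * w for comp, w in parsed.items()
        }
        if spec.occupancy < 1.0:
            fractions[None] = 1.0 - spec.occupancy

        mol_neuac = sum(f * comp.neuac for comp, f in parsed.items()) * spec.occupancy
        mol_fuc = sum(f * comp.fuc for comp, f in parsed.items()) * spec.occupancy
        mol_core = (
            sum(f * min(comp.fuc, 1) for comp, f in parsed.items()) * spec.occupancy
        )

        antenna = None
        if spec.site_kind == "N":
            by_class = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
            for comp, f in parsed.items():
                n = comp.hexnac - 2  # antennal HexNAc beyond the chitobiose core
                if n in by_class:
                    by_class[n] += spec.occupancy * f
            pool = by_class[2] + by_class[3] + by_class[4]
            if pool > 0:
                antenna = AntennaPercentages(
                    mono=100.0 * by_class[1],
                    bi=100.0 * by_class[2] / pool,
                    tri=100.0 * by_class[3] / pool,
                    tetra=100.0 * by_class[4] / pool,
                )
        profiles.append(
            SiteGlycoProfile(
                site=spec.site,
                site_kind=spec.site_kind,
                fractions=fractions,
                occupancy_pct=100.0 * spec.occupancy,
                mol_neuac=mol_neuac,
                mol_total_fuc=mol_fuc,
                mol_core_fuc=mol_core if spec.site_kind == "N" else None,
                antenna_pct=antenna,
            )
        )

    n_sites = [p for p in profiles if p.site_kind == "N"]
    o_sites = [p for p in profiles if p.site_kind == "O"]
    with_ant = [p for p in n_sites if p.antenna_pct is not None]
    antenna_total = (
        AntennaPercentages(
            mono=_mean([p.antenna_pct.mono for p in with_ant]),
            bi=_mean([p.antenna_pct.bi for p in with_ant]),
            tri=_mean([p.antenna_pct.tri for p in with_ant]),
            tetra=_mean([p.antenna_pct.tetra for p in with_ant]),
        )
        if with_ant
        else None
    )
    total_n = AggregateMetrics(
        occupancy_pct=_mean([p.occupancy_pct for p in n_sites]),
        mol_neuac=sum(p.mol_neuac for p in n_sites),
        mol_core_fuc=sum(p.mol_core_fuc for p in n_sites),
        mol_total_fuc=sum(p.mol_total_fuc for p in n_sites),
        antenna_pct=antenna_total,
    )
    overall = AggregateMetrics(
        occupancy_pct=_mean([p.occupancy_pct for p in profiles]),
        mol_neuac=total_n.mol_neuac + sum(p.mol_neuac for p in o_sites),
    )
    return GlycoReport(profiles=tuple(profiles), total_n=total_n, overall=overall)


def simulate_glycopeptide_table(
    config: GlycoSimConfig,
) -> tuple[list[GlycopeptideRecord], GlycoReport]:
    """Draw one glycopeptide identification table plus its ground truth.

    Each species at a site — every glycoform and, at partially occupied
    sites, the unglycosylated peptide — receives abundance
    ``abundance_scale × true fraction``, split across ``redundant_features``
    rows by a symmetric Dirichlet(1) draw (emulating missed-cleavage and
    charge-state redundancy that grouping must undo), each row multiplied
    by independent lognormal(0, σ) noise.  Bit-reproducible for a fixed
    seed.
    """
    rng = np.random.default_rng(config.seed)
    k = config.redundant_features
    records: list[GlycopeptideRecord] = []
    for spec in config.sites:
        species: list[tuple[MonosaccharideCounts | None, float]] = [
            (parse_composition(comp, aliases=True), spec.occupancy * w)
            for comp, w in spec.glycoforms.items()
        ]
        if spec.occupancy < 1.0:
            species.append((None, 1.0 - spec.occupancy))
        for comp, weight in species:
            split = rng.dirichlet(np.ones(k))
            noise = rng.lognormal(mean=0.0, sigma=config.noise_sigma, size=k)
            for j in range(k):
                records.append(
                    GlycopeptideRecord(
                        site=spec.site,
                        site_kind=spec.site_kind,
                        peptide=f"{spec.site}_PEPTIDE",
                        missed_cleavages=j,
                        composition=comp,
                        abundance=float(
                            config.abundance_scale * weight * split[j] * noise[j]
                        ),
                    )
                )
    return records, ground_truth_report(config)


def simulate_droplet_assay(
    true_copies_per_ng: float,
    input_mass_ng: float = 50.0,
    droplets_total: int = 20000,
    reaction_volume_ul: float = 20.0,
    droplet_volume_nl: float = 0.85,
    seed: int = 0,
) -> DropletAssay:
    """Draw one droplet assay from a known concentration.

    The true copies per reaction set λ per droplet; the positive count is
    binomial(total, 1 − e^{−λ}).  Default input is 50 ng of gDNA in a
    20 µL reaction.
    """
    capacity = reaction_volume_ul * 1000.0 / droplet_volume_nl
    lam = true_copies_per_ng * input_mass_ng / capacity
    p = -np.expm1(-lam)
    rng = np.random.default_rng(seed)
    positives = int(rng.binomial(droplets_total, p))
    return DropletAssay(
        droplets_total=droplets_total,
        droplets_positive=positives,
        input_mass_ng=input_mass_ng,
        reaction_volume_ul=reaction_volume_ul,
        droplet_volume_nl=droplet_volume_nl,
    )


def simulate_culture(
    mu: float,
    qp: float,
    vcd0: float,
    times_h: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
    vcd_ceiling: float | None = None,
) -> CultureTimeSeries:
    """Draw one fed-batch trajectory.

    VCD grows exponentially at rate ``mu`` (optionally capped at a
    stationary ceiling); titer is ``qp`` times the cumulative trapezium
    IVCD of the sampled VCD, so with zero noise both µ (within the
    exponential window) and q_p are recovered exactly by the fitting
    routines.  ``noise_sigma`` applies multiplicative lognormal noise to
    each titer sample.
    """
    t = np.asarray(times_h, dtype=float)
    vcd = vcd0 * np.exp(mu * t)
    if vcd_ceiling is not None:
        vcd = np.minimum(vcd, vcd_ceiling)
    increments = 0.5 * (vcd[1:] + vcd[:-1]) * np.diff(t)
    ivcd = np.concatenate(([0.0], np.cumsum(increments)))
    titer = qp * ivcd
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        titer = titer * rng.lognormal(0.0, noise_sigma, size=t.size)
    return CultureTimeSeries(t=t, vcd=vcd, titer=titer)
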