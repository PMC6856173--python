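"""Droplet digital PCR copy-number quantification.

A ddPCR reaction partitions the sample into ~20,000 sub-nanoliter droplets;
template molecules distribute over droplets approximately Poisson, so the
mean copies per droplet is λ = −ln(1 − p) with p the positive-droplet
fraction.  From λ the absolute copy count per reaction follows from the
droplet and reaction volumes, and downstream:

* copies per ng = copies per reaction ÷ input mass (ng of gDNA, or RNA
  converted to cDNA);
* genomic copies per cell = (target copies/ng ÷ reference copies/ng) ×
  reference copy number, against a locus of known copy number in the host
  genome (e.g. PDHA2, 2 copies in HEK293);
* expression fold change = sample copies/ng ÷ baseline copies/ng, with
  detection-limit baselines ("< x copies/ng") propagated as lower bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DropletAssay",
    "CopyNumberResult",
    "FoldChange",
    "DdpcrError",
    "SaturatedAssayError",
    "BelowDetectionError",
    "copies_per_droplet",
    "estimate_copies_per_reaction",
    "copies_per_ng",
    "genomic_copies_per_cell",
    "expression_ratio",
    "analyze_assay",
]


class DdpcrError(ValueError):
    """Invalid droplet assay data."""


class SaturatedAssayError(DdpcrError):
    """Every droplet positive: λ unbounded, sample too concentrated."""


class BelowDetectionError(DdpcrError):
    """No positive droplet: target below the assay's detection limit."""


@dataclass(frozen=True)
class DropletAssay:
    """Raw readout of one ddPCR well.

    Default geometry is instrument-typical for droplet readers: a 20 µL
    reaction partitioned into 0.85 nL droplets.
    """

    droplets_total: int
    droplets_positive: int
    input_mass_ng: float
    reaction_volume_ul: float = 20.0
    droplet_volume_nl: float = 0.85

    def __post_init__(self) -> None:
        if self.droplets_total <= 0:
            raise DdpcrError("droplets_total must be > 0")
        if not 0 <= self.droplets_positive <= self.droplets_total:
            raise DdpcrError("droplets_positive must be in [0, droplets_total]")
        if self.input_mass_ng <= 0:
            raise DdpcrError("input_mass_ng must be > 0")
        if self.reaction_volume_ul <= 0 or self.droplet_volume_nl <= 0:
            raise DdpcrError("volumes must be > 0")

    @property
    def droplet_capacity(self) -> float:
        """Effective number of droplet volumes in one reaction."""
        return self.reaction_volume_ul * 1000.0 / self.droplet_volume_nl


@dataclass(frozen=True)
class CopyNumberResult:
    """Copy-number quantities derived from one target/reference well pair."""

    copies_per_reaction: float
    copies_per_ng: float
    genomic_copies_per_cell: float | None
    reference_copies: int = 2


@dataclass(frozen=True)
class FoldChange:
    """An expression ratio; ``lower_bound`` marks ratios computed against a
    detection-limit baseline, i.e. 'at least this large'."""

    value: float
    lower_bound: bool = False


def copies_per_droplet(assay: DropletAssay) -> float:
    """Poisson-corrected mean template copies per droplet,
    λ = −ln(1 − positives/total)."""
    p = assay.droplets_positive / assay.droplets_total
    if p >= 1.0:
        raise SaturatedAssayError(
            f"all {assay.droplets_total} droplets positive; λ is unbounded"
        )
    if p <= 0.0:
        raise BelowDetectionError("no positive droplets; target below detection")
    return -math.log1p(-p)


def estimate_copies_per_reaction(assay: DropletAssay) -> float:
    """Absolute copies in the reaction: λ × (reaction volume / droplet
    volume)."""
    return copies_per_droplet(assay) * assay.droplet_capacity


def copies_per_ng(copies_per_reaction: float, input_mass_ng: float) -> float:
    """Copies per ng of input gDNA or RNA: copies per reaction ÷ input
    mass."""
    if input_mass_ng <= 0:
        raise DdpcrError("input mass must be > 0")
    return copies_per_reaction / input_mass_ng


def genomic_copies_per_cell(
    target_cpn: float, reference_cpn: float, reference_copies: int = 2
) -> float:
    """Target copy number per cell against a reference locus of known
    genomic copy number (default 2, a diploid locus)."""
    if reference_cpn <= 0:
        raise DdpcrError("reference copies/ng must be > 0")
    return (target_cpn / reference_cpn) * reference_copies


def expression_ratio(
    sample_cpn: float,
    baseline_cpn: float,
    baseline_is_bound: bool = False,
) -> FoldChange:
    """Fold change of sample over baseline copies/ng.

    When the baseline is a detection-limit bound ("< x copies/ng"), pass
    ``baseline_is_bound=True``: the ratio is then a lower bound.  A zero
    baseline is undefined as a ratio and raises unless flagged as a bound.
    """
    if baseline_cpn < 0 or sample_cpn < 0:
        raise DdpcrError("copies/ng must be non-negative")
    if baseline_cpn == 0:
        if baseline_is_bound:
            return FoldChange(value=math.inf, lower_bound=True)
        raise DdpcrError("zero baseline: pass it as a detection-limit bound")
    return FoldChange(value=sample_cpn / baseline_cpn, lower_bound=baseline_is_bound)


def analyze_assay(
    target: DropletAssay,
    reference: DropletAssay | None = None,
    reference_copies: int = 2,
) -> CopyNumberResult:
    """Full pipeline for one well: Poisson copies → copies/ng → (optionally)
    genomic copies per cell against a reference well."""
    copies = estimate_copies_per_reaction(target)
    cpn = copies_per_ng(copies, target.input_mass_ng)
    per_cell = None
    if reference is not None:
        ref_cpn = copies_per_ng(
            estimate_copies_per_reaction(reference), reference.input_mass_ng
        )
        per_cell = genomic_copies_per_cell(cpn, ref_cpn, reference_copies)
    return CopyNumberResult(
        copies_per_reaction=copies,
        copies_per_ng=cpn,
        genomic_copies_per_cell=per_cell,
        reference_copies=reference_copies,
    )
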