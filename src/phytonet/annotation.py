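"""Compound annotation and affinity-ultrafiltration enrichment screening.

Annotation matches LC-MS features to a compound library by accurate mass:
a feature's measured m/z is compared to each library compound's theoretical
[M+H]+ m/z and retained when the relative deviation is within a ppm
tolerance (default +/- 5 ppm).  The ultrafiltration screen then keeps the
annotated compounds whose peak area in the receptor-containing sample
exceeds the enzyme-free control — the putative ligands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formula import monoisotopic_mass, parse_formula, ppm_error, protonated_mz

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "PeakRecord",
    "AnnotationHit",
    "annotate_peaks",
    "screen_enriched",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One library compound with its theoretical neutral and [M+H]+ masses."""

    name: str
    category: str
    formula: dict[str, int] = field(compare=False)
    theoretical_monoisotopic_mass: float
    theoretical_mh_mz: float
    cas: str | None = None

    def __post_init__(self) -> None:
        if not self.theoretical_mh_mz > self.theoretical_monoisotopic_mass:
            raise ValueError(
                f"[M+H]+ m/z ({self.theoretical_mh_mz}) must exceed the neutral "
                f"mass ({self.theoretical_monoisotopic_mass}) for {self.name!r}"
            )

    @classmethod
    def from_formula(
        cls, name: str, formula_text: str, category: str = "", cas: str | None = None
    ) -> "CompoundRecord":
        comp = parse_formula(formula_text)
        mass = monoisotopic_mass(comp)
        return cls(
            name=name,
            category=category,
            formula=comp,
            theoretical_monoisotopic_mass=mass,
            theoretical_mh_mz=protonated_mz(mass),
            cas=cas,
        )


@dataclass(frozen=True)
class PeakRecord:
    """One LC-MS feature: measured m/z, retention time, and the peak areas
    in the receptor-containing sample and the receptor-free control."""

    feature_id: str
    measured_mz: float
    retention_time: float
    area_sample: float
    area_control: float

    def __post_init__(self) -> None:
        if self.measured_mz <= 0:
            raise ValueError(f"measured m/z must be positive ({self.feature_id})")
        if self.retention_time < 0:
            raise ValueError(f"retention time must be >= 0 ({self.feature_id})")
        if self.area_sample < 0 or self.area_control < 0:
            raise ValueError(f"peak areas must be >= 0 ({self.feature_id})")

    @property
    def enrichment_ratio(self) -> float:
        """area_sample / area_control; +inf when the control area is 0 but
        the sample area is not, 0.0 when both are 0."""
        if self.area_control > 0:
            return self.area_sample / self.area_control
        return float("inf") if self.area_sample > 0 else 0.0


@dataclass(frozen=True)
class AnnotationHit:
    """A (feature, compound) accurate-mass match within tolerance."""

    feature_id: str
    compound_name: str
    ppm_error: float
    enrichment_ratio: float
    ambiguous: bool = False
    peak: PeakRecord | None = field(default=None, compare=False, repr=False)


def annotate_peaks(
    peaks: Iterable[PeakRecord],
    library: Sequence[CompoundRecord],
    tol_ppm: float = 5.0,
) -> list[AnnotationHit]:
    """Match peaks to library compounds by [M+H]+ accurate mass.

    Every (peak, compound) pair with |ppm error| <= ``tol_ppm`` is reported;
    a peak matching several compounds yields several hits, all flagged
    ``ambiguous`` (resolution by MS/MS or retention time is left to the
    caller).  An empty library yields no hits.
    """
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")
    hits: list[AnnotationHit] = []
    for peak in peaks:
        matches = [
            (compound, ppm_error(peak.measured_mz, compound.theoretical_mh_mz))
            for compound in library
            if abs(ppm_error(peak.measured_mz, compound.theoretical_mh_mz)) <= tol_ppm
        ]
        ambiguous = len(matches) > 1
        for compound, err in matches:
            hits.append(
                AnnotationHit(
                    feature_id=peak.feature_id,
                    compound_name=compound.name,
                    ppm_error=err,
                    enrichment_ratio=peak.enrichment_ratio,
                    ambiguous=ambiguous,
                    peak=peak,
                )
            )
    logger.info(
        "annotated %d hit(s) at +/-%.3g ppm (%d ambiguous)",
        len(hits),
        tol_ppm,
        sum(h.ambiguous for h in hits),
    )
    return hits


def screen_enriched(
    hits: Iterable[AnnotationHit],
    ratio_threshold: float = 1.0,
) -> list[AnnotationHit]:
    """Keep hits whose sample peak area strictly exceeds ``ratio_threshold``
    times the control area (a zero control with a positive sample area
    counts as enriched)."""
    if ratio_threshold < 0:
        raise ValueError(f"ratio_threshold must be >= 0, got {ratio_threshold}")
    kept = [h for h in hits if h.enrichment_ratio > ratio_threshold]
    kept_list = list(kept)
    logger.info(
        "enrichment screen kept %d hit(s) at ratio > %.3g", len(kept_list), ratio_threshold
    )
    return kept_list
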