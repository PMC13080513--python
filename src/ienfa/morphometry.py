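"""Particle analysis inside the epidermis mask and biomarker computation.

The segmented nerve mask is intersected with the epidermis mask and split
into 8-connected components ("particles").  Particles touching the inner
boundary ring of the epidermis mask and particles smaller than a calibrated
minimum area (default 0.40 µm²) are excluded; the summed retained area is
the IENFa.  Two normalised biomarkers follow:

``IENFa/P``  IENFa / epidermis perimeter, in µm²/µm.
``IENFa/A``  100 × IENFa / epidermis area (reported on the ×100 scale).

The classical IENFd (fibres per mm of epidermis) and the age-specific
denervation call (cut-offs 5.88 fibres/mm below age 60, 2.50 at or above
60) are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .image_model import EpidermisROI, as_binary_mask

__all__ = [
    "MorphometryError",
    "Particle",
    "ParticleSet",
    "SectionMetrics",
    "SubjectMetrics",
    "extract_particles",
    "section_metrics",
    "subject_metrics",
    "ienfd_from_counts",
    "classify_denervation",
    "MIN_PARTICLE_AREA_UM2",
    "IENFD_CUTOFF_YOUNG",
    "IENFD_CUTOFF_OLD",
    "AGE_CUTOFF_BOUNDARY",
]

#: Minimum retained particle area (µm²); smaller particles are noise.
MIN_PARTICLE_AREA_UM2 = 0.40
#: IENFd denervation cut-off for subjects younger than 60 years (fibres/mm).
IENFD_CUTOFF_YOUNG = 5.88
#: IENFd denervation cut-off for subjects aged 60 or older (fibres/mm).
IENFD_CUTOFF_OLD = 2.50
AGE_CUTOFF_BOUNDARY = 60.0

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


class MorphometryError(ValueError):
    pass


@dataclass(frozen=True)
class Particle:
    label: int
    n_pixels: int
    area_um2: float
    touches_periphery: bool


@dataclass(frozen=True)
class ParticleSet:
    """Retained particles of one section plus exclusion bookkeeping."""

    particles: tuple[Particle, ...]
    n_total: int
    n_excluded_periphery: int
    n_excluded_small: int
    scale: float
    min_area_um2: float
    labels: np.ndarray = field(repr=False, default=None)

    @property
    def n_retained(self) -> int:
        return len(self.particles)

    @property
    def ienfa_um2(self) -> float:
        return float(sum(p.area_um2 for p in self.particles))


def extract_particles(
    nerve_mask: np.ndarray,
    epi: EpidermisROI,
    scale: float | None = None,
    min_area_um2: float = MIN_PARTICLE_AREA_UM2,
    periphery_ring_px: int = 1,
) -> ParticleSet:
    """Gate a nerve mask by the epidermis and return retained particles.

    The mask is intersected with the epidermis mask and labelled with
    8-connectivity.  A component is excluded when (a) any of its pixels lies
    on the ``periphery_ring_px``-wide inner boundary ring of the epidermis
    mask, or (b) its calibrated area falls below ``min_area_um2``.
    """
    nerve_mask = as_binary_mask(nerve_mask)
    if scale is None:
        scale = epi.scale
    if nerve_mask.shape != epi.mask.shape:
        raise MorphometryError(
            f"mask shape {nerve_mask.shape} != epidermis shape {epi.mask.shape}"
        )
    if min_area_um2 < 0:
        raise MorphometryError("min_area_um2 must be non-negative")
    if scale <= 0:
        raise MorphometryError("scale must be positive")

    inside = nerve_mask & epi.mask
    labels, n_total = ndi.label(inside, structure=_EIGHT_CONNECTED)
    if periphery_ring_px > 0:
        eroded = ndi.binary_erosion(
            epi.mask, structure=_EIGHT_CONNECTED, iterations=periphery_ring_px,
            border_value=0,
        )
        ring = epi.mask & ~eroded
    else:
        ring = np.zeros_like(epi.mask)

    px_area = scale**2
    retained: list[Particle] = []
    n_periph = n_small = 0
    if n_total:
        counts = np.bincount(labels.ravel())[1:]
        on_ring = np.zeros(n_total + 1, dtype=bool)
        on_ring_labels = np.unique(labels[ring])
        on_ring[on_ring_labels] = True
        for lab in range(1, n_total + 1):
            area = counts[lab - 1] * px_area
            if on_ring[lab]:
                n_periph += 1
                continue
            if area < min_area_um2:
                n_small += 1
                continue
            retained.append(
                Particle(
                    label=lab,
                    n_pixels=int(counts[lab - 1]),
                    area_um2=float(area),
                    touches_periphery=False,
                )
            )
    return ParticleSet(
        particles=tuple(retained),
        n_total=int(n_total),
        n_excluded_periphery=n_periph,
        n_excluded_small=n_small,
        scale=float(scale),
        min_area_um2=float(min_area_um2),
        labels=labels,
    )


@dataclass(frozen=True)
class SectionMetrics:
    """Per-section biomarkers for one segmentation algorithm."""

    algorithm: str
    ienfa_um2: float
    ienfa_per_p: float  # µm²/µm
    ienfa_per_a: float  # 100·µm²/µm²
    section_id: str | None = None


def section_metrics(
    particles: ParticleSet,
    epi: EpidermisROI,
    algorithm: str,
    section_id: str | None = None,
) -> SectionMetrics:
    """Normalise retained particle area by epidermis perimeter and area."""
    if epi.area_um2 <= 0 or epi.perimeter_um <= 0:
        raise MorphometryError("epidermis area and perimeter must be positive")
    ienfa = particles.ienfa_um2
    return SectionMetrics(
        algorithm=algorithm,
        ienfa_um2=ienfa,
        ienfa_per_p=ienfa / epi.perimeter_um,
        ienfa_per_a=100.0 * ienfa / epi.area_um2,
        section_id=section_id,
    )


@dataclass(frozen=True)
class SubjectMetrics:
    """Section-averaged biomarkers (two sections per subject typically)."""

    algorithm: str
    ienfa_um2: float
    ienfa_per_p: float
    ienfa_per_a: float
    n_sections: int


def subject_metrics(sections: list[SectionMetrics]) -> SubjectMetrics:
    """Arithmetic mean of the section metrics of one subject."""
    if not sections:
        raise MorphometryError("need at least one section")
    algorithms = {s.algorithm for s in sections}
    if len(algorithms) > 1:
        raise MorphometryError(f"mixed algorithms in one average: {algorithms}")
    return SubjectMetrics(
        algorithm=sections[0].algorithm,
        ienfa_um2=float(np.mean([s.ienfa_um2 for s in sections])),
        ienfa_per_p=float(np.mean([s.ienfa_per_p for s in sections])),
        ienfa_per_a=float(np.mean([s.ienfa_per_a for s in sections])),
        n_sections=len(sections),
    )


def ienfd_from_counts(fibre_count: int, epidermis_length_mm: float) -> float:
    """IENF density: fibre count per mm of epidermal length."""
    if fibre_count < 0 or int(fibre_count) != fibre_count:
        raise MorphometryError("fibre_count must be a non-negative integer")
    if epidermis_length_mm <= 0:
        raise MorphometryError("epidermis length must be positive")
    return fibre_count / epidermis_length_mm


def classify_denervation(
    ienfd: float,
    age: float,
    cutoff_young: float = IENFD_CUTOFF_YOUNG,
    cutoff_old: float = IENFD_CUTOFF_OLD,
    age_boundary: float = AGE_CUTOFF_BOUNDARY,
) -> bool:
    """True iff IENFd lies strictly below the age-specific cut-off.

    Ages at the boundary use the older stratum's cut-off.
    """
    if ienfd < 0 or age <= 0:
        raise MorphometryError("ienfd must be >= 0 and age > 0")
    cutoff = cutoff_young if age < age_boundary else cutoff_old
    return ienfd < cutoff
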