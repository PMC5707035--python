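"""Quality metrics for extracellular-vesicle preparations.

Works from nanoparticle-tracking (NTA) particle-diameter samples and bulk
protein quantitation:

* modal particle size — center of the most populated fixed-width histogram
  bin (NTA-instrument convention; deterministic, ties broken toward the
  smaller bin);
* fraction of particles in the exosome size window (default 30–200 nm,
  closed interval; the stricter 30–150 nm endosomal definition is available
  by passing different bounds);
* particle yield per mL of plasma input (concentration x dilution factor /
  input volume);
* Webber–Clayton purity: total nanoparticle count per microgram of total
  protein.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

__all__ = [
    "SizeDistribution",
    "QcReport",
    "modal_size",
    "fraction_in_range",
    "purity",
    "particle_yield",
    "qc_report",
]


@dataclasses.dataclass
class SizeDistribution:
    """NTA particle diameters (nm) plus the bookkeeping needed for yield.

    ``concentration`` is particles per mL of the *analyzed* (diluted)
    suspension; ``dilution_factor`` maps back to the original plasma.
    """

    diameters: np.ndarray
    concentration: float = 0.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.diameters.size and (self.diameters <= 0).any():
            raise ValueError("particle diameters must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


def modal_size(dist: SizeDistribution, bin_width_nm: float = 1.0) -> float:
    """Center of the highest-count histogram bin.

    Bins are aligned at integer multiples of ``bin_width_nm`` starting from
    zero; on ties the smaller bin wins.
    """
    if bin_width_nm <= 0:
        raise ValueError("bin_width_nm must be positive")
    d = dist.diameters
    if d.size == 0:
        raise ValueError("empty size distribution")
    edges = np.arange(0.0, d.max() + 2 * bin_width_nm, bin_width_nm)
    counts, _ = np.histogram(d, bins=edges)
    best = int(np.argmax(counts))  # argmax takes the first (smallest) bin on ties
    return float(edges[best] + bin_width_nm / 2.0)


def fraction_in_range(dist: SizeDistribution, lo_nm: float = 30.0, hi_nm: float = 200.0) -> float:
    """Proportion of diameters d with lo <= d <= hi (closed interval)."""
    if lo_nm >= hi_nm:
        raise ValueError("lo_nm must be < hi_nm")
    d = dist.diameters
    if d.size == 0:
        raise ValueError("empty size distribution")
    return float(((d >= lo_nm) & (d <= hi_nm)).mean())


def purity(total_particles: float, total_protein_ug: float) -> float:
    """Webber–Clayton purity: nanoparticles per microgram of protein."""
    if total_protein_ug <= 0:
        raise ValueError("total_protein_ug must be positive")
    if total_particles < 0:
        raise ValueError("total_particles must be nonnegative")
    return total_particles / total_protein_ug


def particle_yield(dist: SizeDistribution, input_plasma_ml: float) -> float:
    """Particles recovered per mL of plasma input.

    ``concentration`` refers to the analyzed suspension, so the yield is
    concentration x dilution_factor / input volume.
    """
    if input_plasma_ml <= 0:
        raise ValueError("input_plasma_ml must be positive")
    return dist.concentration * dist.dilution_factor / input_plasma_ml


@dataclasses.dataclass
class QcReport:
    modal_size_nm: float
    fraction_in_range: float
    range_nm: tuple[float, float]
    particles_per_ml_plasma: float | None
    purity_particles_per_ug: float | None

    def to_dict(self) -> dict:
        return {
            "modal_size_nm": self.modal_size_nm,
            "fraction_in_range": self.fraction_in_range,
            "range_nm": list(self.range_nm),
            "particles_per_ml_plasma": self.particles_per_ml_plasma,
            "purity_particles_per_ug": self.purity_particles_per_ug,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def __str__(self) -> str:
        lines = [
            f"modal size:        {self.modal_size_nm:.1f} nm",
            f"in [{self.range_nm[0]:g}, {self.range_nm[1]:g}] nm: "
            f"{100 * self.fraction_in_range:.1f}%",
        ]
        if self.particles_per_ml_plasma is not None:
            lines.append(f"yield:             {self.particles_per_ml_plasma:.3g} particles/mL plasma")
        if self.purity_particles_per_ug is not None:
            lines.append(f"purity:            {self.purity_particles_per_ug:.3g} particles/ug")
        return "\n".join(lines)


def qc_report(
    dist: SizeDistribution,
    total_protein_ug: float | None = None,
    input_plasma_ml: float | None = None,
    lo_nm: float = 30.0,
    hi_nm: float = 200.0,
    bin_width_nm: float = 1.0,
) -> QcReport:
    """Bundle all QC metrics computable from the supplied inputs."""
    yield_val = particle_yield(dist, input_plasma_ml) if input_plasma_ml else None
    pur = None
    if total_protein_ug is not None:
        total_particles = dist.concentration * dist.dilution_factor
        pur = purity(total_particles, total_protein_ug)
    return QcReport(
        modal_size_nm=modal_size(dist, bin_width_nm),
        fraction_in_range=fraction_in_range(dist, lo_nm, hi_nm),
        range_nm=(lo_nm, hi_nm),
        particles_per_ml_plasma=yield_val,
        purity_particles_per_ug=pur,
    )
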