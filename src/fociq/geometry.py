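"""Imaging-field geometry and unit conversions.

A field is a single 2-D widefield image of a tissue cryosection. Pixel
measurements are converted to physical units (μm, μm², μm³) through the
pixel scale, and — via section thickness, tissue density and per-mass RNA
yield — to the tissue mass and total-RNA content that one field represents.
The defaults describe a 1388×1040 px camera at 20× (~2 px/μm), an 8 μm
section, muscle density 1.06 g·ml⁻¹ and RNA yields of 0.25–0.5 μg per mg
of tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class FieldGeometry:
    """Physical description of one imaging field.

    Parameters
    ----------
    width_px, height_px
        Camera frame size in pixels.
    px_per_um
        Lateral pixel scale (pixels per micron).
    thickness_um
        Cryosection thickness in μm.
    density_mg_per_mm3
        Tissue density (1.06 mg/mm³ ≡ 1.06 g/ml for skeletal muscle).
    rna_yield_ug_per_mg
        (low, high) total-RNA yield per mg of tissue.
    """

    width_px: int = 1388
    height_px: int = 1040
    px_per_um: float = 2.0
    thickness_um: float = 8.0
    density_mg_per_mm3: float = 1.06
    rna_yield_ug_per_mg: tuple[float, float] = (0.25, 0.5)

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "px_per_um", "thickness_um",
                     "density_mg_per_mm3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        low, high = self.rna_yield_ug_per_mg
        if low <= 0 or high <= 0 or low > high:
            raise ValueError("rna_yield_ug_per_mg must satisfy 0 < low <= high")

    # ---- lateral extents -------------------------------------------------
    @property
    def width_um(self) -> float:
        return self.width_px / self.px_per_um

    @property
    def height_um(self) -> float:
        return self.height_px / self.px_per_um

    @property
    def area_um2(self) -> float:
        """Field area in μm² (width·height / px_per_um²)."""
        return self.width_px * self.height_px / self.px_per_um**2

    # ---- volumetric / mass conversions -----------------------------------
    @property
    def volume_um3(self) -> float:
        return self.area_um2 * self.thickness_um

    @property
    def tissue_mass_ug(self) -> float:
        """Tissue mass represented by one field, in μg."""
        volume_mm3 = self.volume_um3 * 1e-9
        return volume_mm3 * self.density_mg_per_mm3 * 1e3

    @property
    def rna_ng_range(self) -> tuple[float, float]:
        """(low, high) estimate of total RNA per field, in ng."""
        mass_mg = self.tissue_mass_ug * 1e-3
        low, high = self.rna_yield_ug_per_mg
        return (mass_mg * low * 1e3, mass_mg * high * 1e3)

    def pixel_area_to_um2(self, pixel_count: float) -> float:
        """Convert a pixel count (apparent particle area) to μm²."""
        if pixel_count < 0:
            raise ValueError("pixel_count must be >= 0")
        return pixel_count / self.px_per_um**2
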