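"""Stroke-outcome quantification formulas.

The downstream arithmetic for the study's wet-lab readouts, starting from
already-measured quantities (areas traced on TTC-stained slices, chamber
fluorescences, impedance series, binary-mask intensities, qPCR threshold
cycles). Image segmentation, curve fitting and between-group statistics are
out of scope.

* Stroke volumetrics: each 2 mm coronal slice is imaged on its anterior and
  posterior faces; each measured face area contributes a 1 mm-thick volume.
  The edema-adjusted stroke volume is
  SV = V_infarct * (1 - (V_ipsi - V_contra) / V_contra)
  and the edema volume is V_ipsi - V_contra.
* Transwell permeability: pe = (B - bg) / (T - bg), the
  background-corrected bottom-to-top chamber fluorescence ratio.
* TEER: resistances are rescaled so the pre-treatment value is 100%;
  treated series can additionally be expressed as percent of their matched
  control at each timepoint.
* Immunostaining intensity (a.u.): binary-mask area times the mean
  intensity within the mask; the overlap variant uses the between-channel
  overlap area with the mean intensity of the channel of interest.
* qPCR: relative expression by 2^-ddCt, with a non-amplifying target's
  dCt capped at 15 by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: default dCt assigned when the target shows no amplification
NO_AMPLIFICATION_DCT = 15.0


@dataclass
class FaceMeasurement:
    """One imaged slice face: traced areas in mm^2, thickness in mm."""

    slice_index: int
    face: str  # "anterior" | "posterior"
    area_ipsi: float
    area_contra: float
    area_infarct: float
    thickness: float = 1.0

    def __post_init__(self) -> None:
        for name in ("area_ipsi", "area_contra", "area_infarct", "thickness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (slice {self.slice_index})")
        if self.area_infarct > self.area_ipsi:
            raise ValueError(
                f"infarct area exceeds ipsilateral hemisphere area on slice "
                f"{self.slice_index} ({self.face})"
            )


@dataclass
class VolumetricRecord:
    """Per-animal TTC volumetry: faces in, volumes (mm^3) out."""

    animal_id: str
    faces: list[FaceMeasurement]
    v_ipsi: float | None = None
    v_contra: float | None = None
    v_infarct: float | None = None
    sv: float | None = None
    v_edema: float | None = None


def stroke_volumes(record: VolumetricRecord, per_slice_mean: bool = False) -> VolumetricRecord:
    """Fill hemisphere/infarct volumes, edema volume and stroke volume.

    Default: every face volume (area x thickness) is summed. With
    ``per_slice_mean`` the two faces of each slice are averaged first and
    scaled to the 2 mm slice thickness instead — an alternative reading of
    face-wise imaging.
    """
    if not record.faces:
        raise ValueError("at least one face measurement is required")
    if per_slice_mean:
        by_slice: dict[int, list[FaceMeasurement]] = {}
        for f in record.faces:
            by_slice.setdefault(f.slice_index, []).append(f)
        v_i = v_c = v_inf = 0.0
        for faces in by_slice.values():
            slice_th = sum(f.thickness for f in faces)
            v_i += np.mean([f.area_ipsi for f in faces]) * slice_th
            v_c += np.mean([f.area_contra for f in faces]) * slice_th
            v_inf += np.mean([f.area_infarct for f in faces]) * slice_th
    else:
        v_i = sum(f.area_ipsi * f.thickness for f in record.faces)
        v_c = sum(f.area_contra * f.thickness for f in record.faces)
        v_inf = sum(f.area_infarct * f.thickness for f in record.faces)
    if v_c <= 0:
        raise ValueError("contralateral hemisphere volume must be > 0")
    record.v_ipsi, record.v_contra, record.v_infarct = v_i, v_c, v_inf
    record.v_edema = v_i - v_c
    record.sv = v_inf * (1.0 - (v_i - v_c) / v_c)
    return record


@dataclass
class TracerMeasurement:
    """One transwell tracer read-out, all fluorescences in the same a.u."""

    tracer: str
    top: float
    bottom: float
    background: float = 0.0
    molecular_weight: str | None = None


def permeability_index(m: TracerMeasurement) -> float:
    """pe = (B - bg) / (T - bg); a negative numerator clips to 0."""
    denom = m.top - m.background
    if denom <= 0:
        raise ValueError(
            f"{m.tracer}: top fluorescence must exceed background "
            f"(T={m.top}, bg={m.background})"
        )
    num = m.bottom - m.background
    if num < 0:
        log.warning("%s: bottom fluorescence below background; pe clipped to 0",
                    m.tracer)
        num = 0.0
    return num / denom


@dataclass
class TEERSeries:
    """Ordered (time h, resistance Ohm*cm^2) measurements for one insert."""

    insert_id: str
    condition: str
    times: list[float]
    resistances: list[float]
    treatment_start: float = 0.0
    normalized: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.resistances):
            raise ValueError("times and resistances differ in length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")

    def value_at(self, t: float) -> float:
        """Resistance at t, linearly interpolating between bracketing points."""
        times = np.asarray(self.times)
        if t < times[0] or t > times[-1]:
            raise ValueError(
                f"{self.insert_id}: time {t} outside measured range "
                f"[{times[0]}, {times[-1]}]"
            )
        return float(np.interp(t, times, self.resistances))


def normalize_teer(
    series: TEERSeries,
    control: TEERSeries | None = None,
    timepoints: list[float] | None = None,
) -> tuple[TEERSeries, dict[float, float] | None]:
    """Rescale a TEER series to percent of its pre-treatment value.

    normalized(t) = 100 * R(t) / R(treatment_start). With a matched
    control, percent-of-control = 100 * normalized_treated(t) /
    normalized_control(t) is returned at the requested timepoints.
    """
    r0 = series.value_at(series.treatment_start)
    if r0 <= 0:
        raise ValueError(f"{series.insert_id}: pre-treatment resistance is not positive")
    series.normalized = [100.0 * r / r0 for r in series.resistances]
    if control is None:
        return series, None
    control, _ = normalize_teer(control)
    pct: dict[float, float] = {}
    for t in timepoints or series.times:
        treated = 100.0 * series.value_at(t) / r0
        ctrl = 100.0 * control.value_at(t) / control.value_at(control.treatment_start)
        pct[t] = 100.0 * treated / ctrl
    return series, pct


@dataclass
class ROIIntensity:
    """Binary-mask area and mean intensity for one region of interest."""

    area: float
    mean_intensity: float
    overlap_area: float | None = None

    def __post_init__(self) -> None:
        if self.area < 0 or self.mean_intensity < 0:
            raise ValueError("area and mean intensity must be >= 0")
        if self.overlap_area is not None and self.overlap_area > self.area:
            raise ValueError("overlap area cannot exceed the parent area")


def ihc_intensity(roi: ROIIntensity, mode: str = "single") -> float:
    """Expression intensity (a.u.): area (or overlap area) x mean intensity."""
    if mode == "single":
        return roi.area * roi.mean_intensity
    if mode == "overlap":
        if roi.overlap_area is None:
            raise ValueError("overlap mode requires an overlap area")
        return roi.overlap_area * roi.mean_intensity
    raise ValueError("mode must be 'single' or 'overlap'")


@dataclass
class QPCRRecord:
    """Threshold cycles for target and housekeeping genes, two conditions.

    ``None`` marks no amplification; a non-amplifying target's dCt is set
    to ``no_amp_dct`` (default 15). A non-amplifying housekeeping gene
    makes normalization impossible and is an error.
    """

    ct_target_test: float | None
    ct_housekeeping_test: float | None
    ct_target_reference: float | None
    ct_housekeeping_reference: float | None
    no_amp_dct: float = NO_AMPLIFICATION_DCT


def _dct(ct_target: float | None, ct_hk: float | None, cap: float) -> float:
    if ct_hk is None:
        raise ValueError("housekeeping gene did not amplify; cannot normalize")
    if ct_target is None:
        return cap
    return ct_target - ct_hk


def ddct_relative_expression(rec: QPCRRecord) -> float:
    """Relative expression 2^-ddCt of test vs reference condition."""
    dct_test = _dct(rec.ct_target_test, rec.ct_housekeeping_test, rec.no_amp_dct)
    dct_ref = _dct(rec.ct_target_reference, rec.ct_housekeeping_reference,
                   rec.no_amp_dct)
    return math.pow(2.0, -(dct_test - dct_ref))
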