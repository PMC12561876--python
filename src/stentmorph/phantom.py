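"""Synthetic stent phantoms with known ground-truth centerlines.

The clinical radiograph set behind this method is restricted, so validation
runs on phantoms: binary masks of a roughly vertical tube whose midline is a
single-frequency sinusoid

    lateral(t) = center + A * sin(2 * pi * t / wavelength + phase),

with ``t`` the axial row index.  One amplitude parameter A gives a clean
monotone curvature dial and an analytic slope oracle (the mean absolute
gradient of the midline is computable by quadrature).  Optional 270-degree
pigtail loops tangent to the tube ends reproduce the high-curvature end
artifact that the 5% end trim exists to remove, and i.i.d. pixel flips
exercise contour robustness without modelling radiographic physics.

:func:`make_cohort` builds paired pre/post cohorts: each patient draws a pre
amplitude from a truncated normal, and the follow-up amplitude is the pre
amplitude scaled by a straightening factor (optionally with per-patient
follow-up jitter), emulating the clinically observed straightening between
insertion and follow-up imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from skimage import measure, morphology

from .centerline import Centerline

__all__ = ["PhantomSpec", "CohortSpec", "PatientRecord", "make_stent_mask", "make_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one rendered stent mask.

    Defaults approximate an adult stent ROI on a resampled radiograph: a
    400-row crop, a tube of ~7 px diameter, lateral excursion of +-20 px over
    a 300-row wavelength, and 8 px pigtail loops.
    """

    height_px: int = 400
    width_px: int = 160
    tube_radius_px: int = 3
    amplitude_px: float = 20.0
    wavelength_px: float = 300.0
    phase_rad: float = 0.0
    pigtail_radius_px: int = 8
    noise_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 16 or self.width_px < 8:
            raise ValueError(f"raster {self.height_px}x{self.width_px} too small")
        if self.tube_radius_px < 1:
            raise ValueError(f"tube_radius_px must be >= 1, got {self.tube_radius_px}")
        if self.amplitude_px < 0:
            raise ValueError(f"amplitude_px must be >= 0, got {self.amplitude_px}")
        if self.wavelength_px <= 0:
            raise ValueError(f"wavelength_px must be > 0, got {self.wavelength_px}")
        if self.pigtail_radius_px < 0:
            raise ValueError(f"pigtail_radius_px must be >= 0, got {self.pigtail_radius_px}")
        if not 0.0 <= self.noise_prob <= 0.1:
            raise ValueError(f"noise_prob must be in [0, 0.1], got {self.noise_prob}")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a paired pre/post phantom cohort.

    Per patient i, the pre amplitude is drawn A_i ~ Normal(pre_amplitude_px,
    between_patient_sd) truncated at 0 (truncation rather than rejection keeps
    the draw count, and hence determinism, independent of the parameters), and
    the follow-up amplitude is ``A_i * straightening_factor``;
    ``straightening_factor = 1`` means no morphological change.
    ``post_amplitude_sd`` adds independent Normal per-patient jitter to the
    follow-up amplitude (clipped at 0), modelling patient-level variability in
    how far the ureter actually straightens; it defaults to 0, in which case
    the follow-up amplitude is exactly the scaled pre amplitude.
    """

    n_patients: int = 30
    pre_amplitude_px: float = 20.0
    straightening_factor: float = 0.7
    between_patient_sd: float = 4.0
    post_amplitude_sd: float = 0.0
    seed: int = 0
    base: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError(f"n_patients must be >= 2, got {self.n_patients}")
        if not 0.0 <= self.straightening_factor <= 1.0:
            raise ValueError(
                f"straightening_factor must be in [0, 1], got {self.straightening_factor}"
            )
        if self.pre_amplitude_px < 0 or self.between_patient_sd < 0 or self.post_amplitude_sd < 0:
            raise ValueError("amplitude parameters must be non-negative")


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient: paired masks, ground truth, and the amplitudes used."""

    patient_id: str
    pre_mask: np.ndarray = field(repr=False)
    post_mask: np.ndarray = field(repr=False)
    truth_pre: Centerline = field(repr=False)
    truth_post: Centerline = field(repr=False)
    amplitude_pre: float = 0.0
    amplitude_post: float = 0.0


def _midline(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    center = (spec.width_px - 1) / 2.0
    return center + spec.amplitude_px * np.sin(
        2.0 * np.pi * t / spec.wavelength_px + spec.phase_rad
    )


def _pigtail_arc(
    p0: np.ndarray, tangent_into_body: np.ndarray, radius: float, side: int
) -> np.ndarray:
    """Sample a 270-degree circular arc tangent to the midline at ``p0``.

    ``side`` (+1/-1) picks the lateral side the loop curls toward; the sweep
    direction is chosen so the arc leaves ``p0`` away from the tube body.
    Points are (axial, lateral) floats.
    """
    perp = np.array([-tangent_into_body[1], tangent_into_body[0]])
    if perp[1] * side < 0:
        perp = -perp
    center = p0 + radius * perp
    radial = p0 - center
    theta0 = np.arctan2(radial[1], radial[0])
    # d(position)/d(theta) at p0 for increasing theta:
    tangent_plus = np.array([-radial[1], radial[0]]) / radius
    sweep_sign = -1.0 if np.dot(tangent_plus, tangent_into_body) > 0 else 1.0
    n = max(int(radius * 1.5 * np.pi / 0.3), 16)
    thetas = theta0 + sweep_sign * np.linspace(0.0, 1.5 * np.pi, n)
    return center + radius * np.column_stack([np.cos(thetas), np.sin(thetas)])


def make_stent_mask(spec: PhantomSpec) -> tuple[np.ndarray, Centerline]:
    """Render a binary stent mask and its exact midline ground truth.

    The sinusoidal midline is rasterized with axial supersampling, optionally
    extended by pigtail arcs at both ends, dilated to the tube radius, and
    finally perturbed by salt-and-pepper pixel flips.  The returned truth is
    the analytic midline sampled at every axial row of the tube body; pigtail
    rows are excluded from the truth.  Before noise, the rendered mask is a
    single 8-connected component (tangency of the arcs guarantees it; the
    invariant is verified).
    """
    H, W, r = spec.height_px, spec.width_px, spec.tube_radius_px
    margin = (2 * spec.pigtail_radius_px + r + 2) if spec.pigtail_radius_px > 0 else 0
    t0, t1 = margin, H - margin  # body occupies rows [t0, t1)
    if t1 - t0 < 8:
        raise ValueError(
            f"pigtail_radius_px={spec.pigtail_radius_px} leaves too few body rows in "
            f"height_px={H}"
        )

    t_rows = np.arange(t0, t1, dtype=float)
    truth = Centerline(axial=t_rows, lateral=_midline(spec, t_rows))

    t_dense = np.arange(t0, t1 - 1 + 1e-9, 0.2)
    body = np.column_stack([t_dense, _midline(spec, t_dense)])
    pieces = [body]

    if spec.pigtail_radius_px > 0:
        omega = 2.0 * np.pi / spec.wavelength_px
        center_col = (W - 1) / 2.0
        for t_end, into_sign in ((float(t0), 1.0), (float(t1 - 1), -1.0)):
            slope = spec.amplitude_px * omega * np.cos(omega * t_end + spec.phase_rad)
            tangent = np.array([into_sign, into_sign * slope])
            tangent /= np.linalg.norm(tangent)
            p0 = np.array([t_end, float(_midline(spec, np.array([t_end]))[0])])
            side = 1 if p0[1] <= center_col else -1
            pieces.append(_pigtail_arc(p0, tangent, float(spec.pigtail_radius_px), side))

    # Laterally the full tube (midline +- radius) must fit; axially only the
    # midline itself must, since the dilation end caps may clip at the edge.
    skeleton_pts = np.vstack(pieces)
    lo = skeleton_pts.min(axis=0)
    hi = skeleton_pts.max(axis=0)
    if lo[1] - r < 0 or hi[1] + r > W - 1:
        raise ValueError(
            f"curve exits the raster laterally: amplitude_px={spec.amplitude_px} "
            f"(with tube_radius_px={r}, pigtail_radius_px={spec.pigtail_radius_px}) "
            f"does not fit width_px={W}"
        )
    if lo[0] < 0 or hi[0] > H - 1:
        raise ValueError(
            f"curve exits the raster axially: pigtail_radius_px={spec.pigtail_radius_px} "
            f"does not fit height_px={H}"
        )

    skel = np.zeros((H, W), dtype=bool)
    idx = np.rint(skeleton_pts).astype(int)
    skel[idx[:, 0], idx[:, 1]] = True
    mask = ndi.binary_dilation(skel, structure=morphology.disk(r))

    n_comp = measure.label(mask, connectivity=2, return_num=True)[1]
    if n_comp != 1:  # tangency should make this unreachable
        raise RuntimeError(f"rendered mask has {n_comp} components, expected 1")

    if spec.noise_prob > 0:
        rng = np.random.default_rng(spec.seed)
        mask = mask ^ (rng.random(mask.shape) < spec.noise_prob)

    return mask, truth


def make_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate a paired pre/post cohort of stent phantoms.

    Deterministic under ``spec.seed``: per-patient amplitudes and per-image
    noise sub-seeds all derive from one seeded generator.  The drawn
    amplitudes are stored on each record so simulation studies can read back
    the exact ground-truth parameters.
    """
    rng = np.random.default_rng(spec.seed)
    mu, sd = spec.pre_amplitude_px, spec.between_patient_sd
    if sd > 0:
        amplitudes = stats.truncnorm.rvs(
            (0.0 - mu) / sd, np.inf, loc=mu, scale=sd, size=spec.n_patients, random_state=rng
        )
    else:
        amplitudes = np.full(spec.n_patients, mu)
    post_jitter = (
        rng.normal(0.0, spec.post_amplitude_sd, size=spec.n_patients)
        if spec.post_amplitude_sd > 0
        else np.zeros(spec.n_patients)
    )

    records: list[PatientRecord] = []
    for i in range(spec.n_patients):
        a_pre = float(amplitudes[i])
        a_post = float(max(0.0, a_pre * spec.straightening_factor + post_jitter[i]))
        seed_pre = int(rng.integers(0, 2**31))
        seed_post = int(rng.integers(0, 2**31))
        pre_mask, truth_pre = make_stent_mask(
            replace(spec.base, amplitude_px=a_pre, seed=seed_pre)
        )
        post_mask, truth_post = make_stent_mask(
            replace(spec.base, amplitude_px=a_post, seed=seed_post)
        )
        records.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                pre_mask=pre_mask,
                post_mask=post_mask,
                truth_pre=truth_pre,
                truth_post=truth_post,
                amplitude_pre=a_pre,
                amplitude_post=a_post,
            )
        )
    return records
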