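"""Synthetic dynamic-PET phantom cohorts with the statistical structure of a
tau-tracer test-retest study.

The generator builds a spherical-blob "brain" on a small isotropic grid:
a cerebellar grey-matter annulus (the reference region), cerebellar white
matter, pons, a cerebral white-matter core, nine cortical/limbic target blobs
(including a small entorhinal-like region of ~650 voxels), surrounding
nonspecific brain tissue, and a high-uptake extracerebral shell just outside
the brain. Regional kinetics follow the simplified reference tissue model
around a shared reference input (fast rise, bi-exponential washout); the
shell follows its own slowly accumulating curve with large between-subject
amplitude variability and smooth within-shell spatial heterogeneity.

Dynamic 4-D volumes are produced by painting regional time-activity curves
into the label map, blurring each frame with a Gaussian point-spread
function (the source of partial-volume effects), and adding Gaussian noise
whose standard deviation scales with the local value and inversely with the
square root of frame duration. Test/retest pairs share the truth and label
map; each session draws its own multiplicative state (a global dose/weight
analogue plus region-class factors) and independent noise.

Everything is deterministic under explicit seeds, and a truth table
(per-region R1, k2, BP, DVR = 1 + BP) is always emitted with the images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .kinetics import SrtmParams, srtm_forward
from .rois import LabelVolume, RegionInfo, build_extracerebral_shell
from .tacs import FrameSchedule, ScanMeta, TimeActivityCurve

__all__ = [
    "ReferenceKinetics",
    "reference_tac_model",
    "PhantomSpec",
    "Phantom",
    "RetestPerturbation",
    "make_phantom",
    "simulate_dynamic",
    "make_trt_pair",
    "Cohort",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# Reference-region input model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceKinetics:
    """Continuous reference curve: fast rise times bi-exponential washout.

    c(t) = amplitude * (w1 e^{-k1 t} + w2 e^{-k2 t}) * (1 - e^{-rise t}),
    in kBq/mL with t in minutes. The default is calibrated so that the
    90-110 min SUV lands near 0.55 g/mL at 185 MBq / 74 kg (2.5 kBq/g), the
    middle of the reference-region range reported for cognitively normal
    subjects, with the peak before 5 min.
    """

    amplitude: float = 6.78  # kBq/mL scale; see calibration note in docs
    weights: tuple[float, float] = (0.7, 0.3)
    washout_rates: tuple[float, float] = (0.06, 0.004)  # 1/min
    rise_rate: float = 2.0  # 1/min

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if any(r <= 0 for r in self.washout_rates) or self.rise_rate <= 0:
            raise ValueError("rates must be positive")

    def _exp_terms(self) -> list[tuple[float, float]]:
        """(coefficient, rate) pairs of the equivalent sum of exponentials."""
        terms = []
        for w, k in zip(self.weights, self.washout_rates):
            terms.append((self.amplitude * w, k))
            terms.append((-self.amplitude * w, k + self.rise_rate))
        return terms

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, b in self._exp_terms():
            out = out + a * np.exp(-b * t)
        return out

    def frame_averages(self, schedule: FrameSchedule) -> np.ndarray:
        """Exact per-frame time averages of the continuous curve."""
        s, e, d = schedule.starts, schedule.ends, schedule.durations
        out = np.zeros(schedule.n_frames)
        for a, b in self._exp_terms():
            out += a * (np.exp(-b * s) - np.exp(-b * e)) / (b * d)
        return out


def reference_tac_model(params: ReferenceKinetics, schedule: FrameSchedule) -> TimeActivityCurve:
    """Frame-averaged reference TAC from the continuous reference model."""
    return TimeActivityCurve(schedule, params.frame_averages(schedule), region="reference")


@dataclass(frozen=True)
class ShellKinetics:
    """Slowly accumulating extracerebral curve c(t) = A (1 - e^{-k t})."""

    amplitude: float
    rate: float = 0.02  # 1/min

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.amplitude * (1.0 - np.exp(-self.rate * t))

    def frame_averages(self, schedule: FrameSchedule) -> np.ndarray:
        s, e, d = schedule.starts, schedule.ends, schedule.durations
        k = self.rate
        exp_avg = (np.exp(-k * s) - np.exp(-k * e)) / (k * d)
        return self.amplitude * (1.0 - exp_avg)


# ---------------------------------------------------------------------------
# Geometry and group kinetic profiles
# ---------------------------------------------------------------------------

# (name, label id, role, center offset mm, inner radius mm, outer radius mm)
REGION_GEOMETRY = (
    ("cerebellar_gm", 1, "reference", (0.0, 0.0, -34.0), 6.0, 14.0),
    ("cerebellar_wm", 2, "reference", (0.0, 0.0, -34.0), 0.0, 6.0),
    ("pons", 3, "reference", (0.0, 22.0, -30.0), 0.0, 6.0),
    ("cerebral_wm", 4, "reference", (0.0, 0.0, 10.0), 0.0, 13.0),
    ("entorhinal", 10, "target", (-26.0, -20.0, -10.0), 0.0, 10.7),
    ("parahippocampus", 11, "target", (26.0, -20.0, -10.0), 0.0, 8.0),
    ("amygdala", 12, "target", (-26.0, 20.0, -10.0), 0.0, 7.0),
    ("hippocampus", 13, "target", (26.0, 20.0, -10.0), 0.0, 8.0),
    ("fusiform", 14, "target", (-28.0, 0.0, 14.0), 0.0, 9.0),
    ("inferior_temporal", 15, "target", (28.0, 0.0, 14.0), 0.0, 9.0),
    ("middle_temporal", 16, "target", (0.0, -30.0, 14.0), 0.0, 9.0),
    ("precuneus", 17, "target", (0.0, 30.0, 14.0), 0.0, 9.0),
    ("insula", 18, "target", (0.0, 0.0, 36.0), 0.0, 8.0),
)

OTHER_BRAIN_LABEL = 80
SHELL_LABEL = 90

# Per-group kinetic truth profiles: region -> (R1, BP). The reference region
# is (1, 0) by construction; target BP values are set so noise-free SUVR
# lands inside the published group ranges (SUVR ~ 0.6-1.2 for older
# controls, up to ~2.75 in the AD precuneus), and R1 spans ~0.66-1.39.
GROUP_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "oCN": {
        "cerebellar_wm": (0.75, -0.25),
        "pons": (0.75, -0.35),
        "cerebral_wm": (0.70, -0.22),
        "entorhinal": (0.69, 0.08),
        "parahippocampus": (0.80, -0.08),
        "amygdala": (0.91, -0.24),
        "hippocampus": (0.91, -0.18),
        "fusiform": (0.90, 0.00),
        "inferior_temporal": (0.83, 0.06),
        "middle_temporal": (0.85, 0.00),
        "precuneus": (1.06, -0.14),
        "insula": (1.39, -0.22),
        "other_brain": (1.00, -0.08),
    },
    "yCN": {
        "cerebellar_wm": (0.75, -0.30),
        "pons": (0.75, -0.38),
        "cerebral_wm": (0.70, -0.30),
        "entorhinal": (0.68, -0.02),
        "parahippocampus": (0.80, -0.10),
        "amygdala": (0.72, -0.38),
        "hippocampus": (0.79, -0.34),
        "fusiform": (0.95, -0.04),
        "inferior_temporal": (0.85, 0.10),
        "middle_temporal": (0.86, 0.00),
        "precuneus": (1.05, -0.18),
        "insula": (1.22, -0.28),
        "other_brain": (1.00, -0.10),
    },
    "AD": {
        "cerebellar_wm": (0.75, -0.25),
        "pons": (0.75, -0.40),
        "cerebral_wm": (0.75, 0.20),
        "entorhinal": (0.66, 0.74),
        "parahippocampus": (0.75, 0.76),
        "amygdala": (0.76, 0.30),
        "hippocampus": (0.77, 0.04),
        "fusiform": (0.84, 1.15),
        "inferior_temporal": (0.70, 1.42),
        "middle_temporal": (0.72, 1.15),
        "precuneus": (0.83, 1.66),
        "insula": (0.93, 0.33),
        "other_brain": (0.90, 0.10),
    },
}

# Safety clamps on subject truth DVR = 1 + BP. Group-mean SUVR stays inside
# the published calibration bands (checked in tests); individual subjects may
# range beyond them, as the published per-region standard deviations imply,
# which is what gives the cohorts realistic between-subject variance (ICC).
_DVR_CLAMP = {"oCN": (0.55, 1.35), "yCN": (0.50, 1.35), "AD": (1.00, 2.75)}
_R1_CLAMP = (0.66, 1.39)
_REF_K2_PRIME = 0.04  # 1/min; phantom k2 = R1 * k2' so the implied reference
# efflux matches the default analysis setting.


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, group profile, and between-subject variability settings."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    group: str = "oCN"
    brain_radius_mm: float = 50.0
    shell_thickness_mm: float = 5.0
    shell_suvr: float = 1.38
    shell_rate: float = 0.02
    # between-subject variability
    amplitude_cv: float = 0.20
    r1_sd: float = 0.10
    bp_sd: float = 0.10
    shell_cv: float = 0.40
    shell_heterogeneity: float = 0.30

    def __post_init__(self) -> None:
        if self.group not in GROUP_PROFILES:
            raise ValueError(f"unknown group profile {self.group!r}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        for name in ("amplitude_cv", "r1_sd", "bp_sd", "shell_cv", "shell_heterogeneity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class Phantom:
    """A subject: label volume, kinetic truth, and subject-level factors."""

    spec: PhantomSpec
    labels: LabelVolume
    truth: pd.DataFrame  # region, label, role, r1, k2, bp, dvr
    ref_kinetics: ReferenceKinetics
    shell: ShellKinetics
    shell_field: np.ndarray  # multiplicative spatial heterogeneity on the shell
    brain_mask: np.ndarray
    superior_cerebellum: np.ndarray
    seed: int

    def reference_tac(self, schedule: FrameSchedule) -> TimeActivityCurve:
        return reference_tac_model(self.ref_kinetics, schedule)

    def region_params(self, region: str) -> SrtmParams:
        row = self.truth.loc[self.truth.region == region].iloc[0]
        return SrtmParams(r1=row.r1, k2=row.k2, bp=row.bp)


def _coordinate_grids(shape, voxel_size_mm):
    center = [(n - 1) * v / 2.0 for n, v in zip(shape, voxel_size_mm)]
    axes = [np.arange(n) * v - c for n, v, c in zip(shape, voxel_size_mm, center)]
    return np.meshgrid(*axes, indexing="ij")


def _build_labels(spec: PhantomSpec) -> tuple[LabelVolume, np.ndarray, np.ndarray]:
    xx, yy, zz = _coordinate_grids(spec.shape, spec.voxel_size_mm)
    rr = np.sqrt(xx**2 + yy**2 + zz**2)
    brain = rr <= spec.brain_radius_mm
    data = np.zeros(spec.shape, dtype=np.int16)
    info: dict[int, RegionInfo] = {}
    for name, lid, role, (cx, cy, cz), r_in, r_out in REGION_GEOMETRY:
        d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2)
        mask = (d <= r_out) & (d > r_in)
        if np.any(data[mask] != 0):
            raise ValueError(f"region {name!r} overlaps a previously placed region")
        if not mask.any():
            raise ValueError(f"region {name!r} is empty on this grid")
        data[mask] = lid
        info[lid] = RegionInfo(name, role)
    other = brain & (data == 0)
    data[other] = OTHER_BRAIN_LABEL
    info[OTHER_BRAIN_LABEL] = RegionInfo("other_brain", "other")
    shell = build_extracerebral_shell(brain, spec.voxel_size_mm,
                                      spec.shell_thickness_mm, brain_mask=brain)
    data[shell] = SHELL_LABEL
    info[SHELL_LABEL] = RegionInfo("extracerebral", "extracerebral")
    # superior cerebellum: upper half of the cerebellar annulus, used to
    # derive the inferior-cerebellum reference variant by subtraction
    cer_center_z = -34.0
    superior = (data == 1) & (zz > cer_center_z)
    vol = LabelVolume(data, spec.voxel_size_mm, info)
    return vol, brain, superior


def make_phantom(spec: PhantomSpec, seed: int) -> Phantom:
    """Deterministic subject phantom: labels plus jittered kinetic truth.

    Subject-level draws: a global reference-amplitude factor (clamped so the
    reference SUV stays in the calibration band), additive R1 and BP jitter
    per region (clamped to the group calibration windows), a shell amplitude
    factor, and a smooth within-shell heterogeneity field.
    """
    rng = np.random.default_rng(seed)
    vol, brain, superior = _build_labels(spec)
    profile = GROUP_PROFILES[spec.group]

    amp_factor = float(np.clip(1.0 + spec.amplitude_cv * rng.standard_normal(), 0.67, 1.28))
    base = ReferenceKinetics()
    ref = replace(base, amplitude=base.amplitude * amp_factor)

    dvr_lo, dvr_hi = _DVR_CLAMP[spec.group]
    rows = []
    for lid, region_info in sorted(vol.labels.items()):
        name = region_info.name
        if name == "cerebellar_gm":
            r1, bp = 1.0, 0.0
        elif name == "extracerebral":
            r1, bp = np.nan, np.nan
        else:
            r1_0, bp_0 = profile[name]
            r1 = float(np.clip(r1_0 + spec.r1_sd * rng.standard_normal(), *_R1_CLAMP))
            dvr = float(np.clip(1.0 + bp_0 + spec.bp_sd * rng.standard_normal(), dvr_lo, dvr_hi))
            bp = dvr - 1.0
        k2 = _REF_K2_PRIME * r1 if np.isfinite(r1) else np.nan
        rows.append(
            {"region": name, "label": lid, "role": region_info.role,
             "r1": r1, "k2": k2, "bp": bp, "dvr": 1.0 + bp}
        )
    truth = pd.DataFrame(rows)

    # shell amplitude: calibrated so the shell-to-reference SUVR over the
    # late window matches spec.shell_suvr before the subject factor
    window_sched = FrameSchedule(np.array([90.0, 95.0, 100.0, 105.0]),
                                 np.array([95.0, 100.0, 105.0, 110.0]))
    ref_window = float(np.mean(ref.frame_averages(window_sched)))
    unit_shell = ShellKinetics(amplitude=1.0, rate=spec.shell_rate)
    shape_window = float(np.mean(unit_shell.frame_averages(window_sched)))
    shell_factor = float(np.clip(np.exp(spec.shell_cv * rng.standard_normal()
                                        - 0.5 * spec.shell_cv**2), 0.45, 2.2))
    shell_amp = spec.shell_suvr * ref_window / shape_window * shell_factor
    shell = ShellKinetics(amplitude=shell_amp, rate=spec.shell_rate)

    # smooth multiplicative heterogeneity across the shell (same for both
    # sessions of a subject)
    noise = rng.standard_normal(spec.shape)
    smooth = gaussian_filter(noise, sigma=6.0 / np.asarray(spec.voxel_size_mm))
    sd = smooth.std()
    field_arr = 1.0 + spec.shell_heterogeneity * (smooth / sd if sd > 0 else smooth)
    field_arr = np.clip(field_arr, 0.2, None)
    in_shell = vol.data == SHELL_LABEL
    field_arr /= field_arr[in_shell].mean()  # shell mean exactly the truth TAC
    shell_field = np.where(in_shell, field_arr, 1.0).astype(np.float32)

    return Phantom(
        spec=spec, labels=vol, truth=truth, ref_kinetics=ref, shell=shell,
        shell_field=shell_field, brain_mask=brain, superior_cerebellum=superior,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Dynamic simulation
# ---------------------------------------------------------------------------

def region_truth_tacs(phantom: Phantom, schedule: FrameSchedule) -> dict[str, TimeActivityCurve]:
    """Noise-free regional TACs implied by the phantom truth."""
    ref_tac = phantom.reference_tac(schedule)
    out = {"cerebellar_gm": TimeActivityCurve(schedule, ref_tac.values, region="cerebellar_gm")}
    for _, row in phantom.truth.iterrows():
        if row.region in ("cerebellar_gm", "extracerebral"):
            continue
        params = SrtmParams(r1=row.r1, k2=row.k2, bp=row.bp)
        tac = srtm_forward(ref_tac, params)
        out[row.region] = TimeActivityCurve(schedule, tac.values, region=row.region)
    out["extracerebral"] = TimeActivityCurve(
        schedule, phantom.shell.frame_averages(schedule), region="extracerebral"
    )
    return out


def simulate_dynamic(
    phantom: Phantom,
    schedule: FrameSchedule,
    psf_fwhm_mm: float = 5.0,
    noise_cv: float = 0.03,
    seed: int = 0,
    region_scale: dict[int, float] | None = None,
    global_scale: float = 1.0,
) -> np.ndarray:
    """Simulate a 4-D (x, y, z, frame) dynamic volume from the phantom truth.

    Regional TACs are painted into the label map, each frame is blurred with
    the Gaussian PSF (partial-volume generation), and zero-mean Gaussian
    noise is added with per-frame SD = noise_cv * value * sqrt(5 min /
    duration), i.e. noise_cv is the coefficient of variation at 300-s
    frames. ``region_scale`` (label id -> factor) and ``global_scale`` apply
    session-level multiplicative jitter to the measured (post-blur) signal,
    so the factors act as exact within-subject CVs of regional outcomes.
    """
    from .pvc import fwhm_to_sigma

    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be nonnegative")
    rng = np.random.default_rng(seed)
    tacs = region_truth_tacs(phantom, schedule)
    data = phantom.labels.data
    max_label = int(data.max())
    lut = np.zeros((max_label + 1, schedule.n_frames), dtype=np.float64)
    for lid, info in phantom.labels.labels.items():
        lut[lid] = tacs[info.name].values

    scale_map = None
    if region_scale or global_scale != 1.0:
        factors = np.full(max_label + 1, global_scale, dtype=np.float64)
        if region_scale:
            for lid, f in region_scale.items():
                factors[lid] *= f
        scale_map = factors[data]

    sigma = fwhm_to_sigma(psf_fwhm_mm, phantom.labels.voxel_size_mm) if psf_fwhm_mm > 0 else None
    out = np.empty(data.shape + (schedule.n_frames,), dtype=np.float32)
    durations = schedule.durations
    for f in range(schedule.n_frames):
        frame = lut[data, f] * phantom.shell_field
        if sigma is not None:
            frame = gaussian_filter(frame, sigma=sigma, mode="nearest")
        if scale_map is not None:
            frame = frame * scale_map
        if noise_cv > 0:
            sd = noise_cv * np.sqrt(5.0 / durations[f]) * np.abs(frame)
            frame = frame + sd * rng.standard_normal(frame.shape)
        out[..., f] = frame.astype(np.float32)
    return out


@dataclass(frozen=True)
class RetestPerturbation:
    """Within-subject session-state variability.

    Each session (test and retest) draws independent multiplicative factors
    around the subject truth: one per region ~ Normal(1, CV) with the CV set
    by region class (reference/target/other vs extracerebral shell), plus a
    global scale factor (dose/weight analogue, cancels in ratios). The CVs
    are therefore within-subject per-session CVs, so the expected T-RT% of
    an outcome with session CV c is about 112.8 c.
    """

    reference_cv: float = 0.02
    target_cv: float = 0.05
    shell_cv: float = 0.12
    other_cv: float = 0.05
    global_scale_cv: float = 0.05

    def __post_init__(self) -> None:
        for name in ("reference_cv", "target_cv", "shell_cv", "other_cv", "global_scale_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def class_cv(self, role: str) -> float:
        return {
            "reference": self.reference_cv,
            "target": self.target_cv,
            "extracerebral": self.shell_cv,
        }.get(role, self.other_cv)


def make_trt_pair(
    phantom: Phantom,
    schedule: FrameSchedule,
    perturbation: RetestPerturbation = RetestPerturbation(),
    seed: int = 0,
    psf_fwhm_mm: float = 5.0,
    noise_cv: float = 0.03,
) -> tuple[np.ndarray, np.ndarray, tuple[ScanMeta, ScanMeta]]:
    """Test/retest 4-D pair sharing one truth and one label volume.

    Both sessions draw independent session-state jitter (per-region class
    factors plus a global scale) around the same subject truth, and each
    gets independent acquisition noise.
    """
    ss = np.random.SeedSequence(seed)
    s_test, s_retest, s_jitter = (int(s) for s in ss.generate_state(3, dtype=np.uint32) >> 1)
    rng = np.random.default_rng(s_jitter)

    def draw_session():
        scale = {}
        for lid, info in phantom.labels.labels.items():
            cv = perturbation.class_cv(info.role)
            scale[lid] = float(max(1.0 + cv * rng.standard_normal(), 0.05))
        g = float(max(1.0 + perturbation.global_scale_cv * rng.standard_normal(), 0.05))
        return scale, g

    scale_t, g_t = draw_session()
    scale_r, g_r = draw_session()
    test = simulate_dynamic(phantom, schedule, psf_fwhm_mm, noise_cv, seed=s_test,
                            region_scale=scale_t, global_scale=g_t)
    retest = simulate_dynamic(
        phantom, schedule, psf_fwhm_mm, noise_cv, seed=s_retest,
        region_scale=scale_r, global_scale=g_r,
    )
    sid = f"sub-{phantom.seed:08d}"
    meta_test = ScanMeta(sid, "test", phantom.spec.group)
    meta_retest = ScanMeta(sid, "retest", phantom.spec.group)
    return test, retest, (meta_test, meta_retest)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSubject:
    subject_id: str
    phantom: Phantom
    pair_seed: int
    has_retest: bool = True


@dataclass
class Cohort:
    """A simulated cohort; images are realized lazily, one subject at a time."""

    spec: PhantomSpec
    schedule: FrameSchedule
    subjects: list[CohortSubject]
    perturbation: RetestPerturbation
    psf_fwhm_mm: float
    noise_cv: float
    seed: int

    def realize(self, subject: CohortSubject):
        """(test, retest | None, (meta_test, meta_retest | None)) for one subject."""
        test, retest, metas = make_trt_pair(
            subject.phantom, self.schedule, self.perturbation,
            seed=subject.pair_seed, psf_fwhm_mm=self.psf_fwhm_mm,
            noise_cv=self.noise_cv,
        )
        meta_test = replace(metas[0], subject_id=subject.subject_id)
        if not subject.has_retest:
            return test, None, (meta_test, None)
        meta_retest = replace(metas[1], subject_id=subject.subject_id)
        return test, retest, (meta_test, meta_retest)


def simulate_cohort(
    n: int = 7,
    group: str = "oCN",
    seed: int = 0,
    schedule: FrameSchedule | None = None,
    spec: PhantomSpec | None = None,
    perturbation: RetestPerturbation = RetestPerturbation(),
    psf_fwhm_mm: float = 5.0,
    noise_cv: float = 0.03,
    retest: bool = True,
) -> Cohort:
    """Seeded cohort of subject phantoms with test/retest acquisitions."""
    from .tacs import mk6240_frame_schedule

    if n < 1:
        raise ValueError("cohort size must be at least 1")
    schedule = schedule or mk6240_frame_schedule()
    spec = spec or PhantomSpec(group=group)
    if spec.group != group:
        spec = replace(spec, group=group)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n, dtype=np.uint32) >> 1
    subjects = []
    for i in range(n):
        phantom = make_phantom(spec, int(seeds[2 * i]))
        subjects.append(
            CohortSubject(
                subject_id=f"{group}-{i + 1:02d}",
                phantom=phantom,
                pair_seed=int(seeds[2 * i + 1]),
                has_retest=retest,
            )
        )
    return Cohort(spec, schedule, subjects, perturbation, psf_fwhm_mm, noise_cv, int(seed))
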