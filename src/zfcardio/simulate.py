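"""Synthetic beating-heart simulator with closed-form ground truth.

A GFP-labelled larval ventricle is modelled as a filled ellipse whose full
long and short axes contract periodically:

    a(t) = a_ED * (1 - c_long  * s(t))
    b(t) = b_ED * (1 - c_short * s(t))

where ``s(t)`` is a raised-cosine pulse with period ``1/beat_freq``: s = 0 at
end diastole (cycle start) and s = 1 at peak systole.  With the default
``systole_fraction = 1`` the pulse spans the whole cycle, giving a smooth
trace with a single, well-defined ED/ES extremum per beat; smaller fractions
confine contraction to the leading part of the cycle and leave a diastolic
plateau.

Rendering rasterizes the ellipse (pixel-center inclusion), applies a Gaussian
PSF, background offset, additive Gaussian read noise and optional Poisson
shot noise.  Every rendered frame carries analytic ground-truth geometry, so
the whole measurement pipeline can be validated against known kinematics.

Cohorts emulate a pre-treatment screen: a healthy control group, a
calcium-channel-blocker ("model") group with depressed rate and contraction,
and treatment groups that restore a fraction ``rho`` of the deficit
(``rho = 0`` reproduces the model group, ``rho = 1`` the control group).
Per-fish biological variability is lognormal, mean 1, with a configurable
coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import CanvasOverflowError, ConfigurationError
from .indicators import (CardiacIndicators, compute_co, compute_ef,
                         compute_fac, compute_fs, compute_sv,
                         ventricular_volume)
from .segmentation import HeartGeometry, ImageSequence

CONTROL = "control"
MODEL = "model"


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeartSimParams:
    """Kinematic and imaging parameters of one simulated fish.

    Defaults describe a healthy 3-dpf larva: 150 bpm, a 100 x 60 um
    diastolic ventricle, 15% long-axis and 30% short-axis systolic
    shortening, imaged at 30 frames/s for 3 s at 0.5 um/px.
    """

    a_ed_um: float = 100.0          # full long axis at end diastole
    b_ed_um: float = 60.0           # full short axis at end diastole
    contraction_long: float = 0.15  # fractional long-axis shortening at ES
    contraction_short: float = 0.30
    beat_freq_hz: float = 2.5       # 150 bpm
    systole_fraction: float = 1.0   # fraction of the cycle spent contracting
    pixel_size_um: float = 0.5
    frame_interval_s: float = 1.0 / 30.0
    n_frames: int = 90
    psf_sigma_px: float = 1.0
    signal_level: float = 1000.0
    background_level: float = 100.0
    noise_sd: float = 0.0
    poisson_noise: bool = False
    rotation_rad: float = 0.0       # fixed in-plane rotation of the ellipse

    def validate(self) -> None:
        if not (self.a_ed_um >= self.b_ed_um > 0):
            raise ValueError("need a_ed_um >= b_ed_um > 0")
        for c in (self.contraction_long, self.contraction_short):
            if not (0 <= c < 1):
                raise ValueError("contractions must lie in [0, 1)")
        if self.beat_freq_hz <= 0:
            raise ValueError("beat_freq_hz must be positive")
        if not (0 < self.systole_fraction <= 1):
            raise ValueError("systole_fraction must lie in (0, 1]")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration fields must be positive")
        if self.n_frames < 2:
            raise ValueError("need n_frames >= 2")
        if self.signal_level <= self.background_level:
            raise ValueError("signal_level must exceed background_level")


@dataclass(frozen=True)
class GroupEffectSpec:
    """How a cohort group perturbs the control kinematics.

    Either explicit multipliers on beat frequency and contraction amplitudes,
    or a recovery fraction ``rho`` interpolating linearly between the model
    group (rho=0) and control (rho=1).
    """

    hr_multiplier: float = 1.0
    contraction_multiplier: float = 1.0
    recovery: float | None = None

    def validate(self) -> None:
        if self.hr_multiplier <= 0 or self.contraction_multiplier <= 0:
            raise ValueError("effect multipliers must be positive")
        if self.recovery is not None and not (0 <= self.recovery <= 1):
            raise ValueError("recovery must lie in [0, 1]")


#: Default insult: verapamil-like depression of rate and contractility.
DEFAULT_MODEL_EFFECT = GroupEffectSpec(hr_multiplier=0.6,
                                       contraction_multiplier=0.4)


@dataclass
class CohortSpec:
    """Design of a simulated screen: groups, group size, seed and jitter."""

    n_per_group: int = 10
    groups: Mapping[str, GroupEffectSpec] = field(default_factory=lambda: {
        CONTROL: GroupEffectSpec(),
        MODEL: DEFAULT_MODEL_EFFECT,
    })
    seed: int = 0
    inter_fish_cv: float = 0.05

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.inter_fish_cv < 0:
            raise ValueError("inter_fish_cv must be >= 0")
        if CONTROL not in self.groups or MODEL not in self.groups:
            raise ConfigurationError(
                "cohort groups must include 'control' and 'model'")
        for effect in self.groups.values():
            effect.validate()


@dataclass
class SimulatedFish:
    """One rendered fish with its ground truth."""

    fish_id: str
    group: str
    params: HeartSimParams
    sequence: ImageSequence
    truth_geometry: list[HeartGeometry]
    truth: CardiacIndicators


# ---------------------------------------------------------------------------
# ground-truth kinematics
# ---------------------------------------------------------------------------

def contraction_pulse(t: np.ndarray | float, beat_freq_hz: float,
                      systole_fraction: float = 1.0) -> np.ndarray:
    """The periodic pulse s(t): 0 at end diastole, 1 at peak systole."""
    phase = np.mod(np.asarray(t, dtype=float) * beat_freq_hz, 1.0)
    inside = phase < systole_fraction
    s = np.where(inside,
                 0.5 * (1.0 - np.cos(2.0 * np.pi * phase / systole_fraction)),
                 0.0)
    return s


def axis_waveform(params: HeartSimParams, t: np.ndarray | float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Exact long/short axis lengths (um) at time(s) ``t`` (seconds)."""
    s = contraction_pulse(t, params.beat_freq_hz, params.systole_fraction)
    a = params.a_ed_um * (1.0 - params.contraction_long * s)
    b = params.b_ed_um * (1.0 - params.contraction_short * s)
    return a, b


def expected_indicators(params: HeartSimParams) -> CardiacIndicators:
    """Closed-form indicator panel implied by the kinematic parameters.

    Uses exactly the same formulas as the measurement pipeline, applied to
    the analytic diastolic and peak-systolic axes; depends only on the
    kinematic fields, never on imaging or noise settings.  Serves as the
    oracle in recovery tests.
    """
    a_ed, b_ed = params.a_ed_um, params.b_ed_um
    a_es = a_ed * (1.0 - params.contraction_long)
    b_es = b_ed * (1.0 - params.contraction_short)

    hr = 60.0 * params.beat_freq_hz
    eda = math.pi * (a_ed / 2.0) * (b_ed / 2.0)
    esa = math.pi * (a_es / 2.0) * (b_es / 2.0)
    edv = ventricular_volume(a_ed, b_ed)
    esv = ventricular_volume(a_es, b_es)
    sv = compute_sv(edv, esv)
    return CardiacIndicators(
        hr_bpm=hr,
        fac=compute_fac(eda, esa),
        fs=compute_fs(b_ed, b_es),
        edv_um3=edv,
        esv_um3=esv,
        sv_um3=sv,
        ef=compute_ef(sv, edv),
        co_um3_min=compute_co(sv, hr),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _canvas_shape(params: HeartSimParams) -> tuple[int, int]:
    """Smallest canvas holding the rotated diastolic ellipse plus margin."""
    half_a = params.a_ed_um / 2.0 / params.pixel_size_um
    half_b = params.b_ed_um / 2.0 / params.pixel_size_um
    cos_t, sin_t = abs(math.cos(params.rotation_rad)), abs(math.sin(params.rotation_rad))
    half_x = math.hypot(half_a * cos_t, half_b * sin_t)
    half_y = math.hypot(half_a * sin_t, half_b * cos_t)
    margin = math.ceil(4.0 * params.psf_sigma_px) + 4
    return (2 * (math.ceil(half_y) + margin), 2 * (math.ceil(half_x) + margin))


def _rasterize_ellipse(shape: tuple[int, int], a_um: float, b_um: float,
                       pixel_size_um: float, rotation_rad: float) -> np.ndarray:
    """Boolean mask of the centred ellipse via pixel-center inclusion."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    x = (xx - cx) * pixel_size_um
    y = (yy - cy) * pixel_size_um
    cos_t, sin_t = math.cos(rotation_rad), math.sin(rotation_rad)
    u = x * cos_t + y * sin_t       # along the long axis
    v = -x * sin_t + y * cos_t
    return (u / (a_um / 2.0)) ** 2 + (v / (b_um / 2.0)) ** 2 <= 1.0


def render_sequence(params: HeartSimParams, seed: int = 0,
                    shape: tuple[int, int] | None = None,
                    fish_id: str = "sim"
                    ) -> tuple[ImageSequence, list[HeartGeometry]]:
    """Render a beating-heart stack and its analytic per-frame ground truth.

    Each frame samples the axis waveform at the frame's midpoint time
    ``(i + 0.5) * frame_interval``.  Identical ``(params, seed)`` give
    bit-identical stacks.  Ground truth records the exact ellipse area
    ``pi * a * b / 4`` and axes per frame.

    Raises :class:`CanvasOverflowError` if an explicit ``shape`` cannot hold
    the diastolic ellipse plus the PSF margin.
    """
    params.validate()
    needed = _canvas_shape(params)
    if shape is None:
        shape = needed
    elif shape[0] < needed[0] or shape[1] < needed[1]:
        raise CanvasOverflowError(
            f"canvas {shape} cannot hold the diastolic ellipse "
            f"(needs at least {needed})")

    rng = np.random.default_rng(seed)
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    frames = np.empty((params.n_frames, h, w), dtype=np.uint16)
    truth: list[HeartGeometry] = []

    times = (np.arange(params.n_frames) + 0.5) * params.frame_interval_s
    a_t, b_t = axis_waveform(params, times)

    for i in range(params.n_frames):
        mask = _rasterize_ellipse(shape, a_t[i], b_t[i],
                                  params.pixel_size_um, params.rotation_rad)
        img = np.where(mask, params.signal_level,
                       params.background_level).astype(float)
        if params.psf_sigma_px > 0:
            img = gaussian_filter(img, params.psf_sigma_px)
        if params.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        frames[i] = np.clip(np.rint(img), 0, np.iinfo(np.uint16).max)

        truth.append(HeartGeometry(
            frame_index=i,
            area_um2=math.pi * a_t[i] * b_t[i] / 4.0,
            centroid_xy_px=(cx, cy),
            long_axis_um=float(a_t[i]),
            short_axis_um=float(b_t[i]),
            orientation_rad=params.rotation_rad,
            valid=True,
        ))

    seq = ImageSequence(frames=frames, pixel_size_um=params.pixel_size_um,
                        frame_interval_s=params.frame_interval_s,
                        fish_id=fish_id)
    return seq, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def effective_params(base: HeartSimParams, effect: GroupEffectSpec,
                     model_effect: GroupEffectSpec | None = None
                     ) -> HeartSimParams:
    """Apply a group effect to the control kinematics.

    Recovery-style effects need the model group's effect to interpolate
    against; ``rho`` moves beat frequency and both contraction amplitudes
    linearly from the model values (rho=0) back to control (rho=1).
    """
    effect.validate()
    if effect.recovery is None:
        hr_mult, c_mult = effect.hr_multiplier, effect.contraction_multiplier
    else:
        if model_effect is None:
            raise ConfigurationError(
                "a recovery-type group needs the model group's effect")
        rho = effect.recovery
        hr_mult = model_effect.hr_multiplier + rho * (1.0 - model_effect.hr_multiplier)
        c_mult = (model_effect.contraction_multiplier
                  + rho * (1.0 - model_effect.contraction_multiplier))
    return replace(
        base,
        beat_freq_hz=base.beat_freq_hz * hr_mult,
        contraction_long=min(base.contraction_long * c_mult, 0.95),
        contraction_short=min(base.contraction_short * c_mult, 0.95),
    )


def _jitter_params(params: HeartSimParams, cv: float,
                   rng: np.random.Generator) -> HeartSimParams:
    """Lognormal per-fish jitter (mean 1, coefficient of variation ``cv``)
    on beat frequency, diastolic axes and contraction amplitudes."""
    if cv <= 0:
        return params
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    mu = -0.5 * sigma * sigma  # mean-one lognormal
    f = rng.lognormal(mu, sigma, size=5)
    a_ed = params.a_ed_um * f[1]
    b_ed = min(params.b_ed_um * f[2], a_ed)  # keep the axis ordering
    return replace(
        params,
        beat_freq_hz=params.beat_freq_hz * f[0],
        a_ed_um=a_ed,
        b_ed_um=b_ed,
        contraction_long=min(params.contraction_long * f[3], 0.95),
        contraction_short=min(params.contraction_short * f[4], 0.95),
    )


def generate_cohort(spec: CohortSpec,
                    base: HeartSimParams | None = None) -> list[SimulatedFish]:
    """Render a full cohort with per-fish ground truth.

    Group order follows the cohort design's mapping; fish are numbered
    globally so a
    fish's random stream depends only on (seed, fish index) and the whole
    cohort is reproducible.
    """
    base = base or HeartSimParams()
    spec.validate()
    base.validate()
    model_effect = spec.groups[MODEL]

    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(len(spec.groups) * spec.n_per_group)

    fishes: list[SimulatedFish] = []
    index = 0
    for group, effect in spec.groups.items():
        group_params = effective_params(base, effect, model_effect=model_effect)
        for k in range(spec.n_per_group):
            stream = streams[index]
            jitter_rng = np.random.default_rng(stream)
            fish_params = _jitter_params(group_params, spec.inter_fish_cv,
                                         jitter_rng)
            render_seed = int(stream.generate_state(1)[0] % (2 ** 31))
            fish_id = f"{group}_{k:03d}"
            seq, truth_geom = render_sequence(fish_params, seed=render_seed,
                                              fish_id=fish_id)
            fishes.append(SimulatedFish(
                fish_id=fish_id, group=group, params=fish_params,
                sequence=seq, truth_geometry=truth_geom,
                truth=expected_indicators(fish_params)))
            index += 1
    return fishes


def cohort_manifest(fishes: list[SimulatedFish],
                    paths: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Manifest table: id, group, calibration, optional file path."""
    rows = []
    for fish in fishes:
        rows.append({
            "fish_id": fish.fish_id,
            "group": fish.group,
            "path": (paths or {}).get(fish.fish_id, ""),
            "pixel_size_um": fish.params.pixel_size_um,
            "frame_interval_s": fish.params.frame_interval_s,
        })
    return pd.DataFrame(rows)


def cohort_ground_truth(fishes: list[SimulatedFish]) -> pd.DataFrame:
    """Ground-truth indicator table, one row per fish."""
    rows = []
    for fish in fishes:
        row = {"fish_id": fish.fish_id, "group": fish.group}
        row.update(fish.truth.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(fishes: list[SimulatedFish], outdir: str | Path
                 ) -> tuple[Path, Path]:
    """Write per-fish TIFF stacks plus manifest and ground-truth CSVs.

    Returns the manifest and ground-truth CSV paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for fish in fishes:
        tiff = outdir / f"{fish.fish_id}.tif"
        fish.sequence.to_tiff(tiff)
        paths[fish.fish_id] = tiff.name
    manifest_path = outdir / "manifest.csv"
    truth_path = outdir / "ground_truth.csv"
    cohort_manifest(fishes, paths).to_csv(manifest_path, index=False)
    cohort_ground_truth(fishes).to_csv(truth_path, index=False)
    return manifest_path, truth_path
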