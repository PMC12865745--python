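"""Synthetic dual-contrast fMRI phantom.

Generates BOLD and interleaved diffusion-weighted 4-D series with known
ground truth, embodying the three mechanisms that shape a diffusion-fMRI
experiment:

* **multiplicative BOLD** — a T2/T2*-like factor ``(1 + a_v * r_v(t))``
  scaling the whole signal, which cancels in an ADC computed as a ratio of
  two diffusion-weighted images;
* **diffusivity modulation** — an activity-locked change of the tissue
  diffusivity ``D(t) = d0 * (1 + a_d * r_d(t))``; a *negative* ``a_d``
  (ADC decrease) encodes excitatory activity;
* **IVIM perfusion contamination** — a biexponential perfusion compartment
  with fraction ``f(t) = f0 * (1 + a_f * r_f(t))`` and pseudo-diffusivity
  ``d_star``, the mechanism behind residual vascular (positive) ADC
  responses at the lower b-value.

The voxel signal model is

``S(b, t) = s0 * (1 + a_v*r_v(t)) * [(1-f(t))*exp(-b*D(t)) + f(t)*exp(-b*d_star)]``

with each ``r_x`` a unit response waveform (peak value 1) derived from the
stimulation paradigm.  Magnitude-MRI (Rician) noise and a slow
multiplicative sinusoidal drift are applied on top.

Presets encode, as generator ground truth, the response polarities and peak
amplitudes observed in the rat visual system at 9.4 T: an excitatory
(negative-ADC) medial superior colliculus, a vascularly contaminated
(positive-ADC) lateral superior colliculus, and a BOLD-silent but
ADC-responsive corpus callosum, at both 1-Hz and 25-Hz flash frequencies.
Amplitudes are calibrated by scalar root-finding on the noise-free
biexponential ADC change so that the downstream pipeline recovers the
configured peak exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .paradigm import AcquisitionScheme, StimulationParadigm, build_stimulus_timecourse

__all__ = [
    "RegionLabelMap",
    "ResponseShape",
    "TissueParams",
    "VolumeSeries",
    "GroundTruth",
    "make_label_phantom",
    "signal_model",
    "simulate_series",
    "preset",
    "PRESET_NAMES",
    "DEFAULT_REGION_NAMES",
]

DEFAULT_REGION_NAMES = ("mSC", "lSC", "DLGn", "V1", "CC", "Hipp", "RSC")


# --------------------------------------------------------------------------
# container types
# --------------------------------------------------------------------------

@dataclass
class RegionLabelMap:
    """3-D integer label map with a name for every nonzero label.

    Label 0 is background.  Stands in for an atlas-based segmentation of the
    visual-pathway regions (superior colliculus subdivisions, geniculate
    nucleus, visual cortex, corpus callosum, hippocampus, retrosplenial
    cortex).
    """

    labels: np.ndarray
    names: dict[int, str]
    voxel_size_mm: tuple[float, float, float] = (0.38, 0.38, 1.5)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without a name: {sorted(missing)}")

    def mask(self, name: str) -> np.ndarray:
        for lab, nm in self.names.items():
            if nm == name:
                return self.labels == lab
        raise KeyError(f"no region named {name!r}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([*self.voxel_size_mm, 1.0])
        return aff


@dataclass(frozen=True)
class ResponseShape:
    """Parametric response waveform locked to the stimulation blocks.

    ``kind="block"``: an on/off response smoothed by a first-order
    exponential with time constant ``rise_tau_s`` (rise during stimulation,
    decay during rest).

    ``kind="double_peak"``: Gaussian peaks of width ``peak_width_s`` at
    block onset and offset over a plateau — the "novelty peak" shape seen
    at high flash frequencies.  ``onset_peak_pct``/``offset_peak_pct``/
    ``plateau_pct`` set the relative heights; the plateau may be negative
    (a response dipping below baseline between the peaks).

    ``amplitude_pct`` is the signed peak fractional change times 100.  The
    waveform delivered to the signal model is normalized to unit absolute
    peak, so the peak modulation equals ``amplitude_pct / 100`` exactly.
    """

    kind: str = "block"
    amplitude_pct: float = 0.0
    onset_peak_pct: float | None = None
    offset_peak_pct: float | None = None
    plateau_pct: float | None = None
    peak_width_s: float = 2.0
    rise_tau_s: float = 2.5

    def __post_init__(self) -> None:
        if self.kind not in ("block", "double_peak"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.kind == "double_peak":
            on = self.onset_peak_pct if self.onset_peak_pct is not None else self.amplitude_pct
            plat = self.plateau_pct if self.plateau_pct is not None else 0.0
            if not (-abs(on) <= plat <= abs(on) or on == 0):
                raise ValueError("double_peak plateau must lie between -|onset| and onset")

    @property
    def amplitude(self) -> float:
        """Signed fractional peak amplitude (``amplitude_pct / 100``)."""
        return self.amplitude_pct / 100.0

    def unit_waveform(self, paradigm: StimulationParadigm, tr_s: float) -> np.ndarray:
        """Sampled response waveform normalized to unit absolute peak.

        Returns the all-zero waveform when ``amplitude_pct`` is 0.
        """
        n = round(paradigm.total_duration_s / tr_s)
        t = np.arange(n) * tr_s
        if self.amplitude_pct == 0.0:
            return np.zeros(n)
        if self.kind == "block":
            r = _exp_smoothed_boxcar(paradigm, tr_s, self.rise_tau_s)
        else:
            on = self.onset_peak_pct if self.onset_peak_pct is not None else self.amplitude_pct
            off = self.offset_peak_pct if self.offset_peak_pct is not None else 0.8 * on
            plat = self.plateau_pct if self.plateau_pct is not None else 0.4 * on
            box = _exp_smoothed_boxcar(paradigm, tr_s, self.rise_tau_s)
            r = plat * box
            w = self.peak_width_s
            for onset in paradigm.onset_times_s():
                r = r + (on - plat) * np.exp(-0.5 * ((t - onset - w) / w) ** 2)
                r = r + off * np.exp(
                    -0.5 * ((t - onset - paradigm.stim_dur_s - w) / w) ** 2
                )
            # express relative to the nominal onset-peak height so the
            # normalized peak is 1 regardless of plateau/offset settings
            r = r / on
        peak = np.max(np.abs(r))
        if peak == 0:
            return r
        return r / peak


def _exp_smoothed_boxcar(
    paradigm: StimulationParadigm, tr_s: float, tau_s: float
) -> np.ndarray:
    """Stimulus boxcar passed through a first-order low-pass (time const tau)."""
    # simulate on a fine grid so the smoothing is sampling-independent
    dt = min(tr_s, 0.1)
    n_fine = round(paradigm.total_duration_s / dt)
    t_fine = np.arange(n_fine) * dt
    box = np.zeros(n_fine)
    for onset in paradigm.onset_times_s():
        box[(t_fine >= onset) & (t_fine < onset + paradigm.stim_dur_s)] = 1.0
    if tau_s <= 0:
        r_fine = box
    else:
        from scipy.signal import lfilter

        a = math.exp(-dt / tau_s)
        r_fine = lfilter([1.0 - a], [1.0, -a], box)
    # sample at volume start times
    idx = np.round(np.arange(round(paradigm.total_duration_s / tr_s)) * tr_s / dt).astype(int)
    return r_fine[np.clip(idx, 0, n_fine - 1)]


@dataclass(frozen=True)
class TissueParams:
    """Per-region tissue and response parameters of the signal model."""

    s0: float = 1000.0
    d0: float = 0.7e-3           # baseline diffusivity, mm^2/s
    f0: float = 0.0              # perfusion (IVIM) fraction
    d_star: float = 1.0e-2       # pseudo-diffusivity, mm^2/s
    beta_bold: ResponseShape = field(default_factory=ResponseShape)
    beta_d: ResponseShape = field(default_factory=ResponseShape)
    beta_f: ResponseShape = field(default_factory=ResponseShape)
    noise_sigma: float = 1.5     # same units as s0 (default image SNR ~670)
    drift_amp_pct: float = 0.5
    drift_period_s: float = 300.0
    noise_model: str = "rician"  # "rician" (magnitude MRI) or "gaussian"

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if not (0 <= self.f0 < 1):
            raise ValueError("f0 must be in [0, 1)")
        if not (self.d_star > self.d0 > 0):
            raise ValueError("need d_star > d0 > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class VolumeSeries:
    """A 4-D functional series (x, y, z, t) with acquisition metadata."""

    data: np.ndarray
    tr_s: float
    contrast: str
    bvals: np.ndarray | None = None
    affine: np.ndarray | None = None
    source_volume_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.affine is None:
            self.affine = np.eye(4)
        if self.bvals is not None:
            self.bvals = np.asarray(self.bvals, dtype=float)
            if len(self.bvals) != self.n_volumes:
                raise ValueError(
                    f"b-value vector length {len(self.bvals)} != "
                    f"{self.n_volumes} volumes"
                )
        if self.contrast == "dw_interleaved":
            if self.bvals is None:
                raise ValueError("dw_interleaved series requires a b-value vector")
            _check_alternating(self.bvals)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def _check_alternating(bvals: np.ndarray) -> None:
    vals = np.unique(bvals)
    if len(vals) != 2:
        raise ValueError(f"dw series must contain exactly two b-values, got {vals}")
    for i in range(1, len(bvals)):
        if bvals[i] == bvals[i - 1]:
            raise ValueError(f"b-value vector does not alternate at index {i}")


@dataclass
class GroundTruth:
    """Noise-free per-region time courses and planted voxel polarities."""

    region_waveforms: dict[str, dict[str, np.ndarray]]  # name -> {d, v, f}
    adc_peak_change: dict[str, float]                   # name -> fractional ADC change
    polarity: np.ndarray                                # 3-D int8: -1, 0, +1
    seed: int


# --------------------------------------------------------------------------
# label phantom
# --------------------------------------------------------------------------

_DEFAULT_CENTERS = {
    # (center x, y, z fractions of grid, radius in voxels)
    "mSC": ((0.34, 0.30), 3.4),
    "lSC": ((0.66, 0.30), 3.4),
    "DLGn": ((0.28, 0.62), 3.0),
    "V1": ((0.72, 0.62), 3.4),
    "CC": ((0.50, 0.50), 2.9),
    "Hipp": ((0.30, 0.84), 3.0),
    "RSC": ((0.70, 0.86), 3.0),
}


def make_label_phantom(
    grid_shape: tuple[int, int, int] = (32, 32, 4),
    region_spec: str | dict = "default",
    seed: int = 0,
) -> RegionLabelMap:
    """Place ellipsoidal region blobs on a regular grid.

    ``region_spec`` is either ``"default"`` (seven visual-pathway regions on
    the grid) or a mapping ``name -> ((cx, cy, cz), radius_voxels)`` with
    voxel-unit centers.  Overlapping regions raise a ``ValueError`` naming
    the collision.  Deterministic for a fixed seed (the seed perturbs the
    default centers by at most half a voxel).
    """
    nx, ny, nz = grid_shape
    if nx < 16 or ny < 16 or nz < 2:
        raise ValueError("grid must be at least 16 x 16 x 2")
    rng = np.random.default_rng(seed)
    if region_spec == "default":
        # radii are laid out for the nominal 32 x 32 grid; scale with the grid
        scale = min(nx, ny) / 32.0
        spec = {}
        for name, ((fx, fy), rad) in _DEFAULT_CENTERS.items():
            jitter = rng.uniform(-0.5, 0.5, size=2) * scale
            spec[name] = ((fx * nx + jitter[0], fy * ny + jitter[1], nz / 2.0), rad * scale)
    else:
        spec = dict(region_spec)

    labels = np.zeros(grid_shape, dtype=np.int16)
    names: dict[int, str] = {}
    xx, yy, zz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    for i, (name, ((cx, cy, cz), rad)) in enumerate(spec.items(), start=1):
        # flatten in z so thin slabs still get full-extent blobs
        dz_scale = max(1.0, rad / max(nz / 2.0, 1.0))
        dist2 = (xx - cx) ** 2 + (yy - cy) ** 2 + ((zz - cz) * dz_scale) ** 2
        blob = dist2 <= rad**2
        collision = blob & (labels > 0)
        if np.any(collision):
            other = names[int(labels[collision][0])]
            raise ValueError(f"region {name!r} overlaps region {other!r}")
        if blob.sum() < 8:
            raise ValueError(f"region {name!r} has only {int(blob.sum())} voxels (< 8)")
        labels[blob] = i
        names[i] = name
    return RegionLabelMap(labels=labels, names=names)


# --------------------------------------------------------------------------
# signal model
# --------------------------------------------------------------------------

def signal_model(
    b: float,
    tissue: TissueParams,
    r_v: float,
    r_d: float,
    r_f: float,
) -> float:
    """Scalar biexponential IVIM signal with activity modulation.

    ``r_v``, ``r_d``, ``r_f`` are the unit response waveforms evaluated at
    one time point (peak value 1); the fractional amplitudes come from the
    tissue's :class:`ResponseShape` settings.
    """
    if b < 0:
        raise ValueError("b must be >= 0")
    a_v = tissue.beta_bold.amplitude
    a_d = tissue.beta_d.amplitude
    a_f = tissue.beta_f.amplitude
    d_t = tissue.d0 * (1.0 + a_d * r_d)
    f_t = tissue.f0 * (1.0 + a_f * r_f)
    if f_t >= 1.0:
        raise ValueError(f"perfusion fraction {f_t} >= 1 after modulation")
    f_t = max(f_t, 0.0)
    return (
        tissue.s0
        * (1.0 + a_v * r_v)
        * ((1.0 - f_t) * math.exp(-b * d_t) + f_t * math.exp(-b * tissue.d_star))
    )


def _adc_from_model(
    tissue: TissueParams, b_low: float, b_high: float, r_d: float, r_f: float
) -> float:
    """Noise-free ADC implied by the signal model at one time point."""
    s_lo = signal_model(b_low, tissue, 0.0, r_d, r_f)
    s_hi = signal_model(b_high, tissue, 0.0, r_d, r_f)
    return math.log(s_lo / s_hi) / (b_high - b_low)


def adc_peak_fractional_change(
    tissue: TissueParams, b_low: float = 200.0, b_high: float = 1000.0
) -> float:
    """Fractional change of the model ADC at response peak vs. baseline."""
    base = _adc_from_model(tissue, b_low, b_high, 0.0, 0.0)
    peak = _adc_from_model(tissue, b_low, b_high, 1.0, 1.0)
    return peak / base - 1.0


def _epoch_peak(course: np.ndarray, paradigm: StimulationParadigm, tr_s: float) -> float:
    """Signed peak of the epoch-averaged fractional change of a 1-D course.

    Applies the same per-epoch first-six-sample baseline normalization the
    analysis uses, so calibration targets exactly what the pipeline reports.
    """
    from .paradigm import epoch_windows

    windows = epoch_windows(paradigm, tr_s, pre_onset_samples=6)
    win_len = windows[0][1] - windows[0][0]
    acc = np.zeros(win_len)
    for start, stop in windows:
        seg = course[start:stop]
        acc += seg / seg[:6].mean() - 1.0
    mean = acc / len(windows)
    return float(mean[np.argmax(np.abs(mean))])


def _measured_adc_peak(
    tissue: TissueParams,
    paradigm: StimulationParadigm,
    b_low: float = 200.0,
    b_high: float = 1000.0,
) -> float:
    """Noise-free epoch-averaged peak ADC fractional change of the model."""
    tr = 2.0  # native ADC sampling under the default 1-s interleaved scheme
    r_d = tissue.beta_d.unit_waveform(paradigm, tr)
    r_f = tissue.beta_f.unit_waveform(paradigm, tr)
    d_t = tissue.d0 * (1.0 + tissue.beta_d.amplitude * r_d)
    f_t = np.clip(tissue.f0 * (1.0 + tissue.beta_f.amplitude * r_f), 0.0, None)
    if np.any(f_t >= 1.0):
        raise ValueError("perfusion fraction >= 1 after modulation")
    s_lo = (1.0 - f_t) * np.exp(-b_low * d_t) + f_t * np.exp(-b_low * tissue.d_star)
    s_hi = (1.0 - f_t) * np.exp(-b_high * d_t) + f_t * np.exp(-b_high * tissue.d_star)
    adc = np.log(s_lo / s_hi) / (b_high - b_low)
    return _epoch_peak(adc, paradigm, tr)


def _measured_bold_peak(tissue: TissueParams, paradigm: StimulationParadigm) -> float:
    """Noise-free epoch-averaged peak fractional BOLD change of the model."""
    r_v = tissue.beta_bold.unit_waveform(paradigm, 1.0)
    course = 1.0 + tissue.beta_bold.amplitude * r_v
    return _epoch_peak(course, paradigm, 1.0)


def _calibrate_bold(
    tissue: TissueParams, target_frac: float, paradigm: StimulationParadigm
) -> TissueParams:
    """Set the BOLD amplitude so the pipeline peak equals ``target_frac``."""
    if target_frac == 0.0:
        return replace(tissue, beta_bold=replace(tissue.beta_bold, amplitude_pct=0.0))

    def gap(a_pct: float) -> float:
        t = replace(tissue, beta_bold=replace(tissue.beta_bold, amplitude_pct=a_pct))
        return _measured_bold_peak(t, paradigm) - target_frac

    a_pct = brentq(gap, -40.0, 40.0, xtol=1e-12)
    return replace(tissue, beta_bold=replace(tissue.beta_bold, amplitude_pct=a_pct))


def _calibrate_a_d(
    tissue: TissueParams, target_frac: float, paradigm: StimulationParadigm
) -> TissueParams:
    """Set beta_d.amplitude_pct so the pipeline ADC peak equals ``target_frac``."""

    def gap(a_pct: float) -> float:
        t = replace(tissue, beta_d=replace(tissue.beta_d, amplitude_pct=a_pct))
        return _measured_adc_peak(t, paradigm) - target_frac

    a_pct = brentq(gap, -50.0, 50.0, xtol=1e-12)
    return replace(tissue, beta_d=replace(tissue.beta_d, amplitude_pct=a_pct))


def _calibrate_a_f(
    tissue: TissueParams, target_frac: float, paradigm: StimulationParadigm
) -> TissueParams:
    """Set beta_f.amplitude_pct so the pipeline ADC peak equals ``target_frac``."""
    if tissue.f0 <= 0:
        raise ValueError("f0 must be positive to calibrate a perfusion response")
    hi = 0.99 * (1.0 / tissue.f0 - 1.0) * 100.0  # keep f(t) < 1

    def gap(a_pct: float) -> float:
        t = replace(tissue, beta_f=replace(tissue.beta_f, amplitude_pct=a_pct))
        return _measured_adc_peak(t, paradigm) - target_frac

    a_pct = brentq(gap, -99.0, hi, xtol=1e-12)
    return replace(tissue, beta_f=replace(tissue.beta_f, amplitude_pct=a_pct))


# --------------------------------------------------------------------------
# series simulation
# --------------------------------------------------------------------------

def simulate_series(
    label_map: RegionLabelMap,
    tissue_by_region: dict[str, TissueParams],
    paradigm: StimulationParadigm,
    scheme: AcquisitionScheme,
    seed: int = 0,
    background: TissueParams | None = None,
) -> tuple[VolumeSeries, GroundTruth]:
    """Simulate one functional series from per-region tissue parameters.

    The BOLD contrast samples the model at ``b = 0`` every TR; the
    ``dw_interleaved`` contrast alternates ``b_low``/``b_high`` volume by
    volume.  Rician noise (two independent Gaussian draws of width
    ``noise_sigma``) and a multiplicative sinusoidal drift are applied per
    voxel.  Returns the series together with the noise-free ground truth.
    """
    region_names = [label_map.names[lab] for lab in sorted(label_map.names)]
    missing = [nm for nm in region_names if nm not in tissue_by_region]
    if missing:
        raise ValueError(f"missing TissueParams for regions: {missing}")
    if background is None:
        any_t = next(iter(tissue_by_region.values()))
        background = TissueParams(
            s0=any_t.s0,
            d0=any_t.d0,
            noise_sigma=any_t.noise_sigma,
            drift_amp_pct=any_t.drift_amp_pct,
            drift_period_s=any_t.drift_period_s,
            noise_model=any_t.noise_model,
        )

    n_vol = round(paradigm.total_duration_s / scheme.tr_s)
    bvals = scheme.bval_vector(n_vol)
    t_axis = np.arange(n_vol) * scheme.tr_s
    shape3d = label_map.labels.shape
    rng = np.random.default_rng(seed)

    data = np.zeros((*shape3d, n_vol))
    region_waveforms: dict[str, dict[str, np.ndarray]] = {}
    adc_change: dict[str, float] = {}
    polarity = np.zeros(shape3d, dtype=np.int8)

    entries = [("background", background, label_map.labels == 0)]
    entries += [(nm, tissue_by_region[nm], label_map.mask(nm)) for nm in region_names]

    # For the interleaved contrast the physiological waveforms are sampled at
    # pair resolution (2 TR) and held constant across the two volumes of each
    # b-value pair: the two images of a pair then share one tissue state, so
    # the multiplicative (BOLD/T2) factor cancels exactly in the ADC ratio and
    # the planted D(t) is recovered sample for sample.  This idealizes away
    # the residual T2-transient leakage of real alternating acquisitions.
    paired = scheme.contrast == "dw_interleaved"
    wave_tr = 2 * scheme.tr_s if paired else scheme.tr_s

    def _waveform(shape: ResponseShape) -> np.ndarray:
        r = shape.unit_waveform(paradigm, wave_tr)
        if paired:
            r = np.repeat(r, 2)[:n_vol]
        return r

    for name, tissue, mask in entries:
        if not np.any(mask):
            continue
        r_v = _waveform(tissue.beta_bold)
        r_d = _waveform(tissue.beta_d)
        r_f = _waveform(tissue.beta_f)
        a_v = tissue.beta_bold.amplitude
        a_d = tissue.beta_d.amplitude
        a_f = tissue.beta_f.amplitude
        d_t = tissue.d0 * (1.0 + a_d * r_d)
        f_t = tissue.f0 * (1.0 + a_f * r_f)
        if np.any(f_t >= 1.0):
            raise ValueError(f"region {name!r}: perfusion fraction >= 1 after modulation")
        f_t = np.clip(f_t, 0.0, None)
        clean = (
            tissue.s0
            * (1.0 + a_v * r_v)
            * ((1.0 - f_t) * np.exp(-bvals * d_t) + f_t * np.exp(-bvals * tissue.d_star))
        )
        if tissue.drift_amp_pct != 0.0:
            phase = rng.uniform(0, 2 * np.pi)
            clean = clean * (
                1.0
                + tissue.drift_amp_pct / 100.0
                * np.sin(2 * np.pi * t_axis / tissue.drift_period_s + phase)
            )
        n_vox = int(mask.sum())
        if tissue.noise_sigma > 0:
            g1 = rng.normal(0.0, tissue.noise_sigma, size=(n_vox, n_vol))
            if tissue.noise_model == "rician":
                g2 = rng.normal(0.0, tissue.noise_sigma, size=(n_vox, n_vol))
                vox = np.sqrt((clean[None, :] + g1) ** 2 + g2**2)
            else:
                vox = clean[None, :] + g1
        else:
            vox = np.broadcast_to(clean, (n_vox, n_vol))
        data[mask] = vox

        region_waveforms[name] = {
            "d": tissue.d0 * (1.0 + a_d * r_d),
            "v": 1.0 + a_v * r_v,
            "f": f_t,
        }
        change = adc_peak_fractional_change(tissue, scheme.b_low, scheme.b_high)
        adc_change[name] = change
        if name != "background":
            if abs(change) > 1e-6:
                polarity[mask] = 1 if change > 0 else -1

    series = VolumeSeries(
        data=data,
        tr_s=scheme.tr_s,
        contrast=scheme.contrast,
        bvals=bvals if scheme.contrast == "dw_interleaved" else np.zeros(n_vol),
        affine=label_map.affine,
    )
    truth = GroundTruth(
        region_waveforms=region_waveforms,
        adc_peak_change=adc_change,
        polarity=polarity,
        seed=seed,
    )
    return series, truth


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

PRESET_NAMES = (
    "mSC_1Hz",
    "lSC_1Hz",
    "CC_1Hz",
    "mSC_25Hz",
    "lSC_25Hz",
    "CC_25Hz",
    "null",
)

# (BOLD peak %, ADC peak %, mechanism for the ADC response, BOLD shape kind)
_PRESET_TABLE = {
    "mSC_1Hz": (2.2, -0.5, "d", "block"),
    "lSC_1Hz": (1.5, +0.7, "f", "block"),
    "CC_1Hz": (0.0, -0.3, "d", "block"),
    "mSC_25Hz": (2.2, -0.2, "d", "double_peak"),
    "lSC_25Hz": (1.2, +0.6, "f", "double_peak"),
    "CC_25Hz": (0.0, -0.2, "d", "block"),
    "null": (0.0, 0.0, "d", "block"),
}


def preset(
    name: str,
    noise_sigma: float = 1.5,
    paradigm: StimulationParadigm | None = None,
) -> dict[str, TissueParams]:
    """Per-region tissue parameters reproducing the reported response signs
    and peak amplitudes for one stimulation condition.

    The named region carries the condition's responses; all other default
    regions are quiet tissue.  ``"null"`` plants no modulation anywhere.
    The ADC amplitude is delivered through diffusivity modulation
    (mechanism ``d``, the excitatory signature) or through the perfusion
    fraction (mechanism ``f``, vascular contamination), calibrated so the
    noise-free pipeline peak matches the configured value.
    """
    if name not in _PRESET_TABLE:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    bold_pct, adc_pct, mech, bold_kind = _PRESET_TABLE[name]
    if paradigm is None:
        paradigm = StimulationParadigm()

    quiet = TissueParams(noise_sigma=noise_sigma)
    params = {nm: quiet for nm in DEFAULT_REGION_NAMES}
    if name == "null":
        return params

    region = name.split("_")[0]
    bold_shape = ResponseShape(
        kind=bold_kind,
        amplitude_pct=bold_pct,
        # high-frequency "novelty" response: onset/offset peaks over a plateau;
        # fixing the peak heights keeps the waveform shape independent of the
        # calibrated amplitude
        onset_peak_pct=bold_pct if bold_kind == "double_peak" else None,
        offset_peak_pct=0.8 * bold_pct if bold_kind == "double_peak" else None,
        plateau_pct=0.4 * bold_pct if bold_kind == "double_peak" else None,
    )
    if mech == "f":
        tissue = TissueParams(
            f0=0.05,
            beta_bold=bold_shape,
            beta_f=ResponseShape(kind="block", amplitude_pct=1.0),
            noise_sigma=noise_sigma,
        )
        tissue = _calibrate_a_f(tissue, adc_pct / 100.0, paradigm)
    else:
        tissue = TissueParams(
            f0=0.0,
            beta_bold=bold_shape,
            beta_d=ResponseShape(kind="block", amplitude_pct=-1.0),
            noise_sigma=noise_sigma,
        )
        tissue = _calibrate_a_d(tissue, adc_pct / 100.0, paradigm)
    tissue = _calibrate_bold(tissue, bold_pct / 100.0, paradigm)
    params[region] = tissue
    return params
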