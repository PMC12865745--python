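"""Block-design stimulation paradigm and acquisition scheme.

The paradigm used throughout this package is a visual block design: an
initial rest period followed by ``n_epochs`` repetitions of a stimulation
block and a rest block.  All regressors (boxcar, FIR) and epoch windows are
derived from a :class:`StimulationParadigm`.

Time convention: sample ``i`` of a series with repetition time ``tr_s``
covers the half-open interval ``[i*tr_s, (i+1)*tr_s)``; a sample counts as
"stimulation" when its start time lies inside a stimulation block.  This is
the natural convention for trigger-locked acquisitions where each volume is
excited at its nominal start time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulationParadigm",
    "AcquisitionScheme",
    "total_duration",
    "build_stimulus_timecourse",
    "epoch_windows",
]


@dataclass(frozen=True)
class StimulationParadigm:
    """Timing of a block-stimulation paradigm.

    Parameters
    ----------
    initial_rest_s:
        Rest period before the first stimulation block, in seconds.
    stim_dur_s, rest_dur_s:
        Duration of the stimulation and rest blocks of each epoch (s).
    n_epochs:
        Number of stimulation+rest epochs.
    flash_freq_hz, flash_dur_ms:
        Flash frequency and single-flash duration of the visual stimulus.
        Metadata only: the regressors model whole blocks, not flashes.
    """

    initial_rest_s: float = 24.0
    stim_dur_s: float = 16.0
    rest_dur_s: float = 24.0
    n_epochs: int = 12
    flash_freq_hz: float = 1.0
    flash_dur_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.initial_rest_s <= 0 or self.stim_dur_s <= 0 or self.rest_dur_s <= 0:
            raise ValueError("all durations must be positive")
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be >= 0")

    @property
    def epoch_dur_s(self) -> float:
        return self.stim_dur_s + self.rest_dur_s

    @property
    def total_duration_s(self) -> float:
        return self.initial_rest_s + self.n_epochs * self.epoch_dur_s

    def onset_times_s(self) -> np.ndarray:
        """Start times of every stimulation block, in seconds."""
        return self.initial_rest_s + self.epoch_dur_s * np.arange(self.n_epochs)


@dataclass(frozen=True)
class AcquisitionScheme:
    """Acquisition parameters of one functional series.

    ``contrast`` is ``"bold"`` for a gradient-echo BOLD series (all volumes
    unweighted) or ``"dw_interleaved"`` for a diffusion-weighted series that
    strictly alternates between ``b_low`` and ``b_high``.  ``n_dummies``
    records discarded steady-state volumes for real acquisitions; the
    synthetic phantom emits post-dummy series directly.
    """

    tr_s: float = 1.0
    b_low: float = 200.0
    b_high: float = 1000.0
    interleave_order: str = "low_first"
    n_dummies: int = 12
    contrast: str = "dw_interleaved"

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not (0 <= self.b_low < self.b_high):
            raise ValueError("need 0 <= b_low < b_high")
        if self.n_dummies < 0:
            raise ValueError("n_dummies must be >= 0")
        if self.contrast not in ("bold", "dw_interleaved"):
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.interleave_order not in ("low_first", "high_first"):
            raise ValueError(f"unknown interleave_order {self.interleave_order!r}")

    def bval_vector(self, n_volumes: int) -> np.ndarray:
        """Per-volume b-values for ``n_volumes`` volumes of this scheme."""
        if self.contrast == "bold":
            return np.zeros(n_volumes)
        pair = (self.b_low, self.b_high) if self.interleave_order == "low_first" else (
            self.b_high, self.b_low)
        return np.asarray([pair[i % 2] for i in range(n_volumes)], dtype=float)


def total_duration(paradigm: StimulationParadigm) -> float:
    """Total paradigm duration in seconds."""
    return paradigm.total_duration_s


def _n_samples(paradigm: StimulationParadigm, tr_s: float) -> int:
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    n_float = paradigm.total_duration_s / tr_s
    n = round(n_float)
    residue = abs(n_float - n)
    if residue > 1e-9:
        raise ValueError(
            f"total duration {paradigm.total_duration_s} s is not divisible by "
            f"tr={tr_s} s (residue {residue * tr_s:.6g} s)"
        )
    return int(n)


def build_stimulus_timecourse(paradigm: StimulationParadigm, tr_s: float) -> np.ndarray:
    """Binary stimulus boxcar sampled at ``tr_s``.

    Sample ``i`` is 1 when its start time ``i*tr_s`` falls inside a
    stimulation block, else 0.
    """
    n = _n_samples(paradigm, tr_s)
    t = np.arange(n) * tr_s
    box = np.zeros(n)
    for onset in paradigm.onset_times_s():
        box[(t >= onset) & (t < onset + paradigm.stim_dur_s)] = 1.0
    return box


def epoch_windows(
    paradigm: StimulationParadigm, tr_s: float, pre_onset_samples: int = 6
) -> list[tuple[int, int]]:
    """Sample-index windows ``(start, stop)`` around each stimulus onset.

    Each window has fixed length ``epoch_dur_s / tr_s`` samples and begins
    ``pre_onset_samples`` samples before the stimulus onset, so the first
    ``pre_onset_samples`` samples of every window are pre-onset baseline.
    """
    if pre_onset_samples < 0:
        raise ValueError("pre_onset_samples must be >= 0")
    pre_s = pre_onset_samples * tr_s
    if pre_s > paradigm.initial_rest_s or pre_s > paradigm.rest_dur_s:
        raise ValueError(
            f"pre-onset span {pre_s} s exceeds initial rest "
            f"({paradigm.initial_rest_s} s) or inter-epoch rest ({paradigm.rest_dur_s} s)"
        )
    n_total = _n_samples(paradigm, tr_s)
    win_len = round(paradigm.epoch_dur_s / tr_s)
    windows = []
    for onset in paradigm.onset_times_s():
        start = round(onset / tr_s) - pre_onset_samples
        stop = start + win_len
        if start < 0 or stop > n_total:
            raise ValueError(f"epoch window [{start}, {stop}) overruns series of {n_total}")
        windows.append((start, stop))
    return windows
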