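"""Epoch-averaged response extraction, K-means classification, polarity.

The FIR omnibus test marks voxels as responsive without telling whether
the response is positive or negative.  This module extracts each
significant voxel's epoch-averaged fractional-change response, classifies
the responses with Euclidean time-series K-means (k-means++ seeding,
k = 10 by default), and pools clusters by the sign of their centroid mean
over the stimulation window — producing the positive/negative response
maps and the region-average response plots.

Baseline normalization follows the epoch convention: each epoch window is
divided by the mean of its first six samples (the pre-onset baseline at
the stream's native sampling) and 1 is subtracted, giving fractional
change; for ADC streams this difference-over-baseline is applied
identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .paradigm import StimulationParadigm, epoch_windows

__all__ = [
    "VoxelResponseSet",
    "ResponseClusterSet",
    "extract_voxel_responses",
    "kmeans_classify",
    "pool_by_polarity",
    "epoch_average_region",
    "epoch_average_voxelwise",
]

log = logging.getLogger(__name__)

_BASELINE_SAMPLES = 6


@dataclass
class VoxelResponseSet:
    """Epoch-averaged fractional-change responses, one row per voxel."""

    responses: np.ndarray          # (n_voxels, window_samples)
    provenance: pd.DataFrame       # subject, x, y, z per row
    tr_s: float
    stim_sample_idx: np.ndarray    # window samples during stimulation

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[0]


@dataclass
class ResponseClusterSet:
    """K-means centroids, assignments, and per-cluster polarity."""

    centroids: np.ndarray          # (k, window_samples)
    assignments: np.ndarray        # (n_voxels,)
    polarity: np.ndarray           # (k,) in {-1, 0, +1}; 0 = excluded tie
    response_set: VoxelResponseSet

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def _window_stim_samples(
    paradigm: StimulationParadigm, tr_s: float, pre_onset_samples: int
) -> np.ndarray:
    """Window sample indices whose start time falls in the stimulation block."""
    win_len = round(paradigm.epoch_dur_s / tr_s)
    t_rel = (np.arange(win_len) - pre_onset_samples) * tr_s
    return np.nonzero((t_rel >= 0) & (t_rel < paradigm.stim_dur_s))[0]


def epoch_average_voxelwise(
    data: np.ndarray,
    paradigm: StimulationParadigm,
    tr_s: float,
    pre_onset_samples: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-averaged fractional change per voxel.

    For each voxel: slice the epoch windows, divide each window by the mean
    of its first six samples, subtract 1, and average across epochs.
    Returns ``(responses, ok)`` where ``responses`` is ``(n_vox, win_len)``
    for flattened voxels and ``ok`` flags rows whose every epoch had a
    positive baseline (others are NaN).
    """
    windows = epoch_windows(paradigm, tr_s, pre_onset_samples)
    flat = data.reshape(-1, data.shape[-1])
    n_vox = flat.shape[0]
    win_len = windows[0][1] - windows[0][0]
    acc = np.zeros((n_vox, win_len))
    ok = np.ones(n_vox, dtype=bool)
    for start, stop in windows:
        seg = flat[:, start:stop]
        base = seg[:, :_BASELINE_SAMPLES].mean(axis=1)
        good = base > 0
        ok &= good & ~np.any(np.isnan(seg), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            acc += seg / base[:, None] - 1.0
    resp = acc / len(windows)
    resp[~ok] = np.nan
    return resp, ok


def extract_voxel_responses(
    data: np.ndarray,
    cluster_mask: np.ndarray,
    paradigm: StimulationParadigm,
    tr_s: float,
    pre_onset_samples: int = 6,
    subject: int | str = 0,
) -> VoxelResponseSet:
    """Epoch-averaged responses of the voxels selected by ``cluster_mask``.

    Voxels whose baseline mean is nonpositive in any epoch are dropped with
    a log entry.
    """
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not np.any(cluster_mask):
        raise ValueError("cluster mask selects no voxels")
    resp, ok = epoch_average_voxelwise(data, paradigm, tr_s, pre_onset_samples)
    flat_idx = np.nonzero(cluster_mask.ravel())[0]
    keep = ok[flat_idx]
    dropped = int((~keep).sum())
    if dropped:
        log.warning("dropped %d voxel(s) with nonpositive epoch baseline", dropped)
    flat_idx = flat_idx[keep]
    coords = np.column_stack(np.unravel_index(flat_idx, cluster_mask.shape))
    prov = pd.DataFrame(coords, columns=["x", "y", "z"])
    prov.insert(0, "subject", subject)
    return VoxelResponseSet(
        responses=resp[flat_idx],
        provenance=prov,
        tr_s=tr_s,
        stim_sample_idx=_window_stim_samples(paradigm, tr_s, pre_onset_samples),
    )


def concat_response_sets(sets: list[VoxelResponseSet]) -> VoxelResponseSet:
    """Pool responses across subjects (rows stacked, provenance kept)."""
    if not sets:
        raise ValueError("no response sets to pool")
    tr = {s.tr_s for s in sets}
    if len(tr) != 1:
        raise ValueError("response sets have mixed sampling intervals")
    return VoxelResponseSet(
        responses=np.vstack([s.responses for s in sets]),
        provenance=pd.concat([s.provenance for s in sets], ignore_index=True),
        tr_s=sets[0].tr_s,
        stim_sample_idx=sets[0].stim_sample_idx,
    )


def kmeans_classify(
    response_set: VoxelResponseSet, k: int = 10, seed: int = 0, n_init: int = 10
) -> ResponseClusterSet:
    """Euclidean K-means of the response rows with k-means++ seeding.

    Deterministic for a fixed seed.  When there are fewer voxels than
    clusters, k is reduced to the voxel count with a warning.
    """
    n = response_set.n_voxels
    if n == 0:
        raise ValueError("empty response set")
    if n < k:
        log.warning("only %d voxels < k=%d; reducing k", n, k)
        k = n
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    assignments = km.fit_predict(response_set.responses)
    centroids = km.cluster_centers_
    polarity = _centroid_polarity(centroids, response_set.stim_sample_idx)
    return ResponseClusterSet(
        centroids=centroids,
        assignments=assignments,
        polarity=polarity,
        response_set=response_set,
    )


def _centroid_polarity(centroids: np.ndarray, stim_idx: np.ndarray) -> np.ndarray:
    means = centroids[:, stim_idx].mean(axis=1)
    pol = np.sign(means).astype(np.int8)
    pol[np.abs(means) < 1e-12] = 0
    return pol


def pool_by_polarity(
    cluster_set: ResponseClusterSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of voxels in positive- and negative-polarity clusters.

    A cluster's polarity is the sign of its centroid mean over the
    stimulation-window samples; voxels inherit their cluster's polarity.
    Exactly-zero centroids (|mean| < 1e-12) join neither pool and are
    logged.
    """
    pol_per_voxel = cluster_set.polarity[cluster_set.assignments]
    n_zero = int(np.sum(cluster_set.polarity == 0))
    if n_zero:
        log.info("%d cluster(s) with zero-mean centroid excluded from pooling", n_zero)
    return np.nonzero(pol_per_voxel > 0)[0], np.nonzero(pol_per_voxel < 0)[0]


def epoch_average_region(
    series_list: list[np.ndarray],
    region_mask: np.ndarray,
    paradigm: StimulationParadigm,
    tr_s: float,
    pre_onset_samples: int = 6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and SD response of a region across runs.

    Order of operations, per run: average the signal across the region's
    voxels, normalize each epoch window to the mean of its first six
    samples (subtracting 1), average across epochs; then the mean and
    standard deviation across runs are computed.  Returns
    ``(t_rel_onset_s, mean, sd)`` with time relative to stimulus onset.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not np.any(region_mask):
        raise ValueError("region mask is empty")
    windows = epoch_windows(paradigm, tr_s, pre_onset_samples)
    win_len = windows[0][1] - windows[0][0]
    per_run = []
    for data in series_list:
        course = np.nanmean(data[region_mask], axis=0)
        acc = np.zeros(win_len)
        for start, stop in windows:
            seg = course[start:stop]
            base = seg[:_BASELINE_SAMPLES].mean()
            if base <= 0:
                raise ValueError("nonpositive epoch baseline in region average")
            acc += seg / base - 1.0
        per_run.append(acc / len(windows))
    stack = np.stack(per_run)
    t_rel = (np.arange(win_len) - pre_onset_samples) * tr_s
    sd = stack.std(axis=0, ddof=0) if len(per_run) > 1 else np.zeros(win_len)
    return t_rel, stack.mean(axis=0), sd


def plot_region_response(
    t_rel: np.ndarray,
    mean: np.ndarray,
    sd: np.ndarray,
    stim_dur_s: float,
    ax=None,
    label: str | None = None,
    color=None,
):
    """Mean +/- SD response with a shaded stimulus bar (percent units)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.axvspan(0, stim_dur_s, color="0.85", zorder=0)
    ax.plot(t_rel, 100 * mean, label=label, color=color)
    ax.fill_between(t_rel, 100 * (mean - sd), 100 * (mean + sd), alpha=0.3, color=color)
    ax.axhline(0.0, lw=0.5, color="k")
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel("signal change (%)")
    return ax
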