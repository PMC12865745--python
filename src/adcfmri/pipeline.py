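"""End-to-end pipeline driver and run configuration.

``run_pipeline`` chains: simulate (optional) -> split per b-value -> ADC ->
high-pass filter -> GLM (boxcar for BOLD, FIR for ADC) -> cluster
correction -> group map -> K-means polarity -> region epoch averages, and
writes every intermediate as NIfTI/CSV under an output directory together
with a manifest recording the package version, seeds, parameters, and
content hashes of everything written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adc import compute_adc, highpass_filter, split_interleaved
from .glm import boxcar_glm, cluster_correct, fir_glm, group_cluster_correct, group_level_map
from .io import write_series, write_volume
from .paradigm import AcquisitionScheme, StimulationParadigm
from .phantom import make_label_phantom, preset, simulate_series
from .response import (
    concat_response_sets,
    epoch_average_region,
    extract_voxel_responses,
    kmeans_classify,
    pool_by_polarity,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults are the study values."""

    paradigm: StimulationParadigm = field(default_factory=StimulationParadigm)
    scheme: AcquisitionScheme = field(default_factory=AcquisitionScheme)
    cutoff_s: float = 100.0
    z_threshold: float = 2.3
    group_z_threshold: float = 1.5
    alpha: float = 0.05
    n_perm: int = 500
    n_impulses: int = 4
    window_s: float = 16.0
    k: int = 10
    pre_onset_samples: int = 6
    preset_name: str = "mSC_1Hz"
    grid_shape: tuple[int, int, int] = (32, 32, 4)
    n_subjects: int = 6
    seed: int = 0
    out_dir: str = "adcfmri_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        par = StimulationParadigm(**raw.pop("paradigm", {}))
        sch = AcquisitionScheme(**raw.pop("scheme", {}))
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(paradigm=par, scheme=sch, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic dual-contrast analysis; return a result bundle.

    Each synthetic subject is a fresh seed (``config.seed + subject``).
    Raises from the failing stage with the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "simulate"
        label_map = make_label_phantom(config.grid_shape, "default", seed=config.seed)
        tissue = preset(config.preset_name)
        written.append(
            write_volume(out / "labels.nii", label_map.labels.astype(np.int16), label_map.affine)
        )
        bold_scheme = dataclasses.replace(config.scheme, contrast="bold")
        dw_scheme = dataclasses.replace(config.scheme, contrast="dw_interleaved")

        subject_z_bold, subject_z_adc = [], []
        response_sets = []
        truths = []
        adc_filtered_by_subject = []
        for s in range(config.n_subjects):
            seed = config.seed + s
            bold, _ = simulate_series(label_map, tissue, config.paradigm, bold_scheme, seed=seed)
            dw, truth = simulate_series(
                label_map, tissue, config.paradigm, dw_scheme, seed=seed + 10_000
            )
            truths.append(truth)
            written.append(write_series(out / f"sub-{s:02d}_bold.nii", bold))
            written.append(write_series(out / f"sub-{s:02d}_dw.nii", dw))

            stage = "adc"
            low, high = split_interleaved(dw, dw_scheme)
            adc = compute_adc(low, high, (dw_scheme.b_low, dw_scheme.b_high))

            stage = "filter"
            bold_f = highpass_filter(bold.data, bold.tr_s, config.cutoff_s)
            adc_f = highpass_filter(adc.data, adc.tr_s, config.cutoff_s)
            adc_filtered_by_subject.append(adc_f)
            written.append(write_volume(out / f"sub-{s:02d}_adc.nii", adc.data, adc.affine))
            written.append(
                write_volume(out / f"sub-{s:02d}_adc_valid.nii",
                             adc.valid_mask.astype(np.uint8), adc.affine)
            )

            stage = "glm"
            res_bold = boxcar_glm(bold_f, config.paradigm, bold.tr_s)
            res_adc = fir_glm(
                adc_f, config.paradigm, adc.tr_s,
                n_impulses=config.n_impulses, window_s=config.window_s,
                valid_mask=adc.valid_mask,
            )
            subject_z_bold.append(res_bold.z_map)
            subject_z_adc.append(res_adc.z_map)
            written.append(write_volume(out / f"sub-{s:02d}_zbold.nii", res_bold.z_map, bold.affine))
            written.append(write_volume(out / f"sub-{s:02d}_zadc.nii", res_adc.z_map, adc.affine))

            stage = "cluster"
            cmask = cluster_correct(
                res_adc, adc_f, z_threshold=config.z_threshold,
                alpha=config.alpha, n_perm=config.n_perm, seed=seed,
            )
            cmask.table.to_csv(out / f"sub-{s:02d}_adc_clusters.csv", index=False)
            written.append(out / f"sub-{s:02d}_adc_clusters.csv")

            stage = "respond"
            if cmask.n_clusters:
                response_sets.append(
                    extract_voxel_responses(
                        adc_f, cmask.mask, config.paradigm, adc.tr_s,
                        pre_onset_samples=config.pre_onset_samples, subject=s,
                    )
                )

        stage = "group"
        group_z = group_level_map(subject_z_adc)
        written.append(write_volume(out / "group_zadc.nii", group_z, label_map.affine))
        gmask = group_cluster_correct(
            subject_z_adc, z_threshold=config.group_z_threshold,
            alpha=config.alpha, n_perm=max(config.n_perm, 500), seed=config.seed,
        )
        gmask.table.to_csv(out / "group_adc_clusters.csv", index=False)
        written.append(out / "group_adc_clusters.csv")

        stage = "respond"
        polarity_pos = polarity_neg = None
        cluster_set = None
        if response_sets:
            pooled = concat_response_sets(response_sets)
            cluster_set = kmeans_classify(pooled, k=config.k, seed=config.seed)
            pos_idx, neg_idx = pool_by_polarity(cluster_set)
            pd.DataFrame(cluster_set.centroids).to_csv(out / "centroids.csv", index=False)
            written.append(out / "centroids.csv")
            polarity_pos, polarity_neg = _polarity_maps(
                cluster_set, pos_idx, neg_idx, config.grid_shape
            )
            written.append(write_volume(out / "polarity_pos.nii",
                                        polarity_pos.astype(np.uint8), label_map.affine))
            written.append(write_volume(out / "polarity_neg.nii",
                                        polarity_neg.astype(np.uint8), label_map.affine))

        stage = "epoch_average"
        region = config.preset_name.split("_")[0]
        region_rows = []
        if region in ("mSC", "lSC", "CC"):
            mask = label_map.mask(region)
            t_rel, mean, sd = epoch_average_region(
                adc_filtered_by_subject, mask, config.paradigm,
                tr_s=config.scheme.tr_s * 2, pre_onset_samples=config.pre_onset_samples,
            )
            region_rows = pd.DataFrame(
                {"t_rel_s": t_rel, "mean_frac": mean, "sd_frac": sd}
            )
            region_rows.to_csv(out / f"{region}_adc_epoch_average.csv", index=False)
            written.append(out / f"{region}_adc_epoch_average.csv")

        stage = "manifest"
        manifest = {
            "adcfmri_version": __version__,
            "config": {
                **{k: v for k, v in dataclasses.asdict(config).items()
                   if k not in ("paradigm", "scheme")},
                "paradigm": dataclasses.asdict(config.paradigm),
                "scheme": dataclasses.asdict(config.scheme),
            },
            "files": {p.name: _sha256(p) for p in written if p.exists()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as err:  # noqa: BLE001 - annotate with the stage and re-raise
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    return {
        "label_map": label_map,
        "group_z_adc": group_z,
        "group_clusters": gmask,
        "subject_z_bold": subject_z_bold,
        "subject_z_adc": subject_z_adc,
        "cluster_set": cluster_set,
        "polarity_pos": polarity_pos,
        "polarity_neg": polarity_neg,
        "truths": truths,
        "manifest": manifest,
    }


def _polarity_maps(cluster_set, pos_idx, neg_idx, grid_shape):
    prov = cluster_set.response_set.provenance
    pos = np.zeros(grid_shape, dtype=bool)
    neg = np.zeros(grid_shape, dtype=bool)
    coords = prov[["x", "y", "z"]].to_numpy()
    for idx, target in ((pos_idx, pos), (neg_idx, neg)):
        c = coords[idx]
        target[c[:, 0], c[:, 1], c[:, 2]] = True
    return pos, neg
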