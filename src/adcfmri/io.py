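"""NIfTI, sidecar, and config file handling."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .paradigm import AcquisitionScheme, StimulationParadigm
from .phantom import VolumeSeries

__all__ = [
    "write_series",
    "read_series",
    "write_volume",
    "read_paradigm_config",
]


def write_volume(path: str | Path, data: np.ndarray, affine: np.ndarray) -> Path:
    """Write a 3-D or 4-D array as NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    return path


def write_series(path: str | Path, series: VolumeSeries, extra: dict | None = None) -> Path:
    """Write a series as NIfTI-1 with a b-value table and a JSON sidecar.

    The b-value vector is written next to the image as a two-column
    ``<stem>.bval.txt`` (volume index, b); the sidecar ``<stem>.json``
    records TR, contrast, and any extra metadata.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(series.data, series.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], series.tr_s))
    nib.save(img, str(path))
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    if series.bvals is not None:
        bval_path = path.parent / f"{stem}.bval.txt"
        np.savetxt(
            bval_path,
            np.column_stack([np.arange(series.n_volumes), series.bvals]),
            fmt=["%d", "%g"],
            header="volume b_s_per_mm2",
        )
    sidecar = {"tr_s": series.tr_s, "contrast": series.contrast}
    if extra:
        sidecar.update(extra)
    (path.parent / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_series(
    path: str | Path,
    scheme: AcquisitionScheme | None = None,
    strip_dummies: bool = False,
) -> VolumeSeries:
    """Read a NIfTI series, validating the sidecar against the scheme.

    For diffusion-weighted data the ``.bval.txt`` sidecar is required and
    the b-vector must alternate as configured.  A TR mismatch between the
    header and the scheme raises, naming both values.  When
    ``strip_dummies`` is set, the scheme's ``n_dummies`` leading volumes
    are discarded.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D series, got {data.ndim}-D")
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    sidecar_path = path.parent / f"{stem}.json"
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    tr = float(sidecar.get("tr_s", img.header.get_zooms()[3] if len(img.header.get_zooms()) > 3 else 0))
    contrast = sidecar.get("contrast", "bold")

    if scheme is not None:
        if scheme.contrast != contrast:
            raise ValueError(f"{path}: contrast {contrast!r} != configured {scheme.contrast!r}")
        expected_tr = scheme.tr_s
        if tr and abs(tr - expected_tr) > 1e-6:
            raise ValueError(
                f"{path}: TR mismatch — header/sidecar says {tr} s, config says {expected_tr} s"
            )
        tr = expected_tr

    bvals = None
    if contrast == "dw_interleaved":
        bval_path = path.parent / f"{stem}.bval.txt"
        if not bval_path.exists():
            raise FileNotFoundError(
                f"{path}: diffusion-weighted series requires b-value sidecar {bval_path.name}"
            )
        table = np.loadtxt(bval_path)
        bvals = table[:, 1] if table.ndim == 2 else table
        if data.shape[3] % 2 != 0:
            raise ValueError(f"{path}: interleaved series has odd volume count {data.shape[3]}")
    if strip_dummies and scheme is not None and scheme.n_dummies:
        data = data[..., scheme.n_dummies:]
        if bvals is not None:
            bvals = bvals[scheme.n_dummies:]
    return VolumeSeries(
        data=data, tr_s=tr, contrast=contrast, bvals=bvals, affine=img.affine
    )


def read_paradigm_config(path: str | Path) -> tuple[StimulationParadigm, AcquisitionScheme]:
    """Read paradigm and scheme from a YAML/JSON config.

    Keys mirror the dataclass field names; missing keys take the default
    block-design values (24-s initial rest, 12 x (16 s + 24 s), TR 1 s,
    b = 200/1000 s/mm2, 12 dummies).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    par = StimulationParadigm(**raw.get("paradigm", {}))
    sch = AcquisitionScheme(**raw.get("scheme", {}))
    return par, sch
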