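"""Reading dynamic series and writing models, maps and curves.

Supported inputs: single-slice 4-D/3-D NIfTI (time last), multi-page TIFF
(time first), delimited text and ``.npy`` matrices (T x P, needing an
explicit grid shape unless square).  Outputs are plain formats: JSON for
models and manifests, CSV for curves, NIfTI plus 16-bit PNG for maps,
paletted PNG plus a delimited label matrix for segmentations.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

from .hemodynamics import HemodynamicMaps
from .ifa import IFAModel
from .mog import MoGSourceParams
from .segmentation import TissueSegmentation
from .series import DynamicSeries

_DELIMITED = {".csv", ".tsv", ".txt", ".dat"}


def _infer_grid(p: int, grid_shape: tuple[int, int] | None) -> tuple[int, int]:
    if grid_shape is not None:
        return (int(grid_shape[0]), int(grid_shape[1]))
    side = int(round(np.sqrt(p)))
    if side * side != p:
        raise ValueError(
            f"cannot infer a square grid for P={p} pixels; pass grid_shape"
        )
    return (side, side)


def read_series(
    path: str | Path,
    fmt: str | None = None,
    grid_shape: tuple[int, int] | None = None,
    frame_times: np.ndarray | None = None,
    te: float | None = None,
) -> DynamicSeries:
    """Load a dynamic series from NIfTI, TIFF stack, delimited text or NPY.

    ``fmt`` overrides extension-based detection ("nifti", "tiff",
    "delimited", "npy").  For matrix inputs rows are time frames; the grid
    shape is required unless the pixel count is a perfect square.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif name.endswith((".tif", ".tiff")):
            fmt = "tiff"
        elif path.suffix.lower() == ".npy":
            fmt = "npy"
        elif path.suffix.lower() in _DELIMITED:
            fmt = "delimited"
        else:
            raise ValueError(f"cannot infer format of {path.name}; pass fmt=")

    if fmt == "nifti":
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj, dtype=float)
        vol = np.squeeze(vol)
        if vol.ndim != 3:
            raise ValueError(
                f"expected a single-slice dynamic NIfTI (rows x cols x T), got shape {vol.shape}"
            )
        rows, cols, t = vol.shape
        data = np.moveaxis(vol, -1, 0).reshape(t, rows * cols)
        return DynamicSeries(data, (rows, cols), frame_times, te)
    if fmt == "tiff":
        stack = np.asarray(tifffile.imread(str(path)), dtype=float)
        if stack.ndim == 2:
            raise ValueError("TIFF holds a single page; a dynamic series needs >= 2 frames")
        if stack.ndim != 3:
            raise ValueError(f"expected a T x rows x cols TIFF stack, got shape {stack.shape}")
        t, rows, cols = stack.shape
        return DynamicSeries(stack.reshape(t, rows * cols), (rows, cols), frame_times, te)
    if fmt == "npy":
        data = np.asarray(np.load(str(path)), dtype=float)
    elif fmt == "delimited":
        delim = "\t" if path.suffix.lower() == ".tsv" else ","
        data = np.loadtxt(str(path), delimiter=delim, ndmin=2)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if data.ndim != 2:
        raise ValueError(f"matrix input must be 2-D (T x P), got shape {data.shape}")
    return DynamicSeries(data, _infer_grid(data.shape[1], grid_shape), frame_times, te)


# ---------------------------------------------------------------------------
# Model serialisation
# ---------------------------------------------------------------------------

def save_model(model: IFAModel, path: str | Path, extra: dict | None = None) -> None:
    """Serialise a fitted model (and optional config echo) to JSON."""
    payload = {
        "mixing": model.mixing.tolist(),
        "noise_diag": model.noise_diag.tolist(),
        "mog": {
            "weights": [w.tolist() for w in model.mog.weights],
            "means": [m.tolist() for m in model.mog.means],
            "variances": [v.tolist() for v in model.mog.variances],
        },
        "loss_trace": [float(v) for v in model.loss_trace],
        "converged": bool(model.converged),
        "seed": model.seed,
    }
    if extra:
        payload["extra"] = extra
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> IFAModel:
    payload = json.loads(Path(path).read_text())
    mog = MoGSourceParams(
        weights=[np.asarray(w) for w in payload["mog"]["weights"]],
        means=[np.asarray(m) for m in payload["mog"]["means"]],
        variances=[np.asarray(v) for v in payload["mog"]["variances"]],
    )
    return IFAModel(
        mixing=np.asarray(payload["mixing"]),
        noise_diag=np.asarray(payload["noise_diag"]),
        mog=mog,
        loss_trace=list(payload.get("loss_trace", [])),
        converged=bool(payload.get("converged", True)),
        seed=payload.get("seed"),
    )


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def write_curves_csv(
    path: str | Path,
    times: np.ndarray,
    curves: np.ndarray,
    names: list[str],
) -> None:
    """Write a time column plus one column per curve."""
    curves = np.atleast_2d(np.asarray(curves, float))
    if curves.shape[0] != np.asarray(times).size:
        curves = curves.T
    table = np.column_stack([np.asarray(times, float), curves])
    header = ",".join(["time"] + list(names))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(str(path), table, delimiter=",", header=header, comments="")


def _to_uint16(img: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(img)), float(np.max(img))
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint16)
    return np.round((img - lo) / (hi - lo) * 65535).astype(np.uint16)


def write_maps(maps: HemodynamicMaps, out_dir: str | Path, stem: str = "maps") -> list[Path]:
    """Write rCBV/rCBF/MTT as NIfTI and 16-bit PNG with a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in ("rcbv", "rcbf", "mtt"):
        img = maps.map_image(name)
        nii = out_dir / f"{stem}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(img.astype(np.float32), np.eye(4)), str(nii))
        png = out_dir / f"{stem}_{name}.png"
        iio.imwrite(png, _to_uint16(img))
        written += [nii, png]
    sidecar = out_dir / f"{stem}.json"
    sidecar.write_text(
        json.dumps(
            {
                "units": {"rcbv": "arbitrary", "rcbf": "arbitrary", "mtt": "seconds"},
                "first_pass": list(maps.first_pass),
                "svd_threshold_fraction": maps.svd_threshold_fraction,
                "png_scaling": "min-max to uint16 per map",
            },
            indent=2,
        )
    )
    written.append(sidecar)
    return written


def write_segmentation(
    seg: TissueSegmentation, out_dir: str | Path, stem: str = "segmentation"
) -> list[Path]:
    """Write the composite label map (PNG + delimited matrix) and masks."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comp = seg.composite_image()
    written: list[Path] = []
    png = out_dir / f"{stem}_composite.png"
    iio.imwrite(png, (comp * (255 // max(1, comp.max()))).astype(np.uint8))
    txt = out_dir / f"{stem}_composite.csv"
    np.savetxt(str(txt), comp, fmt="%d", delimiter=",")
    written += [png, txt]
    labels = out_dir / f"{stem}_labels.json"
    labels.write_text(json.dumps({"labels": seg.labels, "background": 0}, indent=2))
    written.append(labels)
    return written


def write_manifest(path: str | Path, config: dict, seed: int | None = None) -> None:
    """Record the configuration and seed of a run for reproducibility."""
    import perfifa

    manifest = {
        "package": "perfifa",
        "version": getattr(perfifa, "__version__", "unknown"),
        "seed": seed,
        "config": config,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(manifest, indent=2))
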