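"""File I/O: NIfTI volumes, motion tables, TSV/JSON outputs.

Voxel ordering convention: in-mask columns follow mask scan order with
the first (x) axis varying fastest, 0-based.  The same convention is
used when writing spatial maps back into volumes, so map round-trips
are bit-consistent up to storage precision.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .decompose import Decomposition, GroupMatrix
from .preprocess import VoxelTimeSeriesMatrix

logger = logging.getLogger(__name__)


def _mask_scan_order(mask: np.ndarray) -> np.ndarray:
    flat = mask.reshape(-1, order="F")
    lin = np.flatnonzero(flat)
    nx, ny, _ = mask.shape
    i = lin % nx
    j = (lin // nx) % ny
    k = lin // (nx * ny)
    return np.column_stack([i, j, k])


def load_masked_4d(
    fmri_path: str | Path,
    mask_path: str | Path,
    tr_seconds: float | None = None,
    subject_id: str | None = None,
) -> VoxelTimeSeriesMatrix:
    """Load a 4D NIfTI restricted to a 3D mask as a time-by-voxel matrix.

    TR is read from the NIfTI header (pixdim[4]) unless overridden.
    """
    img = nib.load(str(fmri_path))
    mask_img = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj)
    mask = np.asanyarray(mask_img.dataobj) > 0
    if data.ndim != 4:
        raise ValueError(f"{fmri_path}: expected 4D data, got {data.ndim}D")
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"grid mismatch: data {data.shape[:3]} vs mask {mask.shape}"
        )
    if not mask.any():
        raise ValueError(f"{mask_path}: mask selects no voxels")
    if tr_seconds is None:
        tr_seconds = float(img.header.get_zooms()[3])
    if tr_seconds <= 0:
        raise ValueError(
            f"{fmri_path}: TR {tr_seconds} s is not positive; pass "
            "tr_seconds explicitly"
        )
    voxel_index = _mask_scan_order(mask)
    idx = tuple(voxel_index.T)
    matrix = np.asarray(data[idx], dtype=np.float64).T  # (T, V)
    if not np.all(np.isfinite(matrix)):
        raise ValueError(f"{fmri_path}: non-finite values inside mask")
    return VoxelTimeSeriesMatrix(
        data=matrix,
        tr_seconds=tr_seconds,
        voxel_index=voxel_index,
        subject_id=subject_id or Path(fmri_path).stem.split(".")[0],
        grid_shape=tuple(mask.shape),
    )


def _default_affine(voxel_mm: float = 3.0) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_mm
    return aff


def save_matrix_as_nifti(
    m: VoxelTimeSeriesMatrix, path: str | Path, affine: np.ndarray | None = None
) -> None:
    """Write a time-by-voxel matrix back into a 4D NIfTI volume."""
    vol = np.zeros((*m.grid_shape, m.n_volumes), dtype=np.float32)
    idx = tuple(m.voxel_index.T)
    vol[idx] = m.data.T.astype(np.float32)
    img = nib.Nifti1Image(vol, affine if affine is not None else _default_affine())
    img.header.set_zooms((*img.header.get_zooms()[:3], m.tr_seconds))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def save_mask(
    mask: np.ndarray, path: str | Path, affine: np.ndarray | None = None
) -> None:
    img = nib.Nifti1Image(
        mask.astype(np.uint8), affine if affine is not None else _default_affine()
    )
    nib.save(img, str(path))


def write_maps(
    maps: np.ndarray,
    voxel_index: np.ndarray,
    grid_shape: tuple[int, int, int],
    path: str | Path,
    affine: np.ndarray | None = None,
) -> None:
    """Write (n_components, n_voxels) spatial maps as a 4D NIfTI, one
    volume per component."""
    maps = np.atleast_2d(maps)
    vol = np.zeros((*grid_shape, maps.shape[0]), dtype=np.float32)
    idx = tuple(np.asarray(voxel_index).T)
    vol[idx] = maps.T.astype(np.float32)
    img = nib.Nifti1Image(vol, affine if affine is not None else _default_affine())
    nib.save(img, str(path))


def load_maps(
    path: str | Path, mask_path: str | Path
) -> np.ndarray:
    """Reload component maps written by :func:`write_maps`."""
    img = nib.load(str(path))
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    data = np.asanyarray(img.dataobj)
    voxel_index = _mask_scan_order(mask)
    idx = tuple(voxel_index.T)
    return np.asarray(data[idx], dtype=np.float64).T


def read_motion(path: str | Path) -> np.ndarray:
    """Read a 6-column whitespace/TSV motion parameter file."""
    table = np.loadtxt(str(path))
    if table.ndim != 2 or table.shape[1] != 6:
        raise ValueError(f"{path}: expected a time-by-6 motion table")
    return table


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    np.savetxt(str(path), motion, fmt="%.8f", delimiter="\t")


def write_timecourses_tsv(
    timecourses: np.ndarray,
    path: str | Path,
    boundaries: list[tuple[str, int, int]] | None = None,
) -> None:
    """IC (or source) time courses as TSV, with subject boundaries in a
    JSON sidecar when provided."""
    df = pd.DataFrame(
        timecourses,
        columns=[f"IC{i + 1:02d}" for i in range(timecourses.shape[1])],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")
    if boundaries is not None:
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "subject_boundaries": [
                        {"subject_id": sid, "row_start": s, "row_end": e}
                        for sid, s, e in boundaries
                    ]
                },
                indent=2,
            )
        )


def write_decomposition(
    d: Decomposition, g: GroupMatrix, outdir: str | Path
) -> None:
    """Write maps (NIfTI), time courses (TSV+sidecar) and singular
    values (TSV) of a decomposition."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_maps(d.spatial_maps, g.voxel_index, g.grid_shape, outdir / "ic_maps.nii.gz")
    write_timecourses_tsv(
        d.ic_timecourses, outdir / "ic_timecourses.tsv", g.subject_boundaries
    )
    pd.DataFrame({"singular_value": d.singular_values}).to_csv(
        outdir / "singular_values.tsv", sep="\t", index=False, float_format="%.8f"
    )
    (outdir / "decomposition.json").write_text(
        json.dumps(
            {
                "n_pcs": d.n_pcs,
                "n_ics": d.n_ics,
                "convergence": d.convergence,
                "tr_seconds": g.tr_seconds,
            },
            indent=2,
        )
    )


def write_dataset(
    matrices: list[VoxelTimeSeriesMatrix],
    truth,
    motion_tables: list[np.ndarray],
    outdir: str | Path,
) -> None:
    """Write a simulated dataset: per-subject 4D NIfTI + motion files, a
    mask, and the ground-truth bundle (TSV time courses, NIfTI maps,
    JSON metadata)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = matrices[0]
    mask = np.zeros(ref.grid_shape, dtype=bool)
    mask[tuple(ref.voxel_index.T)] = True
    save_mask(mask, outdir / "mask.nii.gz")
    for m, motion in zip(matrices, motion_tables):
        save_matrix_as_nifti(m, outdir / f"{m.subject_id}.nii.gz")
        write_motion(motion, outdir / f"{m.subject_id}_motion.tsv")
    gt_dir = outdir / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    write_maps(
        truth.spatial_maps, ref.voxel_index, ref.grid_shape, gt_dir / "source_maps.nii.gz"
    )
    for m, tc in zip(matrices, truth.source_timecourses):
        pd.DataFrame(tc, columns=truth.names).to_csv(
            gt_dir / f"{m.subject_id}_sources.tsv",
            sep="\t",
            index=False,
            float_format="%.8f",
        )
    (gt_dir / "metadata.json").write_text(
        json.dumps(
            {
                "labels": truth.labels,
                "names": truth.names,
                "subject_of": truth.subject_of,
                "cardiac_rates_hz": truth.cardiac_rates,
                "tr_seconds": ref.tr_seconds,
                "grid_shape": list(ref.grid_shape),
            },
            indent=2,
        )
    )
    logger.info("wrote simulated dataset to %s", outdir)


def write_component_table(reports, path: str | Path) -> pd.DataFrame:
    """Per-component summary TSV: keep flag, consistency ratio, dominant
    subject, peak frequency, five band fractions, label."""
    rows = []
    for r in reports:
        row = {
            "component": r.component + 1,
            "keep": int(r.consistency.keep),
            "max_ratio": r.consistency.max_ratio,
            "dominant_subject": r.consistency.dominant_subject,
            "peak_freq_hz": r.spectrum.peak_freq,
            "label": r.label.label,
            "heart_rate_bpm": r.heart_rate_bpm,
        }
        edges = r.spectrum.band_edges
        for i, frac in enumerate(r.spectrum.band_fractions):
            row[f"frac_{edges[i]:g}-{edges[i + 1]:g}Hz"] = frac
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return df
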