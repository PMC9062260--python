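"""File formats: HDF5 event lists and sinogram sets, NIfTI volumes,
JSON/CSV reports.

Every container carries a format version, the provenance metadata of the
run that produced it (scanner hash, configuration, seed, duration,
decimation) and a CRC32 footer checksum written last, so that partial or
corrupted files are detected on read.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import h5py
import numpy as np

from .geometry import ScannerSpec, SinogramLayout
from .recon import ImageGrid, ReconImage
from .simulate import Acquisition, CoincidenceList, DigitizerConfig

EVENT_FORMAT_VERSION = "petchain-events-1"
SINO_FORMAT_VERSION = "petchain-sino-1"


class FileFormatError(RuntimeError):
    pass


def _config_json(obj) -> str:
    if dataclasses.is_dataclass(obj):
        d = dataclasses.asdict(obj)
    else:
        d = dict(obj)
    return json.dumps(d, default=lambda o: list(o) if isinstance(o, tuple) else str(o))


def scanner_hash(spec: ScannerSpec) -> str:
    return f"{zlib.crc32(spec.to_yaml().encode()):08x}"


def _checksum(arrays) -> int:
    crc = 0
    for a in arrays:
        crc = zlib.crc32(np.ascontiguousarray(a).tobytes(), crc)
    return crc


# --------------------------------------------------------------------------
# event lists
# --------------------------------------------------------------------------

_EVENT_COLUMNS = ("ring1", "tax1", "ring2", "tax2", "e1", "e2",
                  "tof_delta", "label", "lu", "time1", "scat1", "scat2")


def write_event_list(path, acq: Acquisition, scanner: ScannerSpec,
                     digitizer: DigitizerConfig) -> None:
    path = Path(path)
    c = acq.coincidences
    with h5py.File(path, "w") as f:
        f.attrs["version"] = EVENT_FORMAT_VERSION
        f.attrs["scanner_hash"] = scanner_hash(scanner)
        f.attrs["scanner_spec"] = scanner.to_yaml()
        f.attrs["digitizer"] = _config_json(digitizer)
        f.attrs["seed"] = acq.seed
        f.attrs["duration_s"] = acq.duration_s
        f.attrs["decimation"] = acq.decimation
        f.attrs["summary"] = json.dumps(acq.summary)
        g = f.create_group("events")
        arrays = []
        for name in _EVENT_COLUMNS:
            a = getattr(c, name)
            g.create_dataset(name, data=a, chunks=(min(1 << 18, max(len(c), 1)),)
                             if len(c) else None)
            arrays.append(a)
        f.create_dataset("singles_per_crystal", data=acq.singles_per_crystal)
        arrays.append(acq.singles_per_crystal)
        f.attrs["checksum"] = _checksum(arrays)
        f.attrs["complete"] = True


def read_event_list(path) -> Acquisition:
    path = Path(path)
    with h5py.File(path, "r") as f:
        _check_header(f, EVENT_FORMAT_VERSION, path)
        cols = {name: f["events"][name][...] for name in _EVENT_COLUMNS}
        spc = f["singles_per_crystal"][...]
        crc = _checksum([cols[n] for n in _EVENT_COLUMNS] + [spc])
        if crc != int(f.attrs["checksum"]):
            raise FileFormatError(f"checksum mismatch in {path}")
        coin = CoincidenceList(**cols)
        return Acquisition(coin, spc, float(f.attrs["duration_s"]),
                           float(f.attrs["decimation"]), int(f.attrs["seed"]),
                           json.loads(f.attrs["summary"]))


def iter_event_chunks(path, chunk: int = 1 << 20):
    """Stream the event columns in bounded-memory chunks of dicts."""
    with h5py.File(Path(path), "r") as f:
        _check_header(f, EVENT_FORMAT_VERSION, Path(path))
        n = f["events"]["ring1"].shape[0]
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            yield {name: f["events"][name][start:stop]
                   for name in _EVENT_COLUMNS}


def _check_header(f, version, path):
    if f.attrs.get("version") != version:
        raise FileFormatError(
            f"{path}: expected format {version!r}, found "
            f"{f.attrs.get('version')!r}")
    if not f.attrs.get("complete", False):
        raise FileFormatError(f"{path}: incomplete file (missing footer)")


# --------------------------------------------------------------------------
# sinogram sets
# --------------------------------------------------------------------------

def write_sinogram_set(path, arrays: dict, layout: SinogramLayout,
                       meta: dict | None = None) -> None:
    """Named bin-congruent arrays (prompts, randoms, scatter, acf, eta,
    tail_mask, ...) plus the layout header."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["version"] = SINO_FORMAT_VERSION
        f.attrs["layout"] = _config_json(layout)
        if meta:
            f.attrs["meta"] = json.dumps(meta, default=str)
        for name, a in arrays.items():
            if tuple(a.shape) != tuple(layout.shape):
                raise FileFormatError(
                    f"array {name!r} shape {a.shape} != layout {layout.shape}")
            f.create_dataset(name, data=a, compression="gzip",
                             compression_opts=1)
        # checksum over name-sorted arrays so reader order cannot matter
        f.attrs["checksum"] = _checksum([arrays[k] for k in sorted(arrays)])
        f.attrs["complete"] = True


def read_sinogram_set(path):
    path = Path(path)
    with h5py.File(path, "r") as f:
        _check_header(f, SINO_FORMAT_VERSION, path)
        d = json.loads(f.attrs["layout"])
        if "max_ring_diff" in d and d["max_ring_diff"] is not None:
            d["max_ring_diff"] = int(d["max_ring_diff"])
        layout = SinogramLayout(**{k: (tuple(v) if isinstance(v, list) else v)
                                   for k, v in d.items()})
        arrays = {k: f[k][...] for k in f.keys()}
        crc = _checksum([arrays[k] for k in sorted(arrays)])
        if crc != int(f.attrs["checksum"]):
            raise FileFormatError(f"checksum mismatch in {path}")
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
        return arrays, layout, meta


# --------------------------------------------------------------------------
# volumes & reports
# --------------------------------------------------------------------------

def write_volume(path, image: ReconImage, wcc: float | None = None,
                 sidecar: dict | None = None) -> None:
    import nibabel as nib

    path = Path(path)
    g = image.grid
    affine = np.diag([g.dx, g.dx, g.dz, 1.0])
    affine[:3, 3] = g.origin + np.array([g.dx, g.dx, g.dz]) / 2.0
    data = image.values if wcc is None else image.values * wcc
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)
    side = dict(image.provenance)
    if wcc is not None:
        side["wcc_kbq_per_ml_per_unit"] = wcc
    if sidecar:
        side.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(side, indent=2, default=str))


def read_volume(path):
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    dx = float(img.affine[0, 0])
    dz = float(img.affine[2, 2])
    grid = ImageGrid(data.shape[0], data.shape[1], data.shape[2], dx, dz)
    return ReconImage(data, grid)


def write_report(prefix, report) -> None:
    """IqReport -> <prefix>.json and <prefix>.csv."""
    prefix = Path(prefix)
    d = dataclasses.asdict(report)
    prefix.with_suffix(".json").write_text(json.dumps(d, indent=2, default=float))
    lines = ["diameter_mm,crc_pct,snr,bv_pct"]
    for k in report.crc_pct:
        lines.append(f"{k},{report.crc_pct[k]:.3f},{report.snr[k]:.3f},"
                     f"{report.bv_pct[k]:.3f}")
    if report.lung_error_pct is not None:
        lines.append(f"lung_error_pct,{report.lung_error_pct:.3f},,")
    if report.sf_pct is not None:
        lines.append(f"scatter_fraction_pct,{report.sf_pct:.3f},,")
    prefix.with_suffix(".csv").write_text("\n".join(lines) + "\n")


def write_profile_csv(path, positions_mm, values) -> None:
    lines = ["position_mm,value"]
    for p, v in zip(positions_mm, values):
        lines.append(f"{p:.3f},{v:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
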