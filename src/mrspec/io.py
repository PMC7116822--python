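"""Reading and writing MRS data and basis sets.

Signal data live in NIfTI files (native complex datatype, canonical
``[x,y,z,time,coil,average]`` dimension order) with a JSON "sidecar" holding
acquisition metadata.  Required sidecar keys are ``dwell_time`` (s),
``spectrometer_frequency`` (MHz) and ``nucleus``; ``ppm_reference`` is
optional (default water, 4.65 ppm) and unknown keys are preserved verbatim.

Basis sets are read from three dialects:

``json``
    One JSON file per metabolite with keys ``name``, ``dwell_time``,
    ``spectrometer_frequency``, ``fid_real``, ``fid_imag`` and optionally
    ``ppm_reference``.  This is also the write format.
``lcmodel_basis``
    A single ``.BASIS`` FORTRAN-namelist style file; spectra are stored as
    alternating real/imaginary values per metabolite block.
``jmrui_txt``
    A single jMRUI-style text file with a header and one signal block per
    metabolite.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import (BasisSet, FormatError, MetadataError, MRSData, WATER_PPM,
                   to_fid, to_spectrum)

__all__ = [
    "read_mrs", "write_mrs", "read_basis", "write_basis",
    "write_lcmodel_basis", "write_jmrui_txt", "resample_fid",
]

_REQUIRED_KEYS = ("dwell_time", "spectrometer_frequency", "nucleus")
_KNOWN_KEYS = _REQUIRED_KEYS + ("ppm_reference", "echo_time", "repetition_time")


# ---------------------------------------------------------------------------
# NIfTI + sidecar
# ---------------------------------------------------------------------------

def write_mrs(data: MRSData, nifti_path, sidecar_path=None) -> None:
    """Write ``data`` as NIfTI (complex128) plus a JSON sidecar.

    ``sidecar_path`` defaults to the NIfTI path with a ``.json`` suffix.
    """
    nifti_path = Path(nifti_path)
    if sidecar_path is None:
        sidecar_path = nifti_path.with_suffix(".json")
    img = nib.Nifti2Image(data.signal, affine=data.affine)
    img.set_data_dtype(np.complex128)
    nib.save(img, str(nifti_path))
    sidecar = {
        "dwell_time": data.dwell_time,
        "spectrometer_frequency": data.spectrometer_frequency,
        "nucleus": data.nucleus,
        "ppm_reference": data.ppm_reference,
    }
    for key, val in data.extra.items():
        sidecar.setdefault(key, val)
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_mrs(nifti_path, sidecar_path=None) -> MRSData:
    """Read an MRS NIfTI file and its JSON sidecar into :class:`MRSData`."""
    nifti_path = Path(nifti_path)
    if sidecar_path is None:
        sidecar_path = nifti_path.with_suffix(".json")
    img = nib.load(str(nifti_path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim < 4:
        raise FormatError(f"expected >=4 dims in {nifti_path}, got {arr.ndim}")
    if not np.iscomplexobj(arr):
        # fallback dialect: real/imag pair stacked on a trailing axis of 2
        if arr.shape[-1] == 2:
            arr = arr[..., 0] + 1j * arr[..., 1]
        else:
            raise FormatError(
                "non-complex data stored without a real/imag pair convention")
    try:
        sidecar = json.loads(Path(sidecar_path).read_text())
    except FileNotFoundError:
        raise MetadataError(f"sidecar file not found: {sidecar_path}") from None
    for key in _REQUIRED_KEYS:
        if key not in sidecar:
            raise MetadataError(key)
    extra = {k: v for k, v in sidecar.items() if k not in _KNOWN_KEYS}
    if "echo_time" in sidecar:
        extra["echo_time"] = sidecar["echo_time"]
    if "repetition_time" in sidecar:
        extra["repetition_time"] = sidecar["repetition_time"]
    return MRSData(
        signal=arr,
        dwell_time=float(sidecar["dwell_time"]),
        spectrometer_frequency=float(sidecar["spectrometer_frequency"]),
        nucleus=str(sidecar["nucleus"]),
        ppm_reference=float(sidecar.get("ppm_reference", WATER_PPM)),
        affine=img.affine,
        extra=extra,
    )


# ---------------------------------------------------------------------------
# Fourier-domain resampling
# ---------------------------------------------------------------------------

def resample_fid(fid: np.ndarray, dwell_in: float, dwell_out: float,
                 n_out: int) -> np.ndarray:
    """Resample a FID to a new dwell time / length in the frequency domain.

    The spectrum is cropped (bandwidth reduction) or zero-padded (bandwidth
    increase) around its centre, preserving spectral amplitude density and
    hence relative amplitudes between metabolites resampled the same way.
    """
    n_in = len(fid)
    spec = to_spectrum(np.asarray(fid, dtype=np.complex128))
    # target grid in Hz must match FrequencyAxis.from_params(n_out, dwell_out)
    df_in = 1.0 / (n_in * dwell_in)
    df_out = 1.0 / (n_out * dwell_out)
    hz_in = np.fft.fftshift(np.fft.fftfreq(n_in, d=dwell_in))
    hz_out = np.fft.fftshift(np.fft.fftfreq(n_out, d=dwell_out))
    re = np.interp(hz_out, hz_in, spec.real, left=0.0, right=0.0)
    im = np.interp(hz_out, hz_in, spec.imag, left=0.0, right=0.0)
    out = (re + 1j * im) * np.sqrt(df_in / df_out) * np.sqrt(n_out / n_in)
    return to_fid(out)


# ---------------------------------------------------------------------------
# Basis JSON dialect (read + write)
# ---------------------------------------------------------------------------

def write_basis(basis: BasisSet, directory) -> None:
    """Write one JSON file per metabolite into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, fid in zip(basis.names, basis.fids):
        payload = {
            "name": name,
            "dwell_time": basis.dwell_time,
            "spectrometer_frequency": basis.spectrometer_frequency,
            "ppm_reference": basis.ppm_reference,
            "fid_real": fid.real.tolist(),
            "fid_imag": fid.imag.tolist(),
        }
        (directory / f"{name}.json").write_text(json.dumps(payload))


def _read_basis_json(path: Path) -> BasisSet:
    reserved = {"manifest.json", "ground_truth.json"}
    files = (sorted(f for f in path.glob("*.json") if f.name not in reserved)
             if path.is_dir() else [path])
    if not files:
        raise FormatError(f"no JSON basis files found in {path}")
    names, fids, meta = [], [], []
    for f in files:
        d = json.loads(f.read_text())
        for key in ("name", "dwell_time", "spectrometer_frequency",
                    "fid_real", "fid_imag"):
            if key not in d:
                raise FormatError(f"basis file {f} missing key {key!r}")
        names.append(d["name"])
        fids.append(np.asarray(d["fid_real"]) + 1j * np.asarray(d["fid_imag"]))
        meta.append((float(d["dwell_time"]), float(d["spectrometer_frequency"]),
                     float(d.get("ppm_reference", WATER_PPM))))
    if len(set(names)) != len(names):
        raise FormatError("duplicate metabolite names in basis")
    dwell, f0, ref = meta[0]
    n_out = max(len(f) for f in fids)
    out = []
    for fid, (dw, b0, _) in zip(fids, meta):
        if not np.isclose(b0, f0):
            raise FormatError("basis files have inconsistent spectrometer frequencies")
        if np.isclose(dw, dwell) and len(fid) == n_out:
            out.append(fid)
        else:
            out.append(resample_fid(fid, dw, dwell, n_out))
    return BasisSet(names, np.array(out), dwell, f0, ref)


# ---------------------------------------------------------------------------
# LCModel .BASIS dialect
# ---------------------------------------------------------------------------

def write_lcmodel_basis(basis: BasisSet, path) -> None:
    """Write a minimal LCModel-style ``.BASIS`` file (spectra as re/im pairs)."""
    lines = [
        " $SEQPAR",
        " FWHMBA = 0.0,",
        f" HZPPPM = {basis.spectrometer_frequency:.6f},",
        " SEQ = 'SIM'",
        " $END",
        " $BASIS1",
        " IDBASI = 'mrspec synthetic basis',",
        " FMTBAS = '(6E15.7)',",
        f" BADELT = {basis.dwell_time:.10e},",
        f" NDATAB = {basis.n_timepoints},",
        f" PPMREF = {basis.ppm_reference:.6f}",
        " $END",
    ]
    for name, fid in zip(basis.names, basis.fids):
        spec = to_spectrum(fid)
        lines += [
            " $NMUSED",
            f" METABO = '{name}',",
            " CONC = 1.0, TRAMP = 1.0, VOLUME = 1.0, ISHIFT = 0",
            " $END",
        ]
        vals = np.empty(2 * len(spec))
        vals[0::2] = spec.real
        vals[1::2] = spec.imag
        for i in range(0, len(vals), 6):
            lines.append("".join(f"{v:15.7E}" for v in vals[i:i + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def _namelist_blocks(text: str):
    """Yield (name, body) for each `` $NAME ... $END`` namelist block."""
    for m in re.finditer(r"\$([A-Z0-9]+)\s(.*?)\$END", text, re.S):
        yield m.group(1), m.group(2)


def _namelist_get(body: str, key: str, default=None):
    m = re.search(rf"{key}\s*=\s*('([^']*)'|[-+0-9.Ee]+)", body)
    if m is None:
        return default
    return m.group(2) if m.group(2) is not None else m.group(1)


def _read_lcmodel_basis(path: Path) -> BasisSet:
    text = path.read_text()
    header = dict(_namelist_blocks(text))
    if "BASIS1" not in header:
        raise FormatError(f"{path} lacks a $BASIS1 namelist")
    dwell = float(_namelist_get(header["BASIS1"], "BADELT"))
    ndata = int(float(_namelist_get(header["BASIS1"], "NDATAB")))
    ref = float(_namelist_get(header["BASIS1"], "PPMREF", WATER_PPM))
    f0 = float(_namelist_get(header.get("SEQPAR", ""), "HZPPPM",
                             _namelist_get(header["BASIS1"], "HZPPPM", 0.0)))
    if f0 <= 0:
        raise FormatError(f"{path}: HZPPPM missing")
    names, fids = [], []
    # split on $NMUSED blocks: each is followed by its numeric data
    parts = re.split(r"\$NMUSED", text)[1:]
    for part in parts:
        m = re.search(r"(.*?)\$END(.*)", part, re.S)
        if m is None:
            raise FormatError(f"{path}: malformed metabolite block")
        name = _namelist_get(m.group(1), "METABO")
        if name is None:
            raise FormatError(f"{path}: metabolite block lacks METABO")
        numeric = m.group(2).split("$NMUSED")[0]
        vals = np.array(
            re.findall(r"[-+]?\d*\.?\d+E[+-]\d+", numeric), dtype=float)
        if len(vals) < 2 * ndata:
            raise FormatError(f"{path}: metabolite {name} has too few data points")
        vals = vals[:2 * ndata]
        spec = vals[0::2] + 1j * vals[1::2]
        names.append(name)
        fids.append(to_fid(spec))
    if len(set(names)) != len(names):
        raise FormatError("duplicate metabolite names in basis")
    return BasisSet(names, np.array(fids), dwell, f0, ref)


# ---------------------------------------------------------------------------
# jMRUI .txt dialect
# ---------------------------------------------------------------------------

def write_jmrui_txt(basis: BasisSet, path) -> None:
    """Write a jMRUI-style text basis file (one signal block per metabolite)."""
    lines = [
        "jMRUI Data Textfile", "",
        f"PointsInDataset: {basis.n_timepoints}",
        f"DatasetsInFile: {len(basis)}",
        f"SamplingInterval: {basis.dwell_time * 1e3:.10g}",
        f"TransmitterFrequency: {basis.spectrometer_frequency * 1e6:.10g}",
        f"PpmReference: {basis.ppm_reference:.10g}",
        "SignalNames: " + ";".join(basis.names),
        "", "Signal and FFT", "sig(real)\tsig(imag)",
    ]
    for i, fid in enumerate(basis.fids):
        lines.append(f"Signal {i + 1} out of {len(basis)} in file")
        for v in fid:
            lines.append(f"{v.real:.10e}\t{v.imag:.10e}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_jmrui_txt(path: Path) -> BasisSet:
    text = path.read_text()

    def header(key, default=None):
        m = re.search(rf"^{key}:\s*(.+)$", text, re.M)
        if m is None:
            if default is None:
                raise FormatError(f"{path}: missing jMRUI header {key!r}")
            return default
        return m.group(1).strip()

    npts = int(header("PointsInDataset"))
    nsig = int(header("DatasetsInFile"))
    dwell = float(header("SamplingInterval")) * 1e-3  # ms -> s
    f0 = float(header("TransmitterFrequency")) * 1e-6  # Hz -> MHz
    ref = float(header("PpmReference", str(WATER_PPM)))
    names_hdr = header("SignalNames", "")
    names = ([n for n in names_hdr.split(";") if n]
             if names_hdr else [f"met{i + 1}" for i in range(nsig)])
    if len(names) != nsig:
        raise FormatError(f"{path}: SignalNames count does not match DatasetsInFile")
    blocks = re.split(r"Signal \d+ out of \d+ in file", text)[1:]
    if len(blocks) != nsig:
        raise FormatError(f"{path}: expected {nsig} signal blocks, found {len(blocks)}")
    fids = []
    for block in blocks:
        rows = re.findall(
            r"^\s*([-+0-9.eE]+)\s+([-+0-9.eE]+)", block, re.M)
        if len(rows) < npts:
            raise FormatError(f"{path}: signal block has too few samples")
        arr = np.array(rows[:npts], dtype=float)
        fids.append(arr[:, 0] + 1j * arr[:, 1])
    if len(set(names)) != len(names):
        raise FormatError("duplicate metabolite names in basis")
    return BasisSet(names, np.array(fids), dwell, f0, ref)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_basis(dir_or_file, dialect: str = "json") -> BasisSet:
    """Read a basis set from ``dir_or_file`` under the named dialect."""
    path = Path(dir_or_file)
    if dialect == "json":
        return _read_basis_json(path)
    if dialect == "lcmodel_basis":
        return _read_lcmodel_basis(path)
    if dialect == "jmrui_txt":
        return _read_jmrui_txt(path)
    raise FormatError(f"unknown basis dialect {dialect!r}")
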