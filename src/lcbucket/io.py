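"""mzML ingestion/export and sample manifests.

The ingestion boundary of the pipeline is centroided mzML: vendor raw
files are expected to be converted (and centroided) upstream, and profile
mode data is rejected outright.  Scan times are normalized to seconds at
read time, whatever the file's native unit, because every downstream
parameter (peak widths, bucket sizes) is stated in seconds.

Both directions are implemented against the mzML standard directly: the
reader handles plain and indexed mzML, 32/64-bit float binary arrays,
zlib or no compression, and minute- or second-valued scan times; the
writer emits 64-bit floats uncompressed.  Files written here are
readable by independent mzML software (Bioconductor's mzR is used as a
cross-check in the test suite).
"""

from __future__ import annotations

import base64
import zlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ManifestError,
    MzmlParseError,
    ProfileModeError,
    WindowMatchError,
)

__all__ = [
    "CentroidScan",
    "IsolationWindow",
    "AcquisitionScheme",
    "Run",
    "HONEY_VDIA_SCHEME",
    "read_mzml",
    "write_mzml",
    "load_manifest",
    "MANIFEST_COLUMNS",
]

#: Maximum distance (Da) between an MS2 precursor target and a scheme
#: window target for the scan to be assigned to that window.
WINDOW_MATCH_TOL = 0.5

MANIFEST_COLUMNS = ["path", "sample_id", "class_label", "method", "instrument_id", "batch"]


@dataclass(frozen=True)
class IsolationWindow:
    """One vDIA precursor isolation window.

    ``target_mass`` is the precursor isolation center (Da) and
    ``detect_range`` the (low, high) fragment detection range in Da.
    """

    window_id: str
    target_mass: float
    detect_range: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.detect_range
        if not lo < hi:
            raise ValueError(f"window {self.window_id}: detect range {lo} >= {hi}")


@dataclass(frozen=True)
class AcquisitionScheme:
    """MS1 full-scan range plus the (possibly empty) set of vDIA windows."""

    ms1_range: tuple[float, float]
    windows: tuple[IsolationWindow, ...] = ()

    def __post_init__(self):
        lo, hi = self.ms1_range
        if not lo < hi:
            raise ValueError(f"ms1_range {lo} >= {hi}")
        targets = [w.target_mass for w in self.windows]
        if len(set(targets)) != len(targets):
            raise ValueError("isolation windows overlap in target mass")
        object.__setattr__(self, "windows", tuple(self.windows))

    def match_window(self, target_mass: float) -> IsolationWindow:
        """Nearest-target window assignment (within ±0.5 Da)."""
        if not self.windows:
            raise WindowMatchError(
                f"MS2 precursor target {target_mass} Da but scheme declares no windows"
            )
        best = min(self.windows, key=lambda w: abs(w.target_mass - target_mass))
        if abs(best.target_mass - target_mass) > WINDOW_MATCH_TOL:
            raise WindowMatchError(
                f"MS2 precursor target {target_mass} Da matches no isolation window "
                f"(targets: {[w.target_mass for w in self.windows]})"
            )
        return best

    def window_by_id(self, window_id: str) -> IsolationWindow:
        for w in self.windows:
            if w.window_id == window_id:
                return w
        raise KeyError(window_id)

    def window_for_precursor_mz(self, mz: float) -> IsolationWindow:
        """Window whose isolation span covers a precursor m/z.

        Span boundaries are the midpoints between adjacent window targets,
        clipped to the MS1 range (the windows jointly tile the full scan).
        """
        if not self.windows:
            raise WindowMatchError("scheme declares no isolation windows")
        wins = sorted(self.windows, key=lambda w: w.target_mass)
        return min(wins, key=lambda w: abs(w.target_mass - mz))


#: The instrument vDIA scheme used throughout: full scan 100-1500 Da, six
#: isolation windows fragmenting 150/250/350/450/750/1250 Da with the
#: corresponding fragment detection ranges.
HONEY_VDIA_SCHEME = AcquisitionScheme(
    ms1_range=(100.0, 1500.0),
    windows=(
        IsolationWindow("w0150", 150.0, (50.0, 225.0)),
        IsolationWindow("w0250", 250.0, (50.0, 330.0)),
        IsolationWindow("w0350", 350.0, (50.0, 430.0)),
        IsolationWindow("w0450", 450.0, (50.0, 535.0)),
        IsolationWindow("w0750", 750.0, (69.0, 1045.0)),
        IsolationWindow("w1250", 1250.0, (104.0, 1555.0)),
    ),
)


@dataclass
class CentroidScan:
    """One centroided scan: parallel m/z / intensity arrays at one RT.

    Acquisition times are non-negative (enforced when writing mzML);
    scans warped onto a reference RT axis may carry slightly negative
    times, which downstream bucketing drops into its discard tally.
    """

    rt: float
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    window_id: Optional[str] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z values must be strictly ascending within a scan")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        if self.ms_level == 2 and self.window_id is None:
            raise ValueError("MS2 scan without an isolation window id")


@dataclass
class Run:
    """One LC-MS acquisition: ordered scans plus sample metadata."""

    run_id: str
    sample_id: str
    method: str  # "RP" | "HILIC"
    instrument_id: str
    scans: list[CentroidScan]
    scheme: AcquisitionScheme
    class_label: Optional[str] = None
    polarity: str = "positive"

    def __post_init__(self):
        if self.method not in ("RP", "HILIC"):
            raise ValueError(f"unknown chromatographic method {self.method!r}")
        if not self.scans:
            raise ValueError(f"run {self.run_id}: no scans")
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError(f"run {self.run_id}: scans not sorted by rt")
        known = {w.window_id for w in self.scheme.windows}
        for s in self.scans:
            if s.ms_level == 2 and s.window_id not in known:
                raise ValueError(
                    f"run {self.run_id}: MS2 scan window {s.window_id!r} not in scheme"
                )

    def ms1_scans(self) -> list[CentroidScan]:
        return [s for s in self.scans if s.ms_level == 1]

    def with_scan_rts(self, new_rts: Sequence[float]) -> "Run":
        """Copy of the run with scan RTs replaced (same order)."""
        scans = [
            CentroidScan(rt=float(t), ms_level=s.ms_level, mz=s.mz.copy(),
                         intensity=s.intensity.copy(), window_id=s.window_id)
            for s, t in zip(self.scans, new_rts)
        ]
        return replace(self, scans=scans)


# ---------------------------------------------------------------------------
# Reading


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, dict]:
    """accession -> {name, value, unit} for direct cvParam children."""
    out = {}
    for child in elem:
        if _strip(child.tag) == "cvParam":
            out[child.get("accession", child.get("name"))] = {
                "name": child.get("name", ""),
                "value": child.get("value", ""),
                "unit": child.get("unitName", ""),
            }
    return out


def _find(elem, *tags):
    """First descendant matching the namespace-stripped tag path."""
    current = [elem]
    for tag in tags:
        nxt = []
        for e in current:
            nxt.extend(c for c in e if _strip(c.tag) == tag)
        if not nxt:
            return None
        current = nxt
    return current[0]


def _decode_binary_array(arr_elem) -> tuple[str, np.ndarray]:
    params = _cv_params(arr_elem)
    kind = None
    if "MS:1000514" in params:
        kind = "mz"
    elif "MS:1000515" in params:
        kind = "intensity"
    dtype = "<f8" if "MS:1000523" in params else "<f4"
    compressed = "MS:1000574" in params  # zlib compression
    binary = _find(arr_elem, "binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if compressed and raw:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(spec_elem, path) -> tuple[float, int, Optional[float], np.ndarray, np.ndarray]:
    params = _cv_params(spec_elem)
    if "MS:1000128" in params:
        raise ProfileModeError(
            f"{path}: profile-mode spectrum found; convert to centroided "
            "mzML before import"
        )
    level = int(params.get("MS:1000511", {}).get("value", 1))
    scan = _find(spec_elem, "scanList", "scan")
    if scan is None:
        raise MzmlParseError(f"{path}: spectrum without scanList/scan")
    scan_params = _cv_params(scan)
    if "MS:1000016" not in scan_params:
        raise MzmlParseError(f"{path}: scan without a start time")
    t = float(scan_params["MS:1000016"]["value"])
    if "minute" in scan_params["MS:1000016"]["unit"]:
        t *= 60.0
    precursor_target = None
    if level >= 2:
        prec = _find(spec_elem, "precursorList", "precursor")
        if prec is None:
            raise MzmlParseError(f"{path}: MS2 spectrum without precursor information")
        iso = _find(prec, "isolationWindow")
        if iso is not None and "MS:1000827" in _cv_params(iso):
            precursor_target = float(_cv_params(iso)["MS:1000827"]["value"])
        else:
            si = _find(prec, "selectedIonList", "selectedIon")
            if si is not None and "MS:1000744" in _cv_params(si):
                precursor_target = float(_cv_params(si)["MS:1000744"]["value"])
        if precursor_target is None:
            raise MzmlParseError(f"{path}: MS2 spectrum without an isolation target m/z")
    mz = inten = None
    arr_list = _find(spec_elem, "binaryDataArrayList")
    if arr_list is not None:
        for arr in arr_list:
            if _strip(arr.tag) != "binaryDataArray":
                continue
            kind, values = _decode_binary_array(arr)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
    if mz is None or inten is None:
        raise MzmlParseError(f"{path}: spectrum without m/z or intensity array")
    return t, level, precursor_target, mz, inten


def read_mzml(
    path,
    *,
    sample_id: str,
    scheme: AcquisitionScheme,
    class_label: Optional[str] = None,
    method: str = "RP",
    instrument_id: str = "",
    polarity: str = "positive",
    run_id: Optional[str] = None,
) -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    Handles plain and indexed mzML.  MS2 scans are assigned to the
    scheme window whose precursor target is nearest (within 0.5 Da);
    anything further raises :class:`WindowMatchError` naming the
    offending mass.  Profile-mode spectra raise
    :class:`ProfileModeError` — centroid upstream first.
    """
    path = Path(path)
    scans: list[CentroidScan] = []
    try:
        context = ET.iterparse(str(path), events=("end",))
        saw_mzml = False
        for _, elem in context:
            tag = _strip(elem.tag)
            if tag in ("mzML", "indexedmzML"):
                saw_mzml = True
            if tag != "spectrum":
                continue
            rt, level, target, mz, inten = _parse_spectrum(elem, path)
            window_id = None
            if level == 2:
                window_id = scheme.match_window(target).window_id
            order = np.argsort(mz, kind="stable")
            scans.append(
                CentroidScan(rt=rt, ms_level=level, mz=mz[order],
                             intensity=inten[order], window_id=window_id)
            )
            elem.clear()
        if not saw_mzml:
            raise MzmlParseError(f"{path}: not an mzML document")
    except (ProfileModeError, WindowMatchError, MzmlParseError):
        raise
    except Exception as exc:
        raise MzmlParseError(f"cannot parse mzML file {path}: {exc}") from exc
    if not scans:
        raise MzmlParseError(f"{path}: no spectra found")
    scans.sort(key=lambda s: s.rt)
    return Run(
        run_id=run_id or path.stem,
        sample_id=sample_id,
        class_label=class_label,
        method=method,
        instrument_id=instrument_id,
        polarity=polarity,
        scans=scans,
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# Writing

_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent, accession, name, value="", **extra):
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": str(value)}
    attrs.update(extra)
    return ET.SubElement(parent, "cvParam", attrs)


def _binary_array(parent, values: np.ndarray, kind: str):
    data = np.asarray(values, dtype="<f8").tobytes()
    b64 = base64.b64encode(data).decode("ascii")
    arr = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(b64))})
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    if kind == "mz":
        _cv(arr, "MS:1000514", "m/z array", unitCvRef="MS",
            unitAccession="MS:1000040", unitName="m/z")
    else:
        _cv(arr, "MS:1000515", "intensity array", unitCvRef="MS",
            unitAccession="MS:1000131", unitName="number of detector counts")
    ET.SubElement(arr, "binary").text = b64


def write_mzml(run: Run, path) -> Path:
    """Serialize a :class:`Run` as centroided mzML.

    Scan times are written in seconds; MS2 spectra carry their window's
    precursor isolation target so the file round-trips through
    :func:`read_mzml` (and external mzML readers).
    """
    for s in run.scans:
        if s.mz.size == 0:
            raise ValueError(f"run {run.run_id}: empty scan at rt={s.rt}; refusing to write")
        if s.rt < 0:
            raise ValueError(f"run {run.run_id}: negative acquisition time {s.rt}")

    root = ET.Element("mzML", {"xmlns": _NS, "version": "1.1.0", "id": run.run_id})
    cvlist = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(cvlist, "cv", {
        "id": "MS", "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
        "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"})
    ET.SubElement(cvlist, "cv", {
        "id": "UO", "fullName": "Unit Ontology",
        "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"})
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")
    softlist = ET.SubElement(root, "softwareList", {"count": "1"})
    ET.SubElement(softlist, "software", {"id": "lcbucket", "version": "0.1.0"})
    iconf = ET.SubElement(root, "instrumentConfigurationList", {"count": "1"})
    ET.SubElement(iconf, "instrumentConfiguration", {"id": "IC1"})
    dplist = ET.SubElement(root, "dataProcessingList", {"count": "1"})
    dp = ET.SubElement(dplist, "dataProcessing", {"id": "DP1"})
    pm = ET.SubElement(dp, "processingMethod", {"order": "1", "softwareRef": "lcbucket"})
    _cv(pm, "MS:1000544", "Conversion to mzML")

    runel = ET.SubElement(root, "run", {"id": run.run_id,
                                        "defaultInstrumentConfigurationRef": "IC1"})
    speclist = ET.SubElement(runel, "spectrumList",
                             {"count": str(len(run.scans)),
                              "defaultDataProcessingRef": "DP1"})
    for i, scan in enumerate(run.scans):
        spec = ET.SubElement(speclist, "spectrum", {
            "index": str(i),
            "id": f"scan={i + 1}",
            "defaultArrayLength": str(scan.mz.size),
        })
        _cv(spec, "MS:1000511", "ms level", scan.ms_level)
        _cv(spec, "MS:1000127", "centroid spectrum")
        if scan.ms_level == 1:
            _cv(spec, "MS:1000579", "MS1 spectrum")
        else:
            _cv(spec, "MS:1000580", "MSn spectrum")
        scanlist = ET.SubElement(spec, "scanList", {"count": "1"})
        _cv(scanlist, "MS:1000795", "no combination")
        scanel = ET.SubElement(scanlist, "scan")
        _cv(scanel, "MS:1000016", "scan start time", repr(float(scan.rt)),
            unitCvRef="UO", unitAccession="UO:0000010", unitName="second")
        if scan.ms_level == 2:
            window = run.scheme.window_by_id(scan.window_id)
            plist = ET.SubElement(spec, "precursorList", {"count": "1"})
            prec = ET.SubElement(plist, "precursor")
            iso = ET.SubElement(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z",
                repr(window.target_mass), unitCvRef="MS",
                unitAccession="MS:1000040", unitName="m/z")
            silist = ET.SubElement(prec, "selectedIonList", {"count": "1"})
            si = ET.SubElement(silist, "selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z", repr(window.target_mass),
                unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
        arrlist = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrlist, scan.mz, "mz")
        _binary_array(arrlist, scan.intensity, "intensity")

    path = Path(path)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)
    return path


# ---------------------------------------------------------------------------
# Manifests


def load_manifest(path) -> pd.DataFrame:
    """Load and validate a delimited sample manifest.

    Required header: ``path,sample_id,class_label,method,instrument_id,batch``
    (comma or tab separated).  Paths must be unique; ``method`` must be RP
    or HILIC; empty class labels are normalized to the string "unknown".
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         keep_default_na=False)
    except Exception as exc:
        raise ManifestError(f"{path}: empty or unparseable manifest: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest column(s) {missing}")
    if len(df) == 0:
        raise ManifestError(f"{path}: manifest has no rows")
    dup = df["path"][df["path"].duplicated()]
    if len(dup):
        raise ManifestError(f"{path}: duplicate run paths {sorted(set(dup))}")
    bad = sorted(set(df["method"]) - {"RP", "HILIC"})
    if bad:
        raise ManifestError(f"{path}: unknown method value(s) {bad}; expected RP or HILIC")
    df = df.copy()
    df.loc[df["class_label"].str.strip() == "", "class_label"] = "unknown"
    return df[MANIFEST_COLUMNS]


def save_manifest(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df[MANIFEST_COLUMNS].to_csv(path, index=False)
    return path
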