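"""mzML reading and writing for centroided MS1 runs.

Both directions are self-contained: the writer emits minimal,
schema-conformant mzML (uncompressed 64-bit little-endian arrays, the
standard PSI-MS CV params for m/z / intensity arrays and scan start time),
and the reader parses the subset of mzML needed here — MS1 spectra with
base64-encoded binary arrays (64- or 32-bit floats, plain or zlib
compressed) and per-scan retention times in minutes or seconds.  Round
trips are exact; the writer's output is also verified against an external
mzML implementation in the test suite.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np

from .quantify import Scan, SpectrumRun

__all__ = ["read_mzml", "write_mzml"]

_NS = "{http://psi.hupo.org/ms/mzml}"

# CV accessions used on read
_ACC_SCAN_START = "MS:1000016"
_ACC_MS_LEVEL = "MS:1000511"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element) -> dict[str, ElementTree.Element]:
    return {
        cv.get("accession"): cv
        for cv in element
        if _strip(cv.tag) == "cvParam"
    }


def _decode_array(bda: ElementTree.Element) -> tuple[str, np.ndarray]:
    params = {}
    binary_text = ""
    for child in bda:
        tag = _strip(child.tag)
        if tag == "cvParam":
            params[child.get("accession")] = child
        elif tag == "binary":
            binary_text = child.text or ""
    raw = base64.b64decode(binary_text)
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in params else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    kind = "mz" if _ACC_MZ_ARRAY in params else "intensity" if _ACC_INT_ARRAY in params else ""
    return kind, values


def _parse_spectrum(spec: ElementTree.Element) -> Scan | None:
    direct = _cv_params(spec)
    level_param = direct.get(_ACC_MS_LEVEL)
    if level_param is not None and level_param.get("value") not in (None, "", "1"):
        return None

    rt = None
    mz = intensity = None
    for element in spec.iter():
        tag = _strip(element.tag)
        if tag == "cvParam" and element.get("accession") == _ACC_SCAN_START:
            rt = float(element.get("value"))
            if element.get("unitName", "minute") in ("second", "s"):
                rt /= 60.0
        elif tag == "binaryDataArray":
            kind, values = _decode_array(element)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                intensity = values
    if rt is None or mz is None or intensity is None:
        return None
    return Scan(rt=rt, mz=mz, intensity=intensity)


def read_mzml(path: str | Path) -> SpectrumRun:
    """Read centroided MS1 spectra from an mzML file."""
    tree = ElementTree.parse(str(path))
    scans: list[Scan] = []
    for spec in tree.iter():
        if _strip(spec.tag) != "spectrum":
            continue
        scan = _parse_spectrum(spec)
        if scan is not None:
            scans.append(scan)
    scans.sort(key=lambda s: s.rt)
    return SpectrumRun(scans=tuple(scans), metadata={"source": str(path)})


def _encode(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    return base64.b64encode(raw).decode("ascii")


_ARRAY_CV = {
    "mz": '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>',
    "intensity": '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>',
}


def _binary_array(kind: str, values: np.ndarray) -> str:
    b64 = _encode(values)
    return (
        f'<binaryDataArray encodedLength="{len(b64)}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
        f"{_ARRAY_CV[kind]}"
        f"<binary>{b64}</binary>"
        "</binaryDataArray>"
    )


def write_mzml(run: SpectrumRun, path: str | Path) -> None:
    """Write a run as minimal centroided-MS1 mzML."""
    run_id = escape(str(run.metadata.get("id", "simulated_run")), {'"': "&quot;"})
    parts: list[str] = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">',
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '<cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>',
        "</cvList>",
        '<fileDescription><fileContent>'
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum"/>'
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>'
        "</fileContent></fileDescription>",
        '<softwareList count="1"><software id="qconkit" version="0.1.0"/></softwareList>',
        '<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1"/></instrumentConfigurationList>',
        '<dataProcessingList count="1"><dataProcessing id="DP1">'
        '<processingMethod order="1" softwareRef="qconkit"/>'
        "</dataProcessing></dataProcessingList>",
        f'<run id="{run_id}" defaultInstrumentConfigurationRef="IC1">',
        f'<spectrumList count="{len(run.scans)}" defaultDataProcessingRef="DP1">',
    ]
    for i, scan in enumerate(run.scans):
        parts.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(scan.mz)}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum"/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>'
            '<scanList count="1">'
            '<cvParam cvRef="MS" accession="MS:1000795" name="no combination"/>'
            "<scan>"
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>'
            "</scan></scanList>"
            '<binaryDataArrayList count="2">'
            f"{_binary_array('mz', scan.mz)}"
            f"{_binary_array('intensity', scan.intensity)}"
            "</binaryDataArrayList>"
            "</spectrum>"
        )
    parts.append("</spectrumList></run></mzML>")
    Path(path).write_text("\n".join(parts))
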