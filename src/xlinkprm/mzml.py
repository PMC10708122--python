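"""Minimal mzML reader/writer for PRM runs.

The writer emits plain (non-indexed) mzML 1.1.0 with uncompressed 64-bit
float peak arrays, MS2 scans carrying isolation-window target m/z and scan
start time in minutes — the subset of the standard the rest of the package
needs for round-tripping simulated PRM acquisitions. The reader accepts
that subset plus common variations (32-bit floats, zlib compression,
seconds as the time unit) and is deliberately small: it extracts MS2 scans
with their isolation target, retention time and peak arrays, nothing else.
"""

from __future__ import annotations

import base64
import zlib
from xml.etree import ElementTree
from xml.sax.saxutils import quoteattr

import numpy as np

from .spectra import PrmRun, PrmScan


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_accessions(elem) -> dict[str, str]:
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("accession", "")] = child.get("value", "")
    return out


def _decode_binary_array(elem) -> tuple[str, np.ndarray]:
    acc = _cv_accessions(elem)
    dtype = "<f8" if "MS:1000523" in acc else "<f4"
    kind = "mz" if "MS:1000514" in acc else "intensity" if "MS:1000515" in acc else ""
    binary = ""
    for child in elem:
        if _local(child.tag) == "binary":
            binary = child.text or ""
    raw = base64.b64decode(binary)
    if "MS:1000574" in acc:  # zlib compression
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _iter_descendants(elem, name):
    for child in elem.iter():
        if _local(child.tag) == name:
            yield child


def read_mzml(path, sample_id: str = "", group: str = "") -> PrmRun:
    """Read MS2 scans from mzML, grouped by isolation-window target m/z.

    Raises ValueError when the file contains no MS2 scans with isolation
    metadata. Scan start times are converted to minutes when the file
    records them in seconds.
    """
    run = PrmRun(sample_id=sample_id, group=group)
    n_ms2 = 0
    for _, elem in ElementTree.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        acc = _cv_accessions(elem)
        if acc.get("MS:1000511") != "2":
            elem.clear()
            continue
        target = None
        for window in _iter_descendants(elem, "isolationWindow"):
            wacc = _cv_accessions(window)
            if "MS:1000827" in wacc:
                target = float(wacc["MS:1000827"])
        if target is None:
            for ion in _iter_descendants(elem, "selectedIon"):
                iacc = _cv_accessions(ion)
                if "MS:1000744" in iacc:
                    target = float(iacc["MS:1000744"])
        rt = 0.0
        for scan in _iter_descendants(elem, "scan"):
            sacc = _cv_accessions(scan)
            if "MS:1000016" in sacc:
                rt = float(sacc["MS:1000016"])
                for child in scan:
                    if (
                        _local(child.tag) == "cvParam"
                        and child.get("accession") == "MS:1000016"
                        and child.get("unitName") == "second"
                    ):
                        rt /= 60.0
        if target is None:
            elem.clear()
            continue
        arrays = {}
        for array_elem in _iter_descendants(elem, "binaryDataArray"):
            kind, values = _decode_binary_array(array_elem)
            if kind:
                arrays[kind] = values
        if "mz" in arrays and "intensity" in arrays:
            n_ms2 += 1
            run.scans_by_target.setdefault(round(target, 4), []).append(
                PrmScan(rt=rt, mz=arrays["mz"], intensity=arrays["intensity"])
            )
        elem.clear()
    if n_ms2 == 0:
        raise ValueError(f"{path}: no MS2 scans with isolation-window metadata")
    for scans in run.scans_by_target.values():
        scans.sort(key=lambda s: s.rt)
    return run

_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="xlinkprm" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="xlinkprm"/>
    </dataProcessing>
  </dataProcessingList>
"""


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(
        np.asarray(values, dtype="<f8").tobytes()
    ).decode("ascii")


def _binary_array(values: np.ndarray, kind: str) -> str:
    encoded = _b64(values)
    if kind == "mz":
        name = (
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
        )
    else:
        name = (
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" '
            'value="" unitCvRef="MS" unitAccession="MS:1000131" '
            'unitName="number of detector counts"/>'
        )
    return (
        f'        <binaryDataArray encodedLength="{len(encoded)}">\n'
        '          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f"          {name}\n"
        f"          <binary>{encoded}</binary>\n"
        "        </binaryDataArray>\n"
    )


def write_mzml(run: PrmRun, path) -> None:
    """Write a PRM run as plain mzML (MS2 scans grouped by isolation target)."""
    scans = [
        (target, scan)
        for target in sorted(run.scans_by_target)
        for scan in run.scans_by_target[target]
    ]
    parts = [_HEADER]
    parts.append(
        f'  <run id={quoteattr(run.sample_id or "prm_run")} '
        'defaultInstrumentConfigurationRef="IC1">\n'
        f'    <spectrumList count="{len(scans)}" defaultDataProcessingRef="DP1">\n'
    )
    for i, (target, scan) in enumerate(scans):
        n = len(scan.mz)
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{n}">\n'
            '        <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>\n'
            '        <scanList count="1">\n'
            '          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>\n'
            "          <scan>\n"
            '            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{scan.rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
            "          </scan>\n"
            "        </scanList>\n"
            '        <precursorList count="1">\n'
            "          <precursor>\n"
            "            <isolationWindow>\n"
            '              <cvParam cvRef="MS" accession="MS:1000827" '
            f'name="isolation window target m/z" value="{target:.4f}" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            "            </isolationWindow>\n"
            '            <selectedIonList count="1">\n'
            "              <selectedIon>\n"
            '                <cvParam cvRef="MS" accession="MS:1000744" '
            f'name="selected ion m/z" value="{target:.4f}" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            "              </selectedIon>\n"
            "            </selectedIonList>\n"
            "            <activation>\n"
            '              <cvParam cvRef="MS" accession="MS:1000422" '
            'name="beam-type collision-induced dissociation" value=""/>\n'
            "            </activation>\n"
            "          </precursor>\n"
            "        </precursorList>\n"
            '        <binaryDataArrayList count="2">\n'
        )
        parts.append(_binary_array(scan.mz, "mz"))
        parts.append(_binary_array(scan.intensity, "intensity"))
        parts.append("        </binaryDataArrayList>\n      </spectrum>\n")
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    with open(path, "w") as fh:
        fh.write("".join(parts))
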