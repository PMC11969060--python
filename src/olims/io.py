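"""Reading and writing centroid spectra: mzML and plain peak-list CSV.

The mzML layer is deliberately small: centroided spectra, 64-bit float
arrays, no compression, acquisition conditions as userParam entries. It
writes standards-conformant documents and reads back anything it writes
(and any similarly plain centroid mzML)."""

from __future__ import annotations

import base64
import csv
import struct
from pathlib import Path

import numpy as np
from lxml import etree

from .species import Polarity
from .spectrum import CentroidSpectrum, SpectrumError


def write_peaklist_csv(spectrum: CentroidSpectrum, path: str | Path) -> None:
    """Two-column ``mz,intensity`` CSV with polarity/conditions in ``#`` headers."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# polarity={spectrum.polarity.value}\n")
        for key, value in sorted(spectrum.metadata.items()):
            fh.write(f"# {key}={value}\n")
        writer = csv.writer(fh)
        writer.writerow(["mz", "intensity"])
        for m, i in zip(spectrum.mz, spectrum.intensity):
            writer.writerow([f"{m:.6f}", f"{i:.6f}"])


def read_peaklist_csv(path: str | Path) -> CentroidSpectrum:
    polarity = Polarity.NEGATIVE
    metadata: dict[str, str] = {}
    mz: list[float] = []
    intensity: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    key, value = key.strip(), value.strip()
                    if key == "polarity":
                        polarity = Polarity(value)
                    else:
                        metadata[key] = value
                continue
            first, _, second = line.partition(",")
            if first == "mz":
                continue
            mz.append(float(first))
            intensity.append(float(second))
    return CentroidSpectrum(np.array(mz), np.array(intensity), polarity, metadata)


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode_array(values: np.ndarray, cv_accession: str, cv_name: str) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    b64 = base64.b64encode(raw).decode()
    return (
        f'        <binaryDataArray encodedLength="{len(b64)}">\n'
        f'          <cvParam cvRef="MS" accession="{cv_accession}" name="{cv_name}"/>\n'
        f'          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>\n'
        f'          <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>\n'
        f"          <binary>{b64}</binary>\n"
        f"        </binaryDataArray>\n"
    )


def write_mzml(spectra: list[CentroidSpectrum], path: str | Path) -> None:
    """Write centroid spectra as minimal standards-conformant mzML.

    Acquisition conditions stored in each spectrum's ``metadata`` are
    serialized as userParam entries so a round trip preserves them.
    """
    if not spectra:
        raise SpectrumError("no spectra to write")
    parts = [_MZML_HEADER.format(count=len(spectra))]
    for index, spec in enumerate(spectra):
        pol_param = (
            '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan"/>'
            if spec.polarity is Polarity.NEGATIVE
            else '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan"/>'
        )
        user_params = "".join(
            f'        <userParam name="{k}" value="{v}"/>\n'
            for k, v in sorted(spec.metadata.items())
        )
        parts.append(
            f'      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(spec)}">\n'
            f'        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>\n'
            f"        {pol_param}\n"
            f"{user_params}"
            f'        <binaryDataArrayList count="2">\n'
            + _encode_array(spec.mz, "MS:1000514", "m/z array")
            + _encode_array(spec.intensity, "MS:1000515", "intensity array")
            + "        </binaryDataArrayList>\n"
            + "      </spectrum>\n"
        )
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))


_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(node) -> np.ndarray:
    binary = node.find(f"{_NS}binary")
    raw = base64.b64decode(binary.text or "")
    for param in node.findall(f"{_NS}cvParam"):
        if param.get("name") == "zlib compression":
            import zlib

            raw = zlib.decompress(raw)
    dtype = "<d"
    for param in node.findall(f"{_NS}cvParam"):
        if param.get("accession") == "MS:1000521":  # 32-bit float
            dtype = "<f"
    count = len(raw) // struct.calcsize(dtype)
    return np.array(struct.unpack(f"{dtype[0]}{count}{dtype[1]}", raw))


def read_mzml(path: str | Path) -> list[CentroidSpectrum]:
    """Read centroid spectra (and their userParam metadata) from mzML."""
    tree = etree.parse(str(path))
    out: list[CentroidSpectrum] = []
    for spectrum_node in tree.iter(f"{_NS}spectrum"):
        polarity = Polarity.NEGATIVE
        for param in spectrum_node.findall(f"{_NS}cvParam"):
            if param.get("name") == "positive scan":
                polarity = Polarity.POSITIVE
        metadata = {
            p.get("name"): p.get("value")
            for p in spectrum_node.findall(f"{_NS}userParam")
        }
        mz = intensity = None
        for array_node in spectrum_node.iter(f"{_NS}binaryDataArray"):
            names = {p.get("name") for p in array_node.findall(f"{_NS}cvParam")}
            values = _decode_binary_array(array_node)
            if "m/z array" in names:
                mz = values
            elif "intensity array" in names:
                intensity = values
        if mz is None or intensity is None:
            raise SpectrumError(f"spectrum in {path} lacks m/z or intensity array")
        keep = intensity > 0
        out.append(CentroidSpectrum(mz[keep], intensity[keep], polarity, metadata))
    return out


def read_spectra(path: str | Path) -> list[CentroidSpectrum]:
    """Dispatch on extension: .mzML or peak-list CSV."""
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return read_mzml(path)
    return [read_peaklist_csv(path)]
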