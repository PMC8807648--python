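"""Reading and writing spectra and sample metadata.

Spectra travel as :class:`RawSpectrum` records. Two on-disk formats are
supported: PSI mzML (one run per sample x matrix, shot spectra as scans) and
plain two-column ``mz,intensity`` CSV peak tables. Sample metadata is a
tab-separated table with columns ``sample_id, class_label, stage, split``.

The mzML layer is self-contained: the writer emits a minimal uncompressed
64-bit-float mzML document and the reader parses standard mzML binary data
arrays (64/32-bit float, zlib or uncompressed) directly from the XML.
Filenames follow ``<sample_id>__<matrix>.<ext>``.
"""

from __future__ import annotations

import base64
import csv
import re
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from xml.sax.saxutils import escape, quoteattr

import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd

from .constants import CLASSES, MATRICES, MZ_MAX, MZ_MIN, SPLITS, STAGES


class SpectraIOError(ValueError):
    """Malformed spectrum file or metadata table."""


@dataclass
class RawSpectrum:
    """One acquisition's m/z-intensity trace with provenance.

    ``mz`` is strictly increasing (Da); ``intensity`` is non-negative in
    arbitrary units. ``spot_index``/``shot_index`` locate the laser shot.
    """

    sample_id: str
    matrix_tag: str
    mz: np.ndarray
    intensity: np.ndarray
    spot_index: int = 0
    shot_index: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise SpectraIOError(
                f"m/z and intensity lengths differ: {self.mz.size} vs {self.intensity.size}"
            )
        if self.matrix_tag not in MATRICES:
            raise SpectraIOError(f"unknown matrix tag {self.matrix_tag!r}")

    def copy_with(self, mz: np.ndarray | None = None, intensity: np.ndarray | None = None) -> "RawSpectrum":
        return RawSpectrum(
            sample_id=self.sample_id,
            matrix_tag=self.matrix_tag,
            mz=self.mz.copy() if mz is None else np.asarray(mz, float),
            intensity=self.intensity.copy() if intensity is None else np.asarray(intensity, float),
            spot_index=self.spot_index,
            shot_index=self.shot_index,
        )


@dataclass
class Peak:
    mz: float
    intensity: float
    snr: float
    resolving_power: float


@dataclass
class PeakList:
    """Centroided peaks for one spectrum, sorted by m/z."""

    sample_id: str
    matrix_tag: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def __len__(self) -> int:
        return len(self.peaks)

    def mzs(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)


# ---------------------------------------------------------------------------
# helpers

_FILENAME_RE = re.compile(r"^(?P<sample>.+)__(?P<matrix>GNS|SiNW)$")
_ID_RE = re.compile(
    r"sample=(?P<sample>\S+)\s+matrix=(?P<matrix>GNS|SiNW)\s+spot=(?P<spot>\d+)\s+shot=(?P<shot>\d+)"
)


def _provenance_from_filename(path: Path) -> tuple[str, str | None]:
    m = _FILENAME_RE.match(path.stem)
    if m:
        return m.group("sample"), m.group("matrix")
    return path.stem, None


def _ensure_sorted(mz: np.ndarray, intensity: np.ndarray, origin: str) -> tuple[np.ndarray, np.ndarray]:
    if mz.size and np.any(np.diff(mz) < 0):
        warnings.warn(f"non-monotone m/z in {origin}; repaired by sorting", stacklevel=3)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
    return mz, intensity


def _clip_range(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = (mz >= MZ_MIN) & (mz <= MZ_MAX)
    return mz[keep], intensity[keep]


# ---------------------------------------------------------------------------
# mzML

def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


def _spectrum_xml(spec: RawSpectrum, index: int) -> str:
    native_id = (
        f"sample={spec.sample_id} matrix={spec.matrix_tag} "
        f"spot={spec.spot_index} shot={spec.shot_index}"
    )
    mz_b64 = _encode_array(spec.mz)
    int_b64 = _encode_array(spec.intensity)
    return f"""    <spectrum index="{index}" id={quoteattr(native_id)} defaultArrayLength="{spec.mz.size}">
      <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
      <binaryDataArrayList count="2">
        <binaryDataArray encodedLength="{len(mz_b64)}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
          <binary>{mz_b64}</binary>
        </binaryDataArray>
        <binaryDataArray encodedLength="{len(int_b64)}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
          <binary>{int_b64}</binary>
        </binaryDataArray>
      </binaryDataArrayList>
    </spectrum>
"""


def write_mzml(spectra: Sequence[RawSpectrum], path: str | Path) -> None:
    """Write spectra as one mzML run (minimal, uncompressed, 64-bit)."""
    spectra = list(spectra)
    if not spectra:
        raise SpectraIOError("refusing to write an empty spectrum list")
    path = Path(path)
    run_id = escape(path.stem)
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        '  <cvList count="1">\n'
        '    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology"'
        ' URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
        "  </cvList>\n"
        f'  <run id="{run_id}">\n'
        f'    <spectrumList count="{len(spectra)}">\n'
    ]
    for i, spec in enumerate(spectra):
        parts.append(_spectrum_xml(spec, i))
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    path.write_text("".join(parts))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda: ET.Element, origin: str) -> tuple[np.ndarray, str]:
    dtype = np.float64
    compressed = False
    kind = None
    payload = ""
    for child in bda.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = np.float32
            elif acc == "MS:1000523":
                dtype = np.float64
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    if kind is None:
        raise SpectraIOError(f"{origin}: binaryDataArray lacks an m/z or intensity cvParam")
    return values, kind


def read_mzml(path: str | Path) -> list[RawSpectrum]:
    path = Path(path)
    sample_default, matrix_default = _provenance_from_filename(path)
    out: list[RawSpectrum] = []
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SpectraIOError(f"failed to parse mzML file {path}: {exc}") from exc
    for elem in tree.getroot().iter():
        if _local(elem.tag) != "spectrum":
            continue
        native_id = elem.get("id", "")
        origin = f"{path.name} id {native_id!r}"
        arrays: dict[str, np.ndarray] = {}
        for bda in elem.iter():
            if _local(bda.tag) == "binaryDataArray":
                values, kind = _decode_binary_array(bda, origin)
                arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise SpectraIOError(f"{origin}: missing m/z or intensity array")
        m = _ID_RE.search(native_id)
        if m:
            sample, matrix = m.group("sample"), m.group("matrix")
            spot, shot = int(m.group("spot")), int(m.group("shot"))
        else:
            sample, matrix = sample_default, matrix_default
            spot, shot = 0, len(out)
        if matrix is None:
            raise SpectraIOError(
                f"{path.name}: matrix tag not found in spectrum id {native_id!r} or filename"
            )
        mz, intensity = _ensure_sorted(arrays["mz"], arrays["intensity"], origin)
        mz, intensity = _clip_range(mz, intensity)
        out.append(
            RawSpectrum(
                sample_id=sample,
                matrix_tag=matrix,
                mz=mz,
                intensity=intensity,
                spot_index=spot,
                shot_index=shot,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV peak tables

def write_csv(spectrum: RawSpectrum, path: str | Path) -> None:
    """Write one spectrum as a two-column ``mz,intensity`` CSV table."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mz", "intensity"])
        for mz, inten in zip(spectrum.mz, spectrum.intensity):
            writer.writerow([repr(float(mz)), repr(float(inten))])


def read_csv(path: str | Path, sample_id: str | None = None, matrix_tag: str | None = None) -> RawSpectrum:
    path = Path(path)
    sample_default, matrix_default = _provenance_from_filename(path)
    sample_id = sample_id or sample_default
    matrix_tag = matrix_tag or matrix_default
    if matrix_tag is None:
        raise SpectraIOError(
            f"{path.name}: matrix tag must come from the filename convention "
            "'<sample>__<matrix>.csv' or be passed explicitly"
        )
    mzs: list[float] = []
    intens: list[float] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip().lower() for c in header[:2]] != ["mz", "intensity"]:
            raise SpectraIOError(f"{path.name}: expected header 'mz,intensity', got {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                mzs.append(float(row[0]))
                intens.append(float(row[1]))
            except (ValueError, IndexError) as exc:
                raise SpectraIOError(f"{path.name}: bad record at line {lineno}: {row!r}") from exc
    mz, intensity = _ensure_sorted(np.array(mzs), np.array(intens), path.name)
    mz, intensity = _clip_range(mz, intensity)
    return RawSpectrum(sample_id=sample_id, matrix_tag=matrix_tag, mz=mz, intensity=intensity)


# ---------------------------------------------------------------------------
# dispatch

def read_spectra(path: str | Path, format: str | None = None) -> list[RawSpectrum]:
    """Read spectra from an mzML or CSV file (format inferred from suffix)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mzml":
        return read_mzml(path)
    if fmt == "csv":
        return [read_csv(path)]
    raise SpectraIOError(f"unsupported spectrum format {fmt!r}")


def write_spectra(spectra: Sequence[RawSpectrum], path: str | Path, format: str | None = None) -> None:
    """Write spectra to mzML (many per file) or CSV (single spectrum)."""
    spectra = list(spectra)
    if not spectra:
        raise SpectraIOError("refusing to write an empty spectrum list")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mzml":
        write_mzml(spectra, path)
    elif fmt == "csv":
        if len(spectra) != 1:
            raise SpectraIOError("CSV holds exactly one spectrum per file")
        write_csv(spectra[0], path)
    else:
        raise SpectraIOError(f"unsupported spectrum format {fmt!r}")


def spectrum_filename(sample_id: str, matrix_tag: str, ext: str = "mzML") -> str:
    return f"{sample_id}__{matrix_tag}.{ext}"


# ---------------------------------------------------------------------------
# sample metadata tables

_TABLE_COLUMNS = ["sample_id", "class_label", "stage", "split"]


def _validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SpectraIOError(f"sample table missing columns: {missing}")
    table = table[_TABLE_COLUMNS].copy()
    table["sample_id"] = table["sample_id"].astype(str)
    dup = table["sample_id"][table["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise SpectraIOError(f"duplicate sample_id values: {dup}")
    for col, allowed in [("class_label", CLASSES), ("stage", STAGES), ("split", SPLITS)]:
        bad = sorted(set(table[col].astype(str)) - set(allowed))
        if bad:
            raise SpectraIOError(f"unknown {col} values: {bad}")
    bad_stage = table.loc[(table["class_label"] == "HC") & (table["stage"] != "none"), "sample_id"]
    if len(bad_stage):
        raise SpectraIOError(f"HC samples must have stage 'none': {bad_stage.tolist()}")
    return table


def read_sample_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return _validate_sample_table(table)


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    _validate_sample_table(pd.DataFrame(table)).to_csv(path, sep="\t", index=False)
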