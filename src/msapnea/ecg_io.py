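"""Reading and writing ECG records, per-minute apnea annotations and manifests.

Records travel as WFDB-style pairs (``<name>.hea`` header + ``<name>.dat``
16-bit samples) or as plain two-column delimited text (time, amplitude).
Per-minute apnea annotations use either a symbol stream (one ``N``/``A`` per
line, WFDB apnea-annotation style) or the sidecar ``minute_index,label``
delimited format written by :mod:`msapnea.synth`.

Conventions: sample indices are 0-based; minute ``k`` covers samples
``[k*60*fs, (k+1)*60*fs)`` (half-open). Labels that extend past the last
full minute of signal are dropped with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: label values used throughout the package
LABEL_NORMAL = "N"
LABEL_APNEA = "AH"

#: ADC gain used when writing 16-bit WFDB samples (adu per mV)
DEFAULT_ADC_GAIN = 200.0


@dataclass
class ECGRecord:
    """Single-channel ECG: samples in mV plus optional per-minute labels."""

    record_id: str
    samples: np.ndarray
    sampling_rate: float
    minute_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.sampling_rate

    @property
    def n_full_minutes(self) -> int:
        return int(len(self.samples) // (60 * self.sampling_rate))


@dataclass
class DatasetManifest:
    """List of (record path, annotation path, split tag) entries."""

    entries: list[dict] = field(default_factory=list)

    VALID_SPLITS = ("train", "test")

    def add(self, record: str | Path, annotations: str | Path, split: str) -> None:
        if split not in self.VALID_SPLITS:
            raise ValueError(f"split must be one of {self.VALID_SPLITS}, got {split!r}")
        self.entries.append(
            {"record": str(record), "annotations": str(annotations), "split": split}
        )

    def save(self, path: str | Path) -> None:
        root = Path(path).resolve().parent
        entries = []
        for e in self.entries:
            e2 = dict(e)
            for key in ("record", "annotations"):
                p = Path(e2[key]).resolve()
                try:  # store relative to the manifest so the run dir can move
                    e2[key] = str(p.relative_to(root))
                except ValueError:
                    e2[key] = str(p)
            entries.append(e2)
        with open(path, "w") as fh:
            yaml.safe_dump({"records": entries}, fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        manifest = cls()
        for entry in raw.get("records", []):
            manifest.add(entry["record"], entry["annotations"], entry["split"])
        root = Path(path).parent
        for entry in manifest.entries:
            for key in ("record", "annotations"):
                p = Path(entry[key])
                if not p.is_absolute():
                    entry[key] = str(root / p)
        return manifest

    def split(self, tag: str) -> list[dict]:
        return [e for e in self.entries if e["split"] == tag]


# ---------------------------------------------------------------------------
# WFDB-style header + 16-bit .dat  (single signal, format 16, little-endian)
# ---------------------------------------------------------------------------

def write_record(record: ECGRecord, directory: str | Path,
                 adc_gain: float = DEFAULT_ADC_GAIN) -> Path:
    """Write ``<record_id>.hea`` / ``<record_id>.dat``; returns the header path.

    Samples are quantized to ``1/adc_gain`` mV (16-bit ADC emulation).
    Values outside the int16 range raise rather than silently clip.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adc = np.round(record.samples * adc_gain)
    if adc.size and (adc.max() > 32767 or adc.min() < -32768):
        raise ValueError("samples exceed the 16-bit ADC range at this gain")
    adc = adc.astype("<i2")

    name = record.record_id
    fs = record.sampling_rate
    fs_str = f"{int(fs)}" if float(fs).is_integer() else f"{fs:g}"
    hea = directory / f"{name}.hea"
    with open(hea, "w") as fh:
        fh.write(f"{name} 1 {fs_str} {len(adc)}\n")
        fh.write(f"{name}.dat 16 {adc_gain:g} 16 0 0 0 0 ECG\n")
    adc.tofile(directory / f"{name}.dat")
    return hea


def _read_wfdb(header_path: Path) -> ECGRecord:
    lines = [ln.strip() for ln in header_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty WFDB header: {header_path}")
    head = lines[0].split()
    if len(head) < 3:
        raise ValueError(f"unparseable WFDB header line: {lines[0]!r}")
    name = head[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0])  # fs may carry a counter-freq suffix
    if n_sig < 1 or len(lines) < 2:
        raise ValueError(f"header declares no signals: {header_path}")
    sig = lines[1].split()
    dat_name, fmt = sig[0], sig[1]
    if fmt.split("+")[0] not in ("16",):
        raise ValueError(f"unsupported WFDB format {fmt!r} (only 16)")
    # gain may look like "200", "200/mV" or "200(0)/mV"
    gain_tok = sig[2].split("/")[0].split("(")[0] if len(sig) > 2 else ""
    gain = float(gain_tok) if gain_tok else DEFAULT_ADC_GAIN
    if gain == 0:
        gain = DEFAULT_ADC_GAIN
    dat_path = header_path.parent / dat_name
    raw = np.fromfile(dat_path, dtype="<i2")
    if n_sig > 1:  # interleaved multi-signal .dat: keep channel 0
        raw = raw[::n_sig]
    return ECGRecord(record_id=name, samples=raw.astype(np.float64) / gain,
                     sampling_rate=fs)


def _read_two_column(path: Path) -> ECGRecord:
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        raise ValueError(f"empty ECG text file: {path}")
    if data.shape[1] < 2:
        raise ValueError(f"expected two columns (time, amplitude) in {path}")
    t, v = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError(f"need at least 2 samples in {path}")
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"non-monotonic time column in {path} at row {bad}")
    fs = 1.0 / float(np.median(dt))
    return ECGRecord(record_id=path.stem, samples=v, sampling_rate=fs)


def read_record(path: str | Path) -> ECGRecord:
    """Read a WFDB header (``.hea``) or a two-column delimited text file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    if path.suffix == ".hea":
        return _read_wfdb(path)
    return _read_two_column(path)


# ---------------------------------------------------------------------------
# Per-minute annotations
# ---------------------------------------------------------------------------

_SYMBOL_MAP = {"A": LABEL_APNEA, "N": LABEL_NORMAL,
               LABEL_APNEA: LABEL_APNEA, LABEL_NORMAL: LABEL_NORMAL}


def read_minute_annotations(path: str | Path) -> list[str]:
    """One label (``N``/``AH``) per annotated minute, order preserved.

    Accepts the sidecar ``minute_index,label`` format or a bare symbol
    stream (one ``N``/``A`` per line). Unknown symbols raise with the
    offending symbol and line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    labels: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("minute"):
                continue
            symbol = line.split(",")[-1].strip() if "," in line else line
            if symbol not in _SYMBOL_MAP:
                raise ValueError(
                    f"unknown annotation symbol {symbol!r} at line {lineno} of {path}"
                )
            labels.append(_SYMBOL_MAP[symbol])
    return labels


def write_minute_annotations(labels: Sequence[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("minute_index,label\n")
        for k, lab in enumerate(labels):
            fh.write(f"{k},{lab}\n")
    return path


def attach_annotations(record: ECGRecord, labels: Sequence[str]) -> ECGRecord:
    """Attach labels, dropping any beyond the last full minute of signal."""
    n = record.n_full_minutes
    labels = list(labels)
    if len(labels) > n:
        logger.warning(
            "record %s: dropping %d label(s) beyond the last full minute "
            "(%d labels, %d full minutes)",
            record.record_id, len(labels) - n, len(labels), n,
        )
        labels = labels[:n]
    record.minute_labels = labels
    return record
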