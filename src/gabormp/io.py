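"""Epoch and book file formats.

Epochs travel either as raw little-endian float32 binary (multiplexed
channel-fastest: channel index varies fastest, then time, then trial) with a
JSON sidecar header ``<path>.hdr.json``, or as delimited text with one column
per channel (single-trial only).  Samples are calibrated to microvolts on
read (data = raw * calibration).

Books (decompositions) are structured text: a provenance header (dictionary
parameters, stopping rule, sampling metadata) followed by one record per
atom -- iteration, family, u [samples], f [Hz], omega [rad/sample],
s [samples], and per-channel/per-trial weight/phase pairs -- printed at 17
significant digits for a lossless float64 round trip.  Books without a
provenance header are rejected: every decomposition must be reproducible
from its file alone.

Readers reject malformed input (size mismatches, non-finite samples, missing
headers) instead of guessing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mp import BookEntry, Decomposition

__all__ = [
    "EpochHeader",
    "TrialMatrix",
    "read_epoch",
    "write_epoch",
    "read_book",
    "write_book",
]

_BOOK_MAGIC = "# gabormp book v1"


@dataclass
class EpochHeader:
    """Sidecar metadata of a stored epoch."""

    n_samples: int
    n_channels: int = 1
    n_trials: int = 1
    fs: float = 1.0
    calibration: float = 1.0
    channel_labels: list[str] = field(default_factory=list)
    encoding: str = "float32-le"  # or "text"

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_channels, self.n_trials) < 1:
            raise ValueError("all counts must be >= 1")
        if self.fs <= 0.0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel label count does not match n_channels")


@dataclass
class TrialMatrix:
    """Calibrated channels x trials x time signal block (microvolts)."""

    data: np.ndarray  # (n_channels, n_trials, n_samples), float64, uV
    fs: float = 1.0
    calibration: float = 1.0
    channel_labels: list[str] = field(default_factory=list)
    montage: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[None, None, :]
        elif self.data.ndim == 2:
            self.data = self.data[:, None, :]
        if self.data.ndim != 3:
            raise ValueError("data must be (n_channels, n_trials, n_samples)")
        if self.fs <= 0.0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def header(self, encoding: str = "float32-le") -> EpochHeader:
        return EpochHeader(
            n_samples=self.n_samples,
            n_channels=self.n_channels,
            n_trials=self.n_trials,
            fs=self.fs,
            calibration=self.calibration,
            channel_labels=list(self.channel_labels),
            encoding=encoding,
        )


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".hdr.json")


def write_epoch(matrix: TrialMatrix, path, fmt: str = "binary") -> None:
    """Write an epoch as raw float32 binary or delimited text, plus sidecar.

    Binary multiplexing is channel-fastest; text holds one column per channel
    and supports single-trial data only.
    """
    path = Path(path)
    if fmt == "binary":
        header = matrix.header("float32-le")
        raw = (matrix.data / matrix.calibration).astype("<f4")
        # channel-fastest: (trial, time, channel)
        raw.transpose(1, 2, 0).tofile(path)
    elif fmt == "text":
        if matrix.n_trials != 1:
            raise ValueError("text epochs support single-trial data only")
        header = matrix.header("text")
        raw = matrix.data[:, 0, :] / matrix.calibration
        np.savetxt(path, raw.T, fmt="%.9g", delimiter="\t")
    else:
        raise ValueError(f"unknown epoch format {fmt!r}")
    _sidecar_path(path).write_text(json.dumps(header.__dict__, indent=1) + "\n")


def read_epoch(path, header: EpochHeader | None = None) -> TrialMatrix:
    """Read an epoch written by :func:`write_epoch` into a calibrated
    TrialMatrix.

    The sidecar header is used unless an explicit header is given.  Size
    mismatches and non-finite samples are rejected.
    """
    path = Path(path)
    if header is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar header {sidecar}")
        header = EpochHeader(**json.loads(sidecar.read_text()))
    expected = header.n_samples * header.n_channels * header.n_trials
    if header.encoding == "float32-le":
        raw = np.fromfile(path, dtype="<f4")
        if raw.size != expected:
            raise ValueError(
                f"epoch size mismatch: header promises {expected} samples, "
                f"file holds {raw.size}"
            )
        data = raw.reshape(header.n_trials, header.n_samples, header.n_channels)
        data = data.transpose(2, 0, 1).astype(float)
    elif header.encoding == "text":
        raw = np.loadtxt(path, ndmin=2)
        if raw.shape != (header.n_samples, header.n_channels):
            raise ValueError(
                f"epoch size mismatch: header promises "
                f"{(header.n_samples, header.n_channels)}, file holds {raw.shape}"
            )
        data = raw.T[:, None, :]
    else:
        raise ValueError(f"unknown encoding {header.encoding!r}")
    data = data * header.calibration
    if not np.all(np.isfinite(data)):
        raise ValueError("epoch contains non-finite samples")
    return TrialMatrix(
        data=data,
        fs=header.fs,
        calibration=header.calibration,
        channel_labels=list(header.channel_labels),
    )


# ---------------------------------------------------------------------------
# books


def _fmt(x) -> str:
    if x is None:
        return "nan"
    return f"{float(x):.17g}"


def write_book(decomposition: Decomposition, path) -> None:
    """Serialize a decomposition with full provenance (lossless)."""
    dec = decomposition
    lines = [_BOOK_MAGIC]
    meta = {
        "n_samples": dec.n_samples,
        "n_channels": dec.n_channels,
        "n_trials": dec.n_trials,
        "fs": dec.fs,
        "calibration": dec.calibration,
        "signal_energy": dec.signal_energy,
        "provenance": dec.provenance,
    }
    lines.append("# meta " + json.dumps(meta))
    lines.append(
        "# residual_energy " + " ".join(_fmt(e) for e in dec.residual_energy)
    )
    lines.append(
        "# columns iteration family u_samples f_hz omega_rad s_samples "
        "then weight,phase per (channel,trial), channel-major"
    )
    for e in dec.entries:
        f_hz = e.omega * dec.fs / (2.0 * math.pi) if e.omega is not None else None
        cols = [
            str(e.iteration),
            e.family,
            _fmt(e.u),
            _fmt(f_hz),
            _fmt(e.omega),
            _fmt(e.s),
        ]
        for w, p in zip(e.weights.ravel(), e.phases.ravel()):
            cols.append(_fmt(w))
            cols.append(_fmt(p))
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse(x: str) -> float | None:
    v = float(x)
    return None if math.isnan(v) else v


def read_book(path) -> Decomposition:
    """Read a book written by :func:`write_book`.

    Books lacking the provenance header are rejected.
    """
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != _BOOK_MAGIC:
        raise ValueError("not a gabormp book (missing magic line)")
    meta = None
    residual_energy = None
    entries: list[BookEntry] = []
    for line in text[1:]:
        line = line.strip()
        if not line:
            continue
        if line.startswith("# meta "):
            meta = json.loads(line[len("# meta ") :])
            continue
        if line.startswith("# residual_energy"):
            vals = line.split()[2:]
            residual_energy = np.array([float(v) for v in vals])
            continue
        if line.startswith("#"):
            continue
        if meta is None:
            raise ValueError("book record appears before the provenance header")
        cols = line.split("\t")
        it = int(cols[0])
        family = cols[1]
        u = _parse(cols[2])
        omega = _parse(cols[4])
        s = _parse(cols[5])
        wp = [float(c) for c in cols[6:]]
        n_c, n_k = meta["n_channels"], meta["n_trials"]
        if len(wp) != 2 * n_c * n_k:
            raise ValueError(
                f"record holds {len(wp) // 2} weight/phase pairs, "
                f"expected {n_c * n_k}"
            )
        weights = np.array(wp[0::2]).reshape(n_c, n_k)
        phases = np.array(wp[1::2]).reshape(n_c, n_k)
        entries.append(
            BookEntry(
                iteration=it, family=family, u=u, omega=omega, s=s,
                weights=weights, phases=phases,
            )
        )
    if meta is None or not meta.get("provenance"):
        raise ValueError("book lacks a provenance header; refusing to load")
    if residual_energy is None:
        residual_energy = np.array([meta["signal_energy"]])
    return Decomposition(
        entries=entries,
        residual_energy=residual_energy,
        signal_energy=meta["signal_energy"],
        n_samples=meta["n_samples"],
        n_channels=meta["n_channels"],
        n_trials=meta["n_trials"],
        fs=meta["fs"],
        calibration=meta["calibration"],
        provenance=meta["provenance"],
    )
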