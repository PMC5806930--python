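"""Recording sessions, electrode grids, and the two block types the pipeline analyzes.

A :class:`RecordingSession` is a multichannel voltage matrix with a sampling
rate, an electrode grid layout, and clinical annotations (seizure intervals,
exclusion intervals, and the expert "electrodes of interest").  The analysis
operates on 10-second :class:`Block` windows of two kinds: *ictal* blocks
anchored at each annotated seizure start, and *rest* blocks sampled uniformly
at random from the seizure-free, artifact-free remainder of the recording.

Conventions: sample indices are 0-based, time intervals are half-open
``[start, end)`` in seconds.
"""

from __future__ import annotations

import json
import logging
import string
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GridLayout",
    "Block",
    "RecordingSession",
    "load_session",
    "save_session",
    "write_edf",
    "extract_ictal_blocks",
    "sample_rest_starts",
    "sample_rest_blocks",
    "admissible_rest_intervals",
]


def _validate_intervals(intervals, t_max, name):
    out = []
    for iv in intervals:
        s, e = float(iv[0]), float(iv[1])
        if not (0.0 <= s < e <= t_max + 1e-9):
            raise ValueError(f"{name} interval ({s}, {e}) outside recording [0, {t_max:.3f}]")
        out.append((s, e))
    return out


@dataclass(frozen=True)
class GridLayout:
    """Rectangular electrode grid with a bijection between (row, col) and labels.

    The default labelling follows the clinical digit-letter scheme: row ``r``
    (1-based) and column ``c`` map to ``f"{r}{ABC...[c]}"`` so the top-left
    electrode of a 6x8 grid is ``1A`` and the bottom-right is ``6H``.
    """

    n_rows: int
    n_cols: int
    labels: tuple[str, ...] = ()  # row-major; filled by __post_init__ if empty

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not self.labels:
            if self.n_cols > 26:
                raise ValueError("default labelling supports at most 26 columns")
            labs = tuple(
                f"{r + 1}{string.ascii_uppercase[c]}"
                for r in range(self.n_rows)
                for c in range(self.n_cols)
            )
            object.__setattr__(self, "labels", labs)
        if len(self.labels) != self.n_rows * self.n_cols:
            raise ValueError("labels must have n_rows * n_cols entries")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate grid labels")

    @property
    def n_nodes(self) -> int:
        return self.n_rows * self.n_cols

    def label_of(self, row: int, col: int) -> str:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        return self.labels[row * self.n_cols + col]

    def position_of(self, label: str) -> tuple[int, int]:
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown grid label {label!r}") from None
        return divmod(idx, self.n_cols)

    def index_of(self, label: str) -> int:
        r, c = self.position_of(label)
        return r * self.n_cols + c

    def to_dict(self) -> dict:
        return {"n_rows": self.n_rows, "n_cols": self.n_cols, "labels": list(self.labels)}

    @classmethod
    def from_dict(cls, d: dict) -> "GridLayout":
        return cls(int(d["n_rows"]), int(d["n_cols"]), tuple(d.get("labels", ())))


@dataclass
class Block:
    """One fixed-length analysis window: a T x N matrix plus its provenance."""

    data: np.ndarray
    fs: float
    start_time: float
    label: str  # "ictal" | "rest" | "pre_ictal"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("block data must be T x N")
        if self.label not in ("ictal", "rest", "pre_ictal"):
            raise ValueError(f"unknown block label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class RecordingSession:
    """Validated multichannel session: signal, annotations, and grid geometry."""

    signal: np.ndarray  # T_total x N, microvolts
    fs: float
    channel_labels: list[str]
    grid: GridLayout
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)
    exclusion_intervals: list[tuple[float, float]] = field(default_factory=list)
    eoi: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a T x N matrix")
        n = self.signal.shape[1]
        if n != self.grid.n_nodes:
            raise ValueError(
                f"{n} channels do not match {self.grid.n_rows}x{self.grid.n_cols} grid"
            )
        if len(self.channel_labels) != n:
            raise ValueError("channel_labels length mismatch")
        if len(set(self.channel_labels)) != n:
            raise ValueError("duplicate channel labels")
        unknown = set(self.channel_labels) - set(self.grid.labels)
        if unknown:
            raise ValueError(f"channels not on the grid: {sorted(unknown)}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        t_max = self.duration
        self.seizure_intervals = _validate_intervals(self.seizure_intervals, t_max, "seizure")
        self.exclusion_intervals = _validate_intervals(
            self.exclusion_intervals, t_max, "exclusion"
        )
        self.eoi = set(self.eoi)
        bad_eoi = self.eoi - set(self.channel_labels)
        if bad_eoi:
            raise ValueError(f"EOI labels not among channels: {sorted(bad_eoi)}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.signal.shape[0] / self.fs

    @property
    def n_seizures(self) -> int:
        return len(self.seizure_intervals)

    def annotations_dict(self) -> dict:
        return {
            "fs": self.fs,
            "channel_labels": list(self.channel_labels),
            "grid": self.grid.to_dict(),
            "seizures": [list(iv) for iv in self.seizure_intervals],
            "exclusions": [list(iv) for iv in self.exclusion_intervals],
            "eoi": sorted(self.eoi),
        }


# ---------------------------------------------------------------------------
# Session container I/O
#
# The native container is a ``.npy`` signal matrix next to a JSON sidecar
# holding the sampling rate, labels, grid, and annotations.  EDF files are
# read through mne (if installed) with the same JSON sidecar for annotations.
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_session(session: RecordingSession, path: str | Path) -> Path:
    """Write ``<path>.npy`` (signal) and ``<path>.json`` (header + annotations)."""
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, session.signal)
    _sidecar_path(path).write_text(json.dumps(session.annotations_dict(), indent=1))
    return path


def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs_per_chan = set(raw.info["sfreq"] for _ in [0])
    if len(fs_per_chan) != 1:
        raise ValueError("sampling-rate mismatch across channels")
    # mne returns volts; convert back to microvolts
    return raw.get_data().T * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def load_session(
    path: str | Path,
    annotations: str | Path | None = None,
) -> RecordingSession:
    """Load a session from the native ``.npy``+JSON container or from EDF.

    ``annotations`` defaults to the JSON sidecar next to ``path``.  Channels
    present in the file but absent from the annotated grid are dropped with a
    logged warning; a grid label with no matching channel is an error.
    """
    path = Path(path)
    ann_path = Path(annotations) if annotations is not None else _sidecar_path(path)
    if not ann_path.exists():
        raise FileNotFoundError(f"missing annotation file {ann_path}")
    meta = json.loads(ann_path.read_text())
    grid = GridLayout.from_dict(meta["grid"])

    if path.suffix.lower() == ".edf":
        signal, fs, file_labels = _read_edf(path)
    elif path.suffix == ".npy":
        signal = np.load(path)
        fs = float(meta["fs"])
        file_labels = list(meta["channel_labels"])
    else:
        raise ValueError(f"unsupported session container {path.suffix!r}")

    wanted = meta.get("channel_labels", list(grid.labels))
    missing = [lab for lab in wanted if lab not in file_labels]
    if missing:
        raise ValueError(f"annotated channels absent from the file: {missing}")
    extra = [lab for lab in file_labels if lab not in wanted]
    if extra:
        logger.warning("dropping %d channels not on the analyzed grid: %s", len(extra), extra)
    cols = [file_labels.index(lab) for lab in wanted]
    signal = signal[:, cols]

    return RecordingSession(
        signal=signal,
        fs=fs,
        channel_labels=list(wanted),
        grid=grid,
        seizure_intervals=[tuple(iv) for iv in meta.get("seizures", [])],
        exclusion_intervals=[tuple(iv) for iv in meta.get("exclusions", [])],
        eoi=set(meta.get("eoi", [])),
    )


def write_edf(session: RecordingSession, path: str | Path) -> Path:
    """Write a plain 16-bit EDF file (1-second data records).

    Minimal writer covering the fixed-rate, uniform-channel case used here;
    annotations still travel in the JSON sidecar.
    """
    path = Path(path)
    fs = session.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_chan = session.n_channels
    n_records = session.signal.shape[0] // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    sig = session.signal[: n_records * fs]

    phys_min = float(np.floor(sig.min())) if sig.size else -1.0
    phys_max = float(np.ceil(sig.max())) if sig.size else 1.0
    if phys_max <= phys_min:
        phys_max = phys_min + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((sig - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_chan)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(n_chan), 4),
        ]
    )
    per_field = [
        [pad(lab, 16) for lab in session.channel_labels],
        [pad("ECoG", 80)] * n_chan,
        [pad("uV", 8)] * n_chan,
        [pad(f"{phys_min:g}", 8)] * n_chan,
        [pad(f"{phys_max:g}", 8)] * n_chan,
        [pad(str(dig_min), 8)] * n_chan,
        [pad(str(dig_max), 8)] * n_chan,
        [pad("", 80)] * n_chan,
        [pad(str(fs), 8)] * n_chan,
        [pad("", 32)] * n_chan,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for fields in per_field:
            fh.write(b"".join(fields))
        for rec in range(n_records):
            chunk = digital[rec * fs : (rec + 1) * fs]  # fs x N
            fh.write(chunk.T.tobytes())
    return path


# ---------------------------------------------------------------------------
# Block extraction
# ---------------------------------------------------------------------------


def extract_ictal_blocks(
    session: RecordingSession, block_length: float = 10.0
) -> list[Block]:
    """One block per annotated seizure, anchored exactly at the seizure start.

    A seizure shorter than ``block_length`` still yields a full-length block
    (the window may run past the seizure end); a seizure starting closer than
    ``block_length`` to the end of the recording is skipped with a warning.
    """
    n_samp = int(round(block_length * session.fs))
    blocks = []
    for start, end in session.seizure_intervals:
        i0 = int(round(start * session.fs))
        if i0 + n_samp > session.signal.shape[0]:
            warnings.warn(
                f"seizure at t={start:.3f}s too close to the recording end; skipped"
            )
            continue
        if end - start < block_length:
            warnings.warn(
                f"seizure at t={start:.3f}s shorter than the {block_length:g}s window; "
                "the ictal block extends past the seizure end"
            )
        blocks.append(
            Block(session.signal[i0 : i0 + n_samp], session.fs, start, "ictal")
        )
    return blocks


def admissible_rest_intervals(
    session: RecordingSession,
    block_length: float = 10.0,
    guard: float = 120.0,
) -> list[tuple[float, float]]:
    """Half-open intervals of admissible rest-block *start* times.

    A start ``t`` is admissible when ``[t, t + block_length)`` intersects no
    seizure interval widened by ``guard`` seconds on each side and no
    exclusion interval.
    """
    t_end = session.duration - block_length
    if t_end <= 0:
        return []
    forbidden = []
    for s, e in session.seizure_intervals:
        forbidden.append((s - guard - block_length, e + guard))
    for s, e in session.exclusion_intervals:
        forbidden.append((s - block_length, e))
    forbidden.sort()
    allowed = []
    cursor = 0.0
    for s, e in forbidden:
        if s > cursor:
            allowed.append((cursor, min(s, t_end)))
        cursor = max(cursor, e)
        if cursor >= t_end:
            break
    if cursor < t_end:
        allowed.append((cursor, t_end))
    return [(a, b) for a, b in allowed if b - a > 0]


def sample_rest_starts(
    session: RecordingSession,
    count: int,
    block_length: float = 10.0,
    rng: np.random.Generator | None = None,
    guard: float = 120.0,
) -> np.ndarray:
    """Uniformly random rest-block start times over the admissible region.

    Blocks may overlap one another; only overlap with seizures (plus guard
    bands) and exclusion intervals is forbidden.
    """
    rng = np.random.default_rng(rng)
    allowed = admissible_rest_intervals(session, block_length, guard)
    lengths = np.array([b - a for a, b in allowed])
    total = lengths.sum() if len(lengths) else 0.0
    if total < block_length:
        raise ValueError(
            f"admissible rest region is only {total:.1f}s; cannot sample "
            f"{count} blocks of {block_length:g}s (guard={guard:g}s)"
        )
    u = rng.uniform(0.0, total, size=count)
    edges = np.concatenate([[0.0], np.cumsum(lengths)])
    idx = np.searchsorted(edges, u, side="right") - 1
    return np.array([allowed[i][0] + (u_j - edges[i]) for i, u_j in zip(idx, u)])


def sample_rest_blocks(
    session: RecordingSession,
    count: int,
    block_length: float = 10.0,
    rng: np.random.Generator | None = None,
    guard: float = 120.0,
) -> list[Block]:
    rng = np.random.default_rng(rng)
    starts = sample_rest_starts(session, count, block_length, rng, guard)
    n_samp = int(round(block_length * session.fs))
    blocks = []
    for t in starts:
        i0 = int(round(t * session.fs))
        i0 = min(i0, session.signal.shape[0] - n_samp)
        blocks.append(Block(session.signal[i0 : i0 + n_samp], session.fs, float(t), "rest"))
    return blocks
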