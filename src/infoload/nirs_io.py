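"""Reading, validating and writing NIRS sessions.

A session is a uniformly sampled multi-channel recording with a marked
rest/task boundary. The on-disk dialect is delimited text (comma or tab,
auto-detected) with a small ``#``-prefixed key:value header::

    # fs_hz=10.0
    # rest_end=600
    # channels=L1:1.0,L3:3.0,R1:1.0,R3:3.0
    # subject_id=s01
    # condition=one-back
    0.123<TAB>0.456<TAB>...

One row per sample, one column per channel, column order matching the
``channels`` header. Time is implicit (row index / fs); units are the
device's arbitrary total-blood-flow units and are never converted.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FS = 10.0
DEFAULT_BASELINE_S = 20.0
"""Baseline window length in seconds; the rest period must cover it."""


class SessionFormatError(ValueError):
    """Malformed session file (missing or unparseable header fields)."""


class SessionValidationError(ValueError):
    """Structurally valid file whose contents violate session invariants."""


@dataclass(frozen=True)
class ChannelMeta:
    """One optode channel: label and source-detector separation in cm."""

    label: str
    source_detector_distance: float

    def __post_init__(self):
        if not self.label:
            raise ValueError("channel label must be non-empty")
        if self.source_detector_distance <= 0:
            raise ValueError(
                f"channel {self.label}: source-detector distance must be > 0"
            )


@dataclass(frozen=True, eq=False)
class NirsSession:
    """A validated multi-channel NIRS recording with a rest/task split.

    samples        : [time x channel] float matrix, arbitrary units.
    fs             : sampling rate in Hz.
    channels       : per-column metadata; labels unique.
    rest_end_index : first sample index of the task period.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    channels: tuple[ChannelMeta, ...] = ()
    rest_end_index: int = 0
    subject_id: str = ""
    condition: str = ""
    min_rest_s: float = field(default=DEFAULT_BASELINE_S, compare=False)

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.size == 0:
            raise SessionValidationError("samples must be a non-empty [time x channel] matrix")
        if not np.all(np.isfinite(samples)):
            bad = np.argwhere(~np.isfinite(samples))[0]
            raise SessionValidationError(
                f"non-finite sample at row {bad[0]}, column {bad[1]}"
            )
        if self.fs <= 0:
            raise SessionValidationError("fs must be > 0")
        channels = tuple(self.channels)
        if len(channels) != samples.shape[1]:
            raise SessionValidationError(
                f"{len(channels)} channel entries for {samples.shape[1]} columns"
            )
        labels = [c.label for c in channels]
        if len(set(labels)) != len(labels):
            raise SessionValidationError(f"duplicate channel labels: {labels}")
        if not (0 < self.rest_end_index < samples.shape[0]):
            raise SessionValidationError(
                f"rest_end_index {self.rest_end_index} must lie strictly inside "
                f"the recording (0, {samples.shape[0]})"
            )
        if self.rest_end_index < self.min_rest_s * self.fs:
            raise SessionValidationError(
                f"rest period of {self.rest_end_index / self.fs:.1f} s is shorter "
                f"than the {self.min_rest_s:.0f}-s baseline window"
            )
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channels", channels)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    @property
    def rest_duration_s(self) -> float:
        return self.rest_end_index / self.fs

    @property
    def task_duration_s(self) -> float:
        return (self.n_samples - self.rest_end_index) / self.fs


def select_channel(session: NirsSession, label: str) -> tuple[np.ndarray, np.ndarray]:
    """Rest and task sample vectors for one channel.

    The two outputs partition the channel column exactly: concatenating them
    reproduces it.
    """
    try:
        col = session.labels.index(label)
    except ValueError:
        raise KeyError(
            f"unknown channel {label!r}; session has {session.labels}"
        ) from None
    column = session.samples[:, col]
    return column[: session.rest_end_index], column[session.rest_end_index:]


def _parse_header(lines: list[str], path) -> dict:
    fields: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" not in body:
            continue
        key, _, value = body.partition("=")
        fields[key.strip()] = value.strip()
    missing = {"fs_hz", "rest_end", "channels"} - fields.keys()
    if missing:
        raise SessionFormatError(
            f"{path}: header missing required field(s) {sorted(missing)}"
        )
    return fields


def _parse_channels(spec: str, path) -> tuple[ChannelMeta, ...]:
    metas = []
    for item in spec.split(","):
        label, _, dist = item.strip().partition(":")
        try:
            metas.append(ChannelMeta(label, float(dist)))
        except ValueError as exc:
            raise SessionFormatError(
                f"{path}: bad channel spec {item!r}: {exc}"
            ) from None
    return tuple(metas)


def read_session(path, format_options: dict | None = None) -> NirsSession:
    """Read and validate a session file in the dialect documented above.

    ``format_options`` may override ``delimiter`` (otherwise auto-detected
    from the first data row) and ``min_rest_s``.
    """
    opts = dict(format_options or {})
    path = Path(path)
    text = path.read_text()
    header_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    data_lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    fields = _parse_header(header_lines, path)
    if not data_lines:
        raise SessionFormatError(f"{path}: no data rows")
    delimiter = opts.get("delimiter")
    if delimiter is None:
        delimiter = "\t" if "\t" in data_lines[0] else ","
    try:
        fs = float(fields["fs_hz"])
        rest_end = int(fields["rest_end"])
    except ValueError as exc:
        raise SessionFormatError(f"{path}: unparseable header value: {exc}") from None
    channels = _parse_channels(fields["channels"], path)
    frame = pd.read_csv(
        io.StringIO("\n".join(data_lines)), sep=delimiter, header=None,
        float_precision="round_trip",
    )
    if frame.shape[1] != len(channels):
        raise SessionFormatError(
            f"{path}: {frame.shape[1]} data columns for {len(channels)} channels"
        )
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for j in range(frame.shape[1]):
            col = pd.to_numeric(frame.iloc[:, j], errors="coerce")
            bad = np.flatnonzero(col.isna().to_numpy())
            if bad.size:
                raise SessionValidationError(
                    f"{path}: non-numeric value at row {bad[0]}, column {j} "
                    f"({frame.iloc[bad[0], j]!r})"
                )
        values = values.astype(float)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise SessionValidationError(
            f"{path}: non-finite value at row {bad[0]}, column {bad[1]}"
        )
    return NirsSession(
        samples=values,
        fs=fs,
        channels=channels,
        rest_end_index=rest_end,
        subject_id=fields.get("subject_id", ""),
        condition=fields.get("condition", ""),
        min_rest_s=float(opts.get("min_rest_s", DEFAULT_BASELINE_S)),
    )


def write_session(session: NirsSession, path) -> Path:
    """Write a session in the canonical dialect; round-trips bit-exactly.

    Samples are serialised with ``repr``-exact float formatting so that
    ``read_session(write_session(s)) == s`` at the bit level.
    """
    path = Path(path)
    chan_spec = ",".join(
        f"{c.label}:{c.source_detector_distance:g}" for c in session.channels
    )
    lines = [
        f"# fs_hz={session.fs:g}",
        f"# rest_end={session.rest_end_index}",
        f"# channels={chan_spec}",
    ]
    if session.subject_id:
        lines.append(f"# subject_id={session.subject_id}")
    if session.condition:
        lines.append(f"# condition={session.condition}")
    for row in session.samples:
        lines.append("\t".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def import_wide_table(
    frame: pd.DataFrame,
    fs: float,
    rest_end_index: int,
    distances: dict[str, float] | None = None,
    **session_kwargs,
) -> NirsSession:
    """Build a session from a generic wide table (one column per channel).

    Column names become channel labels; ``distances`` maps labels to
    source-detector separations in cm (default 3.0 for all).
    """
    distances = distances or {}
    channels = tuple(
        ChannelMeta(str(c), float(distances.get(str(c), 3.0))) for c in frame.columns
    )
    return NirsSession(
        samples=frame.to_numpy(dtype=float),
        fs=fs,
        channels=channels,
        rest_end_index=rest_end_index,
        **session_kwargs,
    )
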