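"""Squiggle I/O: FAST5 (HDF5) containers, calibration, and label manifests.

A FAST5 file is an HDF5 container holding one raw current trace per read
plus the channel calibration needed to convert integer digitizer (DAC)
counts to picoamperes.  Two dialects are in the wild:

* single-read: ``/Raw/Reads/Read_<n>/Signal`` with calibration under
  ``/UniqueGlobalKey/channel_id``;
* multi-read: one ``/read_<read_id>`` group per read, each with its own
  ``Raw/Signal`` dataset and ``channel_id`` attribute group.

Both are supported for reading; :func:`write_container` emits the
multi-read layout.  An optional integer class label is stored as a
``label`` attribute on the read group (a package extension used to carry
simulator ground truth; foreign files simply lack it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from nanosieve.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_CALIBRATION_ATTRS = ("digitisation", "offset", "range", "sampling_rate")


@dataclass
class Squiggle:
    """One read's raw signal plus channel calibration.

    Parameters
    ----------
    read_id : str
        Unique read identifier within a container.
    raw : numpy.ndarray
        Raw DAC samples (integers as stored by the sequencer).
    offset : float
        Channel offset in DAC units.
    range_pA : float
        Full-scale current range of the digitizer in pA.
    digitisation : float
        Number of DAC quantisation levels (> 0).
    sampling_rate : float
        Samples per second (> 0); ~4 kHz for DNA chemistry.
    label : int or None
        Optional class index (ground truth), if known.
    """

    read_id: str
    raw: np.ndarray
    offset: float
    range_pA: float
    digitisation: float
    sampling_rate: float
    label: int | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        if self.digitisation <= 0:
            raise ValidationError(f"digitisation must be > 0, got {self.digitisation}")
        if self.sampling_rate <= 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    def __len__(self) -> int:
        return int(self.raw.size)

    def to_pA(self) -> np.ndarray:
        """Convert the raw trace to picoamperes using the stored calibration."""
        return dac_to_pA(self.raw, self.offset, self.range_pA, self.digitisation)


@dataclass
class Manifest:
    """Per-read ground-truth labels: rows of (read_id, label, source_file)."""

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["read_id", "label", "source_file"]))

    def __post_init__(self) -> None:
        required = ["read_id", "label", "source_file"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        if self.rows["read_id"].duplicated().any():
            dups = self.rows.loc[self.rows["read_id"].duplicated(), "read_id"].tolist()
            raise ValidationError(f"duplicate read_ids in manifest: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def labels(self) -> dict[str, int]:
        return dict(zip(self.rows["read_id"], self.rows["label"].astype(int)))

    @property
    def class_set(self) -> list[int]:
        return sorted(self.rows["label"].astype(int).unique().tolist())

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.rows.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Manifest":
        return cls(pd.read_csv(path, sep="\t"))


def dac_to_pA(raw: np.ndarray | Sequence[float], offset: float,
              range_pA: float, digitisation: float) -> np.ndarray:
    """Convert raw DAC counts to picoamperes.

    Uses the community calibration convention
    ``pA = (raw + offset) * range / digitisation``.
    """
    if digitisation <= 0:
        raise ValidationError(f"digitisation must be > 0, got {digitisation}")
    raw = np.asarray(raw, dtype=np.float64)
    return (raw + float(offset)) * float(range_pA) / float(digitisation)


def _squiggle_from_group(read_id: str, signal_ds: h5py.Dataset,
                         channel_attrs, label) -> Squiggle:
    attrs = dict(channel_attrs)
    for name in _CALIBRATION_ATTRS:
        if name not in attrs:
            raise FormatError(
                f"read {read_id!r}: channel_id missing calibration attribute {name!r}")
    return Squiggle(
        read_id=read_id,
        raw=np.asarray(signal_ds[()]),
        offset=float(attrs["offset"]),
        range_pA=float(attrs["range"]),
        digitisation=float(attrs["digitisation"]),
        sampling_rate=float(attrs["sampling_rate"]),
        label=None if label is None else int(label),
    )


def read_fast5(path: str | Path) -> list[Squiggle]:
    """Read all squiggles from a single- or multi-read FAST5 file.

    Reads are returned sorted by read_id.  Reads with an empty signal are
    skipped with a warning; a missing calibration attribute raises
    :class:`FormatError` naming the attribute.
    """
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot open FAST5 file {path}: {exc}") from exc

    squiggles: list[Squiggle] = []
    with f:
        read_groups = [k for k in f.keys() if k.startswith("read_")]
        if read_groups:  # multi-read layout
            for key in read_groups:
                grp = f[key]
                read_id = grp.attrs.get("read_id", key[len("read_"):])
                if isinstance(read_id, bytes):
                    read_id = read_id.decode()
                if "Raw/Signal" not in grp:
                    raise FormatError(f"read group {key!r} lacks Raw/Signal dataset")
                if "channel_id" not in grp:
                    raise FormatError(f"read group {key!r} lacks channel_id group")
                sq = _squiggle_from_group(str(read_id), grp["Raw/Signal"],
                                          grp["channel_id"].attrs,
                                          grp.attrs.get("label"))
                if len(sq) < 1:
                    logger.warning("skipping read %s: empty signal", read_id)
                    continue
                squiggles.append(sq)
        elif "Raw/Reads" in f:  # single-read layout
            if "UniqueGlobalKey/channel_id" not in f:
                raise FormatError("single-read FAST5 lacks UniqueGlobalKey/channel_id")
            channel_attrs = f["UniqueGlobalKey/channel_id"].attrs
            for key in f["Raw/Reads"]:
                grp = f["Raw/Reads"][key]
                read_id = grp.attrs.get("read_id", key)
                if isinstance(read_id, bytes):
                    read_id = read_id.decode()
                if "Signal" not in grp:
                    raise FormatError(f"read group {key!r} lacks Signal dataset")
                sq = _squiggle_from_group(str(read_id), grp["Signal"],
                                          channel_attrs, grp.attrs.get("label"))
                if len(sq) < 1:
                    logger.warning("skipping read %s: empty signal", read_id)
                    continue
                squiggles.append(sq)
        else:
            raise FormatError(f"{path} is neither single- nor multi-read FAST5 layout")

    squiggles.sort(key=lambda s: s.read_id)
    return squiggles


def write_container(squiggles: Iterable[Squiggle], path: str | Path) -> Path:
    """Write squiggles to a multi-read FAST5-style HDF5 container.

    Lossless for (read_id, raw, calibration metadata, label); the result is
    readable by :func:`read_fast5`.  Raises :class:`ValidationError` on an
    empty collection or duplicate read_ids.
    """
    squiggles = list(squiggles)
    if not squiggles:
        raise ValidationError("cannot write an empty container")
    ids = [s.read_id for s in squiggles]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate read_ids: {sorted(set(dups))[:5]}")

    path = Path(path)
    with h5py.File(path, "w") as f:
        for sq in squiggles:
            grp = f.create_group(f"read_{sq.read_id}")
            grp.attrs["read_id"] = sq.read_id
            if sq.label is not None:
                grp.attrs["label"] = int(sq.label)
            raw = np.asarray(sq.raw)
            grp.create_dataset("Raw/Signal", data=raw, compression="gzip",
                               compression_opts=1)
            ch = grp.create_group("channel_id")
            ch.attrs["digitisation"] = float(sq.digitisation)
            ch.attrs["offset"] = float(sq.offset)
            ch.attrs["range"] = float(sq.range_pA)
            ch.attrs["sampling_rate"] = float(sq.sampling_rate)
    return path
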