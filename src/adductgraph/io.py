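"""Centroid spectrum containers and Mascot generic format (mgf) I/O.

Spectra are plain peak lists; MS1 exports carry no precursor, so PEPMASS and
CHARGE headers are tolerated on input and omitted on output.  Peaks removed by
the filters are *flagged*, never deleted, so reports can still show them; the
spectrum TIC and the retained peak list always refer to unflagged peaks only.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import pandas as pd
from pyteomics import mgf as _pymgf

__all__ = [
    "Peak",
    "Spectrum",
    "FeatureRow",
    "MgfFormatError",
    "read_mgf",
    "write_mgf",
    "features_to_mgf",
    "read_feature_table",
]

#: Peaks closer than this (Da) are considered duplicate centroids and merged.
MZ_MERGE_TOL = 1e-4

FLAG_ISOTOPE = "isotope_removed"
FLAG_THRESHOLD = "below_threshold"
FLAG_SINGLETON = "singleton"


class MgfFormatError(ValueError):
    pass


@dataclass(eq=False)
class Peak:
    """One centroid with provenance flags (identity-hashed so it can be a graph node)."""

    mz: float
    intensity: float
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")

    @property
    def retained(self) -> bool:
        return not (self.flags & {FLAG_ISOTOPE, FLAG_THRESHOLD})

    def copy(self) -> "Peak":
        return Peak(self.mz, self.intensity, set(self.flags))


@dataclass
class Spectrum:
    """An ordered centroid peak list with minimal acquisition metadata."""

    peaks: list
    title: str = ""
    retention_time: float | None = None  # minutes
    polarity: str = "positive"

    def __post_init__(self) -> None:
        self.peaks = _merge_duplicates(sorted(self.peaks, key=lambda p: p.mz))

    @property
    def retained(self) -> list:
        return [p for p in self.peaks if p.retained]

    @property
    def tic(self) -> float:
        """Total ion current of the retained peaks, cps."""
        return float(sum(p.intensity for p in self.retained))

    def __len__(self) -> int:
        return len(self.peaks)

    def copy(self) -> "Spectrum":
        return Spectrum(
            [p.copy() for p in self.peaks],
            title=self.title,
            retention_time=self.retention_time,
            polarity=self.polarity,
        )


def _merge_duplicates(sorted_peaks: list) -> list:
    out: list = []
    for p in sorted_peaks:
        if out and p.mz - out[-1].mz < MZ_MERGE_TOL:
            prev = out[-1]
            tot = prev.intensity + p.intensity
            mz = (prev.mz * prev.intensity + p.mz * p.intensity) / tot if tot else prev.mz
            out[-1] = Peak(mz, tot, prev.flags | p.flags)
        else:
            out.append(p)
    return out


@dataclass(frozen=True)
class FeatureRow:
    """One chromatographic feature from a peak-picker export."""

    mz: float
    rt: float  # minutes
    intensity: float
    group_id: str

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("feature m/z must be positive")
        if not str(self.group_id):
            raise ValueError("feature group_id must be non-empty")


# ---------------------------------------------------------------------------
# mgf reading / writing
# ---------------------------------------------------------------------------


def _check_block_balance(text: str) -> None:
    depth = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip().upper()
        if s == "BEGIN IONS":
            if depth:
                raise MgfFormatError(f"line {lineno}: nested BEGIN IONS")
            depth = 1
        elif s == "END IONS":
            if not depth:
                raise MgfFormatError(f"line {lineno}: END IONS without BEGIN IONS")
            depth = 0
    if depth:
        raise MgfFormatError("unexpected end of file: BEGIN IONS without END IONS")


def read_mgf(source: str | IO[str]) -> list[Spectrum]:
    """Read an mgf stream or path into a batch of spectra, in file order.

    One spectrum per ``BEGIN IONS``/``END IONS`` block; TITLE and RTINSECONDS
    are parsed when present (retention time converted to minutes), polarity is
    taken from a CHARGE line when present and defaults to positive.  Unbalanced
    blocks and non-numeric peak lines raise :class:`MgfFormatError`.
    """
    if isinstance(source, str):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()
    _check_block_balance(text)
    out: list[Spectrum] = []
    try:
        with _pymgf.MGF(_stdio.StringIO(text)) as reader:
            for entry in reader:
                params = entry.get("params", {})
                title = str(params.get("title", ""))
                rt = params.get("rtinseconds")
                rt_min = float(rt) / 60.0 if rt is not None else None
                polarity = "positive"
                charge = params.get("charge")
                if charge:
                    polarity = "negative" if str(charge[0]).endswith("-") else "positive"
                peaks = [
                    Peak(float(mz), float(it))
                    for mz, it in zip(entry["m/z array"], entry["intensity array"])
                ]
                out.append(
                    Spectrum(peaks, title=title, retention_time=rt_min, polarity=polarity)
                )
    except MgfFormatError:
        raise
    except Exception as exc:  # pyteomics raises assorted ValueErrors
        raise MgfFormatError(f"malformed mgf input: {exc}") from exc
    return out


def write_mgf(batch: Iterable[Spectrum], destination: str | IO[str] | None = None) -> str:
    """Write a batch of spectra as mgf text; returns the text.

    Peak lines are printed with 5 decimals in m/z and 2 in intensity, so a
    read/write round trip reproduces peaks to 1e-4 m/z and 1e-2 intensity.
    """
    buf = _stdio.StringIO()
    for spec in batch:
        if not spec.peaks:
            warnings.warn(f"writing empty spectrum block {spec.title!r}")
        buf.write("BEGIN IONS\n")
        if spec.title:
            buf.write(f"TITLE={spec.title}\n")
        if spec.retention_time is not None:
            buf.write(f"RTINSECONDS={spec.retention_time * 60.0:.3f}\n")
        for p in spec.peaks:
            buf.write(f"{p.mz:.5f} {p.intensity:.2f}\n")
        buf.write("END IONS\n")
    text = buf.getvalue()
    if destination is not None:
        if isinstance(destination, str):
            with open(destination, "w") as fh:
                fh.write(text)
        else:
            destination.write(text)
    return text


# ---------------------------------------------------------------------------
# feature-table conversion (pseudo-spectra)
# ---------------------------------------------------------------------------

#: Accepted column aliases (CAMERA-style exports use into/pcgroup).
_COLUMN_ALIASES = {
    "mz": ("mz",),
    "rt": ("rt",),
    "intensity": ("intensity", "into"),
    "group_id": ("group_id", "pcgroup"),
}


def read_feature_table(source: str | IO[str]) -> list[FeatureRow]:
    """Read a headered CSV feature table into rows, accepting CAMERA-style names."""
    df = pd.read_csv(source)
    cols: dict[str, str] = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        found = [c for c in df.columns if c.strip().lower() in aliases]
        if not found:
            raise ValueError(
                f"feature table is missing a {canonical!r} column "
                f"(accepted names: {', '.join(aliases)})"
            )
        cols[canonical] = found[0]
    def _gid(v) -> str:
        # numeric group ids read back as floats; print them as integers
        if isinstance(v, float) and v.is_integer():
            return str(int(v))
        return str(v)

    return [
        FeatureRow(
            mz=float(r[cols["mz"]]),
            rt=float(r[cols["rt"]]),
            intensity=float(r[cols["intensity"]]),
            group_id=_gid(r[cols["group_id"]]),
        )
        for _, r in df.iterrows()
    ]


def features_to_mgf(rows: Sequence[FeatureRow]) -> list[Spectrum]:
    """Convert grouped chromatographic features into pseudo-spectra.

    One spectrum per distinct ``group_id``; the pseudo-spectrum retention time
    is the intensity-weighted mean of its features.  Groups are emitted in order
    of first appearance, matching the converter's batch-order guarantee.
    """
    if not rows:
        raise ValueError("empty feature table")
    order: dict[str, list[FeatureRow]] = {}
    for row in rows:
        order.setdefault(str(row.group_id), []).append(row)
    out = []
    for gid, members in order.items():
        tot = sum(r.intensity for r in members)
        rt = (
            sum(r.rt * r.intensity for r in members) / tot
            if tot
            else sum(r.rt for r in members) / len(members)
        )
        out.append(
            Spectrum(
                [Peak(r.mz, r.intensity) for r in members],
                title=f"pseudo-spectrum {gid}",
                retention_time=rt,
            )
        )
    return out
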