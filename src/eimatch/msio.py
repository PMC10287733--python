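"""Spectrum containers and NIST MSP / JSON-lines input-output.

Electron-ionization spectra travel between tools almost exclusively as MSP
text records (``Name:`` / ``Num Peaks:`` headers followed by ``m/z intensity``
pairs).  This module provides a minimal :class:`Spectrum` record, a strict MSP
reader/writer pair that round-trips peak lists exactly, and a JSON-lines
exchange format for programmatic pipelines.

Intensity convention: all downstream computation in this package works on
base-peak-normalized intensities in ``[0, 1]`` (see :func:`normalize_spectrum`);
raw MSP files may use the NIST 0-999 convention or 0-100 percent scales, which
normalization makes equivalent.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "Peak",
    "Spectrum",
    "MSPParseError",
    "read_msp",
    "write_msp",
    "read_jsonl",
    "write_jsonl",
    "normalize_spectrum",
    "round_peaks",
]


class MSPParseError(ValueError):
    """Raised when an MSP record header cannot be parsed."""


@dataclass(frozen=True)
class Peak:
    """A single fragment peak: m/z in Da, relative intensity >= 0."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class Spectrum:
    """A mass spectrum: ordered peak list plus molecule metadata.

    Invariants (enforced by :meth:`validate`): peaks sorted by ascending m/z
    with no duplicates at the working precision, at least one peak, and a
    strictly positive base-peak intensity.
    """

    id: str
    peaks: list[Peak]
    name: str | None = None
    smiles: str | None = None
    mol_mass: float | None = None
    source: str = "measured"
    meta: dict = field(default_factory=dict)

    def validate(self) -> "Spectrum":
        if not self.peaks:
            raise ValueError(f"spectrum {self.id!r} has no peaks")
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError(f"spectrum {self.id!r}: peaks not strictly ascending in m/z")
        if self.base_intensity <= 0:
            raise ValueError(f"spectrum {self.id!r}: base peak intensity must be > 0")
        return self

    @property
    def base_intensity(self) -> float:
        return max(p.intensity for p in self.peaks)

    def mz_values(self) -> list[float]:
        return [p.mz for p in self.peaks]

    def intensities(self) -> list[float]:
        return [p.intensity for p in self.peaks]


def round_peaks(peaks: list[Peak], precision: int = 0) -> list[Peak]:
    """Round peak m/z to ``precision`` decimal places, merging duplicates.

    Duplicate m/z after rounding are merged by *summing* intensities, which
    conserves total ion signal; the result is sorted ascending.
    """
    acc: dict[float, float] = {}
    for p in peaks:
        key = round(p.mz, precision)
        if precision == 0:
            key = float(int(key))
        acc[key] = acc.get(key, 0.0) + p.intensity
    return [Peak(mz, inten) for mz, inten in sorted(acc.items())]


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Rescale intensities so the base peak equals 1.0.

    Idempotent and scale-invariant; relative proportions are preserved.
    Raises ``ValueError`` on all-zero intensities.
    """
    base = s.base_intensity
    if base <= 0:
        raise ValueError(f"spectrum {s.id!r}: cannot normalize, base intensity <= 0")
    if base == 1.0:
        return s
    return replace(s, peaks=[Peak(p.mz, p.intensity / base) for p in s.peaks])


# --- MSP ------------------------------------------------------------------

_HEADER_RE = re.compile(r"^\s*([^:]+?)\s*:\s*(.*)$")
# peak pairs may be separated by whitespace and/or semicolons, several per line
_PAIR_RE = re.compile(r"([0-9.eE+-]+)[\s,]+([0-9.eE+-]+)\s*;?")


def _parse_record(lines: list[str], index: int) -> Spectrum | None:
    headers: dict[str, str] = {}
    peak_lines: list[str] = []
    num_peaks: int | None = None
    for line in lines:
        if num_peaks is None:
            m = _HEADER_RE.match(line)
            if m is None:
                raise MSPParseError(
                    f"record {index}: expected 'Key: value' header, got {line!r}"
                )
            key = m.group(1).strip().lower()
            if key == "num peaks":
                try:
                    num_peaks = int(m.group(2))
                except ValueError as exc:
                    raise MSPParseError(
                        f"record {index}: bad Num Peaks value {m.group(2)!r}"
                    ) from exc
            else:
                headers[key] = m.group(2)
        else:
            peak_lines.append(line)
    if num_peaks is None:
        raise MSPParseError(f"record {index}: missing 'Num Peaks' line")

    pairs = _PAIR_RE.findall(" ; ".join(peak_lines))
    if len(pairs) != num_peaks:
        warnings.warn(
            f"record {index}: 'Num Peaks: {num_peaks}' but {len(pairs)} pairs found; "
            "record skipped",
            stacklevel=3,
        )
        return None

    name = headers.get("name")
    mw: float | None = None
    for key in ("mw", "molecular weight", "exactmass"):
        if key in headers:
            try:
                mw = float(headers[key])
            except ValueError:
                pass
            break
    peaks = sorted(
        (Peak(float(mz), float(inten)) for mz, inten in pairs), key=lambda p: p.mz
    )
    spec = Spectrum(
        id=headers.get("id", name or f"record-{index}"),
        peaks=peaks,
        name=name,
        smiles=headers.get("smiles"),
        mol_mass=mw,
        meta={k: v for k, v in headers.items() if k not in {"name", "smiles", "id"}},
    )
    return spec.validate()


def read_msp(path) -> list[Spectrum]:
    """Read a NIST MSP file into a list of validated :class:`Spectrum`.

    Records are blank-line separated.  A record whose ``Num Peaks`` count
    disagrees with the number of pairs present is skipped with a warning;
    a malformed header raises :class:`MSPParseError` naming the record index.
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    spectra: list[Spectrum] = []
    index = 0
    for block in re.split(r"\n\s*\n", text):
        lines = [ln for ln in block.splitlines() if ln.strip()]
        if not lines:
            continue
        spec = _parse_record(lines, index)
        index += 1
        if spec is not None:
            spectra.append(spec)
    return spectra


def write_msp(spectra: list[Spectrum], path, scale: float | None = None) -> None:
    """Write spectra as MSP records.

    Intensities are emitted exactly as stored so that ``read_msp`` round-trips
    peak lists bit-for-bit.  Pass ``scale=999`` to emit the NIST 0-999
    convention instead (base peak rescaled to 999).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for s in spectra:
            s.validate()
            fh.write(f"Name: {s.name or s.id}\n")
            fh.write(f"Id: {s.id}\n")
            if s.smiles:
                fh.write(f"SMILES: {s.smiles}\n")
            if s.mol_mass is not None:
                fh.write(f"MW: {_fmt(s.mol_mass)}\n")
            fh.write(f"Num Peaks: {len(s.peaks)}\n")
            factor = 1.0 if scale is None else scale / s.base_intensity
            for p in s.peaks:
                fh.write(f"{_fmt(p.mz)} {_fmt(p.intensity * factor)}\n")
            fh.write("\n")


def _fmt(x: float) -> str:
    """Shortest decimal text that parses back to exactly x."""
    if math.isfinite(x) and x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


# --- JSON lines -----------------------------------------------------------


def write_jsonl(spectra: list[Spectrum], path) -> None:
    """Internal exchange format: one JSON object per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in spectra:
            s.validate()
            fh.write(
                json.dumps(
                    {
                        "id": s.id,
                        "name": s.name,
                        "smiles": s.smiles,
                        "mol_mass": s.mol_mass,
                        "source": s.source,
                        "peaks": [[p.mz, p.intensity] for p in s.peaks],
                    }
                )
                + "\n"
            )


def read_jsonl(path) -> list[Spectrum]:
    spectra = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            spectra.append(
                Spectrum(
                    id=obj["id"],
                    peaks=[Peak(mz, inten) for mz, inten in obj["peaks"]],
                    name=obj.get("name"),
                    smiles=obj.get("smiles"),
                    mol_mass=obj.get("mol_mass"),
                    source=obj.get("source", "measured"),
                ).validate()
            )
    return spectra
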