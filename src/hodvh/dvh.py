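"""Cumulative / differential dose–volume histograms and plan records.

A cumulative DVH gives, for each dose level ``D``, the fraction of the
structure volume receiving at least ``D``.  The differential form bins the
volume by absorbed dose and is the substrate of the equivalent-uniform-dose
models in :mod:`hodvh.radiobiology`.

Text dialect: one or more curves per file.  A line starting with ``#``
opens a new curve and carries the structure label (an optional
``structure:`` prefix is stripped).  Data rows are ``dose, volume``
separated by comma, tab or whitespace; a single non-numeric row directly
after the header is treated as a column header and skipped.  Volumes are
auto-detected as percentages when the maximum exceeds 1.5.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Arm",
    "DVHCurve",
    "DifferentialDVH",
    "PlanRecord",
    "DVHFormatError",
    "DVHValidationError",
    "ManifestError",
    "read_dvh_file",
    "write_dvh_file",
    "cumulative_to_differential",
    "differential_to_cumulative",
    "load_cohort",
    "save_cohort",
]

#: tolerance for volume bookkeeping (round trips, bin sums)
VOLUME_TOL = 1e-9
#: tolerance for accepting (and then flattening) non-monotone volume noise on read
READ_MONOTONE_TOL = 1e-6


class Arm(str, Enum):
    """Plan variant: dose computed without or with inhomogeneity correction."""

    IC_OFF = "IC_OFF"
    IC_ON = "IC_ON"


class DVHFormatError(ValueError):
    """Raised when a DVH text file cannot be parsed."""


class DVHValidationError(ValueError):
    """Raised when parsed or constructed DVH data violate an invariant."""


class ManifestError(ValueError):
    """Raised for malformed or inconsistent cohort manifests."""


def _readonly(values) -> np.ndarray:
    arr = np.array(values, dtype=float)
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose–volume curve for one structure in one plan.

    ``cum_volume[i]`` is the fraction of the structure receiving at least
    ``dose_grid[i]`` Gy.  The grid starts at 0 Gy where the fraction is 1.
    """

    structure_label: str
    dose_grid: np.ndarray
    cum_volume: np.ndarray
    total_volume_cc: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_grid", _readonly(self.dose_grid))
        object.__setattr__(self, "cum_volume", _readonly(self.cum_volume))
        d, c = self.dose_grid, self.cum_volume
        if d.ndim != 1 or d.shape != c.shape or d.size == 0:
            raise DVHValidationError("dose_grid and cum_volume must be equal-length 1-D arrays")
        if d[0] != 0.0:
            raise DVHValidationError(f"dose grid must start at 0 Gy, got {d[0]!r}")
        if d.size > 1 and not np.all(np.diff(d) > 0):
            raise DVHValidationError("dose grid must be strictly increasing")
        if abs(c[0] - 1.0) > VOLUME_TOL:
            raise DVHValidationError(f"cumulative volume at 0 Gy must be 1, got {c[0]!r}")
        if d.size > 1 and np.any(np.diff(c) > VOLUME_TOL):
            raise DVHValidationError("cumulative volume must be non-increasing")
        if c[-1] < -VOLUME_TOL:
            raise DVHValidationError("cumulative volume must stay non-negative")
        if self.total_volume_cc is not None and self.total_volume_cc <= 0:
            raise DVHValidationError("total_volume_cc must be positive when given")

    @property
    def max_dose(self) -> float:
        return float(self.dose_grid[-1])


@dataclass(frozen=True)
class DifferentialDVH:
    """Dose bins ``(D_i, v_i)`` with fractional volumes summing to one."""

    bin_dose: np.ndarray
    partial_volume: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_dose", _readonly(self.bin_dose))
        object.__setattr__(self, "partial_volume", _readonly(self.partial_volume))
        d, v = self.bin_dose, self.partial_volume
        if d.ndim != 1 or d.shape != v.shape or d.size == 0:
            raise DVHValidationError("bin_dose and partial_volume must be equal-length 1-D arrays")
        if np.any(np.diff(d) < 0):
            raise DVHValidationError("bin doses must be non-decreasing")
        if np.any(d < 0):
            raise DVHValidationError("bin doses must be non-negative")
        if np.any(v < -VOLUME_TOL):
            raise DVHValidationError("partial volumes must be non-negative")
        if abs(float(v.sum()) - 1.0) > VOLUME_TOL:
            raise DVHValidationError(f"partial volumes must sum to 1, got {float(v.sum())!r}")


@dataclass(frozen=True)
class PlanRecord:
    """One treatment plan: patient, arm, prescription and target DVH.

    ``v100_cc`` / ``v50_cc`` are the absolute volumes enclosed by the 100%
    and 50% prescription isodoses (whole irradiated region, not only the
    target), used for the gradient index.
    """

    patient_id: str
    arm: Arm
    target_dvh: DVHCurve
    prescription_dose_gy: float = 7.0
    n_fractions: int = 1
    v100_cc: float | None = None
    v50_cc: float | None = None

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise DVHValidationError("n_fractions must be >= 1")
        if self.prescription_dose_gy <= 0:
            raise DVHValidationError("prescription dose must be positive")
        if (self.v100_cc is None) != (self.v50_cc is None):
            raise DVHValidationError("v100_cc and v50_cc must be given together")
        if self.v100_cc is not None:
            if not self.v100_cc > 0:
                raise DVHValidationError("v100_cc must be positive")
            if self.v50_cc < self.v100_cc:
                raise DVHValidationError("v50_cc must be >= v100_cc")


# ---------------------------------------------------------------------------
# cumulative <-> differential conversion


def cumulative_to_differential(curve: DVHCurve) -> DifferentialDVH:
    """Bin a cumulative curve into ``(D_i, v_i)`` differential form.

    Each pair of consecutive grid points contributes a bin at their midpoint
    with the volume lost between them; residual volume still present at the
    last grid point is absorbed by a terminal bin at that dose.
    """
    d, c = curve.dose_grid, curve.cum_volume
    if d.size == 1:
        return DifferentialDVH(np.array([d[0]]), np.array([1.0]))
    v = np.clip(-np.diff(c), 0.0, None)
    mid = 0.5 * (d[:-1] + d[1:])
    residual = float(c[-1])
    if residual > VOLUME_TOL:
        mid = np.append(mid, d[-1])
        v = np.append(v, residual)
    total = float(v.sum())
    if abs(total - 1.0) > 1e-6:
        raise DVHValidationError(f"differential volumes sum to {total}, expected 1")
    return DifferentialDVH(mid, v / total)


def differential_to_cumulative(
    diff: DifferentialDVH, structure_label: str = "structure"
) -> DVHCurve:
    """Rebuild a cumulative step curve whose value at each bin dose is the
    tail sum of the volumes of the strictly higher bins."""
    dose, inverse = np.unique(diff.bin_dose, return_inverse=True)
    weight = np.zeros(dose.size)
    np.add.at(weight, inverse, diff.partial_volume)
    positive = dose > 0
    d_pos, w_pos = dose[positive], weight[positive]
    if d_pos.size == 0:
        return DVHCurve(structure_label, np.array([0.0]), np.array([1.0]))
    tail = np.concatenate([np.cumsum(w_pos[::-1])[::-1][1:], [0.0]])
    grid = np.concatenate([[0.0], d_pos])
    cum = np.concatenate([[1.0], tail])
    return DVHCurve(structure_label, grid, cum)


# ---------------------------------------------------------------------------
# text I/O

_NUMERIC_SPLIT = re.compile(r"[,\t;]|\s+")


def _parse_pair(line: str, delimiter: str | None):
    tokens = [t for t in (line.split(delimiter) if delimiter else _NUMERIC_SPLIT.split(line)) if t]
    if len(tokens) < 2:
        return None
    try:
        return float(tokens[0]), float(tokens[1])
    except ValueError:
        return None


def read_dvh_file(
    path: str | Path,
    *,
    delimiter: str | None = None,
    volume_unit: str = "auto",
) -> list[DVHCurve]:
    """Read one or more cumulative DVH curves from a text file.

    Parameters
    ----------
    delimiter:
        Column separator; ``None`` auto-splits on comma, tab, semicolon or
        whitespace.
    volume_unit:
        ``"auto"`` (percent when the maximum volume exceeds 1.5, else
        fraction), ``"percent"``, ``"fraction"`` or ``"cc"`` (absolute
        volumes; rescaled to fractions and recorded as ``total_volume_cc``).
    """
    path = Path(path)
    if volume_unit not in ("auto", "percent", "fraction", "cc"):
        raise ValueError(f"unknown volume_unit {volume_unit!r}")
    blocks: list[tuple[str, list[tuple[int, float, float]]]] = []
    label: str | None = None
    rows: list[tuple[int, float, float]] = []
    header_pending = False

    def close_block() -> None:
        nonlocal rows, label
        if rows:
            blocks.append((label or f"curve_{len(blocks) + 1}", rows))
        rows = []

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            close_block()
            label = re.sub(r"^structure:\s*", "", line.lstrip("#").strip(), flags=re.I) or None
            header_pending = True
            continue
        pair = _parse_pair(line, delimiter)
        if pair is None:
            if header_pending or not rows:
                header_pending = False
                continue  # column-header line
            raise DVHFormatError(f"{path.name}: cannot parse row {lineno}: {raw!r}")
        header_pending = False
        rows.append((lineno, *pair))
    close_block()
    if not blocks:
        raise DVHFormatError(f"{path.name}: no DVH data found")
    return [_build_curve(path, lab, blk, volume_unit) for lab, blk in blocks]


def _build_curve(
    path: Path, label: str, rows: list[tuple[int, float, float]], volume_unit: str
) -> DVHCurve:
    linenos = [r[0] for r in rows]
    doses = np.array([r[1] for r in rows])
    vols = np.array([r[2] for r in rows])
    bad = np.nonzero(np.diff(doses) <= 0)[0]
    if bad.size:
        raise DVHFormatError(
            f"{path.name}: non-monotone dose grid at row {linenos[bad[0] + 1]} "
            f"(dose {doses[bad[0] + 1]} after {doses[bad[0]]})"
        )
    total_cc = None
    if volume_unit == "cc":
        total_cc = float(vols[0])
        if total_cc <= 0:
            raise DVHValidationError(f"{path.name}: non-positive absolute volume")
        vols = vols / total_cc
    elif volume_unit == "percent" or (volume_unit == "auto" and vols.max() > 1.5):
        vols = vols / 100.0
    bad = np.nonzero(np.diff(vols) > READ_MONOTONE_TOL)[0]
    if bad.size:
        raise DVHValidationError(
            f"{path.name}: cumulative volume increases at row {linenos[bad[0] + 1]} "
            f"({vols[bad[0] + 1]:.8g} after {vols[bad[0]]:.8g})"
        )
    vols = np.minimum.accumulate(vols)  # flatten sub-tolerance noise
    if doses[0] > 0:
        doses = np.concatenate([[0.0], doses])
        vols = np.concatenate([[1.0], vols])
    if abs(vols[0] - 1.0) > READ_MONOTONE_TOL:
        raise DVHValidationError(
            f"{path.name}: curve {label!r} has cumulative volume {vols[0]:.8g} at 0 Gy, expected 1"
        )
    vols[0] = 1.0
    return DVHCurve(label, doses, vols, total_volume_cc=total_cc)


def write_dvh_file(
    curves: DVHCurve | Iterable[DVHCurve],
    path: str | Path,
    *,
    volume_unit: str = "fraction",
) -> Path:
    """Write curves in the text dialect read by :func:`read_dvh_file`.

    The default fractional unit with 17 significant digits round-trips the
    arrays bit-for-bit on the same grid.
    """
    if isinstance(curves, DVHCurve):
        curves = [curves]
    if volume_unit not in ("fraction", "percent"):
        raise ValueError("writer supports 'fraction' or 'percent' volumes")
    scale = 100.0 if volume_unit == "percent" else 1.0
    lines: list[str] = []
    for curve in curves:
        lines.append(f"# structure: {curve.structure_label}")
        lines.append(f"dose_gy,volume_{'pct' if volume_unit == 'percent' else 'fraction'}")
        for d, v in zip(curve.dose_grid, curve.cum_volume):
            lines.append(f"{d:.17g},{v * scale:.17g}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# cohort manifest

MANIFEST_COLUMNS = ("patient_id", "arm", "dvh_path", "v100_cc", "v50_cc")


def save_cohort(plans: Sequence[PlanRecord], out_dir: str | Path) -> Path:
    """Write every plan's DVH plus a ``manifest.csv`` tying them together."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for plan in plans:
            fname = f"{plan.patient_id}_{plan.arm.value}.dvh"
            write_dvh_file(plan.target_dvh, out_dir / fname)
            writer.writerow(
                [
                    plan.patient_id,
                    plan.arm.value,
                    fname,
                    "" if plan.v100_cc is None else f"{plan.v100_cc:.17g}",
                    "" if plan.v50_cc is None else f"{plan.v50_cc:.17g}",
                ]
            )
    return manifest


def load_cohort(
    manifest_path: str | Path,
    *,
    prescription_dose_gy: float = 7.0,
    n_fractions: int = 1,
) -> list[PlanRecord]:
    """Load the paired cohort described by a manifest CSV."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    plans: list[PlanRecord] = []
    with manifest_path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ManifestError(f"manifest missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                arm = Arm(row["arm"].strip())
            except ValueError as exc:
                raise ManifestError(f"manifest row {i}: unknown arm {row['arm']!r}") from exc
            dvh_path = manifest_path.parent / row["dvh_path"].strip()
            if not dvh_path.exists():
                raise ManifestError(f"manifest row {i}: DVH file not found: {dvh_path}")
            curve = read_dvh_file(dvh_path)[0]
            v100 = float(row["v100_cc"]) if row["v100_cc"].strip() else None
            v50 = float(row["v50_cc"]) if row["v50_cc"].strip() else None
            plans.append(
                PlanRecord(
                    patient_id=row["patient_id"].strip(),
                    arm=arm,
                    target_dvh=curve,
                    prescription_dose_gy=prescription_dose_gy,
                    n_fractions=n_fractions,
                    v100_cc=v100,
                    v50_cc=v50,
                )
            )
    if not plans:
        raise ManifestError(f"{manifest_path}: empty manifest")
    return plans
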