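"""Proton-transfer scan profiles and bridge-parameter extraction.

A scan profile is the potential-energy curve obtained by stretching the
bridged O–H bond in fixed increments from the optimized molecular form.
For a double-well bridge the curve rises to a barrier (the proton-transfer
activation energy, EA), falls into the proton-transferred well (the second
minimum, SM) and rises again as the proton is pushed past the acceptor.
All energies are handled in kcal/mol, referenced to the first grid point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HARTREE_TO_KCAL",
    "ScanProfile",
    "BridgeParameters",
    "ProfileError",
    "read_profile",
    "extract_bridge_parameters",
]

#: Conversion factor from hartree to kcal/mol.
HARTREE_TO_KCAL = 627.509


class ProfileError(ValueError):
    """Raised for malformed scan-profile input."""


@dataclass(frozen=True)
class ScanProfile:
    """An ordered (O–H distance, relative energy) grid for one bridge scan.

    Parameters
    ----------
    distances
        O–H separations in Å, strictly increasing.
    energies
        Energies in kcal/mol, conventionally referenced so that
        ``energies[0] == 0`` (the optimized molecular form).
    """

    distances: np.ndarray
    energies: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "energies", e)
        if d.ndim != 1 or e.ndim != 1 or d.shape != e.shape:
            raise ProfileError("distances and energies must be 1-D and equal length")
        if d.size < 5:
            raise ProfileError(f"profile needs at least 5 points, got {d.size}")
        if not (np.isfinite(d).all() and np.isfinite(e).all()):
            raise ProfileError("profile contains non-finite values")
        if not np.all(np.diff(d) > 0):
            raise ProfileError("distances must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.distances.size)

    @property
    def step(self) -> float:
        """Mean grid spacing in Å (grids produced here are uniform)."""
        return float(np.mean(np.diff(self.distances)))


@dataclass(frozen=True)
class BridgeParameters:
    """Energetic descriptors of one hydrogen bridge.

    ``activation_energy`` (EA) is the barrier height and ``second_minimum``
    (SM) the depth of the proton-transferred well, both relative to the
    molecular-form minimum at the start of the scan. ``difference`` is
    always derived as EA − SM, never stored independently.
    """

    activation_energy: float | None
    second_minimum: float | None
    has_pt_minimum: bool = True
    degenerate: bool = False
    below_reference: bool = False
    barrier_index: int | None = None
    pt_min_index: int | None = None

    def __post_init__(self) -> None:
        if self.has_pt_minimum:
            if self.activation_energy is None or self.second_minimum is None:
                raise ValueError("EA and SM required when a PT minimum exists")
        else:
            if self.activation_energy is not None or self.second_minimum is not None:
                raise ValueError("EA/SM are undefined without a PT minimum")

    @property
    def difference(self) -> float | None:
        """EA − SM; how steep the return path from the PT well is."""
        if not self.has_pt_minimum:
            return None
        return self.activation_energy - self.second_minimum


def _read_table(source: Path | str) -> np.ndarray:
    """Read a two-column numeric table, tolerating one header line."""
    try:
        df = pd.read_csv(source, sep=None, engine="python", header=None,
                         comment="#", skipinitialspace=True,
                         skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ProfileError(f"cannot parse profile table {source}: {exc}") from exc
    if df.shape[1] < 2:
        raise ProfileError(f"{source}: expected two columns, got {df.shape[1]}")
    df = df.iloc[:, :2]
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():  # header line
        df = df.iloc[1:]
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = int(np.argwhere(np.isnan(values))[0, 0])
        raise ProfileError(f"{source}: non-numeric cell in data row {bad}")
    return values


def read_profile(source: Path | str, energy_unit: str = "kcal_mol") -> ScanProfile:
    """Read a scan profile from a two-column (distance, energy) table.

    Accepts CSV or whitespace-delimited text with an optional header line.
    Energies in hartree are converted (1 hartree = 627.509 kcal/mol) and the
    whole curve is shifted so the first point — the optimized structure the
    scan started from — sits at 0 kcal/mol.
    """
    if energy_unit not in ("kcal_mol", "hartree"):
        raise ValueError(f"unknown energy unit {energy_unit!r}")
    values = _read_table(source)
    distances = values[:, 0]
    energies = values[:, 1]
    if energy_unit == "hartree":
        energies = energies * HARTREE_TO_KCAL
    energies = energies - energies[0]
    return ScanProfile(distances=distances, energies=energies)


def _runs(energies: np.ndarray) -> list[tuple[int, int, float]]:
    """Compress consecutive equal energies into (start, length, value) runs."""
    runs: list[tuple[int, int, float]] = []
    start = 0
    for i in range(1, len(energies)):
        if energies[i] != energies[start]:
            runs.append((start, i - start, float(energies[start])))
            start = i
    runs.append((start, len(energies) - start, float(energies[start])))
    return runs


def _refine_parabolic(profile: ScanProfile, idx: int) -> float:
    """Vertex energy of the parabola through a grid extremum and neighbors."""
    e = profile.energies
    if idx <= 0 or idx >= len(e) - 1:
        return float(e[idx])
    y0, y1, y2 = e[idx - 1], e[idx], e[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(y1)
    # vertex of the interpolating parabola on the unit-spaced stencil
    t = 0.5 * (y0 - y2) / denom
    return float(y1 - 0.25 * (y0 - y2) * t)


def extract_bridge_parameters(
    profile: ScanProfile,
    refine: str = "none",
    rereference: bool = False,
) -> BridgeParameters:
    """Locate the barrier and the proton-transfer minimum on a scan profile.

    Extremum detection works on the discrete grid: the barrier is the first
    interior local maximum after the starting point, the PT minimum the first
    local minimum after it.  Plateaus of exactly equal energies count once,
    at their leftmost point.  A rising "shelf" plateau (flat top with higher
    energy on both sides of the scan direction) is reported as a degenerate
    barrier with EA = SM.

    Energies are referenced to index 0 (the optimized molecular form).  If
    the curve dips below that reference the result is flagged
    ``below_reference`` and a warning is emitted; pass ``rereference=True``
    to re-zero on the global minimum instead.
    """
    if refine not in ("none", "parabolic"):
        raise ValueError(f"unknown refinement {refine!r}")
    energies = profile.energies
    ref = float(energies[0])
    below = bool(np.min(energies) < ref)
    if below:
        warnings.warn(
            "profile global minimum lies below the starting structure; "
            "energies stay referenced to the first point"
            + (" (re-referenced on request)" if rereference else ""),
            stacklevel=2,
        )
        if rereference:
            ref = float(np.min(energies))

    runs = _runs(energies)
    barrier_idx: int | None = None
    pt_idx: int | None = None
    degenerate = False
    # skip the run containing index 0; walk interior runs
    for k in range(1, len(runs) - 1):
        start, length, value = runs[k]
        prev_v = runs[k - 1][2]
        next_v = runs[k + 1][2]
        if barrier_idx is None:
            if value > prev_v and value > next_v:
                barrier_idx = start
            elif value > prev_v and value < next_v and length >= 2:
                # flat-topped saddle: barrier and PT well have merged
                barrier_idx = start
                pt_idx = start
                degenerate = True
                break
        else:
            if value < prev_v and value < next_v:
                pt_idx = start
                break

    if barrier_idx is None or pt_idx is None:
        return BridgeParameters(
            activation_energy=None, second_minimum=None,
            has_pt_minimum=False, below_reference=below,
        )

    if refine == "parabolic" and not degenerate:
        ea = _refine_parabolic(profile, barrier_idx) - ref
        sm = _refine_parabolic(profile, pt_idx) - ref
    else:
        ea = float(energies[barrier_idx]) - ref
        sm = float(energies[pt_idx]) - ref
    return BridgeParameters(
        activation_energy=ea,
        second_minimum=sm,
        has_pt_minimum=True,
        degenerate=degenerate,
        below_reference=below,
        barrier_index=barrier_idx,
        pt_min_index=pt_idx,
    )


def write_profile(profile: ScanProfile, path: Path | str) -> None:
    """Write a profile as a two-column CSV (distance_angstrom, energy_kcal)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("distance_angstrom,energy_kcal_mol\n")
        for d, e in zip(profile.distances, profile.energies):
            fh.write(f"{d:.10f},{e:.10f}\n")
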