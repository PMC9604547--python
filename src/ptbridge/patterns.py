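"""Substitution patterns, compounds and the proximal/distal re-labeling.

The compounds are tri-ring aromatic Schiff bases carrying two symmetric
O–H…N hydrogen bridges.  Each outer ring can hold at most one substituent
(–Br, –NH2 or –NO2) at one of four ring-local positions; a compound is
fully described by its parent group (ortho/meta/para, the relation of the
two imine linkages on the central ring) and the two ring patterns, written
``A,X--B,Y``.  Because the bridges are symmetric, scanning either bridge
turns the absolute A/B labels into a (proximal, distal) pair relative to
the scanned bridge — one physical compound yields two such views.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .profiles import BridgeParameters, extract_bridge_parameters, read_profile

__all__ = [
    "SUBSTITUENTS",
    "POSITIONS",
    "GROUPS",
    "UNSUBSTITUTED",
    "SubstitutionPattern",
    "CompoundSpec",
    "BridgeView",
    "CompoundRecord",
    "PatternError",
    "ManifestError",
    "parse_pattern_label",
    "format_pattern_label",
    "parse_compound_label",
    "format_compound_label",
    "bridge_views",
    "canonical_patterns",
    "mono_substitution_grid",
    "load_dataset",
    "write_dataset",
]

SUBSTITUENTS = ("Br", "NH2", "NO2")
POSITIONS = (1, 2, 3, 4)
GROUPS = ("ortho", "meta", "para")

# ring-local position labels as drawn on the parent structures: position 1
# sits next to the C1–N imine linkage, position 4 next to the C4–O phenol
_CANONICAL_SUBS = {s.upper(): s for s in SUBSTITUENTS}


class PatternError(ValueError):
    """Raised for invalid substitution-pattern input."""


class ManifestError(ValueError):
    """Raised for malformed dataset manifests."""


@dataclass(frozen=True)
class SubstitutionPattern:
    """One substituent at one ring-local position, or nothing at all."""

    substituent: str | None
    position: int | None

    def __post_init__(self) -> None:
        if (self.substituent is None) != (self.position is None):
            raise PatternError(
                "substituent and position must both be set or both be None"
            )
        if self.substituent is not None:
            if self.substituent not in SUBSTITUENTS:
                raise PatternError(f"unknown substituent {self.substituent!r}")
            if self.position not in POSITIONS:
                raise PatternError(f"position {self.position!r} outside 1..4")

    @property
    def is_substituted(self) -> bool:
        return self.substituent is not None

    @property
    def label(self) -> str:
        return format_pattern_label(self)

    def sort_key(self) -> tuple[int, int, int]:
        """Canonical ordering: unsubstituted first, then Br, NH2, NO2 × 1–4."""
        if not self.is_substituted:
            return (0, 0, 0)
        return (1, SUBSTITUENTS.index(self.substituent), self.position)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


UNSUBSTITUTED = SubstitutionPattern(None, None)


def parse_pattern_label(label: str) -> SubstitutionPattern:
    """Parse ``"Br, 3"`` / ``"None, None"`` into a pattern.

    Whitespace-insensitive and case-normalizing (``"br,3"`` → Br at 3).
    """
    parts = [p.strip() for p in str(label).split(",")]
    if len(parts) != 2:
        raise PatternError(f"pattern label {label!r} is not 'substituent, position'")
    sub_tok, pos_tok = parts
    if sub_tok.upper() in ("NONE", ""):
        if pos_tok.upper() not in ("NONE", ""):
            raise PatternError(f"{label!r}: position given without substituent")
        return UNSUBSTITUTED
    sub = _CANONICAL_SUBS.get(sub_tok.upper())
    if sub is None:
        raise PatternError(f"unknown substituent token {sub_tok!r} in {label!r}")
    if pos_tok.upper() == "NONE":
        raise PatternError(f"{label!r}: substituent without a position")
    try:
        pos = int(pos_tok)
    except ValueError:
        raise PatternError(f"{label!r}: position {pos_tok!r} is not an integer")
    if pos not in POSITIONS:
        raise PatternError(f"{label!r}: position {pos} outside {{1..4}}")
    return SubstitutionPattern(sub, pos)


def format_pattern_label(pattern: SubstitutionPattern) -> str:
    """ASCII pattern label, e.g. ``"Br,3"`` or ``"None,None"``."""
    if not pattern.is_substituted:
        return "None,None"
    return f"{pattern.substituent},{pattern.position}"


def parse_compound_label(label: str) -> tuple[SubstitutionPattern, SubstitutionPattern]:
    """Parse a two-ring label ``"A,X--B,Y"`` (em-dash ``—`` also accepted)."""
    text = str(label).replace("—", "--").replace("–", "--")
    parts = text.split("--")
    if len(parts) != 2:
        raise PatternError(f"compound label {label!r} must have two ring patterns")
    return parse_pattern_label(parts[0]), parse_pattern_label(parts[1])


def format_compound_label(ring_a: SubstitutionPattern, ring_b: SubstitutionPattern) -> str:
    return f"{format_pattern_label(ring_a)}--{format_pattern_label(ring_b)}"


@dataclass(frozen=True)
class CompoundSpec:
    """A compound: parent group plus one pattern per outer ring."""

    group: str
    ringA: SubstitutionPattern = UNSUBSTITUTED
    ringB: SubstitutionPattern = UNSUBSTITUTED

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise PatternError(f"unknown parent group {self.group!r}")

    @property
    def label(self) -> str:
        return format_compound_label(self.ringA, self.ringB)


@dataclass(frozen=True)
class BridgeView:
    """One compound seen from one of its two hydrogen bridges.

    Scanning bridge A makes ring A proximal and ring B distal; scanning
    bridge B reverses the roles.
    """

    spec: CompoundSpec
    scanned_bridge: str

    def __post_init__(self) -> None:
        if self.scanned_bridge not in ("A", "B"):
            raise PatternError(f"scanned bridge must be 'A' or 'B', got {self.scanned_bridge!r}")

    @property
    def proximal(self) -> SubstitutionPattern:
        return self.spec.ringA if self.scanned_bridge == "A" else self.spec.ringB

    @property
    def distal(self) -> SubstitutionPattern:
        return self.spec.ringB if self.scanned_bridge == "A" else self.spec.ringA

    @property
    def group(self) -> str:
        return self.spec.group


def bridge_views(spec: CompoundSpec) -> tuple[BridgeView, BridgeView]:
    """Both (proximal, distal) views of a compound, one per bridge."""
    return BridgeView(spec, "A"), BridgeView(spec, "B")


@dataclass
class CompoundRecord:
    """One bridge view with its extracted parameters and auxiliary scalars.

    ``auxiliary_scalars`` holds named per-record values the package never
    computes itself, e.g. a distal-ring partial-charge sum or a tabulated
    heavy-atom distance.
    """

    view: BridgeView
    parameters: BridgeParameters | None = None
    auxiliary_scalars: dict[str, float] = field(default_factory=dict)

    @property
    def key(self) -> tuple[CompoundSpec, str]:
        return (self.view.spec, self.view.scanned_bridge)


def canonical_patterns(include_unsubstituted: bool = True) -> list[SubstitutionPattern]:
    """All 13 patterns in canonical order (12 substituted + unsubstituted)."""
    pats = [UNSUBSTITUTED] if include_unsubstituted else []
    pats.extend(
        SubstitutionPattern(s, p) for s in SUBSTITUENTS for p in POSITIONS
    )
    return pats


def mono_substitution_grid(
    groups: Sequence[str] = GROUPS,
    include_unsub_proximal: bool = True,
) -> list[BridgeView]:
    """Enumerate the mono-substitution grid as bridge-A views.

    For each group: every proximal pattern (12 substituted, plus the
    unsubstituted parent when requested) crossed with all 13 distal
    patterns.  Each view is realized as a compound with the proximal
    pattern on ring A and the distal pattern on ring B, scanned on A.
    """
    views = []
    for g in groups:
        if g not in GROUPS:
            raise PatternError(f"unknown parent group {g!r}")
        for prox in canonical_patterns(include_unsubstituted=include_unsub_proximal):
            for dist in canonical_patterns():
                spec = CompoundSpec(group=g, ringA=prox, ringB=dist)
                views.append(BridgeView(spec, "A"))
    return views


# ---------------------------------------------------------------------------
# dataset manifests

_MANIFEST_COLUMNS = ("group", "ringA", "ringB", "bridge", "profile_path", "ea", "sm")


def _record_from_row(
    row: dict, index: int, base_dir: Path, energy_unit: str
) -> CompoundRecord:
    try:
        group = str(row["group"]).strip()
        ring_a = parse_pattern_label(row["ringA"])
        ring_b = parse_pattern_label(row["ringB"])
        bridge = str(row["bridge"]).strip().upper()
        spec = CompoundSpec(group=group, ringA=ring_a, ringB=ring_b)
        view = BridgeView(spec, bridge)
    except (PatternError, KeyError) as exc:
        raise ManifestError(f"row {index}: {exc}") from exc

    parameters: BridgeParameters | None = None
    ea = row.get("ea")
    sm = row.get("sm")
    has_ea = ea not in (None, "")
    has_sm = sm not in (None, "")
    profile_path = row.get("profile_path")
    if has_ea != has_sm:
        raise ManifestError(f"row {index}: ea and sm must be given together")
    if has_ea:
        try:
            parameters = BridgeParameters(
                activation_energy=float(ea), second_minimum=float(sm)
            )
        except ValueError as exc:
            raise ManifestError(f"row {index}: {exc}") from exc
    elif profile_path not in (None, ""):
        path = Path(profile_path)
        if not path.is_absolute():
            path = base_dir / path
        if not path.exists():
            raise ManifestError(f"row {index}: profile file {path} not found")
        profile = read_profile(path, energy_unit=energy_unit)
        parameters = extract_bridge_parameters(profile)

    aux = {}
    for name, value in row.items():
        if name in _MANIFEST_COLUMNS or value in (None, ""):
            continue
        try:
            aux[name] = float(value)
        except (TypeError, ValueError):
            raise ManifestError(f"row {index}: auxiliary column {name!r} is not numeric")
    return CompoundRecord(view=view, parameters=parameters, auxiliary_scalars=aux)


def load_dataset(manifest: Path | str, energy_unit: str = "kcal_mol") -> list[CompoundRecord]:
    """Load compound records from a CSV or JSON manifest.

    Each row names a compound (group, ringA, ringB), the scanned bridge,
    and either extracted ``ea``/``sm`` values (kcal/mol) or a
    ``profile_path`` to a scan table from which the parameters are
    extracted on the fly.  Extra numeric columns become auxiliary scalars.
    Duplicate (compound, bridge) rows are rejected.
    """
    manifest = Path(manifest)
    if not manifest.exists():
        raise ManifestError(f"manifest {manifest} not found")
    base_dir = manifest.parent
    if manifest.suffix.lower() == ".json":
        rows = json.loads(manifest.read_text(encoding="utf-8"))
        if not isinstance(rows, list):
            raise ManifestError("JSON manifest must be a list of row objects")
    else:
        with manifest.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "group" not in reader.fieldnames:
                raise ManifestError("CSV manifest needs a header with a 'group' column")
            rows = list(reader)

    records: list[CompoundRecord] = []
    seen: dict[tuple, int] = {}
    for i, row in enumerate(rows):
        rec = _record_from_row(row, i, base_dir, energy_unit)
        if rec.key in seen:
            raise ManifestError(
                f"row {i}: duplicate record for "
                f"{rec.view.spec.label} / bridge {rec.view.scanned_bridge} "
                f"(first at row {seen[rec.key]})"
            )
        seen[rec.key] = i
        records.append(rec)
    return records


def write_dataset(records: Iterable[CompoundRecord], manifest: Path | str) -> Path:
    """Write records to a CSV (or JSON) manifest; energies in kcal/mol."""
    manifest = Path(manifest)
    records = list(records)
    aux_names = sorted({n for r in records for n in r.auxiliary_scalars})
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "group": rec.view.group,
            "ringA": format_pattern_label(rec.view.spec.ringA),
            "ringB": format_pattern_label(rec.view.spec.ringB),
            "bridge": rec.view.scanned_bridge,
            "profile_path": "",
            "ea": "",
            "sm": "",
        }
        if rec.parameters is not None and rec.parameters.has_pt_minimum:
            row["ea"] = repr(rec.parameters.activation_energy)
            row["sm"] = repr(rec.parameters.second_minimum)
        for name in aux_names:
            row[name] = (
                repr(rec.auxiliary_scalars[name])
                if name in rec.auxiliary_scalars else ""
            )
        rows.append(row)

    if manifest.suffix.lower() == ".json":
        manifest.write_text(json.dumps(rows, indent=1), encoding="utf-8")
        return manifest
    fieldnames = list(_MANIFEST_COLUMNS) + aux_names
    with manifest.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
    return manifest
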