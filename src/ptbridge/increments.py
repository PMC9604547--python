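"""Additive increment model of the composite substituent effect.

The activation energy of proton transfer in a substituted bridge is
decomposed as

    EA = EBC + IE-SUB + IE-STER + IE-DIST

where EBC is the unsubstituted parent's barrier, IE-SUB the classical
(resonance + induction) substituent effect mediated through the proximal
ring, IE-STER an extra proximity term for substituents adjacent to the
bridge atoms (positions 1 and 4 only), and IE-DIST the small contribution
of the distal ring.  The second minimum SM follows the same decomposition
with its own increments (IS-SUB, IS-STER, and optionally a distal term).

The classical effect is position-pair symmetric: positions 1 and 3 share
one IE-SUB value, positions 2 and 4 another.  The steric term is the
residual that breaks that symmetry, so fitting reduces to differences of
per-position barrier shifts relative to the parent compound.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .patterns import (
    GROUPS,
    SUBSTITUENTS,
    CompoundRecord,
    SubstitutionPattern,
    BridgeView,
    UNSUBSTITUTED,
    format_pattern_label,
    parse_pattern_label,
)
from .profiles import BridgeParameters

__all__ = [
    "PAIR_13",
    "PAIR_24",
    "STERIC_POSITIONS",
    "IncrementTable",
    "BaseParameters",
    "ModelPrediction",
    "FitError",
    "IncrementKeyError",
    "pair_for_position",
    "load_table3",
    "fit_increments",
    "predict",
    "estimate_distal_increments",
    "approximation_error",
    "approximation_report",
]

PAIR_13 = (1, 3)
PAIR_24 = (2, 4)
#: positions adjacent to the bridge atoms, the only ones with a steric term
STERIC_POSITIONS = (1, 4)


class FitError(ValueError):
    """Raised when the dataset cannot support the requested fit."""


class IncrementKeyError(KeyError):
    """Raised when a prediction needs an increment the table lacks."""


def pair_for_position(position: int) -> tuple[int, int]:
    """The symmetry pair a ring position belongs to: {1,3} or {2,4}."""
    if position in PAIR_13:
        return PAIR_13
    if position in PAIR_24:
        return PAIR_24
    raise ValueError(f"position {position!r} outside 1..4")


SubKey = tuple[str, tuple[int, int]]
SterKey = tuple[str, int]


@dataclass
class IncrementTable:
    """Fitted increments, all in kcal/mol.

    ``e_*`` components apply to the activation energy, ``s_*`` to the
    second minimum.  ``*_sub`` are keyed by (substituent, position pair),
    ``*_ster`` by (substituent, position in {1,4}), and the optional
    ``*_dist`` maps by the full distal pattern.  The unsubstituted pattern
    implicitly contributes 0 everywhere.
    """

    e_sub: dict[SubKey, float] = field(default_factory=dict)
    e_ster: dict[SterKey, float] = field(default_factory=dict)
    s_sub: dict[SubKey, float] = field(default_factory=dict)
    s_ster: dict[SterKey, float] = field(default_factory=dict)
    e_dist: dict[SubstitutionPattern, float] = field(default_factory=dict)
    s_dist: dict[SubstitutionPattern, float] = field(default_factory=dict)
    unfit: tuple[str, ...] = ()

    # -- lookups -----------------------------------------------------------
    def proximal_terms(
        self, pattern: SubstitutionPattern, which: str = "ea"
    ) -> tuple[float, float]:
        """(sub, ster) contributions of a proximal pattern; 0s if unsubstituted."""
        if not pattern.is_substituted:
            return 0.0, 0.0
        sub_map = self.e_sub if which == "ea" else self.s_sub
        ster_map = self.e_ster if which == "ea" else self.s_ster
        key = (pattern.substituent, pair_for_position(pattern.position))
        if key not in sub_map:
            raise IncrementKeyError(
                f"no {'IE' if which == 'ea' else 'IS'}-SUB increment for "
                f"({key[0]}, {{{key[1][0]},{key[1][1]}}})"
            )
        sub = sub_map[key]
        ster = 0.0
        if pattern.position in STERIC_POSITIONS:
            skey = (pattern.substituent, pattern.position)
            if skey not in ster_map:
                raise IncrementKeyError(
                    f"no {'IE' if which == 'ea' else 'IS'}-STER increment for "
                    f"({skey[0]}, {skey[1]})"
                )
            ster = ster_map[skey]
        return sub, ster

    # -- serialization -----------------------------------------------------
    @staticmethod
    def _sub_key_str(key: SubKey) -> str:
        return f"{key[0]}|{key[1][0]},{key[1][1]}"

    def to_dict(self) -> dict:
        return {
            "units": "kcal/mol",
            "e_sub": {self._sub_key_str(k): v for k, v in self.e_sub.items()},
            "e_ster": {f"{s}|{p}": v for (s, p), v in self.e_ster.items()},
            "s_sub": {self._sub_key_str(k): v for k, v in self.s_sub.items()},
            "s_ster": {f"{s}|{p}": v for (s, p), v in self.s_ster.items()},
            "e_dist": {format_pattern_label(k): v for k, v in self.e_dist.items()},
            "s_dist": {format_pattern_label(k): v for k, v in self.s_dist.items()},
            "unfit": list(self.unfit),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "IncrementTable":
        def sub_map(d):
            out = {}
            for key, v in d.items():
                sub, pair = key.split("|")
                a, b = (int(x) for x in pair.split(","))
                out[(sub, (a, b))] = float(v)
            return out

        def ster_map(d):
            out = {}
            for key, v in d.items():
                sub, pos = key.split("|")
                out[(sub, int(pos))] = float(v)
            return out

        def dist_map(d):
            return {parse_pattern_label(k): float(v) for k, v in d.items()}

        return cls(
            e_sub=sub_map(data.get("e_sub", {})),
            e_ster=ster_map(data.get("e_ster", {})),
            s_sub=sub_map(data.get("s_sub", {})),
            s_ster=ster_map(data.get("s_ster", {})),
            e_dist=dist_map(data.get("e_dist", {})),
            s_dist=dist_map(data.get("s_dist", {})),
            unfit=tuple(data.get("unfit", ())),
        )

    def to_json(self, path: Path | str) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: Path | str) -> "IncrementTable":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def to_frame(self) -> pd.DataFrame:
        """Long-format view (component, substituent, key, value)."""
        rows = []
        for (s, pair), v in sorted(self.e_sub.items()):
            rows.append(("e_sub", s, f"{pair[0]},{pair[1]}", v))
        for (s, p), v in sorted(self.e_ster.items()):
            rows.append(("e_ster", s, str(p), v))
        for (s, pair), v in sorted(self.s_sub.items()):
            rows.append(("s_sub", s, f"{pair[0]},{pair[1]}", v))
        for (s, p), v in sorted(self.s_ster.items()):
            rows.append(("s_ster", s, str(p), v))
        for pat, v in sorted(self.e_dist.items(), key=lambda kv: kv[0].sort_key()):
            rows.append(("e_dist", pat.substituent or "None", str(pat.position), v))
        for pat, v in sorted(self.s_dist.items(), key=lambda kv: kv[0].sort_key()):
            rows.append(("s_dist", pat.substituent or "None", str(pat.position), v))
        return pd.DataFrame(rows, columns=["component", "substituent", "key", "value_kcal_mol"])


@dataclass(frozen=True)
class BaseParameters:
    """Activation energy (EBC) and second minimum (SBC) of a parent compound."""

    group: str
    e_base: float
    s_base: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown parent group {self.group!r}")
        if not (self.e_base >= self.s_base >= 0.0):
            raise ValueError(
                f"double-well parent requires e_base >= s_base >= 0, "
                f"got ({self.e_base}, {self.s_base})"
            )


@dataclass(frozen=True)
class ModelPrediction:
    """Predicted EA/SM with itemized additive contributions.

    ``ea``/``sm`` are defined as the plain sums of their component maps
    (base, sub, ster, dist), evaluated in that fixed order.
    """

    ea_components: Mapping[str, float]
    sm_components: Mapping[str, float]

    _ORDER = ("base", "sub", "ster", "dist")

    @property
    def ea(self) -> float:
        return sum(self.ea_components[k] for k in self._ORDER if k in self.ea_components)

    @property
    def sm(self) -> float:
        return sum(self.sm_components[k] for k in self._ORDER if k in self.sm_components)


def load_table3() -> IncrementTable:
    """The packaged empirical increment table (fitted on para+meta groups)."""
    data = json.loads(
        resources.files("ptbridge.data").joinpath("table3.json").read_text("utf-8")
    )
    return IncrementTable.from_dict(data)


# ---------------------------------------------------------------------------
# fitting


def _bases_from_records(
    records: Sequence[CompoundRecord], groups: Sequence[str]
) -> dict[str, BaseParameters]:
    bases = {}
    for rec in records:
        v = rec.view
        if v.proximal.is_substituted or v.distal.is_substituted:
            continue
        p = rec.parameters
        if p is None or not p.has_pt_minimum or v.group not in groups:
            continue
        bases[v.group] = BaseParameters(
            group=v.group, e_base=p.activation_energy, s_base=p.second_minimum
        )
    return bases


def _proximal_mono_shifts(
    records: Sequence[CompoundRecord],
    bases: Mapping[str, BaseParameters],
    groups: Sequence[str],
) -> dict[tuple[str, str, int], tuple[float, float]]:
    """(group, substituent, position) → (ΔEA, ΔSM) vs the group's parent."""
    shifts: dict[tuple[str, str, int], tuple[float, float]] = {}
    for rec in records:
        v = rec.view
        if v.group not in groups or not v.proximal.is_substituted:
            continue
        if v.distal.is_substituted:
            continue
        p = rec.parameters
        if p is None or not p.has_pt_minimum:
            continue
        base = bases[v.group]
        shifts[(v.group, v.proximal.substituent, v.proximal.position)] = (
            p.activation_energy - base.e_base,
            p.second_minimum - base.s_base,
        )
    return shifts


def fit_increments(
    dataset: Sequence[CompoundRecord],
    bases: Mapping[str, BaseParameters] | None = None,
    groups: Sequence[str] = ("para", "meta"),
    method: str = "mean",
) -> IncrementTable:
    """Fit substituent and steric increments from proximal mono-substituted records.

    For each substituent S and group g, with Δg(p) the barrier shift of the
    proximal-S-at-p, distally unsubstituted compound relative to the
    group's parent:

    * IE-SUB(S, {1,3}) = mean over groups of Δg(3)
    * IE-SUB(S, {2,4}) = mean over groups of Δg(2)
    * IE-STER(S, 1)    = mean over groups of Δg(1) − Δg(3)
    * IE-STER(S, 4)    = mean over groups of Δg(4) − Δg(2)

    and identically for the second minimum.  Positions 3 and 2 carry no
    steric term, so they identify the classical (position-pair symmetric)
    effect; positions 1 and 4 then isolate the steric residual.  By default
    only the para and meta groups are used — their two bridges are nearly
    uncorrelated, so the shifts generalize; including ortho is possible but
    warned about.

    ``bases`` may be supplied per group; otherwise they are taken from the
    unsubstituted record of each group.  ``method="lstsq"`` solves the same
    per-substituent linear system by least squares instead of averaging
    (identical on complete noiseless grids).

    A substituent missing its position-3 or position-2 record in any
    included group cannot be decomposed and is reported in ``unfit``.
    """
    if method not in ("mean", "lstsq"):
        raise ValueError(f"unknown fit method {method!r}")
    groups = tuple(groups)
    for g in groups:
        if g not in GROUPS:
            raise FitError(f"unknown group {g!r}")
    if "ortho" in groups:
        warnings.warn(
            "including the ortho group: its two bridges are strongly coupled, "
            "which degrades the transferability of the fitted increments",
            stacklevel=2,
        )

    derived = _bases_from_records(dataset, groups)
    if bases:
        derived.update({g: b for g, b in bases.items() if g in groups})
    missing = [g for g in groups if g not in derived]
    if missing:
        raise FitError(
            f"no base parameters for group(s) {missing}: supply them or include "
            "the unsubstituted records"
        )
    shifts = _proximal_mono_shifts(dataset, derived, groups)

    table = IncrementTable()
    unfit = []
    for sub in SUBSTITUENTS:
        present = {
            (g, p) for (g, s, p) in shifts if s == sub
        }
        if not present:
            continue
        # positions 3 and 2 anchor the pair-symmetric classical effect
        if any((g, 3) not in present or (g, 2) not in present for g in groups):
            unfit.append(sub)
            warnings.warn(
                f"substituent {sub}: missing position-3 or position-2 record; "
                "increments not fitted",
                stacklevel=2,
            )
            continue
        if method == "mean":
            for which in (0, 1):  # 0 → EA maps, 1 → SM maps
                sub_map = table.e_sub if which == 0 else table.s_sub
                ster_map = table.e_ster if which == 0 else table.s_ster
                d = {
                    (g, p): shifts[(g, sub, p)][which]
                    for (g, p) in present
                }
                sub_map[(sub, PAIR_13)] = float(np.mean([d[(g, 3)] for g in groups]))
                sub_map[(sub, PAIR_24)] = float(np.mean([d[(g, 2)] for g in groups]))
                if all((g, 1) in d for g in groups):
                    ster_map[(sub, 1)] = float(
                        np.mean([d[(g, 1)] - d[(g, 3)] for g in groups])
                    )
                if all((g, 4) in d for g in groups):
                    ster_map[(sub, 4)] = float(
                        np.mean([d[(g, 4)] - d[(g, 2)] for g in groups])
                    )
        else:
            _fit_substituent_lstsq(table, sub, shifts, groups)
    table.unfit = tuple(unfit)
    return table


def _fit_substituent_lstsq(
    table: IncrementTable,
    sub: str,
    shifts: Mapping[tuple[str, str, int], tuple[float, float]],
    groups: Sequence[str],
) -> None:
    """Least-squares variant: Δg(p) = a_pair(p) + ster_p·[p ∈ {1,4}]."""
    unknowns = [(sub, PAIR_13), (sub, PAIR_24), (sub, 1), (sub, 4)]
    rows, y_ea, y_sm = [], [], []
    for (g, s, p), (de, ds) in shifts.items():
        if s != sub or g not in groups:
            continue
        row = np.zeros(4)
        row[0 if p in PAIR_13 else 1] = 1.0
        if p == 1:
            row[2] = 1.0
        elif p == 4:
            row[3] = 1.0
        rows.append(row)
        y_ea.append(de)
        y_sm.append(ds)
    A = np.vstack(rows)
    used = np.flatnonzero(np.any(A != 0, axis=0))
    for y, sub_map, ster_map in (
        (y_ea, table.e_sub, table.e_ster),
        (y_sm, table.s_sub, table.s_ster),
    ):
        coef = np.zeros(4)
        coef[used], *_ = np.linalg.lstsq(A[:, used], np.asarray(y), rcond=None)
        sub_map[unknowns[0]] = float(coef[0])
        sub_map[unknowns[1]] = float(coef[1])
        if 2 in used:
            ster_map[unknowns[2]] = float(coef[2])
        if 3 in used:
            ster_map[unknowns[3]] = float(coef[3])


# ---------------------------------------------------------------------------
# prediction and error


def predict(
    base: BaseParameters,
    view: BridgeView,
    table: IncrementTable,
) -> ModelPrediction:
    """Predict (EA, SM) for one bridge view by summing increments.

    The distal term is added only when the table carries distal increments
    and the view's distal pattern is present there; a distal pattern absent
    from a non-empty distal map falls back to the proximal-only model with
    a warning.
    """
    e_sub, e_ster = table.proximal_terms(view.proximal, "ea")
    s_sub, s_ster = table.proximal_terms(view.proximal, "sm")
    ea_comp = {"base": base.e_base, "sub": e_sub, "ster": e_ster}
    sm_comp = {"base": base.s_base, "sub": s_sub, "ster": s_ster}
    if view.distal.is_substituted and (table.e_dist or table.s_dist):
        if view.distal in table.e_dist or view.distal in table.s_dist:
            ea_comp["dist"] = table.e_dist.get(view.distal, 0.0)
            sm_comp["dist"] = table.s_dist.get(view.distal, 0.0)
        else:
            warnings.warn(
                f"distal pattern {format_pattern_label(view.distal)} has no "
                "distal increment; predicting with the proximal-only model",
                stacklevel=2,
            )
    return ModelPrediction(ea_components=ea_comp, sm_components=sm_comp)


def estimate_distal_increments(
    dataset: Sequence[CompoundRecord],
    table: IncrementTable,
    groups: Sequence[str] = ("para", "meta"),
    bases: Mapping[str, BaseParameters] | None = None,
) -> IncrementTable:
    """Estimate distal increments from matched record pairs.

    For each distal pattern d, the increment is the mean over groups and
    proximal patterns of EA(prox, distal=d) − EA(prox, distal=None); SM
    analogously.  Base parameters cancel in the difference, so ``bases``
    is accepted only for interface symmetry.  Returns a copy of ``table``
    with ``e_dist``/``s_dist`` filled for every pattern that has at least
    one matched pair.
    """
    by_key: dict[tuple[str, SubstitutionPattern, SubstitutionPattern], BridgeParameters] = {}
    for rec in dataset:
        v = rec.view
        if v.group in groups and rec.parameters is not None and rec.parameters.has_pt_minimum:
            by_key[(v.group, v.proximal, v.distal)] = rec.parameters

    diffs_e: dict[SubstitutionPattern, list[float]] = {}
    diffs_s: dict[SubstitutionPattern, list[float]] = {}
    for (g, prox, dist), p in by_key.items():
        if not dist.is_substituted:
            continue
        ref = by_key.get((g, prox, UNSUBSTITUTED))
        if ref is None:
            continue
        diffs_e.setdefault(dist, []).append(p.activation_energy - ref.activation_energy)
        diffs_s.setdefault(dist, []).append(p.second_minimum - ref.second_minimum)

    out = replace(
        table,
        e_sub=dict(table.e_sub), e_ster=dict(table.e_ster),
        s_sub=dict(table.s_sub), s_ster=dict(table.s_ster),
        e_dist={d: float(np.mean(v)) for d, v in diffs_e.items()},
        s_dist={d: float(np.mean(v)) for d, v in diffs_s.items()},
    )
    return out


def approximation_error(
    actual: BridgeParameters, predicted: ModelPrediction
) -> tuple[float, float]:
    """Relative error of a prediction in percent, (EA, SM) separately."""
    if not actual.has_pt_minimum:
        raise ValueError("approximation error undefined without a PT minimum")
    out = []
    for a, p in ((actual.activation_energy, predicted.ea),
                 (actual.second_minimum, predicted.sm)):
        if a == 0.0:
            raise ZeroDivisionError(
                "reference value is 0; relative error undefined"
            )
        out.append(100.0 * abs(p - a) / abs(a))
    return out[0], out[1]


@dataclass(frozen=True)
class ErrorReport:
    """Dataset-level approximation-error summary, percentages."""

    per_record: pd.DataFrame
    max_ea: float
    mean_ea: float
    max_sm: float
    mean_sm: float


def approximation_report(
    dataset: Sequence[CompoundRecord],
    bases: Mapping[str, BaseParameters],
    table: IncrementTable,
    groups: Sequence[str] | None = None,
) -> ErrorReport:
    """Self-assess the model on every record with a PT minimum."""
    rows = []
    for rec in dataset:
        v = rec.view
        if groups is not None and v.group not in groups:
            continue
        p = rec.parameters
        if p is None or not p.has_pt_minimum:
            continue
        pred = predict(bases[v.group], v, table)
        err_ea, err_sm = approximation_error(p, pred)
        rows.append(
            (v.group, format_pattern_label(v.proximal),
             format_pattern_label(v.distal),
             p.activation_energy, pred.ea, err_ea,
             p.second_minimum, pred.sm, err_sm)
        )
    if not rows:
        raise FitError("no records with a PT minimum to assess")
    df = pd.DataFrame(
        rows,
        columns=["group", "proximal", "distal",
                 "ea_actual", "ea_model", "ea_error_pct",
                 "sm_actual", "sm_model", "sm_error_pct"],
    )
    return ErrorReport(
        per_record=df,
        max_ea=float(df["ea_error_pct"].max()),
        mean_ea=float(df["ea_error_pct"].mean()),
        max_sm=float(df["sm_error_pct"].max()),
        mean_sm=float(df["sm_error_pct"].mean()),
    )
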