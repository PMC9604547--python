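"""Substitution-grid matrices, spread statistics and charge analyses.

The central visual of the substituent-effect analysis is a matrix of one
bridge parameter (EA, SM or their difference) over proximal pattern (rows)
× distal pattern (columns).  Variation down a column measures the proximal
effect, variation along a row the distal effect; their per-slice standard
deviations quantify the claim that proximal substitution dominates.
Partial-charge tables are consumed as plain label→charge maps and only
ever differenced or summed, never computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .patterns import (
    CompoundRecord,
    SubstitutionPattern,
    format_pattern_label,
)

__all__ = [
    "BridgeMatrix",
    "EffectSpread",
    "ChargeDelta",
    "CorrelationReport",
    "build_matrix",
    "effect_spread",
    "charge_delta",
    "read_charges",
    "distal_charge_correlation",
    "plot_bridge_matrices",
]

_PARAMETER_FIELDS = ("activation_energy", "second_minimum", "difference")


@dataclass(frozen=True)
class BridgeMatrix:
    """Proximal × distal grid of one scalar bridge parameter.

    ``values`` is a DataFrame indexed by proximal pattern labels with
    distal pattern labels as columns; absent combinations are NaN.
    """

    values: pd.DataFrame
    parameter_name: str
    group: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def transpose(self) -> "BridgeMatrix":
        return BridgeMatrix(self.values.T, self.parameter_name, self.group)


@dataclass(frozen=True)
class EffectSpread:
    """Mean ± SD of per-slice sample standard deviations, kcal/mol.

    Proximal: SD down each column (across proximal patterns at fixed
    distal), summarized over columns.  Distal: SD along each row,
    summarized over rows.
    """

    proximal_sd_mean: float
    proximal_sd_sd: float
    distal_sd_mean: float
    distal_sd_sd: float


def build_matrix(
    dataset: Sequence[CompoundRecord], group: str, parameter_name: str
) -> BridgeMatrix:
    """Tabulate one scalar over the (proximal, distal) grid of a group.

    ``parameter_name`` is an extracted bridge parameter
    (``activation_energy``, ``second_minimum``, ``difference``) or the name
    of an auxiliary scalar carried by the records.  Rows and columns follow
    the canonical pattern order (unsubstituted first, then Br, NH2, NO2 at
    positions 1–4); records lacking the value leave missing cells.
    """
    cells: dict[tuple[SubstitutionPattern, SubstitutionPattern], float] = {}
    known_aux = set()
    for rec in dataset:
        if rec.view.group != group:
            continue
        known_aux.update(rec.auxiliary_scalars)
        key = (rec.view.proximal, rec.view.distal)
        if parameter_name in _PARAMETER_FIELDS:
            p = rec.parameters
            if p is None or not p.has_pt_minimum:
                continue
            cells[key] = float(getattr(p, parameter_name))
        elif parameter_name in rec.auxiliary_scalars:
            cells[key] = float(rec.auxiliary_scalars[parameter_name])

    if parameter_name not in _PARAMETER_FIELDS and parameter_name not in known_aux:
        raise KeyError(
            f"unknown parameter {parameter_name!r}: not a bridge parameter "
            f"{_PARAMETER_FIELDS} nor an auxiliary scalar of this dataset"
        )

    rows = sorted({k[0] for k in cells}, key=lambda p: p.sort_key())
    cols = sorted({k[1] for k in cells}, key=lambda p: p.sort_key())
    data = np.full((len(rows), len(cols)), np.nan)
    for (prox, dist), v in cells.items():
        data[rows.index(prox), cols.index(dist)] = v
    frame = pd.DataFrame(
        data,
        index=[format_pattern_label(p) for p in rows],
        columns=[format_pattern_label(p) for p in cols],
    )
    return BridgeMatrix(values=frame, parameter_name=parameter_name, group=group)


def _slice_sds(frame: pd.DataFrame, axis: int, what: str) -> np.ndarray:
    """Sample SDs of columns (axis=0) or rows (axis=1), skipping thin slices."""
    counts = frame.notna().sum(axis=axis)
    thin = counts[counts < 2]
    if len(thin):
        warnings.warn(
            f"{len(thin)} {what}(s) with fewer than 2 values excluded from the "
            "spread statistics",
            stacklevel=3,
        )
    sds = frame.std(axis=axis, ddof=1)[counts >= 2]
    return sds.to_numpy()


def effect_spread(matrix: BridgeMatrix) -> EffectSpread:
    """Summarize proximal vs distal variation of a bridge matrix.

    The proximal spread is the sample SD (ddof=1) down each column, the
    distal spread the SD along each row; each set of per-slice SDs is
    reported as mean ± SD.  Slices with fewer than two present values are
    excluded with a warning.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("effect spread needs at least a 2x2 matrix")
    col_sds = _slice_sds(matrix.values, axis=0, what="column")
    row_sds = _slice_sds(matrix.values, axis=1, what="row")
    return EffectSpread(
        proximal_sd_mean=float(np.mean(col_sds)),
        proximal_sd_sd=float(np.std(col_sds, ddof=1)) if len(col_sds) > 1 else 0.0,
        distal_sd_mean=float(np.mean(row_sds)),
        distal_sd_sd=float(np.std(row_sds, ddof=1)) if len(row_sds) > 1 else 0.0,
    )


@dataclass(frozen=True)
class ChargeDelta:
    """Per-atom charge differences relative to an unsubstituted reference."""

    differences: dict[str, float]
    substituent_only: dict[str, float]


def read_charges(path: Path | str) -> dict[str, float]:
    """Read an (atom_label, charge) CSV into a label→charge map."""
    df = pd.read_csv(path)
    labels = df.iloc[:, 0].astype(str)
    if labels.duplicated().any():
        dup = labels[labels.duplicated()].iloc[0]
        raise ValueError(f"duplicate atom label {dup!r} in {path}")
    return dict(zip(labels, df.iloc[:, 1].astype(float)))


def charge_delta(
    charges: Mapping[str, float], base: Mapping[str, float]
) -> ChargeDelta:
    """Charge redistribution of a substituted structure vs its parent.

    Returns (substituted − base) per shared skeleton atom; atoms present
    only in the substituted structure (the substituent itself) are
    reported separately with their raw charges.  Every skeleton atom of
    ``base`` must be matched.
    """
    missing = [k for k in base if k not in charges]
    if missing:
        raise KeyError(f"skeleton atom(s) {missing} missing from the substituted set")
    diffs = {k: float(charges[k]) - float(base[k]) for k in base}
    extra = {k: float(v) for k, v in charges.items() if k not in base}
    return ChargeDelta(differences=diffs, substituent_only=extra)


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation of distal-ring charge sum vs activation energy."""

    r: float
    n: int
    slope: float
    intercept: float
    p_value: float


def distal_charge_correlation(
    dataset: Sequence[CompoundRecord],
    group: str,
    scalar: str = "distal_charge_sum",
) -> CorrelationReport:
    """Correlate a distal-ring charge sum with EA within one group.

    In the weakly coupled (para/meta) groups the distal effect on the
    barrier tracks the summary charge of the distal ring almost linearly;
    this computes the Pearson r and the least-squares line for records
    carrying the named auxiliary scalar and an extracted EA.
    """
    xs, ys = [], []
    for rec in dataset:
        if rec.view.group != group or scalar not in rec.auxiliary_scalars:
            continue
        p = rec.parameters
        if p is None or not p.has_pt_minimum:
            continue
        xs.append(rec.auxiliary_scalars[scalar])
        ys.append(p.activation_energy)
    if len(xs) < 3:
        raise ValueError(
            f"need at least 3 records with {scalar!r} and EA, got {len(xs)}"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in charge sum or EA; correlation undefined")
    fit = stats.linregress(x, y)
    return CorrelationReport(
        r=float(fit.rvalue), n=len(x), slope=float(fit.slope),
        intercept=float(fit.intercept), p_value=float(fit.pvalue),
    )


def plot_bridge_matrices(
    dataset: Sequence[CompoundRecord],
    group: str,
    out: Path | str | None = None,
):
    """Render the three-panel heatmap (EA, SM, difference) for one group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, axes = plt.subplots(1, 3, figsize=(16, 5), constrained_layout=True)
    titles = {
        "activation_energy": "Activation energy [kcal/mol]",
        "second_minimum": "Second minimum [kcal/mol]",
        "difference": "EA − SM [kcal/mol]",
    }
    for ax, name in zip(axes, _PARAMETER_FIELDS):
        matrix = build_matrix(dataset, group, name)
        sns.heatmap(matrix.values, ax=ax, cmap="viridis", annot=False,
                    cbar_kws={"shrink": 0.8})
        ax.set_title(f"{titles[name]} — {group}")
        ax.set_xlabel("distal pattern")
        ax.set_ylabel("proximal pattern")
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
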