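"""Synthetic substitution grids and double-well scan profiles.

The generator stands in for the quantum-chemistry campaign that would
normally produce the scan curves: it evaluates the additive increment
model with a known ground-truth table (optionally perturbed by Gaussian
noise and explicit pairwise interaction terms) and can materialize each
record as a 21-point double-well profile whose extrema sit exactly on
grid nodes.  Because the ground truth is known, every downstream stage —
extraction, fitting, prediction, spread statistics — can be tested for
exact round-trip recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .increments import BaseParameters, IncrementTable, load_table3
from .patterns import (
    GROUPS,
    BridgeView,
    CompoundRecord,
    CompoundSpec,
    SubstitutionPattern,
    canonical_patterns,
    format_pattern_label,
)
from .profiles import BridgeParameters, ScanProfile, write_profile

__all__ = [
    "ProfileShape",
    "SyntheticConfig",
    "default_bases",
    "generate_profile",
    "generate_dataset",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class ProfileShape:
    """Geometry of a generated double-well scan curve.

    Defaults mirror the scan protocol the data emulate: the O–H distance
    starts at 0.95 Å and is stretched in 20 increments of 0.05 Å (21
    points), with the barrier and the proton-transfer minimum placed on
    interior grid nodes and a repulsive tail past the acceptor.
    """

    r_start: float = 0.95
    step: float = 0.05
    n_steps: int = 20
    barrier_index: int = 7
    pt_min_index: int = 14
    tail_rise: float = 2.0

    def __post_init__(self) -> None:
        if self.step <= 0 or self.r_start <= 0:
            raise ValueError("r_start and step must be positive")
        if not (0 < self.barrier_index < self.pt_min_index < self.n_steps):
            raise ValueError(
                "need 0 < barrier_index < pt_min_index < n_steps, got "
                f"({self.barrier_index}, {self.pt_min_index}, {self.n_steps})"
            )
        if self.tail_rise <= 0:
            raise ValueError("tail_rise must be positive")


def generate_profile(
    ea: float,
    sm: float,
    shape: ProfileShape = ProfileShape(),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> ScanProfile:
    """Build a double-well profile with the requested barrier and PT well.

    The curve is a piecewise cubic through the control points
    (0, 0) → (barrier, ea) → (pt_min, sm) → (end, sm + tail_rise) with zero
    slope at the three stationary points, so each segment is monotone and
    the extrema land exactly on grid nodes.  Gaussian noise (sd
    ``noise_sd`` kcal/mol) perturbs non-control points only: noiseless
    round-trips are exact and noisy ones degrade gracefully.
    """
    if sm > ea:
        raise ValueError(f"second minimum above barrier (sm={sm} > ea={ea})")
    if sm < 0:
        raise ValueError(f"second minimum must be non-negative, got {sm}")
    b, p, n = shape.barrier_index, shape.pt_min_index, shape.n_steps
    x_ctrl = np.array([0, b, p, n], dtype=float)
    y_ctrl = np.array([0.0, ea, sm, sm + shape.tail_rise])
    # zero derivative at the stationary points; quadratic-like exit slope
    d_ctrl = np.array([0.0, 0.0, 0.0, 2.0 * shape.tail_rise / (n - p)])
    spline = CubicHermiteSpline(x_ctrl, y_ctrl, d_ctrl)
    idx = np.arange(n + 1, dtype=float)
    energies = spline(idx)
    energies[[0, b, p, n]] = y_ctrl  # control nodes are exact
    if noise_sd > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        noise = rng.normal(0.0, noise_sd, size=n + 1)
        noise[[0, b, p, n]] = 0.0
        energies = energies + noise
    distances = shape.r_start + shape.step * idx
    return ScanProfile(distances=distances, energies=energies)


@dataclass
class SyntheticConfig:
    """Ground truth and sampling plan for a synthetic substitution grid.

    ``interaction_terms`` inject pairwise (proximal, distal) deviations
    from additivity, emulating through-space couplings such as the
    spring-like O/N repulsion of doubly bridge-adjacent nitro groups.
    ``ortho_coupling`` mimics the stronger bridge–bridge correlation of
    the ortho parent by inflating distal increments for that group.
    """

    truth: IncrementTable = field(default_factory=load_table3)
    bases: Mapping[str, BaseParameters] | None = None
    noise_sd: float = 0.0
    interaction_terms: dict[
        tuple[SubstitutionPattern, SubstitutionPattern], float
    ] = field(default_factory=dict)
    groups: Sequence[str] = ("para", "meta")
    include_unsub_proximal: bool = True
    distal_patterns: Sequence[SubstitutionPattern] | None = None
    seed: int = 0
    ortho_coupling: bool = False
    ortho_distal_scale: float = 1.6

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for g in self.groups:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
        if self.bases is None:
            self.bases = default_bases(self.groups)


def default_bases(
    groups: Sequence[str] = GROUPS, e_base: float = 12.0, s_base: float = 10.0
) -> dict[str, BaseParameters]:
    """Arbitrary-but-plausible parent parameters (EBC = 12, SBC = 10 kcal/mol).

    The real parents' values are not packaged; these defaults are chosen so
    that EA ≥ SM ≥ 0 holds across the whole grid under the packaged
    increment table.
    """
    return {g: BaseParameters(group=g, e_base=e_base, s_base=s_base) for g in groups}


def _model_values(
    config: SyntheticConfig, view: BridgeView
) -> tuple[float, float]:
    """Noise-free EA/SM of one view under the ground-truth model."""
    base = config.bases[view.group]
    e_sub, e_ster = config.truth.proximal_terms(view.proximal, "ea")
    s_sub, s_ster = config.truth.proximal_terms(view.proximal, "sm")
    dist_scale = (
        config.ortho_distal_scale
        if (config.ortho_coupling and view.group == "ortho") else 1.0
    )
    e_dist = config.truth.e_dist.get(view.distal, 0.0) * dist_scale
    s_dist = config.truth.s_dist.get(view.distal, 0.0) * dist_scale
    inter = config.interaction_terms.get((view.proximal, view.distal), 0.0)
    ea = base.e_base + e_sub + e_ster + e_dist + inter
    sm = base.s_base + s_sub + s_ster + s_dist + inter
    return ea, sm


def generate_dataset(config: SyntheticConfig) -> list[CompoundRecord]:
    """Evaluate the ground-truth model over the configured substitution grid.

    One record per (group, proximal, distal) view, enumerated in canonical
    order and realized as a ring-A-scanned compound.  EA and SM are the
    additive model values plus any interaction term and i.i.d. Gaussian
    noise; output is byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    prox_patterns = canonical_patterns(
        include_unsubstituted=config.include_unsub_proximal
    )
    dist_patterns = (
        list(config.distal_patterns)
        if config.distal_patterns is not None else canonical_patterns()
    )
    records = []
    for g in config.groups:
        for prox in prox_patterns:
            for dist in dist_patterns:
                view = BridgeView(CompoundSpec(group=g, ringA=prox, ringB=dist), "A")
                ea, sm = _model_values(config, view)
                if config.noise_sd > 0:
                    eps = rng.normal(0.0, config.noise_sd, size=2)
                    ea += eps[0]
                    sm += eps[1]
                records.append(
                    CompoundRecord(
                        view=view,
                        parameters=BridgeParameters(
                            activation_energy=float(ea), second_minimum=float(sm)
                        ),
                    )
                )
    return records


def _profile_filename(view: BridgeView) -> str:
    prox = format_pattern_label(view.proximal).replace(",", "-")
    dist = format_pattern_label(view.distal).replace(",", "-")
    return f"{view.group}__{prox}__{dist}.csv"


def make_fixture_suite(
    out_dir: Path | str,
    seed: int = 42,
    noise_sd: float = 0.1,
    shape: ProfileShape = ProfileShape(),
) -> dict[str, Path]:
    """Write a complete para+meta grid of profiles plus manifests.

    Two variants are produced under ``out_dir``: ``noiseless/`` (exact
    model curves; fitting on it reproduces the packaged increment table)
    and ``noisy/`` (the same curves with Gaussian energy noise of sd
    ``noise_sd`` on non-control points).  Returns the manifest path per
    variant.  Reruns with the same seed produce identical files.
    """
    out_dir = Path(out_dir)
    config = SyntheticConfig(seed=seed)
    records = generate_dataset(config)
    manifests: dict[str, Path] = {}
    for variant, sd in (("noiseless", 0.0), ("noisy", noise_sd)):
        vdir = out_dir / variant
        profile_dir = vdir / "profiles"
        profile_dir.mkdir(parents=True, exist_ok=True)
        rng = np.random.default_rng(seed)
        manifest_records = []
        import csv

        rows = []
        for rec in records:
            fname = _profile_filename(rec.view)
            profile = generate_profile(
                rec.parameters.activation_energy,
                rec.parameters.second_minimum,
                shape=shape,
                noise_sd=sd,
                seed=rng,
            )
            write_profile(profile, profile_dir / fname)
            rows.append(
                {
                    "group": rec.view.group,
                    "ringA": format_pattern_label(rec.view.spec.ringA),
                    "ringB": format_pattern_label(rec.view.spec.ringB),
                    "bridge": rec.view.scanned_bridge,
                    "profile_path": f"profiles/{fname}",
                    "ea": "",
                    "sm": "",
                }
            )
        manifest = vdir / "manifest.csv"
        with manifest.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["group", "ringA", "ringB", "bridge",
                                "profile_path", "ea", "sm"]
            )
            writer.writeheader()
            writer.writerows(rows)
        manifests[variant] = manifest
    return manifests
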