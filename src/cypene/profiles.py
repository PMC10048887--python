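"""Reaction-path assembly, kinetic/thermodynamic descriptors, and diagrams.

A reaction path strings together the stationary points of one hydrogen
abstraction / oxygen rebound route: reactant complex (I) → abstraction
transition state (II) → substrate radical + Fe–OH (III) → rebounded
hydroxylated product (IV). The rebound step could not be characterized by a
transition state at the study's level of theory, so a path with stage IV but
no intervening TS is connected by a barrierless segment — a first-class
state, not an error. Stage II may likewise be absent (flagged, used for
sensitivity checks only).

Descriptors follow the usual conventions: Δ_r quantities are (III − I),
barrier (‡) quantities are (II − I), and the hydroxylation free energy is
(IV − I) in corrected G. Negative = energy released.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import pandas as pd

from .constants import CODATA, Constants
from .energetics import SpeciesLabel, Stage, StationaryPoint, convert_energy

__all__ = [
    "ReactionPath",
    "PathDescriptors",
    "ProfileDiagram",
    "assemble_path",
    "path_descriptors",
    "profile_report",
    "build_diagram",
    "render_diagram",
    "round_sig",
    "REPORT_COLUMNS",
]

_PATH_STAGES = (
    Stage.REACTANT_COMPLEX,
    Stage.ABSTRACTION_TS,
    Stage.RADICAL,
    Stage.HYDROXYLATED,
)


def round_sig(value: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (report cells; internals stay full)."""
    if value == 0 or not math.isfinite(value):
        return value
    return round(value, sig - 1 - int(math.floor(math.log10(abs(value)))))


@dataclass(frozen=True)
class ReactionPath:
    """Stationary points of one site/spin/stereo route, keyed by stage."""

    label: SpeciesLabel
    stage_points: dict[Stage, StationaryPoint]

    def __post_init__(self) -> None:
        if Stage.REACTANT_COMPLEX not in self.stage_points:
            raise ValueError("a reaction path requires a stage-I reactant complex")
        for stage, point in self.stage_points.items():
            if stage not in _PATH_STAGES:
                raise ValueError(f"stage {stage.value} does not belong on a path")
            if point.label != self.label:
                raise ValueError(
                    f"stage {stage.value} point labelled {point.label.describe()} "
                    f"on path {self.label.describe()}"
                )

    def __getitem__(self, stage: Stage) -> StationaryPoint:
        return self.stage_points[stage]

    def get(self, stage: Stage) -> StationaryPoint | None:
        return self.stage_points.get(stage)

    @property
    def barrierless_abstraction(self) -> bool:
        """True when no abstraction TS (stage II) was supplied."""
        return Stage.ABSTRACTION_TS not in self.stage_points

    @property
    def barrierless_rebound(self) -> bool:
        """The III→IV rebound carries no located TS at this level of theory."""
        return Stage.HYDROXYLATED in self.stage_points


def assemble_path(points: Sequence[StationaryPoint]) -> ReactionPath:
    """Group stationary points sharing one label into a path.

    Rejects mixed labels, duplicate stages, and a missing stage I.
    """
    if not points:
        raise ValueError("cannot assemble a path from no points")
    label = points[0].label
    stage_points: dict[Stage, StationaryPoint] = {}
    for p in points:
        if p.label != label:
            raise ValueError(
                f"mixed labels on one path: {label.describe()} vs {p.label.describe()}"
            )
        if p.stage in stage_points:
            raise ValueError(f"duplicate stage {p.stage.value} on path")
        stage_points[p.stage] = p
    return ReactionPath(label=label, stage_points=stage_points)


@dataclass(frozen=True)
class PathDescriptors:
    """The nine kinetic/thermodynamic descriptors of one path, in kcal/mol.

    A descriptor is ``None`` when the energy column it needs is absent from
    the underlying stationary points.
    """

    d_r_e: float | None = None       # Δ_rE   electronic reaction energy
    de_act: float | None = None      # ΔE‡    electronic barrier
    d_r_h: float | None = None       # Δ_rH
    dh_act: float | None = None      # ΔH‡
    d_r_g: float | None = None       # Δ_rG   (uncorrected free energy)
    dg_act: float | None = None      # ΔG‡
    d_r_g_cor: float | None = None   # Δ_rG_cor
    dg_act_cor: float | None = None  # ΔG‡_cor
    hyd_d_r_g_cor: float | None = None  # hydroxylation IV − I in corrected G

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _column(point: StationaryPoint, attr: str) -> float | None:
    return getattr(point, attr)


def path_descriptors(
    path: ReactionPath, constants: Constants = CODATA
) -> PathDescriptors:
    """Derive all available descriptors; missing columns yield ``None`` cells."""
    stage_i = path[Stage.REACTANT_COMPLEX]
    stage_ii = path.get(Stage.ABSTRACTION_TS)
    stage_iii = path.get(Stage.RADICAL)
    stage_iv = path.get(Stage.HYDROXYLATED)

    def diff(a: StationaryPoint | None, b: StationaryPoint | None, attr: str) -> float | None:
        if a is None or b is None:
            return None
        va, vb = _column(a, attr), _column(b, attr)
        if va is None or vb is None:
            return None
        return convert_energy(va - vb, "hartree", "kcal/mol", constants)

    return PathDescriptors(
        d_r_e=diff(stage_iii, stage_i, "e_elec"),
        de_act=diff(stage_ii, stage_i, "e_elec"),
        d_r_h=diff(stage_iii, stage_i, "h"),
        dh_act=diff(stage_ii, stage_i, "h"),
        d_r_g=diff(stage_iii, stage_i, "g_uncorrected"),
        dg_act=diff(stage_ii, stage_i, "g_uncorrected"),
        d_r_g_cor=diff(stage_iii, stage_i, "g"),
        dg_act_cor=diff(stage_ii, stage_i, "g"),
        hyd_d_r_g_cor=diff(stage_iv, stage_i, "g"),
    )


REPORT_COLUMNS = [
    "site",
    "spin",
    "stereopath",
    "enantiomer",
    "dE_r",
    "dE_act",
    "dH_r",
    "dH_act",
    "dG_r",
    "dG_act",
    "dG_r_cor",
    "dG_act_cor",
    "hyd_dG_r_cor",
]

_DESCRIPTOR_TO_REPORT = {
    "d_r_e": "dE_r",
    "de_act": "dE_act",
    "d_r_h": "dH_r",
    "dh_act": "dH_act",
    "d_r_g": "dG_r",
    "dg_act": "dG_act",
    "d_r_g_cor": "dG_r_cor",
    "dg_act_cor": "dG_act_cor",
    "hyd_d_r_g_cor": "hyd_dG_r_cor",
}

_SITE_ORDER = ["alpha", "gamma", "delta", "epsilon", "zeta", "theta", "iota", "kappa"]
_STEREO_ORDER = {"cis": 0, "trans": 1, "none": 2}


def profile_report(
    paths: Iterable[ReactionPath], constants: Constants = CODATA
) -> pd.DataFrame:
    """One row per (site, spin, stereopath) with the nine descriptors, full precision.

    Rows are ordered by site, then spin ascending, then cis before trans.
    Empty cells stay NaN (rendered as empty in CSV), never zero.
    """
    records = []
    for path in paths:
        desc = path_descriptors(path, constants)
        record: dict[str, object] = {
            "site": path.label.site.value,
            "spin": path.label.spin,
            "stereopath": path.label.stereopath.value,
            "enantiomer": path.label.enantiomer.value,
        }
        for name, column in _DESCRIPTOR_TO_REPORT.items():
            record[column] = desc.as_dict()[name]
        records.append(record)
    if not records:
        raise ValueError("profile_report needs at least one path")
    frame = pd.DataFrame(records, columns=REPORT_COLUMNS)
    frame = frame.sort_values(
        by=["site", "spin", "stereopath"],
        key=lambda col: (
            col.map({s: i for i, s in enumerate(_SITE_ORDER)})
            if col.name == "site"
            else col.map(_STEREO_ORDER) if col.name == "stereopath" else col
        ),
        kind="stable",
    ).reset_index(drop=True)
    return frame


@dataclass(frozen=True)
class ProfileDiagram:
    """Per-path relative free energies against a single global reference.

    The reference is the most stable stage-I structure across all paths; all
    values are (G − G_ref) in kcal/mol.
    """

    reference_label: SpeciesLabel
    series: tuple[tuple[str, tuple[tuple[Stage, float], ...]], ...]


def build_diagram(
    paths: Sequence[ReactionPath], constants: Constants = CODATA
) -> ProfileDiagram:
    if not paths:
        raise ValueError("diagram needs at least one path")
    reactants = [p[Stage.REACTANT_COMPLEX] for p in paths]
    ref_point = min(reactants, key=lambda p: p.g)
    series = []
    for path in paths:
        values = tuple(
            (
                stage,
                convert_energy(
                    path[stage].g - ref_point.g, "hartree", "kcal/mol", constants
                ),
            )
            for stage in _PATH_STAGES
            if stage in path.stage_points
        )
        series.append((path.label.describe(), values))
    return ProfileDiagram(reference_label=ref_point.label, series=tuple(series))


_STAGE_X = {s: i for i, s in enumerate(_PATH_STAGES)}


def _diagram_csv(diagram: ProfileDiagram) -> str:
    lines = ["path,stage,relative_g_kcal"]
    for name, values in diagram.series:
        for stage, value in values:
            lines.append(f"{name},{stage.value},{value:.6f}")
    return "\n".join(lines) + "\n"


def _diagram_text(diagram: ProfileDiagram) -> str:
    header = f"reference: {diagram.reference_label.describe()} (0.0 kcal/mol)"
    lines = [header, "-" * len(header)]
    for name, values in diagram.series:
        cells = "  ".join(f"{stage.value}:{value:+9.6f}" for stage, value in values)
        lines.append(f"{name:<28s} {cells}")
    return "\n".join(lines) + "\n"


def _diagram_svg(diagram: ProfileDiagram) -> str:
    # hand-written static SVG: deterministic bytes for snapshot testing
    width, height, margin = 640, 400, 50
    all_vals = [v for _, values in diagram.series for _, v in values]
    lo, hi = min(all_vals + [0.0]), max(all_vals + [0.0])
    span = (hi - lo) or 1.0
    n_stages = len(_PATH_STAGES)

    def x(stage: Stage) -> float:
        return margin + _STAGE_X[stage] * (width - 2 * margin) / (n_stages - 1)

    def y(value: float) -> float:
        return height - margin - (value - lo) * (height - 2 * margin) / span

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
        f'<text x="{margin}" y="20" font-size="12">relative G (kcal/mol) vs '
        f"reaction coordinate; reference {diagram.reference_label.describe()}</text>",
    ]
    palette = ["#1b6ca8", "#d1495b", "#3e885b", "#8d6a9f", "#c77f2d", "#4a4a4a"]
    for i, (name, values) in enumerate(diagram.series):
        color = palette[i % len(palette)]
        pts = " ".join(f"{x(s):.1f},{y(v):.1f}" for s, v in values)
        parts.append(
            f'<polyline points="{pts}" fill="none" stroke="{color}" stroke-width="1.5"/>'
        )
        sx, sv = values[-1]
        parts.append(
            f'<text x="{x(sx) + 4:.1f}" y="{y(sv):.1f}" font-size="9" '
            f'fill="{color}">{name}</text>'
        )
    for stage in _PATH_STAGES:
        parts.append(
            f'<text x="{x(stage):.1f}" y="{height - 20}" font-size="11" '
            f'text-anchor="middle">{stage.value}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_diagram(
    paths: Sequence[ReactionPath],
    format: str = "text",
    constants: Constants = CODATA,
) -> str:
    """Render the multi-path free-energy diagram as csv, text or svg."""
    diagram = build_diagram(paths, constants)
    renderers = {"csv": _diagram_csv, "text": _diagram_text, "svg": _diagram_svg}
    if format not in renderers:
        raise ValueError(f"unsupported diagram format {format!r}; use {sorted(renderers)}")
    return renderers[format](diagram)
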