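"""Morphological classification of simulated wheal masks.

Clinically, urticarial eruptions present as a handful of recurring
geometries — large or small annular rings, broken (arc-like) rings, filled
circular plaques, scattered dots, or near-uniform involvement.  This module
maps a binary wheal mask onto that taxonomy with explicit, reproducible
decision rules (the clinical classes are visual; every threshold used here
is exposed in :class:`ClassifierConfig`), and drives parameter sweeps that
tabulate the minimal developing stimulus and the pattern class over a grid
of kinetic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.measure import label, regionprops

from . import stimulus as _stimulus
from .errors import BracketFailureError, NeverDevelopsError, WhealSimError
from .kinetics import KineticParams
from .rdsolver import SolverConfig, WhealParams, grid_2d, make_state, run

__all__ = ["ClassifierConfig", "PatternReport", "classify", "sweep",
           "render_regime_map"]


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the pattern decision rules (lengths in mm)."""

    uniform_coverage: float = 0.9      # coverage fraction for "uniform"
    fine_dot_mm: float = 3.0           # median diameter below -> fine dots
    dot_mm: float = 8.0                # median diameter below -> dots (if many)
    min_dot_count: int = 20            # "many" components for the dots class
    large_feature_mm: float = 5.0      # components at least this wide drive
                                       # the ring/arc/disk rules
    ring_fill_excess: float = 1.2      # filled/area ratio above -> ring
    large_annulus_mm: float = 20.0     # median outer diameter above -> large
    arc_solidity: float = 0.5          # below, with no hole -> arc fragment
    disk_solidity: float = 0.9         # above, with no hole -> filled disk


@dataclass(frozen=True)
class PatternReport:
    """Classification result for one wheal mask."""

    class_label: str
    n_components: int
    component_diameters: tuple[float, ...]  # equivalent diameters, mm
    coverage_fraction: float
    n_ring_components: int


def _equiv_diam_mm(area_cells: float, scale: float) -> float:
    return 2.0 * np.sqrt(area_cells / np.pi) * scale


def classify(mask: np.ndarray, scale: float,
             cfg: ClassifierConfig = ClassifierConfig()) -> PatternReport:
    """Classify a binary wheal mask.

    Parameters
    ----------
    mask
        Boolean array, True where a wheal is present (H >= 0.5).
    scale
        Millimetres per grid cell.

    Notes
    -----
    Components are 8-connected.  A component is a *ring* when its filled
    area exceeds its own area by the configured excess (it encloses a
    hole); an *arc fragment* when it is strongly non-convex without a hole;
    a *filled disk* when it is nearly convex without a hole.  Decision
    order: empty -> none; high coverage -> uniform; sub-3-mm median
    diameter -> fine dots; many small components -> dots; among components
    at least 5 mm wide, a ring majority -> annular (large/small by median
    outer diameter), arcs outnumbering rings -> broken annular, a disk
    majority -> circular; anything else -> dots.
    """
    mask = np.asarray(mask, dtype=bool)
    coverage = float(mask.mean()) if mask.size else 0.0
    if not mask.any():
        return PatternReport("none", 0, (), 0.0, 0)
    lab = label(mask, connectivity=2)
    props = regionprops(lab)
    diams = tuple(_equiv_diam_mm(p.area, scale) for p in props)
    is_ring = [p.area_filled >= cfg.ring_fill_excess * p.area for p in props]
    n_rings = int(sum(is_ring))
    n = len(props)
    report = lambda label_: PatternReport(label_, n, diams, coverage, n_rings)

    if coverage >= cfg.uniform_coverage:
        return report("uniform")
    med = float(np.median(diams))
    if med < cfg.fine_dot_mm:
        return report("fine_dots")
    if n >= cfg.min_dot_count and med < cfg.dot_mm:
        return report("dots")

    big = [(p, r) for p, r, d in zip(props, is_ring, diams)
           if d >= cfg.large_feature_mm]
    if big:
        rings = [p for p, r in big if r]
        no_hole = [p for p, r in big if not r and p.area_filled <= p.area * (1 + 1e-9)]
        arcs = [p for p in no_hole if p.solidity < cfg.arc_solidity]
        disks = [p for p in no_hole if p.solidity >= cfg.disk_solidity]
        if len(rings) >= 0.5 * len(big) and rings:
            outer = np.median([_equiv_diam_mm(p.area_filled, scale) for p in rings])
            return report("annular_large" if outer >= cfg.large_annulus_mm
                          else "annular_small")
        if arcs and len(arcs) > len(rings):
            return report("broken_annular")
        if len(disks) >= 0.5 * len(big):
            return report("circular")
    return report("dots")


def sweep(params: Iterable[KineticParams | Mapping[str, float]],
          spec: _stimulus.StimulusSpec, wp: WhealParams, cfg: SolverConfig,
          scale: float, clf: ClassifierConfig = ClassifierConfig(),
          c_max: float = 1.0, out_csv=None, resume: bool = True):
    """P_min and pattern class over a list of kinetic parameter points.

    For each point the minimal developing stimulus is located with
    :func:`whealsim.stimulus.find_p_min` and the wheal mask at the template
    stimulus ``spec`` (its ``r`` taken literally) is classified at
    ``t_end``.  Individual failures are recorded (status column) and the
    sweep continues.  When ``out_csv`` exists and ``resume`` is true,
    completed parameter points are skipped.

    Returns a :class:`pandas.DataFrame`, one row per point.
    """
    import pandas as pd

    param_cols = ["gamma", "alpha0", "alpha1", "alpha2", "mu", "u_tot", "d_u"]
    done: set[tuple] = set()
    rows: list[dict] = []
    if out_csv is not None and resume:
        try:
            prev = pd.read_csv(out_csv)
            rows = prev.to_dict("records")
            done = {tuple(np.round([r[c] for c in param_cols], 12)) for r in rows}
        except (FileNotFoundError, pd.errors.EmptyDataError):
            pass

    for point in params:
        p = point if isinstance(point, KineticParams) else KineticParams(**point)
        key = tuple(np.round([getattr(p, c) for c in param_cols], 12))
        if key in done:
            continue
        row: dict = {c: getattr(p, c) for c in param_cols}
        try:
            row["p_min_percent"] = _stimulus.find_p_min(
                p, spec, wp, cfg, c_max=c_max)
            row["status"] = "ok"
        except NeverDevelopsError:
            row["p_min_percent"] = np.nan
            row["status"] = "never_develops"
        except (BracketFailureError, WhealSimError) as exc:
            row["p_min_percent"] = np.nan
            row["status"] = f"failed: {exc}"
        if row["status"] == "ok":
            try:
                eq_u0 = _stimulus.equilibria(p, chi=1).u0_star or 0.0
                u0 = _stimulus.initial_condition(eq_u0, spec, grid_2d(cfg),
                                                 cfg.length)
                traj = run(p, u0, wp, cfg)
                rep = classify(traj.wheal_mask(-1), scale, clf)
                row["class"] = rep.class_label
                row["n_components"] = rep.n_components
                row["coverage_fraction"] = rep.coverage_fraction
                row["n_ring_components"] = rep.n_ring_components
            except WhealSimError as exc:
                row["class"] = "error"
                row["status"] = f"classify failed: {exc}"
        else:
            row["class"] = row["status"]
        rows.append(row)
        if out_csv is not None:
            pd.DataFrame(rows).to_csv(out_csv, index=False)
    return pd.DataFrame(rows)


def render_regime_map(df, x: str, y: str, path,
                      value: str = "p_min_percent") -> None:
    """Render a sweep result as a PNG heatmap of ``value`` over (x, y).

    Never-developing points appear as blanks (NaN).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = df.pivot_table(index=y, columns=x, values=value, aggfunc="mean")
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(pivot.columns.to_numpy(), pivot.index.to_numpy(),
                       pivot.to_numpy(), shading="nearest", cmap="viridis")
    fig.colorbar(im, ax=ax, label=value)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
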