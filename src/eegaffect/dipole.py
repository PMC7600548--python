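"""Equivalent-current-dipole fits of IC topographies and brain-IC selection.

Each IC's scalp pattern is explained by a single dipole: a coarse grid
search over interior locations (the moment at each candidate is the linear
least-squares solution against the 3-column lead-field basis), followed by
derivative-free simplex refinement of the location.  Goodness of fit is the
residual variance RV = 1 − ‖fitted‖²/‖topography‖² in average-reference
space; components are kept for analysis only if RV ≤ 15 %, the dipole lies
inside the brain compartment, and two automated artifact heuristics pass
(no muscle-like rising high-frequency spectrum, no ocular-like frontal
concentration of topography energy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .bandpower import welch_psd
from .headmodel import BRAIN_MARGIN, HeadModel
from .ica import Decomposition


@dataclass
class DipoleFit:
    location_mm: np.ndarray
    moment: np.ndarray
    residual_variance: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.location_mm = np.asarray(self.location_mm, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)


@dataclass
class BrainICSelection:
    """Keep/exclude decision per IC with machine-readable reasons."""

    kept: list[bool]
    reason: list[str | None]            # first failing criterion, None if kept
    reasons: list[list[str]] = field(default_factory=list)  # all failures

    @property
    def kept_indices(self) -> list[int]:
        return [i for i, k in enumerate(self.kept) if k]


# cache of (grid locations, orthonormal lead-field bases) per head model + step
_GRID_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _grid_for(model: HeadModel, step_mm: float, radius_frac: float = BRAIN_MARGIN):
    key = (
        round(model.sphere_radius, 6),
        model.n_channels,
        round(step_mm, 6),
        round(radius_frac, 6),
        hash(model.channel_positions.tobytes()),
    )
    if key in _GRID_CACHE:
        return _GRID_CACHE[key]
    rmax = radius_frac * model.sphere_radius
    ax = np.arange(-rmax, rmax + 1e-9, step_mm)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= rmax]
    bases = model.lead_field_bases(pts)           # (L, C, 3)
    q, _ = np.linalg.qr(bases)                    # orthonormal column spans
    _GRID_CACHE[key] = (pts, q)
    return pts, q


def _rv_at(model: HeadModel, loc: np.ndarray, topo: np.ndarray) -> tuple[float, np.ndarray]:
    """Residual variance and optimal moment of a dipole at ``loc``."""
    basis = model.lead_field_basis(loc)
    moment, *_ = np.linalg.lstsq(basis, topo, rcond=None)
    resid = topo - basis @ moment
    rv = float(resid @ resid) / float(topo @ topo)
    return rv, moment


def fit_dipole(
    topography: np.ndarray,
    model: HeadModel,
    grid_step_mm: float = 10.0,
    refine_tol: float = 0.5,
) -> DipoleFit:
    """Fit a single equivalent dipole to one average-referenced topography.

    The returned residual variance is scale invariant, and the refined
    solution is never worse than the best coarse-grid candidate.
    """
    topo = np.asarray(topography, dtype=float)
    if topo.ndim != 1 or topo.shape[0] != model.n_channels:
        raise ValueError(
            f"topography length {topo.shape} does not match {model.n_channels} channels"
        )
    nrm = np.linalg.norm(topo)
    if nrm == 0:
        raise ValueError("zero topography cannot be localized")
    topo = topo - topo.mean()          # average-reference space
    t_unit = topo / np.linalg.norm(topo)

    pts, q = _grid_for(model, grid_step_mm)
    proj = np.einsum("lcj,c->lj", q, t_unit)
    rv_grid = 1.0 - np.einsum("lj,lj->l", proj, proj)
    best = int(np.argmin(rv_grid))
    x0 = pts[best]

    # clearly non-dipolar patterns keep the (already optimal-on-grid) coarse
    # solution; the local search would chase noise at real cost
    if rv_grid[best] > 0.6:
        rv, moment = _rv_at(model, x0, topo)
        return DipoleFit(location_mm=x0, moment=moment, residual_variance=rv,
                         converged=False)

    r_cap = 0.98 * model.sphere_radius

    def objective(loc):
        r = np.linalg.norm(loc)
        if r >= r_cap:
            return 1.0 + (r - r_cap) / model.sphere_radius
        rv, _ = _rv_at(model, loc, topo)
        return rv

    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": refine_tol,
            "fatol": 1e-10,
            "maxiter": 250,
            "initial_simplex": x0 + np.vstack([np.zeros(3), np.eye(3) * grid_step_mm / 2]),
        },
    )
    loc = res.x if objective(res.x) <= rv_grid[best] else x0
    rv, moment = _rv_at(model, loc, topo)
    return DipoleFit(
        location_mm=loc,
        moment=moment,
        residual_variance=rv,
        converged=bool(res.success) and model.contains(loc),
    )


def fit_all_dipoles(
    decomposition: Decomposition, model: HeadModel, grid_step_mm: float = 10.0,
    refine_tol: float = 0.5,
) -> list[DipoleFit]:
    return [
        fit_dipole(decomposition.mixing[:, j], model, grid_step_mm, refine_tol)
        for j in range(decomposition.n_components)
    ]


def psd_log_slope(
    activation: np.ndarray,
    sampling_rate: float,
    band_hz: tuple[float, float] = (20.0, 45.0),
    max_samples: int = 131072,
) -> float:
    """Slope of log PSD vs log frequency over ``band_hz`` (muscle check)."""
    freqs, psd = welch_psd(activation[..., :max_samples], sampling_rate)
    mask = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    lf = np.log(freqs[mask])
    lp = np.log(psd[mask] + 1e-30)
    slope = np.polyfit(lf, lp, 1)[0]
    return float(slope)


def frontal_energy_fraction(
    topography: np.ndarray, channel_positions: np.ndarray, n_frontal: int = 4
) -> float:
    """Fraction of squared topography weight on the ``n_frontal`` front-most
    channels (largest anterior coordinate)."""
    front = np.argsort(channel_positions[:, 1])[::-1][:n_frontal]
    energy = topography**2
    return float(energy[front].sum() / energy.sum())


def select_brain_ics(
    decomposition: Decomposition,
    fits: list[DipoleFit],
    model: HeadModel,
    sampling_rate: float = 512.0,
    rv_max: float = 0.15,
    brain_margin: float = BRAIN_MARGIN,
    psd_slope_band: tuple[float, float] = (20.0, 45.0),
    frontal_fraction_max: float = 0.6,
    n_frontal: int = 4,
) -> BrainICSelection:
    """Keep ICs that look like brain sources; record why others fail.

    Reasons: ``rv_exceeds_threshold`` (RV > 15 %), ``outside_brain``
    (dipole beyond the brain-compartment radius), ``artifact_spectrum``
    (rising log-log PSD at 20–45 Hz), ``artifact_topography`` (> 60 % of
    topography energy on the 4 front-most channels).  An empty keep-set is
    allowed.
    """
    if len(fits) != decomposition.n_components:
        raise ValueError("need exactly one dipole fit per IC")
    kept, reason, reasons = [], [], []
    for j, fit in enumerate(fits):
        fails = []
        if fit.residual_variance > rv_max:
            fails.append("rv_exceeds_threshold")
        if np.linalg.norm(fit.location_mm) > brain_margin * model.sphere_radius:
            fails.append("outside_brain")
        if psd_log_slope(decomposition.activations[j], sampling_rate, psd_slope_band) > 0:
            fails.append("artifact_spectrum")
        if (
            frontal_energy_fraction(
                decomposition.mixing[:, j], model.channel_positions, n_frontal
            )
            > frontal_fraction_max
        ):
            fails.append("artifact_topography")
        kept.append(not fails)
        reason.append(fails[0] if fails else None)
        reasons.append(fails)
    return BrainICSelection(kept=kept, reason=reason, reasons=reasons)
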