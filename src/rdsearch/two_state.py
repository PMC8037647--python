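"""Stage 1: two-state fits and the SSE-based residue classification.

Difference profiles are first fitted to the fast-limit two-state model,
per residue and globally with a shared exchange rate.  The sum of squared
errors (SSE) of the individual fit classifies each residue: residues whose
profiles the two-state model cannot reproduce (SSE above a cutoff, 0.7 by
default) are carried forward to the three-state searches.

Fitting exploits the model's structure: once ``kex`` is fixed the model is
linear in the per-field baselines R20 and in the dispersion amplitude
A = P_F P_C dw^2 / kex, so the inner parameters are profiled out by linear
least squares and the fit reduces to a one-dimensional problem in ``kex``.
That 1-D profile objective is scanned on a dense logarithmic grid over the
full search range and polished by bounded scalar minimisation, which makes
the reported minimum a global one for all practical purposes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .models import (
    AngularConvention,
    CpmgProfile,
    ResidueDataset,
    TwoStateParams,
)

__all__ = [
    "TwoStateConfig",
    "TwoStateFitResult",
    "fit_two_state_individual",
    "fit_two_state_global",
    "classify_residues",
]

#: Dispersion amplitudes below this (s^-1) are treated as flat profiles.
FLAT_AMPLITUDE = 1e-6


@dataclass(frozen=True)
class TwoStateConfig:
    """Knobs of the two-state stage.

    ``kex_bounds`` reuses the three-state search range; ``n_grid`` is the
    size of the logarithmic kex scan.  Populations are fixed, not fitted.
    """

    p_f: float = 0.95
    p_c: float = 0.05
    kex_bounds: tuple[float, float] = (1.0, 2000.0)
    n_grid: int = 400
    sse_threshold: float = 0.7
    convention: AngularConvention = AngularConvention.HZ_DIRECT


@dataclass
class TwoStateFitResult:
    residue_id: str
    params: TwoStateParams
    r20_by_field: dict[float, float]
    sse: float
    per_field_rmsd: dict[float, float]
    mode: str  # "individual" | "global_shared_kex"
    degenerate: bool = False
    converged: bool = True

    @property
    def classification(self) -> str | None:
        return getattr(self, "_classification", None)


def _fast_shape(nu: np.ndarray, kex: float) -> np.ndarray:
    x = kex / (4.0 * nu)
    return 1.0 - np.tanh(x) / x


def _profiled_fit(
    profiles: Sequence[CpmgProfile], kex: float, config: TwoStateConfig
) -> tuple[float, dict[float, float], float]:
    """Linear solve for (R20 per field, amplitude>=0) at fixed kex.

    Returns (sse, r20_by_field, amplitude) where amplitude is
    P_F P_C dw_ref^2 / kex in the active convention.
    """
    n_f = len(profiles)
    rows = sum(p.n_points for p in profiles)
    design = np.zeros((rows, n_f + 1))
    y = np.zeros(rows)
    pos = 0
    for j, p in enumerate(profiles):
        m = p.n_points
        design[pos : pos + m, j] = 1.0
        design[pos : pos + m, n_f] = p.field.ratio**2 * _fast_shape(p.nu_cpmg, kex)
        y[pos : pos + m] = p.r2_eff
        pos += m
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    amp = coef[n_f]
    if amp < 0.0:  # no physical dispersion: clamp and refit baselines only
        amp = 0.0
        coef = np.array([float(np.mean(p.r2_eff)) for p in profiles] + [0.0])
    resid = y - design @ coef
    sse = float(resid @ resid)
    r20 = {p.field.mhz: float(coef[j]) for j, p in enumerate(profiles)}
    return sse, r20, float(amp)


def _amp_to_dw(amp: float, kex: float, config: TwoStateConfig) -> float:
    w2 = amp * kex / (config.p_f * config.p_c)
    return math.sqrt(max(w2, 0.0)) / config.convention.factor


def _kex_grid(config: TwoStateConfig) -> np.ndarray:
    lo, hi = config.kex_bounds
    return np.geomspace(lo, hi, config.n_grid)


def _scan_kex(sse_of_kex, config: TwoStateConfig) -> tuple[float, bool]:
    """Global 1-D minimisation of the profiled SSE over kex."""
    grid = _kex_grid(config)
    vals = np.array([sse_of_kex(k) for k in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    converged = True
    if lo < hi:
        res = minimize_scalar(sse_of_kex, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        if res.fun <= vals[i]:
            return float(res.x), bool(res.success)
        converged = bool(res.success)
    return float(grid[i]), converged


def _rmsd_by_field(
    profiles: Sequence[CpmgProfile], kex: float, r20: dict[float, float],
    amp: float,
) -> dict[float, float]:
    out = {}
    for p in profiles:
        model = r20[p.field.mhz] + amp * p.field.ratio**2 * _fast_shape(p.nu_cpmg, kex)
        out[p.field.mhz] = float(np.sqrt(np.mean((model - p.r2_eff) ** 2)))
    return out


def fit_two_state_individual(
    dataset: ResidueDataset, config: TwoStateConfig | None = None
) -> TwoStateFitResult:
    """Per-residue two-state fit over {R20 per field, kex, dw_fc}.

    Flat profiles (no resolvable dispersion amplitude) leave kex
    unidentifiable; the result is flagged ``degenerate`` rather than
    raising.
    """
    config = config or TwoStateConfig()
    if dataset.n_points < 3:
        raise ValueError(f"dataset {dataset.residue_id!r} has too few points to fit")

    def sse_of_kex(k: float) -> float:
        return _profiled_fit(dataset.profiles, k, config)[0]

    kex, converged = _scan_kex(sse_of_kex, config)
    sse, r20, amp = _profiled_fit(dataset.profiles, kex, config)
    dw = _amp_to_dw(amp, kex, config)
    degenerate = amp < FLAT_AMPLITUDE
    ref = dataset.reference_mhz
    params = TwoStateParams(r20=r20.get(ref, next(iter(r20.values()))), kex=kex,
                            dw_fc=dw, p_f=config.p_f, p_c=config.p_c)
    return TwoStateFitResult(
        residue_id=dataset.residue_id, params=params, r20_by_field=r20, sse=sse,
        per_field_rmsd=_rmsd_by_field(dataset.profiles, kex, r20, amp),
        mode="individual", degenerate=degenerate, converged=converged,
    )


def fit_two_state_global(
    datasets: Sequence[ResidueDataset], config: TwoStateConfig | None = None
) -> tuple[float, list[TwoStateFitResult]]:
    """Global two-state fit: one shared kex, per-residue {R20, dw_fc}.

    Residues whose individual fit is degenerate (flat profile) are
    excluded from the shared-kex pool but still reported with their
    baseline-only fit.  A single residue reduces to the individual fit.
    """
    config = config or TwoStateConfig()
    if not datasets:
        raise ValueError("no datasets supplied")
    individual = {d.residue_id: fit_two_state_individual(d, config) for d in datasets}
    pool = [d for d in datasets if not individual[d.residue_id].degenerate]
    if not pool:
        raise ValueError("all residues are flat; shared kex is unidentifiable")

    def pooled_sse(k: float) -> float:
        return sum(_profiled_fit(d.profiles, k, config)[0] for d in pool)

    kex, converged = _scan_kex(pooled_sse, config)
    results = []
    for d in datasets:
        if individual[d.residue_id].degenerate:
            r = individual[d.residue_id]
            r.mode = "global_shared_kex"
            results.append(r)
            continue
        sse, r20, amp = _profiled_fit(d.profiles, kex, config)
        dw = _amp_to_dw(amp, kex, config)
        ref = d.reference_mhz
        params = TwoStateParams(r20=r20.get(ref, next(iter(r20.values()))),
                                kex=kex, dw_fc=dw, p_f=config.p_f, p_c=config.p_c)
        results.append(TwoStateFitResult(
            residue_id=d.residue_id, params=params, r20_by_field=r20, sse=sse,
            per_field_rmsd=_rmsd_by_field(d.profiles, kex, r20, amp),
            mode="global_shared_kex", degenerate=False, converged=converged,
        ))
    return kex, results


def classify_residues(
    fits: Iterable[TwoStateFitResult], threshold: float = 0.7
) -> dict[str, list[str]]:
    """Partition residues by fit quality: SSE strictly above ``threshold``
    -> ``three_state``, otherwise ``two_state``.  Exhaustive and disjoint."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    out: dict[str, list[str]] = {"two_state": [], "three_state": []}
    for f in fits:
        label = "three_state" if f.sse > threshold else "two_state"
        f._classification = label
        out[label].append(f.residue_id)
    return out
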