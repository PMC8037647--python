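"""Stage 2: GSIR — global search for individual residues.

For each residue classified as three-state, the five-parameter surface
{R20 (one per field), kex, kzb, dw_fc, dw_bz} is explored by uniform
Monte-Carlo sampling of the chi^2 objective, the lowest-chi^2 draws are
extracted as candidates, and each candidate is polished by bounded
trust-region least squares; the refined minimum is reported as the
residue's global minimum.

Two modes exist.  ``multi_field`` fits all fields of a residue jointly
under the physical cross-field constraints: rate constants are shared
(exchange kinetics cannot depend on the spectrometer) and Hz chemical
shifts at field j equal the reference-field value times j/ref.  This is
the production mode; ``single_field`` fits one field alone and exists to
demonstrate why that is not enough — on noisy data the per-field
estimates disagree with each other by more than the joint fit misses the
truth.

Sampling ranges bound the random draws only; the local refinement runs
inside wide physical bounds so a minimum near a range edge is not
artificially clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .models import (
    AngularConvention,
    CpmgProfile,
    ResidueDataset,
    ThreeStateParams,
)
from .two_state import TwoStateFitResult

__all__ = [
    "SamplingBounds",
    "RefineBounds",
    "GsirConfig",
    "SearchResult",
    "sample_surface",
    "apply_field_constraints",
    "gsir_run",
    "gsir_bootstrap",
    "summarize_gsir",
    "GsirSummary",
    "chi2_map",
]


@dataclass(frozen=True)
class SamplingBounds:
    """Uniform random-draw ranges for the chi^2 surface.

    R20 draws are centred on the residue's two-state baseline estimates
    (one centre per field) with a +/- 0.2 s^-1 half-width; the remaining
    ranges are the search defaults: kex 1-2000 s^-1, kzb 1-50 s^-1, both
    shifts 1-1500 Hz at the reference field.
    """

    r20_center: dict[float, float]
    r20_halfwidth: float = 0.2
    kex_range: tuple[float, float] = (1.0, 2000.0)
    kzb_range: tuple[float, float] = (1.0, 50.0)
    dw_fc_range: tuple[float, float] = (1.0, 1500.0)
    dw_bz_range: tuple[float, float] = (1.0, 1500.0)

    def __post_init__(self) -> None:
        for name in ("kex_range", "kzb_range", "dw_fc_range", "dw_bz_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        if self.r20_halfwidth < 0:
            raise ValueError("r20_halfwidth must be non-negative")

    @classmethod
    def from_two_state(cls, fit: TwoStateFitResult, **kw) -> "SamplingBounds":
        return cls(r20_center=dict(fit.r20_by_field), **kw)


@dataclass(frozen=True)
class RefineBounds:
    """Box constraints for the local polish (wide, physical)."""

    r20: tuple[float, float] = (-20.0, 100.0)
    kex: tuple[float, float] = (1e-2, 5000.0)
    kzb: tuple[float, float] = (0.0, 200.0)
    dw_fc: tuple[float, float] = (0.0, 3000.0)
    dw_bz: tuple[float, float] = (0.0, 3000.0)


@dataclass(frozen=True)
class GsirConfig:
    mode: str = "multi_field"  # or "single_field"
    n_draws: int = 100_000
    n_candidates: int = 5
    seed: int = 0
    field_mhz: float | None = None  # single_field: which field to use
    p_f: float = 0.95
    p_c: float = 0.05
    convention: AngularConvention = AngularConvention.HZ_DIRECT
    refine: RefineBounds = dc_field(default_factory=RefineBounds)
    refine_tol: float = 1e-10
    max_nfev: int = 5000


@dataclass
class SearchResult:
    residue_id: str
    best: ThreeStateParams
    best_r20_by_field: dict[float, float]
    best_chi2: float
    candidates: list[tuple[ThreeStateParams, float]]
    raw_min_chi2: float
    provenance: dict
    converged: bool = True


@dataclass
class GsirSummary:
    kex_mean: float
    kex_sd: float
    kzb_mean: float
    kzb_sd: float
    per_residue: dict[str, SearchResult]
    excluded: tuple[str, ...] = ()


def apply_field_constraints(
    params: ThreeStateParams, target_mhz: float, source_mhz: float
) -> ThreeStateParams:
    """Re-express shift parameters at field ``target_mhz`` given values at
    ``source_mhz``: dw scales by target/source, rates and R20 are shared."""
    return params.at_field(target_mhz, source_mhz)


def _select_profiles(dataset: ResidueDataset, config: GsirConfig) -> list[CpmgProfile]:
    if config.mode == "multi_field":
        if len(dataset.profiles) < 2:
            raise ValueError(
                f"multi_field mode needs >= 2 fields for {dataset.residue_id!r}"
            )
        return list(dataset.profiles)
    if config.mode == "single_field":
        if config.field_mhz is None:
            return [dataset.profiles[0]]
        for p in dataset.profiles:
            if p.field.mhz == config.field_mhz:
                return [p]
        raise ValueError(f"no profile at {config.field_mhz} MHz for {dataset.residue_id!r}")
    raise ValueError(f"unknown mode {config.mode!r}")


def _chi2_batch(
    profiles: Sequence[CpmgProfile],
    r20: np.ndarray,  # (n, F)
    kex: np.ndarray,
    kzb: np.ndarray,
    dw_fc: np.ndarray,
    dw_bz: np.ndarray,
    config: GsirConfig,
) -> np.ndarray:
    """Vectorised chi^2 over n parameter draws."""
    c = config.convention.factor
    pp = config.p_f * config.p_c
    chi2 = np.zeros(kex.shape[0])
    for j, prof in enumerate(profiles):
        w = dw_fc * prof.field.ratio * c
        x = kex[:, None] / (4.0 * prof.nu_cpmg)
        model = r20[:, j, None] + (pp * w * w / kex)[:, None] * (1.0 - np.tanh(x) / x)
        xb = (dw_bz * prof.field.ratio * c)[:, None] / (4.0 * prof.nu_cpmg)
        model += kzb[:, None] * (1.0 - np.sinc(xb / np.pi))
        resid = model - prof.r2_eff
        chi2 += np.einsum("ij,ij->i", resid, resid)
    return chi2


def sample_surface(
    dataset: ResidueDataset,
    bounds: SamplingBounds,
    n_draws: int,
    seed: int,
    config: GsirConfig | None = None,
) -> dict[str, np.ndarray]:
    """Draw ``n_draws`` uniform parameter vectors and evaluate chi^2.

    Returns a dict of aligned arrays (``r20`` has one column per field).
    Fixed seed => bit-identical table.
    """
    config = config or GsirConfig(seed=seed)
    if not dataset.profiles:
        raise ValueError(f"dataset {dataset.residue_id!r} has no profiles")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    profiles = _select_profiles(dataset, config)
    rng = np.random.default_rng(seed)
    r20 = np.column_stack([
        rng.uniform(bounds.r20_center.get(p.field.mhz, 0.0) - bounds.r20_halfwidth,
                    bounds.r20_center.get(p.field.mhz, 0.0) + bounds.r20_halfwidth,
                    n_draws)
        for p in profiles
    ])
    kex = rng.uniform(*bounds.kex_range, n_draws)
    kzb = rng.uniform(*bounds.kzb_range, n_draws)
    dw_fc = rng.uniform(*bounds.dw_fc_range, n_draws)
    dw_bz = rng.uniform(*bounds.dw_bz_range, n_draws)
    chi2 = _chi2_batch(profiles, r20, kex, kzb, dw_fc, dw_bz, config)
    return {"r20": r20, "kex": kex, "kzb": kzb, "dw_fc": dw_fc,
            "dw_bz": dw_bz, "chi2": chi2}


def _residuals(x: np.ndarray, profiles: Sequence[CpmgProfile], config: GsirConfig) -> np.ndarray:
    nf = len(profiles)
    r20, kex, kzb, dw_fc, dw_bz = x[:nf], x[nf], x[nf + 1], x[nf + 2], x[nf + 3]
    c = config.convention.factor
    pp = config.p_f * config.p_c
    out = []
    for j, prof in enumerate(profiles):
        w = dw_fc * prof.field.ratio * c
        xx = kex / (4.0 * prof.nu_cpmg)
        model = r20[j] + (pp * w * w / kex) * (1.0 - np.tanh(xx) / xx)
        xb = dw_bz * prof.field.ratio * c / (4.0 * prof.nu_cpmg)
        model = model + kzb * (1.0 - np.sinc(xb / np.pi))
        out.append(model - prof.r2_eff)
    return np.concatenate(out)


def _refine(
    x0: np.ndarray, profiles: Sequence[CpmgProfile], config: GsirConfig
) -> tuple[np.ndarray, float, bool]:
    nf = len(profiles)
    rb = config.refine
    lo = np.array([rb.r20[0]] * nf + [rb.kex[0], rb.kzb[0], rb.dw_fc[0], rb.dw_bz[0]])
    hi = np.array([rb.r20[1]] * nf + [rb.kex[1], rb.kzb[1], rb.dw_fc[1], rb.dw_bz[1]])
    x0 = np.clip(x0, lo, hi)
    try:
        res = least_squares(
            _residuals, x0, args=(profiles, config), bounds=(lo, hi),
            method="trf", xtol=config.refine_tol, ftol=config.refine_tol,
            gtol=config.refine_tol, max_nfev=config.max_nfev,
        )
    except Exception:
        r = _residuals(x0, profiles, config)
        return x0, float(r @ r), False
    return res.x, float(2.0 * res.cost), bool(res.success)


def gsir_run(
    dataset: ResidueDataset,
    bounds: SamplingBounds,
    config: GsirConfig | None = None,
) -> SearchResult:
    """Monte-Carlo surface sampling + candidate refinement for one residue.

    The ``config.n_candidates`` lowest-chi^2 draws (ties broken by draw
    order) are each refined; the refined minimum is the reported best.
    In multi-field mode the returned shifts are expressed at the
    reference field and one {kex, kzb} pair is shared across fields by
    construction.
    """
    config = config or GsirConfig()
    profiles = _select_profiles(dataset, config)
    table = sample_surface(dataset, bounds, config.n_draws, config.seed, config)
    order = np.argsort(table["chi2"], kind="stable")[: config.n_candidates]
    raw_min = float(table["chi2"][order[0]])

    nf = len(profiles)
    candidates: list[tuple[ThreeStateParams, float]] = []
    cand_r20: list[dict[float, float]] = []
    any_ok = False
    for idx in order:
        x0 = np.concatenate([
            table["r20"][idx],
            [table["kex"][idx], table["kzb"][idx], table["dw_fc"][idx], table["dw_bz"][idx]],
        ])
        x, chi2, ok = _refine(x0, profiles, config)
        any_ok = any_ok or ok
        r20_map = {p.field.mhz: float(x[j]) for j, p in enumerate(profiles)}
        ref = dataset.reference_mhz
        params = ThreeStateParams(
            r20=r20_map.get(ref, float(x[0])), kex=float(x[nf]), kzb=float(x[nf + 1]),
            dw_fc=float(x[nf + 2]), dw_bz=float(x[nf + 3]),
            p_f=config.p_f, p_c=config.p_c,
        )
        candidates.append((params, chi2))
        cand_r20.append(r20_map)

    best_i = int(np.argmin([c for _, c in candidates]))
    best, best_chi2 = candidates[best_i]
    if best_chi2 > raw_min:  # refinement never worsens the reported minimum
        idx = order[0]
        best_chi2 = raw_min
        best = ThreeStateParams(
            r20=float(table["r20"][idx][0]), kex=float(table["kex"][idx]),
            kzb=float(table["kzb"][idx]), dw_fc=float(table["dw_fc"][idx]),
            dw_bz=float(table["dw_bz"][idx]), p_f=config.p_f, p_c=config.p_c,
        )
    provenance = {
        "seed": config.seed, "n_draws": config.n_draws, "mode": config.mode,
        "fields_mhz": [p.field.mhz for p in profiles],
        "reference_mhz": dataset.reference_mhz,
        "convention": config.convention.value,
        "bounds": {
            "r20_center": bounds.r20_center, "r20_halfwidth": bounds.r20_halfwidth,
            "kex_range": bounds.kex_range, "kzb_range": bounds.kzb_range,
            "dw_fc_range": bounds.dw_fc_range, "dw_bz_range": bounds.dw_bz_range,
        },
    }
    return SearchResult(
        residue_id=dataset.residue_id, best=best,
        best_r20_by_field=cand_r20[best_i], best_chi2=best_chi2,
        candidates=candidates, raw_min_chi2=raw_min,
        provenance=provenance, converged=any_ok,
    )


def gsir_bootstrap(
    dataset: ResidueDataset,
    bounds: SamplingBounds,
    config: GsirConfig | None = None,
    n_boot: int = 20,
) -> tuple[SearchResult, dict[str, float]]:
    """Repeat the search over ``n_boot`` independent sampling seeds.

    Returns the overall best result and the spread (sample sd) of the
    refined minima across seeds, the package's parameter-uncertainty
    measure for GSIR.
    """
    config = config or GsirConfig()
    runs = []
    for b in range(n_boot):
        sub = replace(config, seed=(config.seed + 7919 * b) % (2**31 - 1))
        runs.append(gsir_run(dataset, bounds, sub))
    best = min(runs, key=lambda r: r.best_chi2)
    def sd(vals):
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    spread = {
        "kex_sd": sd([r.best.kex for r in runs]),
        "kzb_sd": sd([r.best.kzb for r in runs]),
        "dw_fc_sd": sd([r.best.dw_fc for r in runs]),
        "dw_bz_sd": sd([r.best.dw_bz for r in runs]),
    }
    return best, spread


def summarize_gsir(
    results: Sequence[SearchResult], exclude: Sequence[str] = ()
) -> GsirSummary:
    """Across-residue mean +/- sample sd of the best rate constants.

    ``exclude`` removes named outlier residues from the statistics (they
    stay in the per-residue table).
    """
    kept = [r for r in results if r.residue_id not in set(exclude)]
    if len(kept) < 2:
        raise ValueError("need >= 2 residues for a summary")
    kex = np.array([r.best.kex for r in kept])
    kzb = np.array([r.best.kzb for r in kept])
    return GsirSummary(
        kex_mean=float(kex.mean()), kex_sd=float(kex.std(ddof=1)),
        kzb_mean=float(kzb.mean()), kzb_sd=float(kzb.std(ddof=1)),
        per_residue={r.residue_id: r for r in results},
        excluded=tuple(exclude),
    )


def chi2_map(
    dataset: ResidueDataset,
    at: ThreeStateParams,
    r20_by_field: dict[float, float],
    kex_grid: np.ndarray,
    kzb_grid: np.ndarray,
    config: GsirConfig | None = None,
) -> np.ndarray:
    """Dense chi^2 grid over (kex, kzb) with the other parameters held at
    ``at`` — the exported chi^2 map around a minimum.  Shape
    (len(kex_grid), len(kzb_grid))."""
    config = config or GsirConfig()
    profiles = _select_profiles(dataset, config)
    kk, zz = np.meshgrid(np.asarray(kex_grid, float), np.asarray(kzb_grid, float),
                         indexing="ij")
    n = kk.size
    r20 = np.column_stack([
        np.full(n, r20_by_field.get(p.field.mhz, at.r20)) for p in profiles
    ])
    chi2 = _chi2_batch(profiles, r20, kk.ravel(), zz.ravel(),
                       np.full(n, at.dw_fc), np.full(n, at.dw_bz), config)
    return chi2.reshape(kk.shape)
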