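"""Stage 3: GSTR — global search for total residues.

All three-state residues are fitted jointly: one shared {kex, kzb} pair
for the whole protein plus per-residue baselines and chemical shifts,
minimising the pooled chi^2.  An unconstrained random search over this
many-parameter space does not converge, so initial vectors are drawn from
truncated Gaussian proposals centred on the GSIR stage's results:

* rate constants: centre = across-residue GSIR mean, proposal sd = a
  chosen multiple of the across-residue GSIR sd (the sweep runs 0.25, 0.5,
  1 and 1.5 sigma);
* chemical shifts: centre = each residue's own GSIR point estimate,
  proposal sd = 25% of that value.

Each width's search is refined as in GSIR; the final report averages the
shared rates over the four widths (mean +/- sd) and also quotes the
1-sigma run on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import truncnorm

from .models import AngularConvention, ResidueDataset, ThreeStateParams
from .gsir import GsirSummary, RefineBounds, SamplingBounds, _chi2_batch, GsirConfig

__all__ = [
    "GaussianConstraint",
    "GstrConstraints",
    "GstrConfig",
    "GstrRunResult",
    "GstrResult",
    "build_constraints",
    "gstr_run",
    "sweep_and_average",
]

#: Relative floor applied to degenerate (zero-sd) proposal widths.
WIDTH_FLOOR_FRAC = 1e-2


@dataclass(frozen=True)
class GaussianConstraint:
    """One truncated-Gaussian proposal: N(center, width^2) clipped to
    [lo, hi]."""

    center: float
    width: float
    lo: float
    hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be positive, got {self.width}")
        if not self.lo < self.hi:
            raise ValueError("constraint bounds must satisfy lo < hi")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.lo - self.center) / self.width
        b = (self.hi - self.center) / self.width
        return truncnorm.rvs(a, b, loc=self.center, scale=self.width,
                             size=n, random_state=rng)


@dataclass
class GstrConstraints:
    kex: GaussianConstraint
    kzb: GaussianConstraint
    dw_fc: dict[str, GaussianConstraint]
    dw_bz: dict[str, GaussianConstraint]
    r20_center: dict[str, dict[float, float]]  # residue -> field -> centre
    r20_halfwidth: float = 0.2
    width_spec: str = "1sigma"
    floored: list[str] = dc_field(default_factory=list)


@dataclass(frozen=True)
class GstrConfig:
    n_draws: int = 20_000
    n_candidates: int = 5
    seed: int = 0
    rate_widths: tuple[float, ...] = (0.25, 0.5, 1.0, 1.5)
    shift_frac: float = 0.25
    p_f: float = 0.95
    p_c: float = 0.05
    convention: AngularConvention = AngularConvention.HZ_DIRECT
    refine: RefineBounds = dc_field(default_factory=RefineBounds)
    refine_tol: float = 1e-10
    max_nfev: int = 20_000
    bounds: SamplingBounds | None = None  # truncation ranges; default ranges if None


@dataclass
class GstrRunResult:
    width_spec: str
    kex: float
    kzb: float
    chi2: float
    per_residue: dict[str, ThreeStateParams]
    r20_by_field: dict[str, dict[float, float]]
    candidates: list[tuple[float, float, float]]  # (kex, kzb, chi2)
    converged: bool
    provenance: dict


@dataclass
class GstrResult:
    """Sweep output: one entry per constraint width plus the averages."""

    runs: dict[float, GstrRunResult]
    kex_mean: float
    kex_sd: float
    kzb_mean: float
    kzb_sd: float
    one_sigma: GstrRunResult | None
    dw_fc_mean: dict[str, float]
    dw_fc_sd: dict[str, float]
    dw_bz_mean: dict[str, float]
    dw_bz_sd: dict[str, float]
    failed_widths: list[float]
    provenance: dict


def _floor(width: float, center: float, floored: list[str], label: str) -> float:
    floor = max(WIDTH_FLOOR_FRAC * abs(center), 1e-6)
    if width < floor:
        floored.append(label)
        return floor
    return width


def build_constraints(
    summary: GsirSummary,
    width_spec: float,
    config: GstrConfig | None = None,
    residues: Sequence[str] | None = None,
) -> GstrConstraints:
    """Derive the truncated-Gaussian proposals from a GSIR summary.

    ``width_spec`` multiplies the across-residue sd of the GSIR rate
    constants; shift proposals get sd = ``shift_frac`` (default 25%) of
    each residue's own GSIR value.  Zero-sd degenerate cases are floored
    (and recorded in ``floored``).
    """
    config = config or GstrConfig()
    if width_spec <= 0:
        raise ValueError("width_spec must be positive")
    ranges = config.bounds or SamplingBounds(r20_center={})
    ids = list(residues) if residues is not None else list(summary.per_residue)
    missing = [r for r in ids if r not in summary.per_residue]
    if missing:
        raise ValueError(f"GSIR summary lacks residues {missing}")
    floored: list[str] = []
    kex_c = GaussianConstraint(
        summary.kex_mean, _floor(width_spec * summary.kex_sd, summary.kex_mean, floored, "kex"),
        *ranges.kex_range, label="kex")
    kzb_c = GaussianConstraint(
        summary.kzb_mean, _floor(width_spec * summary.kzb_sd, summary.kzb_mean, floored, "kzb"),
        *ranges.kzb_range, label="kzb")
    dw_fc, dw_bz, r20_center = {}, {}, {}
    for rid in ids:
        best = summary.per_residue[rid].best
        dw_fc[rid] = GaussianConstraint(
            best.dw_fc, _floor(config.shift_frac * best.dw_fc, best.dw_fc, floored, f"dw_fc:{rid}"),
            *ranges.dw_fc_range, label=f"dw_fc:{rid}")
        dw_bz[rid] = GaussianConstraint(
            best.dw_bz, _floor(config.shift_frac * best.dw_bz, best.dw_bz, floored, f"dw_bz:{rid}"),
            *ranges.dw_bz_range, label=f"dw_bz:{rid}")
        r20_center[rid] = dict(summary.per_residue[rid].best_r20_by_field)
    return GstrConstraints(kex=kex_c, kzb=kzb_c, dw_fc=dw_fc, dw_bz=dw_bz,
                           r20_center=r20_center, r20_halfwidth=ranges.r20_halfwidth,
                           width_spec=f"{width_spec}sigma", floored=floored)


def _gsir_cfg(config: GstrConfig) -> GsirConfig:
    return GsirConfig(p_f=config.p_f, p_c=config.p_c, convention=config.convention)


def _pooled_residuals(
    x: np.ndarray, datasets: Sequence[ResidueDataset], config: GstrConfig
) -> np.ndarray:
    kex, kzb = x[0], x[1]
    cfg = _gsir_cfg(config)
    c = config.convention.factor
    pp = config.p_f * config.p_c
    out = []
    pos = 2
    for ds in datasets:
        nf = len(ds.profiles)
        r20 = x[pos : pos + nf]
        dw_fc, dw_bz = x[pos + nf], x[pos + nf + 1]
        pos += nf + 2
        for j, prof in enumerate(ds.profiles):
            w = dw_fc * prof.field.ratio * c
            xx = kex / (4.0 * prof.nu_cpmg)
            model = r20[j] + (pp * w * w / kex) * (1.0 - np.tanh(xx) / xx)
            xb = dw_bz * prof.field.ratio * c / (4.0 * prof.nu_cpmg)
            model = model + kzb * (1.0 - np.sinc(xb / np.pi))
            out.append(model - prof.r2_eff)
    return np.concatenate(out)


def gstr_run(
    datasets: Sequence[ResidueDataset],
    constraints: GstrConstraints,
    config: GstrConfig | None = None,
) -> GstrRunResult:
    """One constraint width: Gaussian-initialised pooled search.

    Minimises the pooled chi^2 over one shared {kex, kzb} plus per-residue
    {R20 per field, dw_fc, dw_bz}, drawing ``n_draws`` initial vectors
    from the proposals, keeping the ``n_candidates`` best and refining
    each by bounded least squares under the cross-field constraints
    (shared rates, field-ratio-scaled shifts).
    """
    config = config or GstrConfig()
    if not datasets:
        raise ValueError("no datasets supplied")
    rng = np.random.default_rng(config.seed)
    n = config.n_draws
    kex = constraints.kex.draw(n, rng)
    kzb = constraints.kzb.draw(n, rng)
    cfg = _gsir_cfg(config)

    chi2 = np.zeros(n)
    per_res_draws = {}
    for ds in datasets:
        rid = ds.residue_id
        if rid not in constraints.dw_fc:
            raise ValueError(f"no constraints for residue {rid!r}")
        dw_fc = constraints.dw_fc[rid].draw(n, rng)
        dw_bz = constraints.dw_bz[rid].draw(n, rng)
        centers = constraints.r20_center.get(rid, {})
        r20 = np.column_stack([
            rng.uniform(centers.get(p.field.mhz, 0.0) - constraints.r20_halfwidth,
                        centers.get(p.field.mhz, 0.0) + constraints.r20_halfwidth, n)
            for p in ds.profiles
        ])
        chi2 += _chi2_batch(ds.profiles, r20, kex, kzb, dw_fc, dw_bz, cfg)
        per_res_draws[rid] = (r20, dw_fc, dw_bz)

    order = np.argsort(chi2, kind="stable")[: config.n_candidates]

    rb = config.refine
    lo, hi = [rb.kex[0], rb.kzb[0]], [rb.kex[1], rb.kzb[1]]
    for ds in datasets:
        nf = len(ds.profiles)
        lo += [rb.r20[0]] * nf + [rb.dw_fc[0], rb.dw_bz[0]]
        hi += [rb.r20[1]] * nf + [rb.dw_fc[1], rb.dw_bz[1]]
    lo, hi = np.array(lo), np.array(hi)

    best_x, best_chi2, cand, any_ok = None, np.inf, [], False
    for idx in order:
        x0 = [kex[idx], kzb[idx]]
        for ds in datasets:
            r20d, fcd, bzd = per_res_draws[ds.residue_id]
            x0 += list(r20d[idx]) + [fcd[idx], bzd[idx]]
        x0 = np.clip(np.array(x0), lo, hi)
        try:
            res = least_squares(
                _pooled_residuals, x0, args=(datasets, config), bounds=(lo, hi),
                method="trf", xtol=config.refine_tol, ftol=config.refine_tol,
                gtol=config.refine_tol, max_nfev=config.max_nfev,
            )
            xr, c2, ok = res.x, float(2.0 * res.cost), bool(res.success)
        except Exception:
            r = _pooled_residuals(x0, datasets, config)
            xr, c2, ok = x0, float(r @ r), False
        any_ok = any_ok or ok
        cand.append((float(xr[0]), float(xr[1]), c2))
        if c2 < best_chi2:
            best_x, best_chi2 = xr, c2

    per_residue, r20_maps = {}, {}
    pos = 2
    for ds in datasets:
        nf = len(ds.profiles)
        r20v = best_x[pos : pos + nf]
        dw_fc, dw_bz = best_x[pos + nf], best_x[pos + nf + 1]
        pos += nf + 2
        r20_map = {p.field.mhz: float(r20v[j]) for j, p in enumerate(ds.profiles)}
        ref = ds.reference_mhz
        per_residue[ds.residue_id] = ThreeStateParams(
            r20=r20_map.get(ref, float(r20v[0])), kex=float(best_x[0]),
            kzb=float(best_x[1]), dw_fc=float(dw_fc), dw_bz=float(dw_bz),
            p_f=config.p_f, p_c=config.p_c)
        r20_maps[ds.residue_id] = r20_map
    return GstrRunResult(
        width_spec=constraints.width_spec, kex=float(best_x[0]), kzb=float(best_x[1]),
        chi2=best_chi2, per_residue=per_residue, r20_by_field=r20_maps,
        candidates=cand, converged=any_ok,
        provenance={"seed": config.seed, "n_draws": config.n_draws,
                    "width_spec": constraints.width_spec,
                    "floored": list(constraints.floored),
                    "convention": config.convention.value},
    )


def sweep_and_average(
    datasets: Sequence[ResidueDataset],
    gsir_summary: GsirSummary,
    config: GstrConfig | None = None,
) -> GstrResult:
    """Run the constraint-width sweep and average the shared rates.

    One ``gstr_run`` per rate width (default 0.25, 0.5, 1, 1.5 sigma) with
    the fixed 25% shift width; the report carries each run, the
    across-width mean +/- sd of the shared rates and per-residue shifts,
    and the 1-sigma run separately.  A width whose refinement fails
    entirely is excluded from the averages.
    """
    config = config or GstrConfig()
    ids = [d.residue_id for d in datasets]
    runs: dict[float, GstrRunResult] = {}
    failed: list[float] = []
    for i, w in enumerate(config.rate_widths):
        cons = build_constraints(gsir_summary, w, config, residues=ids)
        sub_seed = (config.seed + 104729 * i) % (2**31 - 1)
        run = gstr_run(datasets, cons, _with_seed(config, sub_seed))
        if run.converged:
            runs[w] = run
        else:
            failed.append(w)
    if not runs:
        raise RuntimeError("no GSTR width converged")
    kexs = np.array([r.kex for r in runs.values()])
    kzbs = np.array([r.kzb for r in runs.values()])
    def sd(a):
        return float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    dw_fc_mean, dw_fc_sd, dw_bz_mean, dw_bz_sd = {}, {}, {}, {}
    for rid in ids:
        fc = np.array([r.per_residue[rid].dw_fc for r in runs.values()])
        bz = np.array([r.per_residue[rid].dw_bz for r in runs.values()])
        dw_fc_mean[rid], dw_fc_sd[rid] = float(fc.mean()), sd(fc)
        dw_bz_mean[rid], dw_bz_sd[rid] = float(bz.mean()), sd(bz)
    return GstrResult(
        runs=runs, kex_mean=float(kexs.mean()), kex_sd=sd(kexs),
        kzb_mean=float(kzbs.mean()), kzb_sd=sd(kzbs),
        one_sigma=runs.get(1.0), dw_fc_mean=dw_fc_mean, dw_fc_sd=dw_fc_sd,
        dw_bz_mean=dw_bz_mean, dw_bz_sd=dw_bz_sd, failed_widths=failed,
        provenance={"seed": config.seed, "rate_widths": list(config.rate_widths),
                    "shift_frac": config.shift_frac, "n_draws": config.n_draws,
                    "convention": config.convention.value},
    )


def _with_seed(config: GstrConfig, seed: int) -> GstrConfig:
    from dataclasses import replace
    return replace(config, seed=seed)
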