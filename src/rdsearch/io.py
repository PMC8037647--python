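"""Readers, writers, and run configuration.

All tabular output is tab-separated UTF-8 text with a "." decimal point.
Profile tables come in two shapes sharing the key columns ``residue_id``,
``field_mhz`` and ``nu_cpmg_hz``:

* pre-differenced: a ``r2eff_s1`` column holding the complex-minus-free
  difference rate (optional ``err_s1``);
* intensity mode: ``state`` (``free``/``complex``), ``intensity``,
  ``intensity_ref`` and ``t_relax_s`` columns; rates are computed from the
  constant-time decay and differenced on matching
  (residue, field, nu) keys.

Every result table gets a JSON provenance sidecar (config, seed, package
version, angular convention) sufficient to re-run deterministic stages
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .models import (
    AngularConvention,
    CpmgProfile,
    FieldContext,
    ResidueDataset,
    ThreeStateParams,
    TwoStateParams,
    r2_eff,
)
from .two_state import TwoStateFitResult
from .gsir import GsirSummary, SearchResult
from .gstr import GstrResult

__all__ = [
    "RunConfig",
    "read_profiles",
    "write_profiles",
    "write_ground_truth",
    "read_ground_truth",
    "write_two_state_table",
    "write_gsir_table",
    "write_gstr_tables",
    "write_rate_summary",
    "write_chi2_map",
    "write_provenance",
]


@dataclass
class RunConfig:
    """Analysis-wide settings, serialised into every provenance block."""

    p_f: float = 0.95
    p_c: float = 0.05
    convention: str = "hz_direct"
    sse_threshold: float = 0.7
    reference_mhz: float = 800.0
    kex_range: tuple[float, float] = (1.0, 2000.0)
    kzb_range: tuple[float, float] = (1.0, 50.0)
    dw_fc_range: tuple[float, float] = (1.0, 1500.0)
    dw_bz_range: tuple[float, float] = (1.0, 1500.0)
    r20_halfwidth: float = 0.2
    n_draws_gsir: int = 100_000
    n_draws_gstr: int = 20_000
    n_candidates: int = 5
    n_bootstrap: int = 20
    rate_widths: tuple[float, ...] = (0.25, 0.5, 1.0, 1.5)
    shift_frac: float = 0.25
    seed: int = 0

    @property
    def angular_convention(self) -> AngularConvention:
        return AngularConvention(self.convention)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in raw and isinstance(raw[f.name], list):
                raw[f.name] = tuple(raw[f.name])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_profiles(
    path: str | Path, config: RunConfig | None = None
) -> list[ResidueDataset]:
    """Read a profile table (pre-differenced or intensity mode) into
    per-residue datasets.  Validation failures name the offending rows."""
    config = config or RunConfig()
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require(df, ["residue_id", "field_mhz", "nu_cpmg_hz"], path)
    if "r2eff_s1" in df.columns:
        work = df[["residue_id", "field_mhz", "nu_cpmg_hz", "r2eff_s1"]].copy()
        if "err_s1" in df.columns:
            work["err_s1"] = df["err_s1"]
    elif "intensity" in df.columns:
        _require(df, ["state", "intensity", "intensity_ref", "t_relax_s"], path)
        bad = df.index[(df["intensity"] <= 0) | (df["intensity_ref"] <= 0)]
        if len(bad):
            raise ValueError(f"{path}: non-positive intensity at rows {list(bad + 2)}")
        df = df.assign(_r2=[
            r2_eff(i, i0, t) for i, i0, t in
            zip(df["intensity"], df["intensity_ref"], df["t_relax_s"])
        ])
        keys = ["residue_id", "field_mhz", "nu_cpmg_hz"]
        comp = df[df["state"] == "complex"].set_index(keys)
        free = df[df["state"] == "free"].set_index(keys)
        unmatched = comp.index.difference(free.index)
        if len(unmatched):
            raise ValueError(f"{path}: complex rows without free partner: "
                             f"{list(unmatched[:5])}")
        unmatched = free.index.difference(comp.index)
        if len(unmatched):
            raise ValueError(f"{path}: free rows without complex partner: "
                             f"{list(unmatched[:5])}")
        work = (comp["_r2"] - free["_r2"]).rename("r2eff_s1").reset_index()
    else:
        raise ValueError(f"{path}: need either a r2eff_s1 or an intensity column")

    numeric = work.select_dtypes(include=[np.number])
    if not np.isfinite(numeric.to_numpy()).all():
        raise ValueError(f"{path}: non-finite numeric values present")

    t_relax = float(df["t_relax_s"].iloc[0]) if "t_relax_s" in df.columns else 0.060
    datasets = []
    for rid, g in work.groupby("residue_id", sort=False):
        profiles = []
        for mhz, gf in g.groupby("field_mhz", sort=True):
            gf = gf.sort_values("nu_cpmg_hz")
            profiles.append(CpmgProfile(
                residue_id=str(rid),
                field=FieldContext(float(mhz), reference_mhz=config.reference_mhz),
                nu_cpmg=gf["nu_cpmg_hz"].to_numpy(float),
                r2_eff=gf["r2eff_s1"].to_numpy(float),
                err=gf["err_s1"].to_numpy(float) if "err_s1" in gf.columns else None,
                t_relax=t_relax,
            ))
        datasets.append(ResidueDataset(residue_id=str(rid), profiles=profiles))
    return datasets


def write_profiles(datasets: Sequence[ResidueDataset], path: str | Path) -> None:
    rows = []
    for ds in datasets:
        for p in ds.profiles:
            for i in range(p.n_points):
                row = {
                    "residue_id": ds.residue_id, "field_mhz": p.field.mhz,
                    "nu_cpmg_hz": p.nu_cpmg[i], "r2eff_s1": p.r2_eff[i],
                }
                if p.err is not None:
                    row["err_s1"] = p.err[i]
                rows.append(row)
    # %.17g round-trips float64 exactly
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def _params_to_dict(p: TwoStateParams) -> dict:
    d = {"r20": p.r20, "kex": p.kex, "dw_fc": p.dw_fc, "p_f": p.p_f, "p_c": p.p_c}
    if isinstance(p, ThreeStateParams):
        d.update({"kzb": p.kzb, "dw_bz": p.dw_bz, "model": "three_state"})
    else:
        d["model"] = "two_state"
    return d


def write_ground_truth(truth: dict[str, TwoStateParams], path: str | Path) -> None:
    payload = {rid: _params_to_dict(p) for rid, p in truth.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_ground_truth(path: str | Path) -> dict[str, TwoStateParams]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for rid, d in payload.items():
        if d.pop("model") == "three_state":
            out[rid] = ThreeStateParams(**d)
        else:
            out[rid] = TwoStateParams(**d)
    return out


def write_two_state_table(
    results: Sequence[TwoStateFitResult],
    path: str | Path,
    classification: dict[str, list[str]] | None = None,
) -> None:
    label = {}
    if classification:
        for group, ids in classification.items():
            for rid in ids:
                label[rid] = group
    rows = []
    for r in results:
        row = {"residue_id": r.residue_id, "mode": r.mode, "r20_s1": r.params.r20,
               "kex_s1": r.params.kex, "dw_fc_hz": r.params.dw_fc, "sse": r.sse,
               "degenerate": r.degenerate}
        for mhz, v in sorted(r.r20_by_field.items()):
            row[f"r20_{mhz:g}_s1"] = v
        if label:
            row["classification"] = label.get(r.residue_id, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gsir_table(results: Sequence[SearchResult], path: str | Path) -> None:
    rows = []
    for r in results:
        row = {"residue_id": r.residue_id, "kex_s1": r.best.kex,
               "dw_fc_hz": r.best.dw_fc, "kzb_s1": r.best.kzb,
               "dw_bz_hz": r.best.dw_bz, "chi2": r.best_chi2,
               "converged": r.converged}
        for mhz, v in sorted(r.best_r20_by_field.items()):
            row[f"r20_{mhz:g}_s1"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gstr_tables(
    result: GstrResult, residue_path: str | Path, summary_path: str | Path
) -> None:
    """Residue table (averaged +/- sd shifts, 1-sigma values alongside)
    and the shared-rate summary table."""
    one = result.one_sigma
    rows = []
    for rid in result.dw_fc_mean:
        row = {"residue_id": rid,
               "kex_s1": result.kex_mean, "kex_sd_s1": result.kex_sd,
               "kzb_s1": result.kzb_mean, "kzb_sd_s1": result.kzb_sd,
               "dw_fc_hz": result.dw_fc_mean[rid], "dw_fc_sd_hz": result.dw_fc_sd[rid],
               "dw_bz_hz": result.dw_bz_mean[rid], "dw_bz_sd_hz": result.dw_bz_sd[rid]}
        if one is not None:
            row["dw_fc_1sigma_hz"] = one.per_residue[rid].dw_fc
            row["dw_bz_1sigma_hz"] = one.per_residue[rid].dw_bz
        rows.append(row)
    pd.DataFrame(rows).to_csv(residue_path, sep="\t", index=False)

    srows = [{"width_sigma": w, "kex_s1": r.kex, "kzb_s1": r.kzb, "chi2": r.chi2}
             for w, r in sorted(result.runs.items())]
    srows.append({"width_sigma": "averaged", "kex_s1": result.kex_mean,
                  "kzb_s1": result.kzb_mean, "chi2": float("nan")})
    pd.DataFrame(srows).to_csv(summary_path, sep="\t", index=False)


def write_rate_summary(
    path: str | Path,
    two_state_kex: float | None = None,
    gsir: GsirSummary | None = None,
    gstr: GstrResult | None = None,
) -> None:
    """Method-by-method exchange-rate summary (one row per stage)."""
    rows = []
    if two_state_kex is not None:
        rows.append({"method": "two_state", "kex_s1": two_state_kex,
                     "kex_sd_s1": np.nan, "kzb_s1": np.nan, "kzb_sd_s1": np.nan})
    if gsir is not None:
        rows.append({"method": "gsir", "kex_s1": gsir.kex_mean,
                     "kex_sd_s1": gsir.kex_sd, "kzb_s1": gsir.kzb_mean,
                     "kzb_sd_s1": gsir.kzb_sd})
    if gstr is not None:
        rows.append({"method": "gstr_averaged", "kex_s1": gstr.kex_mean,
                     "kex_sd_s1": gstr.kex_sd, "kzb_s1": gstr.kzb_mean,
                     "kzb_sd_s1": gstr.kzb_sd})
        if gstr.one_sigma is not None:
            rows.append({"method": "gstr_1sigma", "kex_s1": gstr.one_sigma.kex,
                         "kex_sd_s1": np.nan, "kzb_s1": gstr.one_sigma.kzb,
                         "kzb_sd_s1": np.nan})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_chi2_map(
    kex_grid: np.ndarray, kzb_grid: np.ndarray, chi2: np.ndarray, path: str | Path
) -> None:
    """Dense (kex, kzb) chi^2 grid as long-format TSV for plotting."""
    kk, zz = np.meshgrid(kex_grid, kzb_grid, indexing="ij")
    pd.DataFrame({"kex_s1": kk.ravel(), "kzb_s1": zz.ravel(),
                  "chi2": np.asarray(chi2).ravel()}).to_csv(path, sep="\t", index=False)


def write_provenance(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    payload = {"package": "rdsearch", "version": _version,
               "config": config.to_dict(), "config_digest": config.digest()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
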