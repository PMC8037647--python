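"""Closed-form forward models for CPMG relaxation-dispersion profiles.

The package analyses constant-time CPMG dispersion data for a system
undergoing pseudo-three-state exchange: a fast two-site exchange between
the free protein (F) and the protein--DNA complex (C), superimposed on a
slow two-site exchange between the B-form-bound and Z-form-bound complex
sub-states (C_B <-> C_Z).  Both processes are treated in their closed-form
limits:

* fast limit (Luz--Meiboom form) for F <-> C:

      dR2(nu) = R20 + (P_F P_C dw_FC^2 / k_ex) * [1 - (4 nu / k_ex) tanh(k_ex / 4 nu)]

* slow limit (sinc form) for C_B <-> C_Z, additive:

      + k_ZB * [1 - sinc(dw_BZ / 4 nu)],   sinc(x) = sin(x)/x

All model evaluation in the fitting stages funnels through this module.
Profiles are complex-minus-free *difference* profiles dR2 = R2,eff(complex)
- R2,eff(free); R20 is the baseline offset of the difference.

Chemical-shift differences are stored in Hz at a designated reference
static field and rescaled by the field ratio before evaluation.  Whether
the Hz value enters the formulas directly or as 2*pi*Hz is controlled by
:class:`AngularConvention` (default ``hz_direct``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AngularConvention",
    "FieldContext",
    "CpmgProfile",
    "ResidueDataset",
    "TwoStateParams",
    "ThreeStateParams",
    "r2_eff",
    "two_state_r2",
    "three_state_r2",
    "chi2_total",
    "SINC_TERM_MAX",
]

#: Global maximum of 1 - sinc(x) over x >= 0 (attained near x = 4.4934);
#: bounds the slow-exchange contribution by SINC_TERM_MAX * k_ZB.
SINC_TERM_MAX = 1.2172336282112217


class AngularConvention(enum.Enum):
    """How Hz-valued chemical-shift differences enter the formulas.

    ``hz_direct`` plugs the Hz value straight in (reproduces the magnitude
    of parameters reported for this system); ``radians`` multiplies by
    2*pi first, the textbook angular-frequency convention.  The mode is
    fixed per analysis run and recorded in all provenance output.
    """

    HZ_DIRECT = "hz_direct"
    RADIANS = "radians"

    @property
    def factor(self) -> float:
        return 1.0 if self is AngularConvention.HZ_DIRECT else 2.0 * math.pi


@dataclass(frozen=True)
class FieldContext:
    """One static magnetic field, identified by its 1H frequency in MHz.

    ``reference_mhz`` is the field at which chemical-shift differences are
    stored; ``None`` marks this field itself as the reference.
    """

    mhz: float
    reference_mhz: float | None = None

    def __post_init__(self) -> None:
        if self.mhz <= 0:
            raise ValueError(f"field frequency must be positive, got {self.mhz}")
        if self.reference_mhz is not None and self.reference_mhz <= 0:
            raise ValueError("reference field frequency must be positive")

    @property
    def is_reference(self) -> bool:
        return self.reference_mhz is None or self.reference_mhz == self.mhz

    @property
    def ratio(self) -> float:
        """Scaling applied to reference-field Hz shifts at this field."""
        if self.reference_mhz is None:
            return 1.0
        return self.mhz / self.reference_mhz


@dataclass
class CpmgProfile:
    """One residue x one field dispersion curve.

    ``r2_eff`` holds complex-minus-free difference rates dR2 (s^-1) on the
    ``nu_cpmg`` grid (Hz, strictly increasing); ``err`` is the optional
    per-point uncertainty and ``t_relax`` the constant-time delay in s.
    """

    residue_id: str
    field: FieldContext
    nu_cpmg: np.ndarray
    r2_eff: np.ndarray
    err: np.ndarray | None = None
    t_relax: float = 0.060

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2_eff = np.asarray(self.r2_eff, dtype=float)
        if self.err is not None:
            self.err = np.asarray(self.err, dtype=float)
        if self.nu_cpmg.ndim != 1 or self.nu_cpmg.shape != self.r2_eff.shape:
            raise ValueError("nu_cpmg and r2_eff must be 1-D arrays of equal length")
        if np.any(self.nu_cpmg <= 0):
            raise ValueError("nu_cpmg values must be strictly positive")
        if np.any(np.diff(self.nu_cpmg) <= 0):
            raise ValueError("nu_cpmg values must be strictly increasing")
        if self.t_relax <= 0:
            raise ValueError(f"t_relax must be positive, got {self.t_relax}")

    @property
    def n_points(self) -> int:
        return self.nu_cpmg.size


@dataclass
class ResidueDataset:
    """All dispersion profiles for one residue across static fields."""

    residue_id: str
    profiles: list[CpmgProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [p.field.mhz for p in self.profiles]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate field labels in dataset {self.residue_id!r}")
        for p in self.profiles:
            if p.residue_id != self.residue_id:
                raise ValueError(
                    f"profile residue {p.residue_id!r} != dataset {self.residue_id!r}"
                )

    @property
    def fields(self) -> list[FieldContext]:
        return [p.field for p in self.profiles]

    @property
    def reference_mhz(self) -> float:
        for p in self.profiles:
            if p.field.is_reference:
                return p.field.mhz
        return min(p.field.mhz for p in self.profiles)

    @property
    def n_points(self) -> int:
        return sum(p.n_points for p in self.profiles)


@dataclass(frozen=True)
class TwoStateParams:
    """Fast-limit two-state parameters.

    ``dw_fc`` (Hz) is stored at the reference field.  Populations are
    fixed inputs, never fitted: only the product P_F*P_C*dw^2 is
    identifiable from a single field, so the reported dw_fc is
    conditional on the configured populations.
    """

    r20: float
    kex: float
    dw_fc: float
    p_f: float = 0.95
    p_c: float = 0.05

    def __post_init__(self) -> None:
        if self.kex <= 0:
            raise ValueError(f"kex must be positive, got {self.kex}")
        if self.dw_fc < 0:
            raise ValueError(f"dw_fc must be non-negative, got {self.dw_fc}")
        if not 0.0 <= self.p_c <= 1.0:
            raise ValueError(f"p_c must lie in [0, 1], got {self.p_c}")
        if abs(self.p_f + self.p_c - 1.0) > 1e-9:
            raise ValueError("populations must satisfy p_f + p_c = 1")


@dataclass(frozen=True)
class ThreeStateParams(TwoStateParams):
    """Two-state parameters plus the slow B<->Z exchange pair."""

    kzb: float = 0.0
    dw_bz: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.kzb < 0:
            raise ValueError(f"kzb must be non-negative, got {self.kzb}")
        if self.dw_bz < 0:
            raise ValueError(f"dw_bz must be non-negative, got {self.dw_bz}")

    def at_field(self, target_mhz: float, source_mhz: float) -> "ThreeStateParams":
        """Re-express the shift parameters at another static field.

        Hz shifts scale proportionally with the field; rate constants and
        the baseline are field-independent.
        """
        if target_mhz <= 0 or source_mhz <= 0:
            raise ValueError("field frequencies must be positive")
        s = target_mhz / source_mhz
        return replace(self, dw_fc=self.dw_fc * s, dw_bz=self.dw_bz * s)


def r2_eff(
    intensity: float | np.ndarray,
    intensity_ref: float | np.ndarray,
    t_relax: float,
) -> float | np.ndarray:
    """Effective transverse relaxation rate from constant-time peak decay.

    R2,eff = (1/T) * ln(I0 / I) where I is the intensity after the CPMG
    block of duration T and I0 the reference intensity at zero delay.
    """
    intensity = np.asarray(intensity, dtype=float)
    intensity_ref = np.asarray(intensity_ref, dtype=float)
    if np.any(intensity <= 0):
        raise ValueError("intensity must be positive")
    if np.any(intensity_ref <= 0):
        raise ValueError("intensity_ref must be positive")
    if t_relax <= 0:
        raise ValueError(f"t_relax must be positive, got {t_relax}")
    out = np.log(intensity_ref / intensity) / t_relax
    return float(out) if out.ndim == 0 else out


def _fast_term(nu: np.ndarray, kex: float | np.ndarray, amp: float | np.ndarray) -> np.ndarray:
    # amp = P_F P_C dw^2 / kex, dw already field-scaled and in the active convention
    x = kex / (4.0 * nu)
    return amp * (1.0 - np.tanh(x) / x)


def _slow_term(nu: np.ndarray, kzb: float | np.ndarray, dw_bz: float | np.ndarray) -> np.ndarray:
    # np.sinc(x/pi) = sin(x)/x with the removable singularity at 0 handled
    x = dw_bz / (4.0 * nu)
    return kzb * (1.0 - np.sinc(x / np.pi))


def two_state_r2(
    params: TwoStateParams,
    nu: float | np.ndarray,
    fctx: FieldContext | None = None,
    convention: AngularConvention = AngularConvention.HZ_DIRECT,
) -> float | np.ndarray:
    """Fast-limit two-state dispersion dR2(nu) in s^-1.

    ``fctx`` rescales the stored reference-field shift by the field ratio;
    ``None`` evaluates at the reference field itself.
    """
    nu_arr = np.asarray(nu, dtype=float)
    if np.any(nu_arr <= 0):
        raise ValueError("nu must be strictly positive")
    ratio = 1.0 if fctx is None else fctx.ratio
    w = params.dw_fc * ratio * convention.factor
    out = params.r20 + _fast_term(nu_arr, params.kex, params.p_f * params.p_c * w * w / params.kex)
    return float(out) if out.ndim == 0 else out


def three_state_r2(
    params: ThreeStateParams,
    nu: float | np.ndarray,
    fctx: FieldContext | None = None,
    convention: AngularConvention = AngularConvention.HZ_DIRECT,
) -> float | np.ndarray:
    """Pseudo-three-state dispersion: fast term plus additive slow term.

    Reduces exactly to :func:`two_state_r2` when ``kzb == 0`` or
    ``dw_bz == 0``.
    """
    nu_arr = np.asarray(nu, dtype=float)
    base = two_state_r2(params, nu_arr, fctx, convention)
    ratio = 1.0 if fctx is None else fctx.ratio
    out = base + _slow_term(nu_arr, params.kzb, params.dw_bz * ratio * convention.factor)
    return float(out) if np.ndim(out) == 0 else out


def _predict_profile(
    params: TwoStateParams,
    profile: CpmgProfile,
    convention: AngularConvention,
) -> np.ndarray:
    fn = three_state_r2 if isinstance(params, ThreeStateParams) else two_state_r2
    return fn(params, profile.nu_cpmg, profile.field, convention)


def chi2_total(
    params_by_residue: Mapping[str, TwoStateParams],
    datasets: Sequence[ResidueDataset],
    convention: AngularConvention = AngularConvention.HZ_DIRECT,
) -> float:
    """Unweighted sum of squared residuals over all residues, fields and
    nu points (the pooled chi^2 objective all searches minimise)."""
    ids = {d.residue_id for d in datasets}
    if ids != set(params_by_residue):
        missing = ids.symmetric_difference(params_by_residue)
        raise ValueError(f"residue sets of params and datasets differ: {sorted(missing)}")
    total = 0.0
    for ds in datasets:
        p = params_by_residue[ds.residue_id]
        for prof in ds.profiles:
            res = _predict_profile(p, prof, convention) - prof.r2_eff
            total += float(np.dot(res, res))
    return total
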