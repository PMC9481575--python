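"""Worm-like chain elasticity of bare double-stranded DNA.

Every downstream stage of the pipeline — nucleosome counting, the fiber
statistical-mechanics model, rupture-size conversion, trace simulation —
rests on the worm-like chain (WLC) description of double-stranded DNA
under tension.  Two functional forms are provided:

* the high-force extensible WLC,

  .. math:: z/L = 1 - \\tfrac12\\sqrt{k_BT/(F L_p)} + F/S,

  valid above roughly 1 pN and used for all fitting, and

* the Marko–Siggia interpolation with an enthalpic stretch term, solved
  numerically, which stays physical down to arbitrarily small force and is
  used for forward simulation below 1 pN.

Here ``F`` is force (pN), ``L_p`` the persistence length (nm), ``S`` the
stretch modulus (pN) and ``L`` the contour length.  Double-stranded DNA
rises 0.34 nm per base pair, which fixes the equivalence 200 bp = 68 nm
used as the rupture-detection threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import lmfit
import numpy as np
from scipy.optimize import brentq

#: Thermal energy k_B*T at 298 K, pN*nm.
KBT_PN_NM = 4.11

#: Helical rise of B-form DNA, nm per base pair.
RISE_NM_PER_BP = 0.34

#: Contour length of the bacteriophage lambda genome, bp.
LAMBDA_DNA_BP = 48_502

#: Length of the end-labeled lambda tether (genome plus handles), bp; the
#: reference length used when projecting nucleosome counts of native-DNA
#: tethers of unknown length onto a common template.
LAMBDA_TEMPLATE_BP = 48_548

_WLC_METHODS = ("high_force", "marko_siggia", "auto")

#: Force (pN) at which the ``auto`` method switches from the Marko-Siggia
#: interpolation to the high-force approximation.
HIGH_FORCE_CROSSOVER_PN = 1.0


class InsufficientDataError(ValueError):
    """Raised when a fit window contains too few samples."""


@dataclass(frozen=True)
class WLCParams:
    """Mechanical parameters of a stretch of bare double-stranded DNA.

    Parameters
    ----------
    contour_bp:
        Contour length in base pairs (non-negative).
    persistence_nm:
        Persistence length, nm.  45–50 nm for dsDNA in physiological buffer.
    stretch_pN:
        Enthalpic stretch modulus, pN (900–1500 pN for dsDNA).
    rise_nm_per_bp:
        Helical rise, nm per bp.
    kBT_pN_nm:
        Thermal energy, pN*nm.
    """

    contour_bp: float
    persistence_nm: float = 50.0
    stretch_pN: float = 1500.0
    rise_nm_per_bp: float = RISE_NM_PER_BP
    kBT_pN_nm: float = KBT_PN_NM

    def __post_init__(self) -> None:
        if self.contour_bp < 0:
            raise ValueError(f"contour_bp must be >= 0, got {self.contour_bp}")
        for name in ("persistence_nm", "stretch_pN", "rise_nm_per_bp", "kBT_pN_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def contour_nm(self) -> float:
        """Contour length in nm (``contour_bp * rise_nm_per_bp``)."""
        return self.contour_bp * self.rise_nm_per_bp

    def replace(self, **changes) -> "WLCParams":
        return dataclasses.replace(self, **changes)


def contour_length_nm(bp: float, rise_nm_per_bp: float = RISE_NM_PER_BP) -> float:
    """Contour length in nm of ``bp`` base pairs of B-DNA.

    200 bp of free DNA corresponds to 68 nm of contour at the canonical
    0.34 nm/bp rise.
    """
    if bp < 0:
        raise ValueError(f"bp must be >= 0, got {bp}")
    if rise_nm_per_bp <= 0:
        raise ValueError("rise_nm_per_bp must be > 0")
    return bp * rise_nm_per_bp


def _ms_relative_extension_scalar(force, persistence_nm, stretch_pN, kBT_pN_nm):
    # Extensible Marko-Siggia: F*Lp/kBT = 1/(4(1-u)^2) - 1/4 + u with
    # u = z/L - F/S; solved by bisection on u in (0, 1).
    fl = force * persistence_nm / kBT_pN_nm

    def g(u):
        return 1.0 / (4.0 * (1.0 - u) ** 2) - 0.25 + u - fl

    u = brentq(g, 0.0, 1.0 - 1e-12, xtol=1e-14, rtol=1e-14)
    return u + force / stretch_pN


def wlc_relative_extension(
    force,
    persistence_nm: float = 50.0,
    stretch_pN: float = 1500.0,
    kBT_pN_nm: float = KBT_PN_NM,
    method: str = "high_force",
):
    """Fractional end-to-end extension z/L of a WLC at the given force.

    Parameters
    ----------
    force:
        Tension in pN, scalar or array; must be strictly positive (the
        high-force expansion diverges at zero force, and the interpolation
        variant is only meaningful under tension).
    method:
        ``"high_force"`` — extensible high-force expansion;
        ``"marko_siggia"`` — numerically solved extensible Marko-Siggia
        interpolation; ``"auto"`` — Marko-Siggia below 1 pN, high-force
        expansion at and above 1 pN.

    Returns
    -------
    Scalar or array of z/L values, strictly increasing in force.
    """
    if method not in _WLC_METHODS:
        raise ValueError(f"unknown WLC method {method!r}; choose from {_WLC_METHODS}")
    if persistence_nm <= 0 or stretch_pN <= 0:
        raise ValueError("persistence_nm and stretch_pN must be > 0")
    f = np.asarray(force, dtype=float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    if np.any(f <= 0):
        raise ValueError("force must be > 0 (low-force regime: use the "
                         "marko_siggia/auto interpolation and still F > 0)")

    out = np.empty_like(f)
    if method == "high_force":
        hi = np.ones_like(f, dtype=bool)
    elif method == "marko_siggia":
        hi = np.zeros_like(f, dtype=bool)
    else:
        hi = f >= HIGH_FORCE_CROSSOVER_PN
    if hi.any():
        fh = f[hi]
        out[hi] = 1.0 - 0.5 * np.sqrt(kBT_pN_nm / (fh * persistence_nm)) + fh / stretch_pN
    if (~hi).any():
        out[~hi] = [
            _ms_relative_extension_scalar(fi, persistence_nm, stretch_pN, kBT_pN_nm)
            for fi in f[~hi]
        ]
    return float(out[0]) if scalar else out


def wlc_extension_nm(force, params: WLCParams, method: str = "high_force"):
    """End-to-end extension in nm of the DNA described by ``params``."""
    if params.contour_bp == 0:
        f = np.asarray(force, dtype=float)
        return 0.0 if f.ndim == 0 else np.zeros_like(f)
    rel = wlc_relative_extension(
        force, params.persistence_nm, params.stretch_pN, params.kBT_pN_nm, method
    )
    return params.contour_nm * rel


def extension_to_bp(step_nm, force, params: WLCParams, method: str = "auto"):
    """Convert an extension change at a given force into base pairs of DNA.

    The inverse of the forward conversion: ``step_nm / (rise * z/L(force))``.
    At full relative extension 68 nm maps back onto 200 bp.
    """
    rel = wlc_relative_extension(
        force, params.persistence_nm, params.stretch_pN, params.kBT_pN_nm, method
    )
    return np.asarray(step_nm, dtype=float) / (params.rise_nm_per_bp * rel) \
        if np.ndim(step_nm) else float(step_nm) / (params.rise_nm_per_bp * rel)


_FREE_CHOICES = ("contour_bp", "persistence_nm", "stretch_pN")


@dataclass(frozen=True)
class WLCFit:
    """Result of :func:`fit_wlc`: best-fit parameters plus diagnostics."""

    params: WLCParams
    residual_rms_nm: float
    n_points: int
    success: bool
    stderr: Mapping[str, float]
    message: str = ""
    flags: frozenset = frozenset()


def fit_wlc(
    trace,
    force_window: tuple,
    params: WLCParams,
    free: Iterable[str] = ("contour_bp",),
    method: str = "auto",
    min_points: int = 10,
) -> WLCFit:
    """Least-squares WLC fit of a force-extension trace inside a force window.

    Ordinary least squares on extension residuals with uniform weights.
    ``params`` supplies both the fixed values and the initial guesses for
    the free parameters; fields not listed in ``free`` are returned
    unchanged.

    Parameters
    ----------
    trace:
        Object with ``force_pN`` and ``extension_nm`` array attributes.
    force_window:
        ``(lo, hi)`` in pN; samples with lo <= F <= hi enter the fit.
    free:
        Subset of ``{"contour_bp", "persistence_nm", "stretch_pN"}``.

    Raises
    ------
    InsufficientDataError
        Fewer than ``min_points`` samples inside the window.
    """
    free = tuple(free)
    for name in free:
        if name not in _FREE_CHOICES:
            raise ValueError(f"cannot free {name!r}; choose from {_FREE_CHOICES}")
    lo, hi = force_window
    f = np.asarray(trace.force_pN, dtype=float)
    z = np.asarray(trace.extension_nm, dtype=float)
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < min_points:
        raise InsufficientDataError(
            f"only {int(mask.sum())} samples in force window {force_window}; "
            f"need >= {min_points}"
        )
    f, z = f[mask], z[mask]

    if not free:
        resid = wlc_extension_nm(f, params, method) - z
        return WLCFit(
            params=params,
            residual_rms_nm=float(np.sqrt(np.mean(resid**2))),
            n_points=f.size,
            success=True,
            stderr={},
            message="all parameters fixed",
        )

    p = lmfit.Parameters()
    p.add("contour_bp", value=max(params.contour_bp, 1.0), min=0.0,
          vary="contour_bp" in free)
    p.add("persistence_nm", value=params.persistence_nm, min=1.0, max=500.0,
          vary="persistence_nm" in free)
    p.add("stretch_pN", value=params.stretch_pN, min=10.0, max=1e5,
          vary="stretch_pN" in free)

    def residual(pars):
        trial = params.replace(
            contour_bp=pars["contour_bp"].value,
            persistence_nm=pars["persistence_nm"].value,
            stretch_pN=pars["stretch_pN"].value,
        )
        return wlc_extension_nm(f, trial, method) - z

    result = lmfit.minimize(residual, p, method="leastsq")
    fitted = params.replace(
        contour_bp=float(result.params["contour_bp"].value),
        persistence_nm=float(result.params["persistence_nm"].value),
        stretch_pN=float(result.params["stretch_pN"].value),
    )
    stderr = {
        name: float(result.params[name].stderr)
        for name in free
        if result.params[name].stderr is not None
    }
    flags = set()
    if not result.success:
        flags.add("non_convergent")
    return WLCFit(
        params=fitted,
        residual_rms_nm=float(np.sqrt(np.mean(result.residual**2))),
        n_points=f.size,
        success=bool(result.success),
        stderr=stderr,
        message=str(getattr(result, "message", "")),
        flags=frozenset(flags),
    )
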