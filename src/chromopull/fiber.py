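"""Equilibrium statistical mechanics of nucleosome-array stretching.

A chromatin fiber under tension passes through a sequence of states per
nucleosome:

* **stacked** — the nucleosome participates in the folded fiber; it
  sequesters one full nucleosome repeat length (NRL) of DNA and the folded
  domain responds to force as a Hookean spring of stiffness ``k_fiber``;
* **state 1** — beads-on-a-string: the nucleosome has unstacked and the
  outer DNA turn partially unwound, leaving 92 bp wrapped; costs ``dG1``
  (kT) relative to stacked;
* **state 2** — further unwinding to 79 bp wrapped (13 bp released); costs
  an additional ``dG2`` (kT).

The largely irreversible release of the last DNA turn (the 25–27 nm steps
above 10 pN) is *not* part of this equilibrium model; it is simulated as
discrete stochastic events (:mod:`chromopull.simulate`) and enters the
analysis only through the 79 bp-per-nucleosome contour reduction used in
counting.

Nucleosomes are treated as independent and identical.  At force ``F`` each
state ``i`` carries Boltzmann weight ``exp(-(G_i - F*dz_i(F))/kBT)`` where
``dz_i(F)`` is the extension gained in state ``i`` relative to the stacked
reference: the WLC extension of the released DNA minus the per-nucleosome
share of the folded-domain Hookean extension.  A fraction ``N_unfold =
N_total - N_folded`` of nucleosomes never stacks; those start in state 1
and can only reach state 2.

The predicted fiber extension is the WLC extension of all released DNA
plus the Hookean stretch of the still-folded domain,
``p_stacked * F / k_fiber``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .wlc import KBT_PN_NM, WLCParams, wlc_relative_extension

_STATES = ("stacked", "state1", "state2")
_STIFFNESS_MODES = ("fiber", "per_nucleosome")


@dataclass(frozen=True)
class FiberParams:
    """Parameters of the two-tier nucleosome-array unfolding model.

    Parameters
    ----------
    k_fiber:
        Hookean stiffness, pN/nm.  In the default ``stiffness_mode="fiber"``
        this is the stiffness of the whole folded domain (the quantity
        reported per tether, typically 0.18–0.53 pN/nm); in
        ``"per_nucleosome"`` mode it is the stiffness of a single stacked
        nucleosome and the folded domain is ``N_folded`` such springs in
        series.
    dG1_kT, dG2_kT:
        Free energies (kT) of unstacking + first unwinding (146 -> 92 bp
        wrapped) and of the second unwinding stage (92 -> 79 bp).
    N_total, N_folded:
        Total nucleosomes on the tether and the subset participating in
        fiber folding.  ``N_unfold = N_total - N_folded`` is derived.
    NRL_bp:
        Nucleosome repeat length; the DNA sequestered per stacked
        nucleosome (linker included in the folded fiber).
    L_DNA_bp:
        Template contour length, bp.
    wrap_full_bp, wrap_state1_bp, wrap_state2_bp:
        DNA wrapped in the fully-wrapped, state-1 and state-2 nucleosome.
    """

    k_fiber: float
    dG1_kT: float
    dG2_kT: float
    N_total: int
    N_folded: int
    NRL_bp: float
    L_DNA_bp: float
    wrap_full_bp: float = 146.0
    wrap_state1_bp: float = 92.0
    wrap_state2_bp: float = 79.0
    stiffness_mode: str = "fiber"

    def __post_init__(self) -> None:
        if self.k_fiber <= 0:
            raise ValueError(f"k_fiber must be > 0, got {self.k_fiber}")
        if not (0 <= self.N_folded <= self.N_total):
            raise ValueError(
                f"need 0 <= N_folded <= N_total, got {self.N_folded}, {self.N_total}"
            )
        if not (self.wrap_full_bp > self.wrap_state1_bp > self.wrap_state2_bp > 0):
            raise ValueError("need wrap_full_bp > wrap_state1_bp > wrap_state2_bp > 0")
        if self.N_total * self.wrap_state2_bp > self.L_DNA_bp:
            raise ValueError(
                "template too short: N_total * wrap_state2_bp exceeds L_DNA_bp"
            )
        if self.NRL_bp <= 0 or self.L_DNA_bp < 0:
            raise ValueError("NRL_bp must be > 0 and L_DNA_bp >= 0")
        if self.stiffness_mode not in _STIFFNESS_MODES:
            raise ValueError(f"stiffness_mode must be one of {_STIFFNESS_MODES}")

    @property
    def N_unfold(self) -> int:
        return self.N_total - self.N_folded

    @property
    def fiber_stiffness(self) -> float:
        """Whole-folded-domain stiffness in pN/nm, whichever the mode."""
        if self.stiffness_mode == "fiber" or self.N_folded == 0:
            return self.k_fiber
        return self.k_fiber / self.N_folded  # springs in series

    def replace(self, **changes) -> "FiberParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class NucleosomeStateOccupancy:
    """Boltzmann occupancies of the three nucleosome states at one force."""

    p_stacked: float
    p_state1: float
    p_state2: float


def state_free_energy(state: str, params: FiberParams) -> float:
    """Zero-force free energy of a nucleosome state, kT, stacked = 0."""
    if state == "stacked":
        return 0.0
    if state == "state1":
        return params.dG1_kT
    if state == "state2":
        return params.dG1_kT + params.dG2_kT
    raise ValueError(f"unknown state {state!r}; choose from {_STATES}")


def _default_wlc(params: FiberParams) -> WLCParams:
    return WLCParams(contour_bp=params.L_DNA_bp)


def _state_weights(force, params: FiberParams, wlc: WLCParams):
    """Log Boltzmann weights of (stacked, state1, state2) for a folded-class
    nucleosome, vectorized over force."""
    f = np.atleast_1d(np.asarray(force, dtype=float))
    rel = np.zeros_like(f)
    pos = f > 0  # at F = 0 the F*dz term vanishes; rel is immaterial there
    if pos.any():
        rel[pos] = np.atleast_1d(
            wlc_relative_extension(
                f[pos], wlc.persistence_nm, wlc.stretch_pN, wlc.kBT_pN_nm,
                method="auto",
            )
        )
    # Extension gained relative to stacked (per nucleosome): released DNA as
    # WLC minus the per-nucleosome share of the folded-domain spring.
    hook = f / (params.fiber_stiffness * max(params.N_folded, 1)) \
        if params.N_folded > 0 else np.zeros_like(f)
    dz1 = (params.NRL_bp - params.wrap_state1_bp) * wlc.rise_nm_per_bp * rel - hook
    dz2 = (params.NRL_bp - params.wrap_state2_bp) * wlc.rise_nm_per_bp * rel - hook
    kBT = wlc.kBT_pN_nm
    log_w = np.stack(
        [
            np.zeros_like(f),
            -params.dG1_kT + f * dz1 / kBT,
            -(params.dG1_kT + params.dG2_kT) + f * dz2 / kBT,
        ]
    )
    return log_w


def _normalize(log_w):
    log_w = log_w - np.max(log_w, axis=0, keepdims=True)
    w = np.exp(log_w)
    return w / w.sum(axis=0, keepdims=True)


def state_probabilities(
    force, params: FiberParams, wlc: WLCParams | None = None
) -> NucleosomeStateOccupancy:
    """Occupancies of (stacked, state1, state2) for a folded-class nucleosome.

    ``p_i \\propto exp(-(G_i - F*dz_i(F)) / kBT)``; occupancies sum to one.
    Scalar force gives scalar probabilities; array force gives arrays.
    """
    if np.any(np.asarray(force) < 0):
        raise ValueError("force must be >= 0")
    wlc = wlc or _default_wlc(params)
    f = np.asarray(force, dtype=float)
    scalar = f.ndim == 0
    if np.all(f == 0):
        # Zero force: weights reduce to the bare state energies.
        g = np.array([0.0, -params.dG1_kT, -(params.dG1_kT + params.dG2_kT)])
        p = _normalize(g.reshape(3, 1))[:, 0]
        if scalar:
            return NucleosomeStateOccupancy(*map(float, p))
        shape = np.atleast_1d(f).shape
        return NucleosomeStateOccupancy(
            *(np.full(shape, pi) for pi in p)
        )
    p = _normalize(_state_weights(f, params, wlc))
    if scalar:
        return NucleosomeStateOccupancy(*(float(pi[0]) for pi in p))
    return NucleosomeStateOccupancy(*p)


def unfolded_state_probabilities(
    force, params: FiberParams, wlc: WLCParams | None = None
):
    """Occupancies (q1, q2) of the unfoldable nucleosomes.

    These nucleosomes have no stacked state: state 1 is their reference and
    only the second unwinding stage (dG2, 13 bp) remains thermally
    accessible.
    """
    wlc = wlc or _default_wlc(params)
    f = np.atleast_1d(np.asarray(force, dtype=float))
    scalar = np.ndim(force) == 0
    rel = np.zeros_like(f)
    pos = f > 0
    if pos.any():
        rel[pos] = np.atleast_1d(
            wlc_relative_extension(
                f[pos], wlc.persistence_nm, wlc.stretch_pN, wlc.kBT_pN_nm, "auto"
            )
        )
    dz12 = (params.wrap_state1_bp - params.wrap_state2_bp) * wlc.rise_nm_per_bp * rel
    log_w = np.stack([np.zeros_like(f), -params.dG2_kT + f * dz12 / wlc.kBT_pN_nm])
    q = _normalize(log_w)
    if scalar:
        return float(q[0][0]), float(q[1][0])
    return q[0], q[1]


def model_extension(force, params: FiberParams, wlc: WLCParams | None = None):
    """Predicted fiber extension (nm) at the given force(s).

    Extension = WLC extension of the released DNA + Hookean stretch of the
    still-folded domain.  The released DNA is the template minus what the
    nucleosomes sequester, with folded-class nucleosomes averaging over
    (stacked, state1, state2) occupancies and unfoldable nucleosomes over
    (state1, state2).  With ``N_total = 0`` this reduces exactly to the
    bare-DNA WLC.
    """
    wlc = wlc or _default_wlc(params)
    f = np.asarray(force, dtype=float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    if np.any(f <= 0):
        raise ValueError("force must be > 0")
    rel = np.atleast_1d(
        wlc_relative_extension(
            f, wlc.persistence_nm, wlc.stretch_pN, wlc.kBT_pN_nm, "auto"
        )
    )
    occ = state_probabilities(f, params, wlc)
    q1, q2 = unfolded_state_probabilities(f, params, wlc)
    sequestered_bp = params.N_folded * (
        occ.p_stacked * params.NRL_bp
        + occ.p_state1 * params.wrap_state1_bp
        + occ.p_state2 * params.wrap_state2_bp
    ) + params.N_unfold * (
        q1 * params.wrap_state1_bp + q2 * params.wrap_state2_bp
    )
    free_bp = params.L_DNA_bp - sequestered_bp
    ext = free_bp * wlc.rise_nm_per_bp * rel
    if params.N_folded > 0:
        ext = ext + occ.p_stacked * f / params.fiber_stiffness
    return float(ext[0]) if scalar else ext


def plateau_force(
    params: FiberParams,
    wlc: WLCParams | None = None,
    bracket: tuple = (0.1, 20.0),
) -> float:
    """Force (pN) at which the stacked-state occupancy crosses one half.

    Diagnostic for the unfolding plateau (2–5 pN for typical fibers).
    Returns ``nan`` when ``p_stacked - 1/2`` does not change sign inside
    ``bracket``.
    """
    wlc = wlc or _default_wlc(params)

    def h(f):
        return state_probabilities(float(f), params, wlc).p_stacked - 0.5

    lo, hi = bracket
    grid = np.geomspace(lo, hi, 128)
    vals = np.array([h(g) for g in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        return float("nan")
    i = sign_change[0]
    return float(brentq(h, grid[i], grid[i + 1], xtol=1e-6))
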