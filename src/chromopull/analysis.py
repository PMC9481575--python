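"""Per-trace inference: nucleosome counting, fiber-model fitting, cohorts.

The composition of a tether is quantified by two force-windowed WLC fits:

* **N_total** from the moderate-force window (8–15 pN), where every intact
  nucleosome still wraps the last 79 bp turn, so the apparent contour is
  ``L_DNA - 79 * N_total``;
* **N_folded** from the low-force window (0.5–2 pN), where the folded
  fiber sequesters one full NRL per stacked nucleosome, so the apparent
  contour is ``L_DNA - NRL * N_folded`` (optionally also subtracting the
  92 bp wrapped by each unfoldable nucleosome — on by default, since those
  nucleosomes do sequester their DNA at low force).

Both counts are obtained as continuous least-squares values and rounded to
the nearest integer.  Because the apparent contour is *linear* in the
count, each window sample yields a direct per-sample estimate; the median
of those estimates is the default (it is robust to the handful of samples
already past a last-turn release or a rupture), with plain least squares
as an alternative.  The N_total estimator additionally restricts itself to
the part of the window below the last-turn onset (10 pN), where the
79-bp-per-nucleosome reduction holds exactly.

With the counts fixed, ``k_fiber``, ``dG1`` and ``dG2`` are fitted by
least squares of the equilibrium fiber model against the 0.3–10 pN region,
with detected rupture segments masked (the model has no rupture term).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from . import ruptures as _ruptures
from .fiber import FiberParams, model_extension, plateau_force
from .io import Trace
from .wlc import InsufficientDataError, WLCParams, wlc_relative_extension

_ESTIMATORS = ("median", "lsq")


def _pending_loop_bp_per_sample(events, f: np.ndarray) -> np.ndarray:
    """DNA (bp) sequestered in still-closed loops at each sample force.

    For every sample, sums the measured sizes of kept rupture events whose
    rupture force lies above that sample's force: those loops are closed
    there and their DNA does not contribute to the extension.
    """
    kept = [(ev.rupture_force, ev.step_bp) for ev in events if ev.kept]
    if not kept:
        return np.zeros_like(f)
    kept.sort()
    forces = np.array([k[0] for k in kept])
    csum = np.concatenate([[0.0], np.cumsum([k[1] for k in kept])])
    idx = np.searchsorted(forces, f, side="right")
    return csum[-1] - csum[idx]


def _window_arrays(trace: Trace, window, min_points: int):
    lo, hi = window
    f = np.asarray(trace.force_pN, dtype=float)
    z = np.asarray(trace.extension_nm, dtype=float)
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < min_points:
        raise InsufficientDataError(
            f"only {int(mask.sum())} samples in force window {window}; "
            f"need >= {min_points}"
        )
    return f[mask], z[mask]


def count_total_nucleosomes(
    trace: Trace,
    wlc: WLCParams,
    window: Tuple[float, float] = (8.0, 15.0),
    wrap_bp: float = 79.0,
    estimator: str = "median",
    force_cap_pN: Optional[float] = 10.0,
    pending_loop_bp: float = 0.0,
    events: Optional[Sequence] = None,
    min_points: int = 10,
) -> int:
    """Count all nucleosomes on the tether from the moderate-force window.

    Fits the WLC with apparent contour ``L - wrap_bp * N`` to the 8–15 pN
    extension data; N is estimated continuously and rounded.  Samples above
    ``force_cap_pN`` (default 10 pN, the last-turn onset) are excluded when
    enough samples remain below it, because last-turn releases inside the
    window progressively hand back 79 bp per nucleosome and would bias the
    count down.  ``pending_loop_bp`` is DNA known to be sequestered in
    still-closed loops inside the window (summed sizes of rupture events
    detected above the window/cap), subtracted from the template before
    inversion.

    ``wlc`` supplies the template length and the fixed DNA elasticity.
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"estimator must be one of {_ESTIMATORS}")
    f, z = _window_arrays(trace, window, min_points)
    if force_cap_pN is not None:
        below = f <= force_cap_pN
        if below.sum() >= min_points:
            f, z = f[below], z[below]
    rel = wlc_relative_extension(
        f, wlc.persistence_nm, wlc.stretch_pN, wlc.kBT_pN_nm, method="auto"
    )
    pending = pending_loop_bp
    if events is not None:
        pending = pending + _pending_loop_bp_per_sample(events, f)
    a = wrap_bp * wlc.rise_nm_per_bp * rel          # nm lost per nucleosome
    z_bare = (wlc.contour_bp - pending) * wlc.rise_nm_per_bp * rel
    if estimator == "median":
        n = float(np.median((z_bare - z) / a))
    else:
        n = float(np.sum(a * (z_bare - z)) / np.sum(a * a))
    return max(int(round(n)), 0)


def count_folded_nucleosomes(
    trace: Trace,
    wlc: WLCParams,
    NRL_bp: float,
    N_total: int,
    window: Tuple[float, float] = (0.5, 2.0),
    wrap_state1_bp: float = 92.0,
    correct_unfolded: bool = True,
    estimator: str = "median",
    pending_loop_bp: float = 0.0,
    events: Optional[Sequence] = None,
    min_points: int = 10,
) -> int:
    """Count the nucleosomes folded into the fiber from the low-force window.

    The apparent contour at low force is ``L - NRL * N_folded`` and, with
    ``correct_unfolded`` (default), additionally ``- 92 * N_unfold`` for
    the DNA still wrapped by beads-on-a-string nucleosomes.
    ``pending_loop_bp`` (DNA sequestered in loops that rupture above the
    window, as measured by the detector) is likewise subtracted, since a
    closed loop would otherwise read as extra folded nucleosomes.  Returns
    the continuous least-squares count rounded and clipped to
    ``[0, N_total]``.
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"estimator must be one of {_ESTIMATORS}")
    f, z = _window_arrays(trace, window, min_points)
    rel = wlc_relative_extension(
        f, wlc.persistence_nm, wlc.stretch_pN, wlc.kBT_pN_nm, method="auto"
    )
    c = wrap_state1_bp if correct_unfolded else 0.0
    denom_bp = NRL_bp - c
    # apparent contour in bp from each sample, then linear inversion for N_f
    pending = pending_loop_bp
    if events is not None:
        pending = pending + _pending_loop_bp_per_sample(events, f)
    L_app = z / (wlc.rise_nm_per_bp * rel)
    n_f = (wlc.contour_bp - pending - c * N_total - L_app) / denom_bp
    if estimator == "median":
        n = float(np.median(n_f))
    else:
        n = float(np.mean(n_f))
    return int(np.clip(round(n), 0, N_total))


def folded_fraction(N_folded: int, N_total: int) -> int:
    """Percent of nucleosomes folded into the fiber, nearest integer.

    49 of 125 -> 39 %, 68 of 198 -> 34 %.
    """
    if N_total <= 0:
        raise ValueError("undefined folded fraction: N_total must be > 0")
    if not (0 <= N_folded <= N_total):
        raise ValueError("need 0 <= N_folded <= N_total")
    return int(round(100.0 * N_folded / N_total))


@dataclass(frozen=True)
class TraceFitResult:
    """Fitted composition and mechanics of one tether."""

    N_total: int
    N_folded: int
    k_fiber: float
    dG1_kT: float
    dG2_kT: float
    contour_bp_fitted: float
    residual_rms_nm: float
    flags: frozenset = frozenset()
    stderr: Mapping[str, float] = field(default_factory=dict)

    @property
    def success(self) -> bool:
        return not ({"degenerate", "non_convergent"} & self.flags)


def _initial_guesses(
    trace: Trace, wlc: WLCParams, base: FiberParams, dG2_init: float
) -> Tuple[float, float, float]:
    """Deterministic initialization replacing manual parameter pre-setting.

    k_fiber from the sub-plateau response (extension excess over the
    free-DNA WLC at ~0.7 pN is attributed to the Hookean fiber); dG1 from
    the plateau-force x plateau-step-size product of the initialized model;
    dG2 at its literature-typical value.
    """
    f = np.asarray(trace.force_pN, dtype=float)
    z = np.asarray(trace.extension_nm, dtype=float)
    sub = (f >= 0.5) & (f <= 1.0)
    k_init = 0.3
    if sub.sum() >= 5:
        f0 = float(np.median(f[sub]))
        rel = wlc_relative_extension(
            f0, wlc.persistence_nm, wlc.stretch_pN, wlc.kBT_pN_nm, "auto"
        )
        free_bp = (
            base.L_DNA_bp
            - base.N_folded * base.NRL_bp
            - base.N_unfold * base.wrap_state1_bp
        )
        excess = float(np.median(z[sub])) - free_bp * wlc.rise_nm_per_bp * rel
        if excess > 0.5:
            k_init = float(np.clip(f0 / excess, 0.02, 2.0))
    # plateau force of the model initialized with k_init and a mid-range dG1
    trial = base.replace(k_fiber=k_init, dG1_kT=18.0, dG2_kT=dG2_init)
    fp = plateau_force(trial, wlc)
    if not np.isfinite(fp):
        fp = 3.0
    rel_p = wlc_relative_extension(
        fp, wlc.persistence_nm, wlc.stretch_pN, wlc.kBT_pN_nm, "auto"
    )
    dz1 = (base.NRL_bp - base.wrap_state1_bp) * wlc.rise_nm_per_bp * rel_p
    dG1_init = float(np.clip(fp * dz1 / wlc.kBT_pN_nm, 2.0, 50.0))
    return k_init, dG1_init, dG2_init


def fit_fiber_params(
    trace: Trace,
    N_total: int,
    N_folded: int,
    wlc: WLCParams,
    NRL_bp: float = 197.0,
    init: Optional[FiberParams] = None,
    fit_window: Tuple[float, float] = (0.3, 10.0),
    rupture_handling: str = "mask",
    mask_pad: int = 5,
    dG2_init: float = 4.5,
    min_points: int = 20,
    events: Optional[Sequence] = None,
) -> TraceFitResult:
    """Least-squares fit of (k_fiber, dG1, dG2) with the counts held fixed.

    Rupture events found by the detector are handled per
    ``rupture_handling``: ``"mask"`` drops the samples of each event
    (padded by ``mask_pad``) from the residuals, ``"stitch"`` additionally
    subtracts the released contour from all later samples (removing the
    post-event offset), ``"none"`` fits the raw trace.  A masked fraction
    above 50 % sets the ``low_confidence`` flag; a bare-DNA tether
    (``N_total == 0``) returns a degenerate result with no estimates.
    """
    if rupture_handling not in ("mask", "stitch", "none"):
        raise ValueError("rupture_handling must be 'mask', 'stitch' or 'none'")
    if N_total == 0:
        return TraceFitResult(
            N_total=0, N_folded=0, k_fiber=float("nan"), dG1_kT=float("nan"),
            dG2_kT=float("nan"), contour_bp_fitted=float(wlc.contour_bp),
            residual_rms_nm=float("nan"), flags=frozenset({"degenerate"}),
        )
    f_all = np.asarray(trace.force_pN, dtype=float)
    z_all = np.asarray(trace.extension_nm, dtype=float).copy()
    keep = np.ones(f_all.size, dtype=bool)
    flags = set()
    if rupture_handling != "none":
        if events is None:
            events = _ruptures.analyze_trace_ruptures(trace, wlc)
        for ev in events:
            if not ev.kept:
                continue
            lo = max(ev.sample_index - mask_pad, 0)
            hi = min(ev.end_index + mask_pad, f_all.size)
            keep[lo:hi] = False
            if rupture_handling == "stitch" and lo > 0:
                # before the rupture the released DNA was sequestered; add
                # its would-be WLC extension back so the whole trace matches
                # the loop-free model
                rel_ev = wlc_relative_extension(
                    f_all[:lo], wlc.persistence_nm, wlc.stretch_pN,
                    wlc.kBT_pN_nm, "auto",
                )
                z_all[:lo] += ev.step_bp * wlc.rise_nm_per_bp * rel_ev

    lo_w, hi_w = fit_window
    window = (f_all >= lo_w) & (f_all <= hi_w)
    masked_fraction = 1.0 - keep[window].sum() / max(window.sum(), 1)
    if masked_fraction > 0.5:
        flags.add("low_confidence")
    sel = window & keep
    if sel.sum() < min_points:
        raise InsufficientDataError(
            f"only {int(sel.sum())} unmasked samples in fit window {fit_window}"
        )
    f, z = f_all[sel], z_all[sel]

    base = FiberParams(
        k_fiber=0.3, dG1_kT=18.0, dG2_kT=dG2_init, N_total=N_total,
        N_folded=N_folded, NRL_bp=NRL_bp, L_DNA_bp=wlc.contour_bp,
    )
    if init is None:
        k0, g1_0, g2_0 = _initial_guesses(trace, wlc, base, dG2_init)
    else:
        k0, g1_0, g2_0 = init.k_fiber, init.dG1_kT, init.dG2_kT

    p = lmfit.Parameters()
    p.add("k_fiber", value=k0, min=0.01, max=5.0)
    p.add("dG1_kT", value=g1_0, min=0.5, max=60.0)
    p.add("dG2_kT", value=g2_0, min=0.1, max=30.0)

    def residual(pars):
        trial = base.replace(
            k_fiber=pars["k_fiber"].value,
            dG1_kT=pars["dG1_kT"].value,
            dG2_kT=pars["dG2_kT"].value,
        )
        return model_extension(f, trial, wlc) - z

    result = lmfit.minimize(residual, p, method="leastsq")
    if not result.success:
        flags.add("non_convergent")
    stderr = {
        name: float(result.params[name].stderr)
        for name in ("k_fiber", "dG1_kT", "dG2_kT")
        if result.params[name].stderr is not None
    }
    return TraceFitResult(
        N_total=N_total,
        N_folded=N_folded,
        k_fiber=float(result.params["k_fiber"].value),
        dG1_kT=float(result.params["dG1_kT"].value),
        dG2_kT=float(result.params["dG2_kT"].value),
        contour_bp_fitted=float(wlc.contour_bp),
        residual_rms_nm=float(np.sqrt(np.mean(result.residual**2))),
        flags=frozenset(flags),
        stderr=stderr,
    )


def pending_loop_bp(events, above_pN: float) -> float:
    """DNA (bp) sequestered in loops that rupture above ``above_pN``.

    Summed measured sizes of kept rupture events with rupture force beyond
    the given force: inside any window below that force these loops are
    still closed and their DNA does not extend.
    """
    if not events:
        return 0.0
    return float(
        sum(ev.step_bp for ev in events if ev.kept and ev.rupture_force > above_pN)
    )


def analyze_trace(
    trace: Trace,
    wlc: WLCParams,
    NRL_bp: float = 197.0,
    count_window: Tuple[float, float] = (8.0, 15.0),
    count_force_cap_pN: Optional[float] = 10.0,
    folded_window: Tuple[float, float] = (0.5, 2.0),
    estimator: str = "median",
    correct_unfolded: bool = True,
    wrap_bp: float = 79.0,
    wrap_state1_bp: float = 92.0,
    detector_kwargs: Optional[dict] = None,
    **fit_kwargs,
) -> TraceFitResult:
    """Full per-trace pipeline: detect ruptures, count, fit the model.

    Rupture events are detected once and reused: loops still closed inside
    a counting window (rupture force above it) are subtracted as
    sequestered DNA, and the same events drive the rupture handling of the
    model fit.
    """
    events = _ruptures.analyze_trace_ruptures(trace, wlc, **(detector_kwargs or {}))
    n_tot = count_total_nucleosomes(
        trace, wlc, window=count_window, wrap_bp=wrap_bp, estimator=estimator,
        force_cap_pN=count_force_cap_pN, events=events,
    )
    n_fol = count_folded_nucleosomes(
        trace, wlc, NRL_bp, n_tot, window=folded_window,
        wrap_state1_bp=wrap_state1_bp, correct_unfolded=correct_unfolded,
        estimator=estimator, events=events,
    )
    return fit_fiber_params(
        trace, n_tot, n_fol, wlc, NRL_bp, events=events, **fit_kwargs
    )


_DEFAULT_PARAMS = ("N_total", "N_folded", "k_fiber", "dG1_kT", "dG2_kT")
_TESTS = ("welch", "mannwhitney")


@dataclass(frozen=True)
class CohortSummary:
    """Per-group summary statistics and pairwise group comparisons.

    ``stats`` has one row per (group, parameter): n, mean, sd (ddof=1),
    5th and 95th percentiles (linear interpolation) and the count of
    outliers beyond the whiskers.  ``pairwise`` holds two-sided p-values
    for every group pair and parameter.
    """

    stats: pd.DataFrame
    pairwise: pd.DataFrame
    outliers: Mapping[tuple, list]


def summarize_cohort(
    results: Sequence[TraceFitResult],
    groups: Sequence[str],
    parameters: Iterable[str] = _DEFAULT_PARAMS,
    test: str = "welch",
) -> CohortSummary:
    """Aggregate per-trace fit results into box-plot-style group statistics.

    Each group's spread is reported as mean ± sd with 5–95 % whiskers
    (values beyond the whiskers are listed as outliers), and groups are
    compared pairwise with a two-sided Welch t-test (or Mann–Whitney U).
    """
    if test not in _TESTS:
        raise ValueError(f"test must be one of {_TESTS}")
    if len(results) != len(groups):
        raise ValueError("results and groups must align")
    if len(results) == 0:
        raise ValueError("empty cohort")
    parameters = tuple(parameters)
    df = pd.DataFrame(
        [{p: getattr(r, p) for p in parameters} for r in results]
    )
    df["group"] = list(groups)

    rows = []
    outliers: dict = {}
    for g, sub in df.groupby("group", sort=True):
        if len(sub) < 1:
            raise ValueError(f"empty group {g!r}")
        for p in parameters:
            vals = sub[p].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(f"group {g!r} has no finite values for {p!r}")
            p5, p95 = np.percentile(vals, [5, 95], method="linear")
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            out = vals[(vals < p5) | (vals > p95)]
            rows.append(
                {
                    "group": g, "parameter": p, "n": int(vals.size),
                    "mean": float(np.mean(vals)), "sd": sd,
                    "p5": float(p5), "p95": float(p95),
                    "n_outliers": int(out.size),
                }
            )
            outliers[(g, p)] = [float(v) for v in out]

    pair_rows = []
    group_names = sorted(df["group"].unique())
    for g1, g2 in combinations(group_names, 2):
        for p in parameters:
            a = df.loc[df["group"] == g1, p].to_numpy(dtype=float)
            b = df.loc[df["group"] == g2, p].to_numpy(dtype=float)
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if a.size < 2 or b.size < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0
                                            and a[0] == b[0]):
                pval = float("nan") if (a.size < 2 or b.size < 2) else 1.0
            elif test == "welch":
                pval = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            else:
                pval = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            pair_rows.append(
                {"group_a": g1, "group_b": g2, "parameter": p, "p_value": pval}
            )
    return CohortSummary(
        stats=pd.DataFrame(rows),
        pairwise=pd.DataFrame(
            pair_rows, columns=["group_a", "group_b", "parameter", "p_value"]
        ),
        outliers=outliers,
    )


def results_to_frame(
    results: Sequence[TraceFitResult], trace_ids: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """One row per tether, mirroring the supplementary-table layout."""
    rows = []
    for i, r in enumerate(results):
        rows.append(
            {
                "trace_id": trace_ids[i] if trace_ids is not None else str(i),
                "N_total": r.N_total,
                "N_folded": r.N_folded,
                "folded_pct": folded_fraction(r.N_folded, r.N_total)
                if r.N_total > 0 else np.nan,
                "k_fiber": r.k_fiber,
                "dG1_kT": r.dG1_kT,
                "dG2_kT": r.dG2_kT,
                "residual_rms_nm": r.residual_rms_nm,
                "flags": ";".join(sorted(r.flags)),
            }
        )
    return pd.DataFrame(rows)
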