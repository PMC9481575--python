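"""Seeded generator of synthetic chromatin fibers and stretching traces.

No public trace dataset accompanies the measurements this pipeline targets,
so the generator produces tethers with the statistical structure the
analysis assumes, giving every stage a known ground truth:

* templates of 10–200 nucleosomes on up-to-lambda-length DNA, placed either
  in clutches of 3–10 nucleosomes separated by 100–300 bp nucleosome-free
  regions (the in-vivo-like clustered mode) or uniformly at random;
* equilibrium unfolding following the fiber statistical-mechanics model
  (low-force Hookean fiber, 2–5 pN unstacking plateau, gradual second
  unwinding stage);
* discrete last-turn release events, 79 bp (25–27 nm) per nucleosome, at
  per-nucleosome forces drawn from a truncated normal above 10 pN;
* embedded chromatin-loop ruptures (default sizes concentrated at a few
  hundred bp with a long tail to 10 kbp, forces spread over 1–15 pN);
* Gaussian extension noise and a Brownian bead XY track with optional
  injected unsticking jumps.

Every random choice derives from one seed; the per-trace truth record is
embedded in ``Trace.metadata["truth"]`` and aggregated into a JSON-ready
manifest by :func:`generate_cohort`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .fiber import FiberParams, model_extension
from .io import Trace
from .wlc import LAMBDA_DNA_BP, WLCParams

#: Nucleosome core-particle footprint on DNA, bp.
NUCLEOSOME_FOOTPRINT_BP = 147


@dataclass(frozen=True)
class ForceRamp:
    """Stretching protocol: a sampled force ramp.

    Defaults: logarithmic ramp 0.3 -> 40 pN over 40 s at 60 samples/s,
    covering the Hookean fiber regime, the unstacking plateau, the second
    unwinding stage and the last-turn release band.
    """

    f_min_pN: float = 0.3
    f_max_pN: float = 40.0
    duration_s: float = 40.0
    rate_hz: float = 60.0
    kind: str = "log"

    def __post_init__(self) -> None:
        if not (0 < self.f_min_pN < self.f_max_pN):
            raise ValueError("need 0 < f_min_pN < f_max_pN")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration_s and rate_hz must be > 0")
        if self.kind not in ("log", "linear"):
            raise ValueError("kind must be 'log' or 'linear'")

    @property
    def n_samples(self) -> int:
        return max(int(round(self.duration_s * self.rate_hz)), 2)

    def sample(self) -> Tuple[np.ndarray, np.ndarray]:
        n = self.n_samples
        t = np.arange(n) / self.rate_hz
        if self.kind == "log":
            f = np.geomspace(self.f_min_pN, self.f_max_pN, n)
        else:
            f = np.linspace(self.f_min_pN, self.f_max_pN, n)
        return t, f


@dataclass(frozen=True)
class FiberSpec:
    """Ground-truth description of one synthetic chromatin tether.

    ``loops`` is a tuple of ``(separation_bp, rupture_force_pN)`` pairs:
    each loop sequesters ``separation_bp`` of DNA until the ramp first
    exceeds its rupture force.  ``n_folded`` defaults to
    ``round(folded_fraction * n_octamers)``.  Last-turn rupture forces are
    drawn per nucleosome from Normal(``last_turn_mean_pN``,
    ``last_turn_sd_pN``) truncated below at ``last_turn_min_pN``.
    """

    n_octamers: int
    L_DNA_bp: int = LAMBDA_DNA_BP
    NRL_bp: float = 197.0
    placement_mode: str = "clustered"
    cluster_size_range: Tuple[int, int] = (3, 10)
    nfr_range_bp: Tuple[float, float] = (100.0, 300.0)
    loops: Tuple[Tuple[float, float], ...] = ()
    n_folded: Optional[int] = None
    folded_fraction: float = 0.39
    k_fiber: float = 0.25
    dG1_kT: float = 20.0
    dG2_kT: float = 4.5
    persistence_nm: float = 50.0
    stretch_pN: float = 1500.0
    last_turn_mean_pN: float = 20.0
    last_turn_sd_pN: float = 5.0
    last_turn_min_pN: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_octamers < 0:
            raise ValueError("n_octamers must be >= 0")
        if self.n_octamers * NUCLEOSOME_FOOTPRINT_BP > self.L_DNA_bp:
            raise ValueError("infeasible packing: nucleosome footprints exceed template")
        loop_bp = sum(sep for sep, _ in self.loops)
        for sep, f in self.loops:
            if sep <= 0 or sep > self.L_DNA_bp:
                raise ValueError(f"loop separation {sep} bp outside (0, L_DNA]")
            if f <= 0:
                raise ValueError("loop rupture force must be > 0")
        if loop_bp + self.n_octamers * NUCLEOSOME_FOOTPRINT_BP > self.L_DNA_bp:
            raise ValueError("loops plus nucleosome footprints exceed template")
        if self.placement_mode not in ("clustered", "uniform"):
            raise ValueError("placement_mode must be 'clustered' or 'uniform'")
        if not (0.0 <= self.folded_fraction <= 1.0):
            raise ValueError("folded_fraction must lie in [0, 1]")
        nf = self.resolved_n_folded
        if not (0 <= nf <= self.n_octamers):
            raise ValueError("n_folded must lie in [0, n_octamers]")

    @property
    def resolved_n_folded(self) -> int:
        if self.n_folded is not None:
            return self.n_folded
        return int(round(self.folded_fraction * self.n_octamers))

    def wlc_params(self) -> WLCParams:
        return WLCParams(
            contour_bp=self.L_DNA_bp,
            persistence_nm=self.persistence_nm,
            stretch_pN=self.stretch_pN,
        )

    def fiber_params(self) -> FiberParams:
        return FiberParams(
            k_fiber=self.k_fiber,
            dG1_kT=self.dG1_kT,
            dG2_kT=self.dG2_kT,
            N_total=self.n_octamers,
            N_folded=self.resolved_n_folded,
            NRL_bp=self.NRL_bp,
            L_DNA_bp=self.L_DNA_bp,
        )

    def replace(self, **changes) -> "FiberSpec":
        return dataclasses.replace(self, **changes)


def ho_dna_ratio(n_octamers: int, L_DNA_bp: float, bp_per_octamer: float = 197.0) -> float:
    """Histone-octamer loading relative to saturation at one octamer per 197 bp."""
    if L_DNA_bp <= 0:
        raise ValueError(f"L_DNA_bp must be > 0, got {L_DNA_bp}")
    return n_octamers / (L_DNA_bp / bp_per_octamer)


def place_nucleosomes(spec: FiberSpec, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw sorted nucleosome start positions (bp) on the template.

    Clustered mode groups nucleosomes into clutches whose sizes are drawn
    uniformly from ``cluster_size_range`` (a final remainder clutch may be
    smaller), spaced internally at one NRL, with inter-clutch gaps drawn
    from ``nfr_range_bp`` and rescaled down if the layout overruns the
    template.  Uniform mode distributes non-overlapping footprints uniformly
    at random.  Deterministic under the supplied generator (or the spec
    seed).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n, L = spec.n_octamers, spec.L_DNA_bp
    if n == 0:
        return np.empty(0, dtype=float)
    if spec.placement_mode == "uniform":
        free = L - n * NUCLEOSOME_FOOTPRINT_BP
        cuts = np.sort(rng.uniform(0.0, free, n))
        return cuts + NUCLEOSOME_FOOTPRINT_BP * np.arange(n)

    lo, hi = spec.cluster_size_range
    sizes: List[int] = []
    remaining = n
    while remaining > 0:
        s = int(rng.integers(lo, hi + 1))
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    gaps = rng.uniform(spec.nfr_range_bp[0], spec.nfr_range_bp[1], len(sizes))
    spans = [(s - 1) * spec.NRL_bp + NUCLEOSOME_FOOTPRINT_BP for s in sizes]
    overshoot = gaps.sum() + sum(spans) - L
    if overshoot > 0:
        scale = (L - sum(spans)) / gaps.sum()
        if scale <= 0:
            raise ValueError("infeasible packing: clutch spans exceed template")
        gaps = gaps * scale * (1 - 1e-9)
    positions = []
    cursor = 0.0
    for gap, s in zip(gaps, sizes):
        cursor += gap
        for _ in range(s):
            positions.append(cursor)
            cursor += spec.NRL_bp
        cursor += NUCLEOSOME_FOOTPRINT_BP - spec.NRL_bp  # clutch end after last core
    positions = np.asarray(positions)
    if positions[-1] + NUCLEOSOME_FOOTPRINT_BP > L:
        raise ValueError("infeasible packing: layout overruns template")
    return positions


def _truncated_normal(rng, mean, sd, lower, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size - filled)
        good = draw[draw > lower]
        out[filled:filled + good.size] = good
        filled += good.size
    return out


def generate_trace(
    spec: FiberSpec,
    protocol: Optional[ForceRamp] = None,
    noise_nm: float = 10.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    xy_noise_um: float = 0.02,
    unsticking_jumps: Sequence[Tuple[int, float, float, float]] = (),
    trace_id: str = "sim-0",
) -> Trace:
    """Simulate one stretching trace for the given fiber.

    The noise-free extension is the equilibrium model prediction with two
    kinds of discrete events superimposed: each loop releases its
    sequestered DNA when the ramp first exceeds its rupture force, and each
    nucleosome's last turn releases its final 79 bp at its drawn rupture
    force (removing it from the equilibrium bookkeeping).  Gaussian noise
    of ``noise_nm`` is then added to the extension and a white Brownian XY
    track of ``xy_noise_um`` is attached.  ``unsticking_jumps`` entries
    ``(index, step_nm, dx_um, dy_um)`` add persistent offsets from
    ``index`` on, emulating a bead tearing off the surface.

    The full ground truth (placement, loop table, last-turn forces, model
    parameters, seed) is embedded in ``metadata["truth"]``.
    """
    protocol = protocol or ForceRamp()
    if rng is None:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
    t, f = protocol.sample()
    n = f.size

    positions = place_nucleosomes(spec, rng)
    lt_forces = np.sort(
        _truncated_normal(
            rng, spec.last_turn_mean_pN, spec.last_turn_sd_pN,
            spec.last_turn_min_pN, spec.n_octamers,
        )
    )
    loops = sorted(spec.loops, key=lambda lp: lp[1])
    wlc = spec.wlc_params()
    base = spec.fiber_params()
    N_unfold0 = base.N_total - base.N_folded

    # Piecewise-constant event state along the monotone ramp: segment
    # boundaries wherever a last turn fires or a loop ruptures.
    thresholds = np.unique(
        np.concatenate([lt_forces, np.array([lp[1] for lp in loops], dtype=float)])
    )
    edges = np.concatenate([[-np.inf], thresholds, [np.inf]])
    ext = np.empty(n)
    loop_forces = np.array([lp[1] for lp in loops], dtype=float)
    loop_seps = np.array([lp[0] for lp in loops], dtype=float)
    for a, b in zip(edges[:-1], edges[1:]):
        seg = (f > a) & (f <= b) if np.isfinite(b) else (f > a)
        if not seg.any():
            continue
        f_ref = f[seg][0]
        fired = int(np.sum(lt_forces < f_ref))  # a last turn fires once F exceeds its threshold
        sequestered = float(loop_seps[loop_forces >= f_ref].sum())
        N_tot = base.N_total - fired
        N_unf = max(N_unfold0 - fired, 0)
        N_fol = N_tot - N_unf
        # Per-nucleosome compliance of the folded domain is a property of
        # the initial fiber; as last turns fire out of the folded class the
        # remaining domain stiffens as springs in series, k -> k*N0/N.
        k_seg = base.k_fiber
        if 0 < N_fol < base.N_folded:
            k_seg = base.k_fiber * base.N_folded / N_fol
        params = base.replace(
            N_total=N_tot, N_folded=N_fol, k_fiber=k_seg,
            L_DNA_bp=base.L_DNA_bp - sequestered,
        )
        ext[seg] = model_extension(f[seg], params, wlc)

    if noise_nm > 0:
        ext = ext + rng.normal(0.0, noise_nm, n)
    x = rng.normal(0.0, xy_noise_um, n)
    y = rng.normal(0.0, xy_noise_um, n)
    for idx, step_nm, dx, dy in unsticking_jumps:
        ext[idx:] += step_nm
        x[idx:] += dx
        y[idx:] += dy

    truth = {
        "n_total": int(spec.n_octamers),
        "n_folded": int(base.N_folded),
        "k_fiber": float(spec.k_fiber),
        "dG1_kT": float(spec.dG1_kT),
        "dG2_kT": float(spec.dG2_kT),
        "NRL_bp": float(spec.NRL_bp),
        "L_DNA_bp": int(spec.L_DNA_bp),
        "persistence_nm": float(spec.persistence_nm),
        "stretch_pN": float(spec.stretch_pN),
        "positions_bp": [round(float(p), 3) for p in positions],
        "loops": [[float(s), float(fr)] for s, fr in loops],
        "last_turn_forces_pN": [round(float(v), 4) for v in lt_forces],
        "noise_nm": float(noise_nm),
        "seed": int(spec.seed if seed is None else seed),
    }
    meta = {
        "trace_id": trace_id,
        "template_bp": int(spec.L_DNA_bp),
        "nrl_bp": int(round(spec.NRL_bp)),
        "ho_dna_ratio": round(ho_dna_ratio(spec.n_octamers, spec.L_DNA_bp), 4),
        "truth": truth,
    }
    return Trace(time_s=t, force_pN=f, extension_nm=ext, x_um=x, y_um=y, metadata=meta)


def draw_loop_sizes(
    rng: np.random.Generator,
    n: int,
    median_bp: float = 400.0,
    sigma: float = 0.8,
    min_bp: float = 250.0,
    max_bp: float = 10_000.0,
) -> np.ndarray:
    """Loop (cluster-cluster separation) sizes: lognormal body concentrated
    at a few hundred bp with a long tail, clipped to the detectable range."""
    return np.clip(rng.lognormal(np.log(median_bp), sigma, n), min_bp, max_bp)


def generate_cohort(
    n_traces: int,
    spec: FiberSpec,
    seed: int = 0,
    protocol: Optional[ForceRamp] = None,
    noise_nm: float = 10.0,
    loop_rate_low_per_10kbp: Optional[float] = None,
    loop_rate_high_per_10kbp: float = 0.0,
    loop_size_sampler: Callable[[np.random.Generator, int], np.ndarray] = draw_loop_sizes,
    trace_id_prefix: str = "sim",
) -> Tuple[List[Trace], List[dict]]:
    """Generate an independent seeded cohort plus its truth manifest.

    When ``loop_rate_low_per_10kbp`` is given, each trace receives a
    Poisson number of low-force loops (rupture forces uniform on [1, 8) pN)
    at that expected density per 10 kbp of template, plus optionally
    high-force loops (uniform on [8, 15] pN); otherwise ``spec.loops`` is
    used verbatim for every trace.  All randomness descends from ``seed``
    via spawned child streams, so the same seed reproduces the cohort
    byte-for-byte.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_traces)
    traces: List[Trace] = []
    manifest: List[dict] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        spec_i = spec
        if loop_rate_low_per_10kbp is not None:
            n_low = rng.poisson(loop_rate_low_per_10kbp * spec.L_DNA_bp / 10_000.0)
            n_high = rng.poisson(loop_rate_high_per_10kbp * spec.L_DNA_bp / 10_000.0)
            sizes = loop_size_sampler(rng, n_low + n_high)
            f_low = rng.uniform(1.0, 8.0, n_low)
            f_high = rng.uniform(8.0, 15.0, n_high)
            forces = np.concatenate([f_low, f_high])
            loops = tuple(
                (float(s), float(fr)) for s, fr in zip(sizes, forces)
            )
            spec_i = spec.replace(loops=loops)
        trace_id = f"{trace_id_prefix}-{i:04d}"
        tr = generate_trace(
            spec_i, protocol=protocol, noise_nm=noise_nm, rng=rng,
            trace_id=trace_id,
        )
        tr.metadata["truth"]["seed"] = int(seed)
        traces.append(tr)
        entry = {"trace_id": trace_id, **tr.metadata["truth"]}
        manifest.append(entry)
    return traces, manifest
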